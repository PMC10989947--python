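"""Codon translation helpers shared by the aligner, ORF caller and simulator.

Translation uses the standard genetic code. Any codon containing a
non-ACGT character (N masks, in particular) translates to ``X`` so that
masked bases contribute neither matches nor mismatches downstream.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, stops mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = tuple(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def translate_codon(codon: str) -> str:
    """Translate a single codon; anything with N (or other junk) gives X."""
    return CODON_TO_AA.get(codon, "X")


def translate_frame(seq: str, frame: int) -> str:
    """Translate one forward frame of ``seq`` (frame in {0,1,2})."""
    end = frame + 3 * ((len(seq) - frame) // 3)
    return "".join(
        CODON_TO_AA.get(seq[i : i + 3], "X") for i in range(frame, end, 3)
    )


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
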