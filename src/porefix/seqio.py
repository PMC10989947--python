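"""Readers/writers for FASTA, FASTQ (Phred+33), a SAM subset and TSV tables.

In-memory coordinates are 0-based, half-open everywhere; conversion to and
from 1-based conventions happens only at format boundaries (SAM).

Normalisation on load: lowercase bases are uppercased; characters outside
{A,C,G,T,N} (IUPAC ambiguity codes etc.) are converted to N with a warning.
Only Phred+33 quality encoding is supported.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, ParseError, UnsupportedFeatureError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
MAX_PHRED = 93

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass
class NanoporeRead:
    """A long read with one Phred quality per base."""

    read_id: str
    sequence: str
    qualities: list[int]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ParseError(f"read {self.read_id!r}: illegal bases {sorted(bad)}")
        if self.qualities and not all(0 <= q <= MAX_PHRED for q in self.qualities):
            raise ParseError(f"read {self.read_id!r}: quality outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """A reference protein with an optional KO label.

    FASTA headers of the form ``>prot_id ko=K00001 taxon=Foo`` round-trip the
    KO and taxon annotations; a separate two-column TSV map may also supply them.
    """

    protein_id: str
    aa_sequence: str
    ko_id: str | None = None
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ParseError(f"protein {self.protein_id!r}: empty sequence")
        if "*" in self.aa_sequence:
            raise ParseError(f"protein {self.protein_id!r}: contains stop symbol")


@dataclass
class ShortReadAlignment:
    """One short read placed on a long read (clips already trimmed)."""

    query_id: str
    target_read_id: str
    target_start: int  # 0-based
    cigar_ops: list[tuple[str, int]]  # ops from {M, I, D}
    query_bases: str
    query_quals: list[int] = field(default_factory=list)

    def query_span(self) -> int:
        return sum(n for op, n in self.cigar_ops if op in "MI")

    def target_span(self) -> int:
        return sum(n for op, n in self.cigar_ops if op in "MD")

    def __post_init__(self) -> None:
        if self.query_span() != len(self.query_bases):
            raise ParseError(
                f"alignment {self.query_id!r}: CIGAR query span "
                f"{self.query_span()} != {len(self.query_bases)} bases"
            )


def _normalize_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    if _NON_ACGTN.search(seq):
        warnings.warn(
            f"record {name!r}: non-ACGTN characters converted to N", stacklevel=3
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def load_sequences(
    path: str | Path, format: Literal["fasta", "fastq"]
) -> list[NanoporeRead] | list:
    """Load FASTA or FASTQ records, preserving order and identifiers.

    FASTQ yields :class:`NanoporeRead` with decoded Phred+33 qualities;
    FASTA yields NanoporeRead with all-zero qualities (no quality on disk).
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise InputError(f"unknown format {format!r}")
    records: list[NanoporeRead] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            seq = _normalize_sequence(str(rec.seq), rec.id)
            if format == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            else:
                quals = [0] * len(seq)
            desc = rec.description[len(rec.id) :].strip() if rec.description else ""
            records.append(NanoporeRead(rec.id, seq, quals, description=desc))
    except ValueError as exc:  # Biopython's malformed-record errors
        raise ParseError(f"{path}: {exc}") from exc
    return records


def load_proteins(path: str | Path, ko_map: str | Path | None = None) -> list[ProteinRecord]:
    """Load a protein FASTA; KO labels from ``ko=`` header keys or a TSV map."""
    mapping: dict[str, str] = {}
    if ko_map is not None:
        with open(ko_map) as fh:
            header = fh.readline()  # header row required
            if "\t" not in header:
                raise ParseError(f"{ko_map}: expected tab-separated header row")
            for line in fh:
                if line.strip():
                    pid, ko = line.rstrip("\n").split("\t")[:2]
                    mapping[pid] = ko
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                aa_sequence=str(rec.seq).upper(),
                ko_id=mapping.get(rec.id, fields.get("ko")),
                taxon_label=fields.get("taxon"),
            )
        )
    return records


def store_sequences(
    records: Sequence,
    path: str | Path,
    format: Literal["fasta", "fastq"],
) -> None:
    """Write records; ``load(store(x)) == x`` for records satisfying the type invariants.

    NanoporeRead descriptions (e.g. ``edits=3`` after correction) are kept in
    the header line. Protein records write their KO/taxon as ``key=value``.
    """
    out: list[SeqRecord] = []
    for r in records:
        if isinstance(r, ProteinRecord):
            desc = " ".join(
                f"{k}={v}"
                for k, v in (("ko", r.ko_id), ("taxon", r.taxon_label))
                if v is not None
            )
            out.append(SeqRecord(Seq(r.aa_sequence), id=r.protein_id, description=desc))
            continue
        rec = SeqRecord(
            Seq(r.sequence.upper()), id=r.read_id, description=r.description
        )
        if format == "fastq":
            rec.letter_annotations["phred_quality"] = list(r.qualities)
        out.append(rec)
    SeqIO.write(out, str(path), format)


_SUPPORTED_CIGAR = {0: "M", 1: "I", 2: "D", 4: "S", 5: "H"}


def read_sam_subset(path: str | Path) -> list[ShortReadAlignment]:
    """Read short-read-to-long-read placements from a SAM file.

    Only M/I/D/S/H CIGAR operations are supported; soft/hard clips are
    trimmed off the reported query bases. Unmapped records are skipped
    (count logged). Positions convert from SAM's 1-based to 0-based.
    """
    alignments: list[ShortReadAlignment] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            ops: list[tuple[str, int]] = []
            for code, length in rec.cigartuples or []:
                op = _SUPPORTED_CIGAR.get(code)
                if op is None:
                    raise UnsupportedFeatureError(
                        f"record {rec.query_name!r}: unsupported CIGAR op code {code}"
                    )
                if op in "MID":
                    ops.append((op, length))
            quals = rec.query_alignment_qualities
            alignments.append(
                ShortReadAlignment(
                    query_id=rec.query_name,
                    target_read_id=rec.reference_name,
                    target_start=rec.reference_start,
                    cigar_ops=ops,
                    query_bases=(rec.query_alignment_sequence or "").upper(),
                    query_quals=list(quals) if quals is not None else [],
                )
            )
    if n_unmapped:
        logger.info("skipped %d unmapped SAM records", n_unmapped)
    return alignments


def write_sam(
    alignments: Iterable[ShortReadAlignment],
    targets: dict[str, int],
    path: str | Path,
) -> None:
    """Write placements as plain-text SAM (targets: read_id -> length)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for rid, length in targets.items():
            fh.write(f"@SQ\tSN:{rid}\tLN:{length}\n")
        for a in alignments:
            cigar = "".join(f"{n}{op}" for op, n in a.cigar_ops)
            qual = (
                "".join(chr(q + 33) for q in a.query_quals)
                if a.query_quals
                else "*"
            )
            fh.write(
                f"{a.query_id}\t0\t{a.target_read_id}\t{a.target_start + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t{a.query_bases}\t{qual}\n"
            )
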