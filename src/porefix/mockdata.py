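"""Synthetic data with known truth for benchmarking correction and annotation.

The generator emulates the evaluation inputs of a correction-based nanopore
annotation study: a coding-dense reference genome whose proteins carry
synthetic KO labels, long reads corrupted at a configurable total per-base
error rate (default 5%, half substitutions and half indels), short accurate
reads with known true placements for polishing, and linear-plus-noise gas
concentration time series for the flux calculator.

Every corrupted read carries a :class:`TruthRecord` whose edit list replays
to the noisy sequence exactly, so correction accuracy can be scored by
string comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._codon import STOP_CODONS, translate_frame
from .errors import InputError
from .quant import GasSeries
from .seqio import NanoporeRead, ProteinRecord, ShortReadAlignment

BASES = "ACGT"


@dataclass(frozen=True)
class MockGenomeSpec:
    n_genes: int = 20
    gene_len_aa: int = 100
    intergenic_len: int = 50
    gc_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.gene_len_aa < 1:
            raise InputError("n_genes and gene_len_aa must be >= 1")
        if not 0.0 < self.gc_fraction < 1.0:
            raise InputError("gc_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ErrorModel:
    """Per-position error injection.

    Each position is hit independently with probability ``total_rate``; the
    hit type is drawn from ``mix`` (substitution, insertion, deletion).
    Substitutions pick a uniformly different base, insertions add a uniform
    base after the position, deletions remove it. ``homopolymer`` switches
    to nanopore-like indels: insertions duplicate the current base, and
    deletions only remove bases equal to their left neighbour (other
    deletion hits degrade to duplications), so every indel sits in a
    homopolymer run as dominant nanopore indels do.
    """

    total_rate: float = 0.05
    mix: tuple[float, float, float] = (0.50, 0.25, 0.25)
    seed: int = 0
    homopolymer: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.total_rate < 1.0:
            raise InputError("total_rate must be in [0, 1)")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise InputError("mix must sum to 1")


@dataclass(frozen=True)
class TruthEdit:
    position: int  # coordinate on the clean source fragment
    kind: str  # 'sub' | 'ins' (after position) | 'del'
    base: str  # new base (sub), inserted base (ins), removed base (del)


@dataclass
class TruthRecord:
    read_id: str
    source_start: int
    source_end: int
    edits: list[TruthEdit] = field(default_factory=list)
    gold_kos: list[str] = field(default_factory=list)


@dataclass
class MockReference:
    genome: str
    proteins: list[ProteinRecord]
    genes: pd.DataFrame  # gene_id, protein_id, ko_id, cds_start, cds_end, strand


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


# a stop codon in all three forward and all three reverse frames: embedded in
# intergenic spacers so no open reading frame can span two adjacent genes
STOP_CASSETTE = "TTAATTAATTAA"


def _spacer(rng: np.random.Generator, length: int, gc: float) -> str:
    if length < len(STOP_CASSETTE):
        return _random_bases(rng, length, gc)
    left = (length - len(STOP_CASSETTE)) // 2
    right = length - len(STOP_CASSETTE) - left
    return (
        _random_bases(rng, left, gc) + STOP_CASSETTE + _random_bases(rng, right, gc)
    )


def gen_reference(spec: MockGenomeSpec) -> MockReference:
    """A genome of stop-free ATG-started genes separated by spacers.

    Each gene gets a unique synthetic KO id (KMOCK00001, ...). Spacers of
    >= 12 nt carry a six-frame stop cassette so reading frames always break
    between genes, mirroring the stop-delimited gene structure of real
    genomes. Deterministic under the spec seed. Genome length is
    ``n_genes * (3*gene_len_aa + 3) + (n_genes + 1) * intergenic_len``.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    parts: list[str] = []
    proteins: list[ProteinRecord] = []
    rows = []
    pos = 0
    stops = set(STOP_CODONS)
    for g in range(spec.n_genes):
        spacer = _spacer(rng, spec.intergenic_len, gc)
        parts.append(spacer)
        pos += len(spacer)
        codons = ["ATG"]
        while len(codons) < spec.gene_len_aa:
            c = _random_bases(rng, 3, gc)
            if c not in stops:
                codons.append(c)
        cds = "".join(codons)
        stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
        parts.append(cds + stop)
        gene_id = f"MOCKG{g + 1:05d}"
        ko_id = f"KMOCK{g + 1:05d}"
        prot_id = f"MOCKP{g + 1:05d}"
        proteins.append(
            ProteinRecord(prot_id, translate_frame(cds, 0), ko_id=ko_id)
        )
        rows.append(
            {
                "gene_id": gene_id,
                "protein_id": prot_id,
                "ko_id": ko_id,
                "cds_start": pos,
                "cds_end": pos + len(cds),
                "strand": "+",
            }
        )
        pos += len(cds) + 3
    parts.append(_spacer(rng, spec.intergenic_len, gc))
    return MockReference("".join(parts), proteins, pd.DataFrame(rows))


def corrupt_sequence(
    seq: str,
    model: ErrorModel,
    read_id: str = "read",
    rng: np.random.Generator | None = None,
    source_start: int = 0,
) -> tuple[NanoporeRead, TruthRecord]:
    """Inject errors per the model; the TruthRecord replays to the noisy read.

    Qualities: error-free positions draw uniform [10, 30]; erroneous bases
    (substituted or inserted) draw uniform [3, 10), so quality masking has
    signal to act on.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = len(seq)
    hits = rng.random(n) < model.total_rate
    kinds = rng.choice(3, size=n, p=list(model.mix))  # 0 sub, 1 ins, 2 del
    sub_pick = rng.integers(0, 3, size=n)  # index among the 3 other bases
    ins_pick = rng.integers(0, 4, size=n)
    qual_lo = rng.integers(3, 10, size=n + 1)
    qual_hi = rng.integers(10, 31, size=n + 1)
    out: list[str] = []
    quals: list[int] = []
    edits: list[TruthEdit] = []
    for p in range(n):
        b = seq[p]
        if not hits[p]:
            out.append(b)
            quals.append(int(qual_hi[p]))
            continue
        kind = int(kinds[p])
        if model.homopolymer and kind == 2 and (p == 0 or seq[p - 1] != b):
            kind = 1  # no homopolymer to shorten: duplicate instead
        if kind == 0:  # substitution
            others = [x for x in BASES if x != b]
            nb = others[int(sub_pick[p]) % 3]
            out.append(nb)
            quals.append(int(qual_lo[p]))
            edits.append(TruthEdit(p, "sub", nb))
        elif kind == 1:  # insertion after p
            ins = b if model.homopolymer else BASES[int(ins_pick[p])]
            out.append(b)
            quals.append(int(qual_hi[p]))
            out.append(ins)
            quals.append(int(qual_lo[p]))
            edits.append(TruthEdit(p, "ins", ins))
        else:  # deletion
            edits.append(TruthEdit(p, "del", b))
    read = NanoporeRead(read_id, "".join(out), quals)
    truth = TruthRecord(read_id, source_start, source_start + n, edits)
    return read, truth


def inject_codon_indels(
    seq: str,
    rate: float,
    seed: int = 0,
    read_id: str = "read",
    rng: np.random.Generator | None = None,
    min_spacing_codons: int = 10,
    margin_codons: int = 6,
) -> tuple[NanoporeRead, TruthRecord]:
    """Inject frameshift errors that the duplicate-previous-base repair rule
    can invert exactly — the round-trip benchmark for the corrector.

    ``seq`` must be a coding sequence read in frame 0. ``rate`` is the target
    per-nucleotide indel rate. At eligible codon boundaries 3k an insertion
    duplicates the boundary base (``seq[3k-1]`` re-emitted) or, where the
    codon's first base equals its left neighbour, a deletion removes
    ``seq[3k]``. Both errors sit in a homopolymer at a codon boundary, the
    geometry where a codon-granularity frameshift alignment localises the
    event and the insert-previous/delete-current repair restores the exact
    string. Mid-codon indels (see :class:`ErrorModel`) are frame-repairable
    but not string-invertible under that rule.

    Events are only localisable by a local aligner when flanked by enough
    coding signal: extending an alignment across a frameshift costs the
    penalty f (default 15) while each matching codon gains ~4-5, so events
    within ~f/4 codons of a read end, or two opposite-sign events closer
    than ~2f/4 codons (where skipping both is cheaper than two shifts), are
    fundamentally unrecoverable. ``margin_codons`` and ``min_spacing_codons``
    keep injected events inside the identifiable regime.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_codons = len(seq) // 3
    edits: list[TruthEdit] = []
    last_k = -(10**9)
    for k in range(max(1, margin_codons), n_codons - margin_codons):
        if rng.random() >= 3 * rate or k - last_k < min_spacing_codons:
            continue
        p = 3 * k
        want_del = rng.random() < 0.5 and seq[p] == seq[p - 1]
        if want_del:
            edits.append(TruthEdit(p, "del", seq[p]))
        else:
            edits.append(TruthEdit(p - 1, "ins", seq[p - 1]))
        last_k = k
    noisy = replay_edits(seq, edits)
    rng_q = rng.integers(10, 31, size=len(noisy))
    read = NanoporeRead(read_id, noisy, [int(q) for q in rng_q])
    return read, TruthRecord(read_id, 0, len(seq), edits)


def replay_edits(source: str, edits: list[TruthEdit]) -> str:
    """Reapply a truth edit list to the clean source fragment."""
    by_pos: dict[int, TruthEdit] = {e.position: e for e in edits}
    out: list[str] = []
    for p, b in enumerate(source):
        e = by_pos.get(p)
        if e is None:
            out.append(b)
        elif e.kind == "sub":
            out.append(e.base)
        elif e.kind == "ins":
            out.append(b)
            out.append(e.base)
        else:  # del
            pass
    return "".join(out)


def gen_mock_reads(
    ref: MockReference,
    n_reads: int,
    read_len: int,
    model: ErrorModel,
    seed: int = 0,
    min_gold_aa: int = 30,
) -> tuple[list[NanoporeRead], list[TruthRecord]]:
    """Uniformly placed fragments of the mock genome, corrupted per the model.

    Gold KOs of a read are the KOs of genes whose coding sequence overlaps
    the source interval by at least ``min_gold_aa`` complete in-frame codons
    (the default matches the ORF caller's minimum length), i.e. the genes an
    ideal annotator of the error-free fragment could detect.
    """
    if read_len > len(ref.genome):
        raise InputError("read_len exceeds genome length")
    rng = np.random.default_rng(seed)
    reads: list[NanoporeRead] = []
    truths: list[TruthRecord] = []
    genes = ref.genes
    for k in range(n_reads):
        start = int(rng.integers(0, len(ref.genome) - read_len + 1))
        frag = ref.genome[start : start + read_len]
        read, truth = corrupt_sequence(
            frag, model, read_id=f"mockread{k + 1:05d}", rng=rng, source_start=start
        )
        gold: list[str] = []
        for _, g in genes.iterrows():
            lo = max(g["cds_start"], start)
            hi = min(g["cds_end"], start + read_len)
            if hi <= lo:
                continue
            # complete codons of the gene's frame inside the overlap
            first = g["cds_start"] + -(-(lo - g["cds_start"]) // 3) * 3
            last = g["cds_start"] + (hi - g["cds_start"]) // 3 * 3
            if (last - first) // 3 >= min_gold_aa:
                gold.append(g["ko_id"])
        truth.gold_kos = gold
        reads.append(read)
        truths.append(truth)
    return reads, truths


def gen_short_reads(
    ref: str,
    coverage: float,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
    target_read_id: str = "ref",
) -> tuple[list[NanoporeRead], list[ShortReadAlignment]]:
    """ceil(coverage * len / read_len) uniformly placed short reads with
    per-base substitution errors, plus their true placements."""
    if read_len > len(ref):
        raise InputError("read_len exceeds reference length")
    n = math.ceil(coverage * len(ref) / read_len)
    rng = np.random.default_rng(seed)
    reads: list[NanoporeRead] = []
    alns: list[ShortReadAlignment] = []
    for k in range(n):
        start = int(rng.integers(0, len(ref) - read_len + 1))
        bases = list(ref[start : start + read_len])
        if error_rate > 0:
            for i in np.flatnonzero(rng.random(read_len) < error_rate):
                bases[i] = BASES[(BASES.index(bases[i]) + int(rng.integers(1, 4))) % 4]
        seq = "".join(bases)
        quals = [40] * read_len
        qid = f"short{k + 1:06d}"
        reads.append(NanoporeRead(qid, seq, quals))
        alns.append(
            ShortReadAlignment(qid, target_read_id, start, [("M", read_len)], seq, quals)
        )
    return reads, alns


def project_to_noisy(
    alignments: list[ShortReadAlignment],
    truth: TruthRecord,
    fragment_len: int,
) -> list[ShortReadAlignment]:
    """Re-express placements on the clean fragment as placements on the noisy read.

    Truth deletions become query-only (I) columns, truth insertions become
    target-only (D) columns; boundary insertions outside the placement are
    dropped and ragged query-only ends are trimmed like local clipping.
    Placements entirely erased by deletions are skipped.
    """
    pos_map: list[int | None] = [None] * fragment_len
    ins_after = [0] * fragment_len
    by_pos = {e.position: e for e in truth.edits}
    c = 0
    for p in range(fragment_len):
        e = by_pos.get(p)
        if e is not None and e.kind == "del":
            continue
        pos_map[p] = c
        c += 1
        if e is not None and e.kind == "ins":
            ins_after[p] = 1
            c += 1
    out: list[ShortReadAlignment] = []
    for aln in alignments:
        s = aln.target_start
        span = aln.target_span()
        ops: list[tuple[str, int]] = []
        for p in range(s, s + span):
            ops.append(("M", 1) if pos_map[p] is not None else ("I", 1))
            if ins_after[p] and p < s + span - 1:
                ops.append(("D", 1))
        bases = aln.query_bases
        quals = list(aln.query_quals)
        while ops and ops[0][0] == "I":
            ops.pop(0)
            bases, quals = bases[1:], quals[1:]
        while ops and ops[-1][0] == "I":
            ops.pop()
            bases, quals = bases[:-1], quals[:-1]
        if not any(op == "M" for op, _ in ops):
            continue
        merged: list[tuple[str, int]] = []
        for op, ln in ops:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + ln)
            else:
                merged.append((op, ln))
        first_m = next(p for p in range(s, s + span) if pos_map[p] is not None)
        # leading D ops (insertions before the first kept M) cannot start a placement
        while merged and merged[0][0] == "D":
            merged.pop(0)
        out.append(
            ShortReadAlignment(
                aln.query_id,
                truth.read_id,
                pos_map[first_m],
                merged,
                bases,
                quals,
            )
        )
    return out


def gen_gas_series(
    slope: float,
    intercept: float,
    times: list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    P: float = 1.0,
    V: float = 10.0,
    T: float = 288.0,
    A: float = 0.1,
    mode: str = "area",
) -> GasSeries:
    """Linear concentration series (ppm) with Gaussian noise.

    Default sampling grid is 0, 20, 40, 60, 80 minutes expressed in hours,
    the standard static-chamber protocol.
    """
    if times is None:
        times = [0.0, 1 / 3, 2 / 3, 1.0, 4 / 3]
    if len(times) < 2:
        raise InputError("need at least two time points")
    rng = np.random.default_rng(seed)
    conc = intercept + slope * np.asarray(times, dtype=float)
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, size=len(times))
    return GasSeries(
        times=list(map(float, times)),
        concentrations=list(map(float, conc)),
        P=P,
        V=V,
        T=T,
        A=A,
        mode=mode,
    )


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (edlib, NW mode)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]
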