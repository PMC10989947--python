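"""Quality masking and short-read pileup polishing of long reads.

Stage 1 replaces bases whose Phred quality is strictly below a threshold
(default Q5, i.e. >~68% error probability) with N so they cannot mislead
downstream alignment. Stage 2 builds a per-position pileup from short-read
placements on the long read and applies a transparent majority-vote
consensus: at sufficiently covered positions the long-read base is replaced,
deleted, or followed by an insertion whenever a consensus fraction of the
covering short reads agrees.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ConsistencyError
from .seqio import NanoporeRead, ShortReadAlignment


@dataclass(frozen=True)
class MaskParams:
    q_min: int = 5  # bases with quality strictly below this become N

    def __post_init__(self) -> None:
        if not 0 <= self.q_min <= 93:
            raise ValueError("q_min must be in [0, 93]")


@dataclass
class PileupColumn:
    position: int
    base_counts: Counter = field(default_factory=Counter)
    insertion_counts: Counter = field(default_factory=Counter)  # anchored after position
    deletion_count: int = 0

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.deletion_count


@dataclass(frozen=True)
class PolishParams:
    min_depth: int = 4
    consensus_fraction: float = 0.7  # tau, in (0.5, 1]

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.5 < self.consensus_fraction <= 1.0:
            raise ValueError("consensus_fraction must be in (0.5, 1]")


@dataclass
class PolishReport:
    read_id: str
    n_substituted: int = 0
    n_inserted: int = 0
    n_deleted: int = 0
    polished_fraction: float = 0.0  # fraction of positions with depth >= min_depth


def mask_low_quality(
    read: NanoporeRead, params: MaskParams = MaskParams()
) -> tuple[NanoporeRead, int]:
    """Replace bases with quality < q_min by N. Qualities are kept unchanged,
    so masking is idempotent and the signal stays available downstream."""
    seq = list(read.sequence)
    n_masked = 0
    for i, q in enumerate(read.qualities):
        if q < params.q_min and seq[i] != "N":
            seq[i] = "N"
            n_masked += 1
    masked = NanoporeRead(
        read.read_id, "".join(seq), list(read.qualities), read.description
    )
    return masked, n_masked


def build_pileup(
    read: NanoporeRead, alignments: list[ShortReadAlignment]
) -> list[PileupColumn]:
    """One column per read position. M ops vote for bases, D ops vote for
    deleting the covered read base, I ops vote for an inserted string
    anchored after the preceding M position (leading insertions, having no
    anchor, are ignored)."""
    n = len(read.sequence)
    columns = [PileupColumn(i) for i in range(n)]
    for aln in alignments:
        if aln.target_read_id and aln.target_read_id != read.read_id:
            raise ConsistencyError(
                f"alignment {aln.query_id!r} targets {aln.target_read_id!r}, "
                f"not {read.read_id!r}"
            )
        if aln.target_start + aln.target_span() > n:
            raise ConsistencyError(
                f"alignment {aln.query_id!r} overruns read end "
                f"({aln.target_start}+{aln.target_span()} > {n})"
            )
        t = aln.target_start
        q = 0
        last_m: int | None = None
        for op, length in aln.cigar_ops:
            if op == "M":
                for k in range(length):
                    columns[t + k].base_counts[aln.query_bases[q + k]] += 1
                last_m = t + length - 1
                t += length
                q += length
            elif op == "D":
                for k in range(length):
                    columns[t + k].deletion_count += 1
                t += length
            else:  # I
                if last_m is not None:
                    columns[last_m].insertion_counts[aln.query_bases[q : q + length]] += 1
                q += length
    return columns


def polish_consensus(
    read: NanoporeRead,
    columns: list[PileupColumn],
    params: PolishParams = PolishParams(),
) -> tuple[NanoporeRead, PolishReport]:
    """Majority-vote consensus polish.

    At each column with depth >= min_depth: delete the read base when the
    deletion fraction reaches tau; otherwise substitute when the majority
    base differs from the read base and reaches tau (this may restore a base
    over an N mask). Insertions anchored after the column are applied when
    the most common inserted string reaches tau. Inserted bases get quality
    min(depth, 40); substituted bases keep their original quality.
    """
    if len(columns) != len(read.sequence):
        raise ConsistencyError(
            f"pileup has {len(columns)} columns for a {len(read.sequence)}-base read"
        )
    tau = params.consensus_fraction
    report = PolishReport(read_id=read.read_id)
    out_seq: list[str] = []
    out_quals: list[int] = []
    n_covered = 0
    for i, col in enumerate(columns):
        base = read.sequence[i]
        qual = read.qualities[i]
        depth = col.depth
        emitted = True
        if depth >= params.min_depth:
            n_covered += 1
            if col.deletion_count / depth >= tau:
                report.n_deleted += 1
                emitted = False
            elif col.base_counts:
                top, cnt = col.base_counts.most_common(1)[0]
                if cnt / depth >= tau and top != base:
                    base = top
                    report.n_substituted += 1
        if emitted:
            out_seq.append(base)
            out_quals.append(qual)
        if depth >= params.min_depth and col.insertion_counts:
            ins, cnt = col.insertion_counts.most_common(1)[0]
            if cnt / depth >= tau:
                out_seq.append(ins)
                out_quals.extend([min(depth, 40)] * len(ins))
                report.n_inserted += 1
    report.polished_fraction = n_covered / len(columns) if columns else 0.0
    polished = NanoporeRead(
        read.read_id, "".join(out_seq), out_quals, read.description
    )
    return polished, report


def polish_read(
    read: NanoporeRead,
    alignments: list[ShortReadAlignment],
    params: PolishParams = PolishParams(),
) -> tuple[NanoporeRead, PolishReport]:
    """Convenience wrapper: pileup + consensus in one step."""
    return polish_consensus(read, build_pileup(read, alignments), params)
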