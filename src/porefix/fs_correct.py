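"""Turn frameshift alignments into base-level read corrections.

A forward shift (``\\``) marks a base missing from the read: the repair
inserts a copy of the previous nucleotide at the shift. A reverse shift
(``/``) marks a spurious extra base: the repair deletes the nucleotide at
the shift. Overlapping alignments are resolved greedily by score so each
read region is corrected by at most one protein.

Minus-strand alignments: the "previous base" of a forward shift lives on
the minus strand; on the original strand that is the complement of the base
immediately 3' of the event, and the duplicate is inserted right after that
base. Deletions map position-for-position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConsistencyError
from .fs_align import (
    FORWARD_SHIFT,
    REVERSE_SHIFT,
    FrameshiftAlignment,
    ProteinSearcher,
    ScoringScheme,
)
from .seqio import NanoporeRead, ProteinRecord

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class CorrectionEdit:
    """One base-level repair: insert ``inserted_base`` before ``position``,
    or delete the base at ``position``."""

    position: int
    kind: str  # 'insert_prev' | 'delete'
    inserted_base: str | None = None


@dataclass
class CorrectedRead:
    read_id: str
    sequence: str
    qualities: list[int]
    edits_applied: list[CorrectionEdit]
    source_alignments: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class CorrectionStats:
    total_aligned_bases: int = 0
    total_frameshift_events: int = 0

    @property
    def frameshifts_per_kb(self) -> float:
        if self.total_aligned_bases == 0:
            return 0.0
        return 1000.0 * self.total_frameshift_events / self.total_aligned_bases


def edits_from_alignment(aln: FrameshiftAlignment) -> list[CorrectionEdit]:
    """Base-level edits implied by an alignment's frameshift events.

    Plus strand: a forward shift at p inserts a copy of read[p-1] before p
    (skipped with a warning if p == 0); a reverse shift at p deletes read[p].
    Minus strand: a forward shift at p inserts a copy of read[p+1] before
    p+1 (the strand-local previous base, complemented back); a reverse shift
    deletes read[p] as on the plus strand.
    """
    edits: list[CorrectionEdit] = []
    n = aln.read_length
    for ev in aln.events:
        p = ev.read_position
        if ev.direction == REVERSE_SHIFT:
            edits.append(CorrectionEdit(p, "delete"))
            continue
        assert ev.direction == FORWARD_SHIFT
        if aln.strand == "+":
            if p < 1:
                logger.warning(
                    "read %s: forward shift at position 0 has no previous base; skipped",
                    aln.read_id,
                )
                continue
            edits.append(CorrectionEdit(p, "insert_prev", ev.context_base))
        else:
            if p + 1 >= n:
                logger.warning(
                    "read %s: minus-strand forward shift at read end; skipped",
                    aln.read_id,
                )
                continue
            base = _COMP[ev.context_base] if ev.context_base else None
            edits.append(CorrectionEdit(p + 1, "insert_prev", base))
    edits.sort(key=lambda e: e.position)
    return edits


def select_alignments(alns: list[FrameshiftAlignment]) -> list[FrameshiftAlignment]:
    """Greedy non-overlapping selection: keep by descending score (ties by
    ascending protein_id, then read start); drop anything overlapping a
    kept read interval. Output sorted by read start."""
    kept: list[FrameshiftAlignment] = []
    order = sorted(
        alns, key=lambda a: (-a.score, a.protein_id, a.read_interval[0], a.strand)
    )
    for aln in order:
        s, e = aln.read_interval
        if all(e <= ks or s >= ke for ks, ke in (k.read_interval for k in kept)):
            kept.append(aln)
    kept.sort(key=lambda a: a.read_interval[0])
    return kept


def apply_edits(read: NanoporeRead, edits: list[CorrectionEdit]) -> CorrectedRead:
    """Apply edits in descending position order so coordinates stay valid.

    Inserted bases take the previous base's quality. Two edits at the same
    position are a conflict (select_alignments should have prevented it).
    """
    positions = [e.position for e in edits]
    if len(set(positions)) != len(positions):
        raise ConsistencyError(f"read {read.read_id}: conflicting edits at one position")
    seq = list(read.sequence)
    quals = list(read.qualities)
    for e in sorted(edits, key=lambda e: -e.position):
        if e.kind == "delete":
            if not 0 <= e.position < len(seq):
                raise ConsistencyError(f"delete at {e.position} outside read")
            del seq[e.position]
            del quals[e.position]
        else:
            if e.inserted_base is None or not 1 <= e.position <= len(seq):
                raise ConsistencyError(f"bad insertion at {e.position}")
            seq.insert(e.position, e.inserted_base)
            quals.insert(e.position, quals[e.position - 1])
    return CorrectedRead(
        read_id=read.read_id,
        sequence="".join(seq),
        qualities=quals,
        edits_applied=sorted(edits, key=lambda e: e.position),
    )


def frameshift_rate(kept: list[FrameshiftAlignment]) -> CorrectionStats:
    """Frameshift events per kilobase of aligned (kept, non-overlapping) sequence."""
    stats = CorrectionStats()
    for aln in kept:
        s, e = aln.read_interval
        stats.total_aligned_bases += e - s
        stats.total_frameshift_events += aln.n_events
    return stats


def correct_read(
    read: NanoporeRead,
    searcher: ProteinSearcher,
    top_k: int = 5,
) -> tuple[CorrectedRead, list[FrameshiftAlignment]]:
    """Search, select non-overlapping alignments, and repair one read."""
    alns = searcher.search(read, top_k=top_k)
    kept = select_alignments(alns)
    edits: dict[int, CorrectionEdit] = {}
    for aln in kept:  # kept are non-overlapping; boundary ties keep first
        for e in edits_from_alignment(aln):
            edits.setdefault(e.position, e)
    corrected = apply_edits(read, list(edits.values()))
    corrected.source_alignments = [(a.protein_id, a.score) for a in kept]
    return corrected, kept


def correct_reads(
    reads: list[NanoporeRead],
    db: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    top_k: int = 5,
    prefilter: bool = True,
) -> tuple[list[CorrectedRead], CorrectionStats]:
    """Full correction stage. Reads with no alignment pass through unchanged."""
    searcher = ProteinSearcher(db, scheme, prefilter=prefilter)
    out: list[CorrectedRead] = []
    all_kept: list[FrameshiftAlignment] = []
    for read in reads:
        corrected, kept = correct_read(read, searcher, top_k=top_k)
        out.append(corrected)
        all_kept.extend(kept)
    return out, frameshift_rate(all_kept)
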