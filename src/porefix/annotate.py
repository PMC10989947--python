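"""Six-frame ORF calling, best-hit KO assignment, and precision/recall
evaluation against a gold standard.

Reads are fragments, so ORFs are maximal stop-free stretches that are
open-ended at the read boundaries (no start codon required). Codons
containing N translate to X and do not terminate an ORF. KO assignment is
alignment-based: each ORF is aligned protein-vs-protein against the
KO-labelled database and the best hit above the score threshold supplies
the call.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._codon import revcomp, translate_frame
from .errors import InputError
from .fs_align import AA_ALPHABET, ScoringScheme
from .seqio import NanoporeRead, ProteinRecord


@dataclass
class ORF:
    read_id: str
    strand: str  # '+' or '-'
    frame: int  # 0/1/2 on its own strand
    nt_interval: tuple[int, int]  # 0-based half-open on the original strand
    aa_sequence: str


@dataclass
class KOCall:
    ko_id: str
    protein_id: str
    score: float
    orf: ORF | None = None


@dataclass
class AnnotationResult:
    read_id: str
    ko_calls: list[KOCall] = field(default_factory=list)

    def ko_multiset(self) -> Counter:
        return Counter(c.ko_id for c in self.ko_calls)


@dataclass
class EvalReport:
    n_tp: int
    n_fp: int
    n_fn: int
    precision: float  # micro; NaN when no predictions
    recall: float  # micro; NaN when gold is empty
    macro_precision: float
    macro_recall: float
    per_record: dict[str, tuple[int, int, int]] = field(default_factory=dict)


def call_orfs(sequence: str, min_aa: int = 30, read_id: str = "") -> list[ORF]:
    """Maximal stop-free stretches of >= min_aa amino acids in all six frames."""
    if min_aa < 1:
        raise InputError("min_aa must be >= 1")
    n = len(sequence)
    orfs: list[ORF] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            aa = translate_frame(seq, frame)
            start = 0
            for segment in aa.split("*"):
                if len(segment) >= min_aa:
                    a, b = start, start + len(segment)
                    lo, hi = frame + 3 * a, frame + 3 * b
                    if strand == "-":
                        lo, hi = n - hi, n - lo
                    orfs.append(ORF(read_id, strand, frame, (lo, hi), segment))
                start += len(segment) + 1  # skip the stop codon
    orfs.sort(key=lambda o: (o.nt_interval[0], o.strand, o.frame))
    return orfs


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    mat = substitution_matrices.Array(
        alphabet=AA_ALPHABET, dims=2, data=np.asarray(scheme.matrix, dtype=float)
    )
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def assign_ko(
    orfs: list[ORF],
    db: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
) -> list[KOCall]:
    """Best-hit KO assignment: one call per ORF when the best local
    protein-protein alignment scores >= scheme.min_score; score ties break
    by ascending protein_id."""
    scheme = scheme or ScoringScheme()
    if not db:
        raise InputError("empty protein database")
    if any(p.ko_id is None for p in db):
        raise InputError("database proteins must carry KO labels")
    aligner = _make_aligner(scheme)
    ordered = sorted(db, key=lambda p: p.protein_id)
    calls: list[KOCall] = []
    for orf in orfs:
        best: tuple[float, str, str] | None = None
        for prot in ordered:
            score = aligner.score(prot.aa_sequence, orf.aa_sequence)
            if score >= scheme.min_score and (best is None or score > best[0]):
                best = (score, prot.protein_id, prot.ko_id)
        if best is not None:
            calls.append(KOCall(best[2], best[1], best[0], orf))
    return calls


def annotate_read(
    read: NanoporeRead | str,
    db: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    min_aa: int = 30,
) -> AnnotationResult:
    if isinstance(read, str):
        read_id, seq = "", read
    else:
        read_id, seq = read.read_id, read.sequence
    orfs = call_orfs(seq, min_aa=min_aa, read_id=read_id)
    return AnnotationResult(read_id, assign_ko(orfs, db, scheme))


def annotate_reads(
    reads: list,
    db: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    min_aa: int = 30,
) -> list[AnnotationResult]:
    """Annotate a batch; accepts NanoporeRead or anything with read_id/sequence."""
    scheme = scheme or ScoringScheme()
    results = []
    for r in reads:
        orfs = call_orfs(r.sequence, min_aa=min_aa, read_id=r.read_id)
        results.append(AnnotationResult(r.read_id, assign_ko(orfs, db, scheme)))
    return results


def evaluate_annotation(
    predicted: list[AnnotationResult],
    gold: dict[str, Counter | list],
) -> EvalReport:
    """Multiset precision/recall of KO calls per read.

    TP = size of the multiset intersection of predicted and gold KOs (a
    duplicate call for the same gene counts as a false positive). Micro
    averages pool counts over reads; macro averages the per-read ratios,
    skipping reads where a ratio is undefined.
    """
    tps = fps = fns = 0
    per_record: dict[str, tuple[int, int, int]] = {}
    precisions: list[float] = []
    recalls: list[float] = []
    for res in predicted:
        if res.read_id not in gold:
            raise InputError(f"read {res.read_id!r} missing from gold standard")
        pred = res.ko_multiset()
        true = Counter(gold[res.read_id])
        tp = sum((pred & true).values())
        fp = sum(pred.values()) - tp
        fn = sum(true.values()) - tp
        per_record[res.read_id] = (tp, fp, fn)
        tps, fps, fns = tps + tp, fps + fp, fns + fn
        if tp + fp > 0:
            precisions.append(tp / (tp + fp))
        if tp + fn > 0:
            recalls.append(tp / (tp + fn))
    precision = tps / (tps + fps) if tps + fps > 0 else math.nan
    recall = tps / (tps + fns) if tps + fns > 0 else math.nan
    return EvalReport(
        n_tp=tps,
        n_fp=fps,
        n_fn=fns,
        precision=precision,
        recall=recall,
        macro_precision=float(np.mean(precisions)) if precisions else math.nan,
        macro_recall=float(np.mean(recalls)) if recalls else math.nan,
        per_record=per_record,
    )
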