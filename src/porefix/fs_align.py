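"""Frameshift-aware local DNA-to-protein alignment.

A Smith-Waterman-style dynamic program over (nucleotide position, protein
position) in which one alignment column normally consumes a 3-nt codon but
may consume 2 nt (a forward shift, rendered ``\\``: one base is missing from
the read) or 4 nt (a reverse shift, rendered ``/``: one spurious base is
present), each at a fixed frameshift penalty.

Translation convention for shifted columns: both shifted columns translate
the last three nucleotides ending at the column boundary, ``dna[i-3:i]``.
For a 2-nt column (consuming ``dna[i-2:i]``) this borrows the preceding
base — exactly the codon obtained after the downstream repair duplicates
that base. For a 4-nt column (consuming ``dna[i-4:i]``) it drops the first
base — the codon obtained after the repair deletes it. The aligner and the
corrector therefore agree by construction on what each shifted codon means.

Gap columns are affine: a run of k skipped amino acids (or k skipped whole
read codons) costs ``gap_open + (k-1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from ._codon import revcomp, translate_codon, translate_frame
from .errors import InputError
from .seqio import NanoporeRead, ProteinRecord

NEG = -(1 << 30)

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

FORWARD_SHIFT = "\\"
REVERSE_SHIFT = "/"


def default_substitution_matrix() -> np.ndarray:
    """BLOSUM62 over ARNDCQEGHILKMFPSTWYVBZX* with X scoring 0 vs everything."""
    mat = np.array(substitution_matrices.load("BLOSUM62"), dtype=np.int64)
    x = AA_INDEX["X"]
    mat[x, :] = 0
    mat[:, x] = 0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Scores for translated search.

    ``gap_open``/``gap_extend`` follow the open-includes-first-residue
    convention: a length-1 gap costs ``gap_open``.
    """

    matrix: np.ndarray = field(default_factory=default_substitution_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    frameshift_penalty: int = 15
    min_score: int = 60
    x_run_cap: int = 10  # consecutive all-X codons that break local extension

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend, self.frameshift_penalty) <= 0:
            raise InputError("all penalties must be positive")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise InputError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[AA_INDEX[a], AA_INDEX[b]])


@dataclass(frozen=True)
class FrameshiftEvent:
    """A frameshift column, in original-strand read coordinates.

    ``read_position`` is the first consumed base of the shifted column on
    the alignment's strand, mapped back to the original strand for minus-
    strand alignments. ``context_base`` is the strand-local base that a
    forward-shift repair would duplicate (None for reverse shifts).
    """

    read_position: int
    direction: str  # FORWARD_SHIFT or REVERSE_SHIFT
    context_base: str | None = None


@dataclass
class AlignmentColumn:
    kind: str  # match | fs_forward | fs_reverse | read_gap | prot_gap
    read_aa: str | None  # translated read codon (None for prot_gap)
    prot_aa: str | None  # protein residue (None for read_gap)
    nt_consumed: int
    codon: str | None = None  # the translated 3-mer source, where applicable


@dataclass
class FrameshiftAlignment:
    """A local DNA-to-protein alignment carrying frameshift events.

    ``read_interval`` is on the original strand (half-open); ``events`` are
    sorted by original-strand position. ``columns`` are in alignment
    (strand-local) order.
    """

    read_id: str
    protein_id: str
    strand: str  # '+' or '-'
    read_interval: tuple[int, int]
    protein_interval: tuple[int, int]
    score: int
    events: list[FrameshiftEvent]
    columns: list[AlignmentColumn]
    read_length: int

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def column_string(self) -> str:
        marks = {"match": "M", "fs_forward": FORWARD_SHIFT,
                 "fs_reverse": REVERSE_SHIFT, "read_gap": "d", "prot_gap": "p"}
        return "".join(marks[c.kind] for c in self.columns)

    def aligned_length(self) -> int:
        s, e = self.read_interval
        return e - s


def _codon_aa_indices(dna: str) -> np.ndarray:
    """aa index of dna[i-3:i] for each i (entries < 3 are -1)."""
    n = len(dna)
    out = np.full(n + 1, -1, dtype=np.int64)
    for i in range(3, n + 1):
        out[i] = AA_INDEX[translate_codon(dna[i - 3 : i])]
    return out


def align_frameshift(
    dna: str,
    protein: str,
    scheme: ScoringScheme | None = None,
    min_score: int = 0,
) -> FrameshiftAlignment | None:
    """Best local frameshift-aware alignment of ``dna`` (plus strand) to ``protein``.

    Returns None when the DNA is shorter than one codon or the best local
    score is below ``min_score`` (and always when no positive-scoring
    alignment exists).
    """
    scheme = scheme or ScoringScheme()
    if set(dna) - set("ACGTN"):
        raise InputError("DNA contains characters outside {A,C,G,T,N}")
    if len(dna) < 3 or not protein:
        return None
    res = _align_local(dna, protein, scheme)
    if res is None or res[0] < max(min_score, 1):
        return None
    score, cols, read_iv, prot_iv, events = res
    return FrameshiftAlignment(
        read_id="",
        protein_id="",
        strand="+",
        read_interval=read_iv,
        protein_interval=prot_iv,
        score=score,
        events=events,
        columns=cols,
        read_length=len(dna),
    )


def _align_local(dna: str, protein: str, scheme: ScoringScheme):
    n, m = len(dna), len(protein)
    f = scheme.frameshift_penalty
    go, ge = scheme.gap_open, scheme.gap_extend
    try:
        pidx = np.array([AA_INDEX[a] for a in protein], dtype=np.int64)
    except KeyError as exc:
        raise InputError(f"illegal protein character {exc}") from exc
    caa = _codon_aa_indices(dna)
    sub = scheme.matrix

    x_idx = AA_INDEX["X"]
    xrun = np.zeros(n + 1, dtype=np.int64)
    for i in range(3, n + 1):
        if caa[i] == x_idx:
            xrun[i] = xrun[i - 3] + 1
    killed = xrun > scheme.x_run_cap

    M = np.zeros((n + 1, m + 1), dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = np.zeros((n + 1, m + 1), dtype=np.int64)

    jr = np.arange(1, m + 1, dtype=np.int64)
    for i in range(3, n + 1):
        srow = sub[caa[i], pidx]
        diag = np.maximum(best[i - 3, :m], best[i - 2, :m] - f)
        if i >= 4:
            np.maximum(diag, best[i - 4, :m] - f, out=diag)
        mrow = srow + diag
        np.maximum(mrow, 0, out=mrow)
        if killed[i]:
            mrow[:] = 0
        M[i, 1:] = mrow
        np.maximum(M[i - 3] - go, Ix[i - 3] - ge, out=Ix[i])
        # Iy(i,j) = max(M(i,j-1)-go, Iy(i,j-1)-ge) as a running max
        cand = M[i, :m] - go + ge * jr
        Iy[i, 1:] = np.maximum.accumulate(cand) - ge * jr
        np.maximum(np.maximum(M[i], Ix[i]), Iy[i], out=best[i])

    score = int(M.max())
    if score <= 0:
        return None
    flat = int(np.argmax(M))  # row-major: smallest i, then smallest j
    i, j = divmod(flat, m + 1)

    # traceback
    cols: list[AlignmentColumn] = []
    events: list[tuple[int, str, str]] = []  # (local pos, direction, context base)
    end_i, end_j = i, j
    state = "M"
    while True:
        if state == "M":
            v = int(M[i, j])
            s = int(sub[caa[i], pidx[j - 1]])
            aa_r = AA_ALPHABET[caa[i]]
            aa_p = protein[j - 1]
            codon = dna[i - 3 : i]
            moved = False
            for k, pen, kind in ((3, 0, "match"), (2, f, "fs_forward"), (4, f, "fs_reverse")):
                if i - k < 0 or (k == 2 and i < 3) or (k == 4 and i < 4):
                    continue
                prev = int(best[i - k, j - 1])
                if v == prev + s - pen:
                    cols.append(AlignmentColumn(kind, aa_r, aa_p, k, codon))
                    if kind == "fs_forward":
                        events.append((i - k, FORWARD_SHIFT, codon[0]))
                    elif kind == "fs_reverse":
                        events.append((i - k, REVERSE_SHIFT, None))
                    i, j = i - k, j - 1
                    if prev == 0:
                        state = "done"
                    elif M[i, j] == prev:
                        state = "M"
                    elif Ix[i, j] == prev:
                        state = "Ix"
                    else:
                        state = "Iy"
                    moved = True
                    break
            if not moved:  # pragma: no cover - DP/traceback mismatch
                raise AssertionError("traceback failed in match state")
            if state == "done":
                break
        elif state == "Ix":
            v = int(Ix[i, j])
            codon = dna[i - 3 : i]
            cols.append(
                AlignmentColumn("read_gap", translate_codon(codon), None, 3, codon)
            )
            if v == M[i - 3, j] - go:
                state = "M"
            i -= 3
        else:  # Iy
            cols.append(AlignmentColumn("prot_gap", None, protein[j - 1], 0))
            if Iy[i, j] == M[i, j - 1] - go:
                state = "M"
            j -= 1
    cols.reverse()
    events.sort()
    evs = [FrameshiftEvent(p, d, c) for p, d, c in events]
    return score, cols, (i, end_i), (j, end_j), evs


# ---------------------------------------------------------------------------
# database search


class ProteinSearcher:
    """Search a KO-labelled protein database with a k-mer prescreen.

    The prescreen translates the read in all six frames and keeps only
    proteins sharing at least one amino-acid k-mer with some frame — a
    seed-and-extend shortcut in the spirit of translated search tools.
    ``prefilter=False`` runs the full dynamic program against every protein.
    """

    def __init__(
        self,
        db: list[ProteinRecord],
        scheme: ScoringScheme | None = None,
        kmer: int = 5,
        prefilter: bool = True,
    ) -> None:
        if not db:
            raise InputError("empty protein database")
        self.db = sorted(db, key=lambda p: p.protein_id)
        self.scheme = scheme or ScoringScheme()
        self.kmer = kmer
        self.prefilter = prefilter
        self._index: dict[str, set[int]] = {}
        if prefilter:
            for pi, prot in enumerate(self.db):
                seq = prot.aa_sequence
                for o in range(len(seq) - kmer + 1):
                    w = seq[o : o + kmer]
                    if "X" not in w:
                        self._index.setdefault(w, set()).add(pi)

    def _candidates(self, read_seq: str) -> list[int]:
        if not self.prefilter:
            return list(range(len(self.db)))
        hits: set[int] = set()
        for seq in (read_seq, revcomp(read_seq)):
            for frame in range(3):
                aa = translate_frame(seq, frame)
                for o in range(len(aa) - self.kmer + 1):
                    w = aa[o : o + self.kmer]
                    if "*" not in w and "X" not in w:
                        found = self._index.get(w)
                        if found:
                            hits.update(found)
        return sorted(hits)

    def search(self, read: NanoporeRead, top_k: int = 5) -> list[FrameshiftAlignment]:
        """All alignments with score >= scheme.min_score, best ``top_k`` kept.

        Both strands are searched; minus-strand coordinates (intervals and
        event positions) are mapped back to the original strand. Sort order:
        descending score, then fewer events, then ascending protein_id, then
        ascending read start.
        """
        scheme = self.scheme
        n = len(read.sequence)
        results: list[FrameshiftAlignment] = []
        rc = revcomp(read.sequence)
        for pi in self._candidates(read.sequence):
            prot = self.db[pi]
            for strand, seq in (("+", read.sequence), ("-", rc)):
                res = _align_local(seq, prot.aa_sequence, scheme) if len(seq) >= 3 else None
                if res is None or res[0] < scheme.min_score:
                    continue
                score, cols, read_iv, prot_iv, events = res
                if strand == "-":
                    s, e = read_iv
                    read_iv = (n - e, n - s)
                    events = [
                        FrameshiftEvent(n - 1 - ev.read_position, ev.direction, ev.context_base)
                        for ev in events
                    ]
                    events.sort(key=lambda ev: ev.read_position)
                results.append(
                    FrameshiftAlignment(
                        read_id=read.read_id,
                        protein_id=prot.protein_id,
                        strand=strand,
                        read_interval=read_iv,
                        protein_interval=prot_iv,
                        score=score,
                        events=events,
                        columns=cols,
                        read_length=n,
                    )
                )
        results.sort(
            key=lambda a: (-a.score, a.n_events, a.protein_id, a.read_interval[0])
        )
        return results[:top_k]


def search_protein_db(
    read: NanoporeRead,
    db: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    top_k: int = 5,
    prefilter: bool = True,
) -> list[FrameshiftAlignment]:
    """One-shot search (builds the index each call; reuse ProteinSearcher in loops)."""
    return ProteinSearcher(db, scheme, prefilter=prefilter).search(read, top_k=top_k)


# ---------------------------------------------------------------------------
# text rendering

_RENDER_SCHEME = ScoringScheme()


def render_alignment(aln: FrameshiftAlignment) -> str:
    """Three-row text block: translated read (with shift marks), match row, protein.

    Shift marks occupy their own column in row 1 immediately before the
    shifted codon's amino acid; rows 2-3 carry a space there.
    """
    r1, r2, r3 = [], [], []
    for c in aln.columns:
        if c.kind in ("fs_forward", "fs_reverse"):
            r1.append(FORWARD_SHIFT if c.kind == "fs_forward" else REVERSE_SHIFT)
            r2.append(" ")
            r3.append(" ")
        if c.kind == "read_gap":
            r1.append(c.read_aa.lower())
            r2.append(" ")
            r3.append("-")
            continue
        if c.kind == "prot_gap":
            r1.append("-")
            r2.append(" ")
            r3.append(c.prot_aa)
            continue
        r1.append(c.read_aa)
        r3.append(c.prot_aa)
        if c.read_aa == c.prot_aa:
            r2.append("|")
        else:
            r2.append("+" if _RENDER_SCHEME.score(c.read_aa, c.prot_aa) > 0 else " ")
    s, e = aln.read_interval
    ps, pe = aln.protein_interval
    header = (
        f">{aln.read_id} strand:{aln.strand} read:{s}-{e} len:{aln.read_length} "
        f"protein:{aln.protein_id} prot:{ps}-{pe} score:{aln.score}"
    )
    return "\n".join([header, " " + "".join(r1), " " + "".join(r2), " " + "".join(r3)])


def parse_rendered(text: str) -> dict:
    """Recover intervals and events from :func:`render_alignment` output."""
    lines = text.splitlines()
    head = dict(kv.split(":", 1) for kv in lines[0].split()[1:] if ":" in kv)
    strand = head["strand"]
    s, e = (int(v) for v in head["read"].split("-"))
    ps, pe = (int(v) for v in head["prot"].split("-"))
    length = int(head["len"])
    row1, row3 = lines[1][1:], lines[3][1:]
    pos = s if strand == "+" else length - e
    events: list[tuple[int, str]] = []
    pending: str | None = None
    for ch1, ch3 in zip(row1, row3):
        if ch1 in (FORWARD_SHIFT, REVERSE_SHIFT):
            pending = ch1
            continue
        if ch1 == "-":  # protein gap: consumes no nucleotides
            continue
        consumed = 3
        if pending == FORWARD_SHIFT:
            consumed = 2
        elif pending == REVERSE_SHIFT:
            consumed = 4
        if pending is not None:
            local = pos
            orig = local if strand == "+" else length - 1 - local
            events.append((orig, pending))
            pending = None
        pos += consumed
    events.sort()
    return {
        "read_interval": (s, e),
        "protein_interval": (ps, pe),
        "strand": strand,
        "score": int(head["score"]),
        "events": events,
    }
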