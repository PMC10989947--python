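"""Exhaustive enumeration oracle for frameshift-aware local alignment.

Enumerates every legal local alignment of a short DNA against a short
protein by depth-first search over codon consumptions (2/3/4 nt) and
affine gap runs, entirely independently of the dynamic program it checks.
Feasible only for tiny inputs (DNA <= ~15 nt, protein <= ~5 aa).

Column semantics mirror the aligner's contract:
  * a match column consumes 3 nt and translates them;
  * a forward-shift column consumes 2 nt and translates the preceding base
    plus those 2 (needs one base of left context), penalty f;
  * a reverse-shift column consumes 4 nt and translates the last 3,
    penalty f;
  * a gap run skips k amino acids or k whole read codons for
    gap_open + (k-1) * gap_extend, sits strictly between match columns;
  * alignments start and end with a match-type column; the empty alignment
    scores 0.
"""

from __future__ import annotations

from porefix._codon import translate_codon
from porefix.fs_align import AA_INDEX, ScoringScheme


def oracle_best_score(dna: str, protein: str, scheme: ScoringScheme | None = None) -> int:
    """Maximum local alignment score over all enumerated paths, floored at 0."""
    scheme = scheme or ScoringScheme()
    n, m = len(dna), len(protein)
    f = scheme.frameshift_penalty
    go, ge = scheme.gap_open, scheme.gap_extend
    sub = scheme.matrix

    def s(codon: str, aa: str) -> int:
        return int(sub[AA_INDEX[translate_codon(codon)], AA_INDEX[aa]])

    best = 0

    def extend(p: int, j: int, score: int) -> None:
        """Path so far ends with a match column at (p, j); try to continue."""
        nonlocal best
        best = max(best, score)
        # direct next match column
        for p2, j2, sc in _matches(p, j, score):
            extend(p2, j2, sc)
        # gap run in the read (skip whole codons), then a match
        k = 1
        while p + 3 * k + 2 <= n:
            gap_cost = go + (k - 1) * ge
            for p2, j2, sc in _matches(p + 3 * k, j, score - gap_cost):
                extend(p2, j2, sc)
            k += 1
        # gap run in the protein (skip amino acids), then a match
        k = 1
        while j + k + 1 <= m:
            gap_cost = go + (k - 1) * ge
            for p2, j2, sc in _matches(p, j + k, score - gap_cost):
                extend(p2, j2, sc)
            k += 1

    def _matches(p: int, j: int, score: int):
        """All single match-type columns starting at read pos p, protein pos j."""
        if j >= m:
            return
        aa = protein[j]
        if p + 3 <= n:
            yield p + 3, j + 1, score + s(dna[p : p + 3], aa)
        if p >= 1 and p + 2 <= n:  # forward shift borrows dna[p-1]
            yield p + 2, j + 1, score + s(dna[p - 1 : p + 2], aa) - f
        if p + 4 <= n:  # reverse shift drops dna[p]
            yield p + 4, j + 1, score + s(dna[p + 1 : p + 4], aa) - f

    for p0 in range(n):
        for j0 in range(m):
            for p2, j2, sc in _matches(p0, j0, 0):
                extend(p2, j2, sc)
    return best
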