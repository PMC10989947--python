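import numpy as np
import pytest

from dp_oracle import oracle_best_score
from porefix._codon import revcomp
from porefix.errors import InputError
from porefix.fs_align import (
    FORWARD_SHIFT,
    REVERSE_SHIFT,
    ProteinSearcher,
    ScoringScheme,
    align_frameshift,
    parse_rendered,
    render_alignment,
    search_protein_db,
)
from porefix.seqio import NanoporeRead, ProteinRecord


class TestAlignFrameshift:
    def test_exact_two_codons_scores_blosum(self, scheme):
        # ATG->M (M:M = 5) + GCC->A (A:A = 4), no shifts
        aln = align_frameshift("ATGGCC", "MA", scheme)
        assert aln.score == 9
        assert aln.events == []
        assert aln.read_interval == (0, 6)
        assert aln.protein_interval == (0, 2)

    def test_internal_insertion_needs_reverse_shift(self):
        # extra T inside ATG|GCC; with a frameshift penalty below the gain of
        # the second match the optimum takes one '/' column: 9 - f
        sch = ScoringScheme(frameshift_penalty=3)
        aln = align_frameshift("ATGTGCC", "MA", sch)
        assert aln.score == 9 - 3 == oracle_best_score("ATGTGCC", "MA", sch)
        assert len(aln.events) == 1
        assert aln.events[0].direction == REVERSE_SHIFT
        assert aln.events[0].read_position == 3  # the spurious T

    def test_default_penalty_prefers_single_match(self, scheme):
        # at f=15 the local optimum drops the shifted codon entirely
        aln = align_frameshift("ATGTGCC", "MA", scheme)
        assert aln.score == 5 == oracle_best_score("ATGTGCC", "MA", scheme)
        assert aln.events == []

    def test_deletion_needs_forward_shift(self):
        # MAW coding ATG GCC TGG with one base of GCC deleted
        sch = ScoringScheme(frameshift_penalty=3)
        aln = align_frameshift("ATGGCTGG", "MAW", sch)
        assert any(e.direction == FORWARD_SHIFT for e in aln.events)
        assert aln.score == oracle_best_score("ATGGCTGG", "MAW", sch)

    def test_too_short_dna_returns_none(self, scheme):
        assert align_frameshift("AT", "MA", scheme) is None

    def test_below_min_score_returns_none(self, scheme):
        assert align_frameshift("ATGGCC", "MA", scheme, min_score=60) is None

    def test_illegal_dna_raises(self, scheme):
        with pytest.raises(InputError):
            align_frameshift("ATGXCC", "MA", scheme)

    def test_n_codons_translate_to_x_and_score_zero(self, scheme):
        # middle codon fully masked: X contributes 0, flanks still align
        aln = align_frameshift("ATGNNNGCC", "MXA", scheme)
        assert aln.score == 9

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_enumeration_oracle_on_random_pairs(self, seed):
        """DP score equals exhaustive enumeration over all codon-consumption
        and gap paths for random dna <= 12 nt x protein <= 4 aa."""
        rng = np.random.default_rng(seed)
        from porefix.fs_align import _align_local

        for _ in range(100):
            n = int(rng.integers(3, 13))
            m = int(rng.integers(1, 5))
            dna = "".join(rng.choice(list("ACGTN"), n, p=[0.24] * 4 + [0.04]))
            prot = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), m))
            sch = ScoringScheme(
                frameshift_penalty=int(rng.integers(1, 16)),
                gap_open=int(rng.integers(2, 12)),
                gap_extend=1,
            )
            res = _align_local(dna, prot, sch)
            dp = res[0] if res else 0
            assert dp == oracle_best_score(dna, prot, sch), (dna, prot, sch)

    def test_single_insertion_costs_exactly_f(self, mock_ref):
        """Adding one internal duplicate base to a perfectly coding read
        lowers the optimal score by exactly the frameshift penalty."""
        g = mock_ref.genes.iloc[0]
        cds = mock_ref.genome[g.cds_start : g.cds_end]
        prot = mock_ref.proteins[0].aa_sequence
        sch = ScoringScheme()
        clean = align_frameshift(cds, prot, sch)
        p = 150  # codon boundary, mid-read
        noisy = cds[:p] + cds[p - 1] + cds[p:]
        shifted = align_frameshift(noisy, prot, sch)
        assert shifted.score == clean.score - sch.frameshift_penalty
        assert len(shifted.events) == 1


class TestSearch:
    def test_self_hit_top_with_zero_events(self, mock_ref, mock_searcher):
        g = mock_ref.genes.iloc[3]
        cds = mock_ref.genome[g.cds_start : g.cds_end]
        hits = mock_searcher.search(NanoporeRead("r", cds, [20] * len(cds)))
        assert hits[0].protein_id == g.protein_id
        assert hits[0].strand == "+"
        assert hits[0].n_events == 0

    def test_reverse_complement_same_protein_same_score(self, mock_ref, mock_searcher):
        g = mock_ref.genes.iloc[3]
        cds = mock_ref.genome[g.cds_start : g.cds_end]
        fwd = mock_searcher.search(NanoporeRead("r", cds, [20] * len(cds)))
        rev = mock_searcher.search(
            NanoporeRead("r", revcomp(cds), [20] * len(cds))
        )
        assert rev[0].protein_id == fwd[0].protein_id
        assert rev[0].score == fwd[0].score
        assert rev[0].strand == "-"
        assert rev[0].read_interval == fwd[0].read_interval  # symmetric coordinates

    def test_random_read_vs_unrelated_db_mostly_empty(self, scheme, rng):
        """Null model: 1 kb uniform reads against unrelated 200-aa proteins
        essentially never reach the score threshold."""
        db = [
            ProteinRecord(
                f"p{i}", "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 200)),
                ko_id=f"K{i}",
            )
            for i in range(5)
        ]
        searcher = ProteinSearcher(db, scheme, prefilter=False)
        n_hit = 0
        for t in range(30):
            read = NanoporeRead(f"r{t}", "".join(rng.choice(list("ACGT"), 1000)), [20] * 1000)
            n_hit += bool(searcher.search(read))
        assert n_hit == 0

    def test_empty_db_raises(self, scheme):
        with pytest.raises(InputError):
            search_protein_db(NanoporeRead("r", "ACGTACGTA", [20] * 9), [], scheme)

    def test_prefilter_agrees_with_exhaustive(self, mock_ref, scheme, rng):
        g = mock_ref.genes.iloc[5]
        cds = mock_ref.genome[g.cds_start : g.cds_end]
        read = NanoporeRead("r", cds, [20] * len(cds))
        fast = ProteinSearcher(mock_ref.proteins, scheme, prefilter=True).search(read)
        slow = ProteinSearcher(mock_ref.proteins, scheme, prefilter=False).search(read)
        assert [(a.protein_id, a.score) for a in fast] == [
            (a.protein_id, a.score) for a in slow
        ]


class TestRendering:
    def _alignments(self, mock_ref, mock_searcher, rng, k=20):
        out = []
        model_bases = list("ACGT")
        for t in range(k):
            g = mock_ref.genes.iloc[t % len(mock_ref.genes)]
            cds = mock_ref.genome[g.cds_start : g.cds_end]
            # sprinkle a couple of indels so some alignments carry events
            seq = list(cds)
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(30, len(seq) - 30))
                if rng.random() < 0.5:
                    seq.insert(p, model_bases[int(rng.integers(4))])
                else:
                    del seq[p]
            s = "".join(seq)
            if t % 3 == 0:
                s = revcomp(s)
            hits = mock_searcher.search(NanoporeRead(f"r{t}", s, [20] * len(s)))
            out.extend(hits[:1])
        return out

    def test_event_free_rendering_has_no_marks(self, mock_ref, mock_searcher):
        g = mock_ref.genes.iloc[0]
        cds = mock_ref.genome[g.cds_start : g.cds_end]
        aln = mock_searcher.search(NanoporeRead("r", cds, [20] * len(cds)))[0]
        text = render_alignment(aln)
        body = text.split("\n", 1)[1]
        assert FORWARD_SHIFT not in body and REVERSE_SHIFT not in body

    def test_single_forward_shift_renders_one_mark(self, mock_ref, mock_searcher):
        g = mock_ref.genes.iloc[0]
        cds = mock_ref.genome[g.cds_start : g.cds_end]
        noisy = cds[:150] + cds[151:]  # one deletion
        aln = mock_searcher.search(NanoporeRead("r", noisy, [20] * len(noisy)))[0]
        rows = render_alignment(aln).splitlines()
        assert rows[1].count(FORWARD_SHIFT) == 1

    def test_render_parse_round_trip(self, mock_ref, mock_searcher, rng):
        for aln in self._alignments(mock_ref, mock_searcher, rng, k=25):
            parsed = parse_rendered(render_alignment(aln))
            assert parsed["read_interval"] == aln.read_interval
            assert parsed["protein_interval"] == aln.protein_interval
            assert parsed["score"] == aln.score
            assert parsed["events"] == [
                (e.read_position, e.direction) for e in aln.events
            ]
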