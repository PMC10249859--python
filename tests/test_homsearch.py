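import numpy as np
import pytest

from numtrisk.errors import AlignmentSizeError
from numtrisk.homsearch import (AlignmentScoring, LocalHit, calibrate_karlin,
                                encode, find_hits, merge_overlapping_hits,
                                revcomp, smith_waterman)
from numtrisk.seqio import Scaffold, ScaffoldSet
from numtrisk.simgen import mutate_segment


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def plain_affine_sw(query, subject, match=2, mismatch=-3, go=7, ge=2):
    """Independent pure-python affine local aligner (score only)."""
    m, n = len(query), len(subject)
    NEG = -(10 ** 9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - go, E[i - 1][j] - ge)
            F[i][j] = max(H[i][j - 1] - go, F[i][j - 1] - ge)
            s = match if query[i - 1] == subject[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_exact_substring(self):
        rng = np.random.default_rng(0)
        sub = _random_dna(rng, 50) + "ACGTACGT" + _random_dna(rng, 50)
        h = smith_waterman("ACGTACGT", sub)
        assert h.score >= 16  # 8 matches x 2; flanks may extend it
        hx = smith_waterman("ACGTACGT", "TT" + "ACGTACGT" + "TT")
        assert hx.score == 16 and hx.identity == 1.0
        assert hx.s_end - hx.s_start == 8

    def test_orientation_asymmetry(self):
        rng = np.random.default_rng(1)
        q = _random_dna(rng, 200)
        fwd = smith_waterman(q, q)
        rev = smith_waterman(q, revcomp(q))
        assert fwd.score == 400
        assert rev.score < 100  # only chance similarity in reverse

    def test_gapped_alignment_invariants(self):
        rng = np.random.default_rng(2)
        q = _random_dna(rng, 300)
        s = q[:140] + q[145:]  # 5 bp deletion
        h = smith_waterman(q, s)
        assert h.q_gapped.replace("-", "") == q[h.q_start:h.q_end]
        assert h.s_gapped.replace("-", "") == s[h.s_start:h.s_end]
        assert len(h.q_gapped) == len(h.s_gapped) == h.aligned_len
        assert "-" in h.s_gapped

    def test_matches_plain_dp_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            q = _random_dna(rng, int(rng.integers(30, 200)))
            s = _random_dna(rng, int(rng.integers(30, 200)))
            assert smith_waterman(q, s).score == plain_affine_sw(q, s)

    def test_size_limit(self):
        with pytest.raises(AlignmentSizeError):
            smith_waterman("A" * 100_001, "ACGT")


class TestFindHits:
    def test_exact_planted_copy(self, mito):
        rng = np.random.default_rng(4)
        barcode = mito.barcode
        flank = _random_dna(rng, 3000)
        scaffold = flank + barcode + _random_dna(rng, 3000)
        ss = ScaffoldSet([Scaffold("s1", "", scaffold)])
        hits = find_hits(barcode, ss)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0 and h.strand == "+"
        assert abs(h.s_start - 3000) <= 5 and abs(h.s_end - 3658) <= 5

    def test_minus_strand_planted_copy(self, mito):
        rng = np.random.default_rng(5)
        scaffold = _random_dna(rng, 2000) + revcomp(mito.barcode) + \
            _random_dna(rng, 2000)
        hits = find_hits(mito.barcode, ScaffoldSet([Scaffold("s", "", scaffold)]))
        assert len(hits) == 1 and hits[0].strand == "-"
        assert abs(hits[0].s_start - 2000) <= 5

    def test_diverged_short_copy_detected(self, mito):
        rng = np.random.default_rng(6)
        piece = mito.barcode[100:220]
        mutated, _ = mutate_segment(piece, 0.25, seed=7)
        scaffold = _random_dna(rng, 4000) + mutated + _random_dna(rng, 4000)
        hits = find_hits(mito.barcode, ScaffoldSet([Scaffold("s", "", scaffold)]))
        assert len(hits) == 1
        assert hits[0].identity >= 0.60

    def test_no_hits_in_random_scaffolds(self, mito):
        rng = np.random.default_rng(8)
        ss = ScaffoldSet([Scaffold(f"r{i}", "", _random_dna(rng, 5000))
                          for i in range(100)])
        hits = find_hits(mito.barcode, ss)
        assert len(hits) <= 1  # <= 0.1 false hits expected per Mb

    def test_hit_score_bounded_by_oracle(self, small_dataset):
        ds = small_dataset
        hits = find_hits(ds.query, ds.assembly)
        assert hits
        for h in hits[:10]:
            scaffold = ds.assembly[h.scaffold_id].sequence
            lo, hi = max(0, h.s_start - 20), min(len(scaffold), h.s_end + 20)
            window = scaffold[lo:hi]
            if h.strand == "-":
                window = revcomp(window)
            oracle = smith_waterman(ds.query, window)
            assert h.score <= oracle.score

    def test_query_length_precondition(self):
        ss = ScaffoldSet([Scaffold("s", "", "ACGT" * 100)])
        with pytest.raises(ValueError):
            find_hits("ACGT" * 10, ss)
        with pytest.raises(ValueError):
            find_hits("A" * 2001, ss)

    def test_empty_scaffold_set(self):
        assert find_hits("ACGT" * 50, ScaffoldSet()) == []


class TestMergeOverlapping:
    def _hit(self, s_start, s_end, score, strand="+"):
        return LocalHit("q", "s", 0, s_end - s_start, s_start, s_end, strand,
                        s_end - s_start, s_end - s_start, 1.0, score, 1e-9,
                        "A", "A")

    def test_majority_overlap_keeps_higher_score(self):
        merged = merge_overlapping_hits(
            [self._hit(100, 300, 50), self._hit(120, 310, 80)])
        assert len(merged) == 1 and merged[0].score == 80

    def test_small_overlap_keeps_both(self):
        merged = merge_overlapping_hits(
            [self._hit(100, 300, 50), self._hit(220, 420, 80)])
        assert len(merged) == 2

    def test_different_strands_not_merged(self):
        merged = merge_overlapping_hits(
            [self._hit(100, 300, 50), self._hit(100, 300, 80, strand="-")])
        assert len(merged) == 2


class TestKarlinCalibration:
    def test_fit_range_and_determinism(self):
        lam1, k1 = calibrate_karlin(seed=0, n_sim=40, seq_len=200)
        lam2, k2 = calibrate_karlin(seed=0, n_sim=40, seq_len=200)
        assert 0.2 < lam1 < 1.5
        assert (lam1, k1) == (lam2, k2)

    def test_tail_prediction_within_factor_two(self):
        from numtrisk.homsearch import _dp_score
        sc = AlignmentScoring()
        lam, K = calibrate_karlin(seed=1, n_sim=80, seq_len=200)
        rng = np.random.default_rng(99)
        scores = [
            _dp_score(rng.integers(0, 4, 200).astype(np.uint8),
                      rng.integers(0, 4, 200).astype(np.uint8),
                      sc.match, sc.mismatch,
                      sc.gap_open + sc.gap_extend, sc.gap_extend)
            for _ in range(120)
        ]
        s = int(np.median(scores))
        pred = min(1.0, K * 200 * 200 * np.exp(-lam * s))
        emp = np.mean([x >= s for x in scores])
        assert pred / 2 <= emp <= pred * 2 + 0.1
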