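import numpy as np
import pytest

from numtrisk.homsearch import LocalHit, find_hits, smith_waterman
from numtrisk.numtclass import (CATEGORY_BOUNDS, assign_category, classify,
                                classify_hits, collapse_gap_pairs,
                                detect_frameshift, detect_premature_stop,
                                evaluate_against_truth, filter_residual_hits)
from numtrisk.simgen import GroundTruthNumt, mutate_segment


def _hit(q_span=658, identity=1.0, s_start=0, length=None, scaffold="s"):
    length = length if length is not None else q_span
    return LocalHit("q", scaffold, 0, q_span, s_start, s_start + length, "+",
                    max(q_span, length), int(identity * q_span), identity,
                    100, 1e-10, "A" * q_span, "A" * q_span)


class TestFilterResidualHits:
    def test_full_coverage_high_identity_removed(self):
        assert filter_residual_hits([_hit(658, 0.995)]) == []

    def test_within_one_bp_coverage_removed(self):
        assert filter_residual_hits([_hit(657, 1.0)]) == []

    def test_full_coverage_lower_identity_retained(self):
        assert len(filter_residual_hits([_hit(658, 0.98)])) == 1

    def test_partial_coverage_high_identity_retained(self):
        assert len(filter_residual_hits([_hit(400, 1.0)])) == 1


class TestAssignCategory:
    @pytest.mark.parametrize("length,expected", [
        (99, None), (100, "C1"), (150, "C1"), (151, "C2"), (300, "C2"),
        (301, "C3"), (450, "C3"), (451, "C4"), (600, "C4"), (601, "C5"),
        (658, "C5"), (754, "C5"), (2000, "C5"),
    ])
    def test_boundaries(self, length, expected):
        assert assign_category(length) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            assign_category(-1)


class TestDetectFrameshift:
    def test_three_bp_deletion_in_frame(self):
        q = "ACGTTTACGTACGTACGT"
        s = "ACGTTT---TACGTACGT".replace("T---T", "---TA")  # clean 3-gap
        q = "ACGTACGTACGTACGTAC"
        s = "ACGTACG---GTACGTAC"
        assert detect_frameshift(q, s) is False

    def test_single_insertion_shifts_frame(self):
        q = "ACGTACG-ACGTACGTA"
        s = "ACGTACGTACGTACGTA"
        assert detect_frameshift(q, s) is True

    def test_compensating_gaps_each_counted(self):
        # 2 bp gap then 1 bp gap: net frame restored, still a frameshift
        q = "ACGTACGT--GTACAGTACGTACA"
        s = "ACGTACGTACGTAC-GTACGTACA"
        assert detect_frameshift(q, s) is True

    def test_end_guard_ignores_terminal_gap(self):
        q = "AC-TACGTACGTACGTACGT"
        s = "ACGTACGTACGTACGTACGT"
        assert detect_frameshift(q, s) is True
        assert detect_frameshift(q, s, end_guard=4) is False


class TestCollapseGapPairs:
    def test_compensating_pair_removed(self):
        q = "ACGTAC-TTGCACGT"
        s = "ACGTACGTT-CACGT"
        cq, cs = collapse_gap_pairs(q, s)
        assert "-" not in cq and "-" not in cs
        assert cq.replace("-", "") == q.replace("-", "")
        assert cs.replace("-", "") == s.replace("-", "")

    def test_distant_gaps_untouched(self):
        q = "AC-TACGTACGTACGTACGTACGTACG"
        s = "ACGTACGTACGTACGTACGTACGT-CG"
        assert collapse_gap_pairs(q, s, max_sep=10) == (q, s)

    def test_unequal_lengths_untouched(self):
        q = "ACGT--ACGTACG"
        s = "ACGTCCAC-TACG"
        assert collapse_gap_pairs(q, s) == (q, s)


def _codon_alignment(codons, frame_offset=0, q_start=0):
    """Build a gap-free alignment whose subject is the given codons."""
    s = "".join(codons)
    q = "A" * len(s)
    return q, s


class TestDetectPrematureStop:
    def test_internal_stop_found(self):
        codons = ["ATT"] * 49 + ["TAA"] + ["ATT"] * 150
        q, s = _codon_alignment(codons)
        assert detect_premature_stop(q, s, 0, 0) is True

    def test_aga_is_not_a_stop_in_invertebrate_mito_code(self):
        codons = ["ATT"] * 20 + ["AGA", "AGG", "TGA"] + ["ATT"] * 20
        q, s = _codon_alignment(codons)
        assert detect_premature_stop(q, s, 0, 0) is False

    def test_terminal_stop_not_premature(self):
        codons = ["ATT"] * 60 + ["TAA"]
        q, s = _codon_alignment(codons)
        assert detect_premature_stop(q, s, 0, 0) is False

    def test_frame_offset_changes_reading(self):
        # 'TAA' present only if translation starts at phase 0
        s = "ATTTAAATTATTATT"
        q = "A" * len(s)
        assert detect_premature_stop(q, s, 0, 0) is True
        # phase 2 for base 0 -> first codon starts at position 1: reads
        # TTT, AAA, TTA, TTA -> no stop codon in frame
        assert detect_premature_stop(q, s, 0, 2) is False

    def test_reanchors_after_frameshift(self):
        # stop codon downstream of a 1 bp subject insertion is still seen
        # because translation re-anchors on the query frame
        left = ["ATT"] * 10
        right = ["ATT"] * 5 + ["TAA"] + ["ATT"] * 10
        q = "A" * 30 + "-" + "A" * 48
        s = "".join(left) + "G" + "".join(right)
        assert detect_premature_stop(q, s, 0, 0) is True

    def test_too_short_span_false(self):
        assert detect_premature_stop("AAA", "TAA", 0, 0) is False


class TestClassify:
    def _planted_hit(self, mito, length, d, seed, with_deletion=False):
        src = mito.barcode[:length]
        mutated, _ = mutate_segment(src, d, seed=seed)
        if with_deletion:
            mutated = mutated[:length // 2] + mutated[length // 2 + 1:]
        flank = "ACGT" * 10
        h = smith_waterman(mito.barcode, flank + mutated + flank)
        return h

    def test_planted_c3_divergence_recovered(self, mito):
        h = self._planted_hit(mito, 400, 0.08, seed=11)
        rec = classify(h, mito.frame_offset)
        assert rec.category == "C3"
        assert abs(rec.divergence - 8.0) <= 0.5
        assert not rec.has_frameshift

    def test_deletion_marks_frameshift_and_ipsc(self, mito):
        h = self._planted_hit(mito, 658, 0.05, seed=12, with_deletion=True)
        rec = classify(h, mito.frame_offset)
        assert rec.has_frameshift and rec.has_ipsc
        assert not rec.is_c5_star

    def test_full_length_ipsc_free_diverged_is_c5_star(self, c5star_pair):
        ds = c5star_pair
        hits = filter_residual_hits(find_hits(ds.query, ds.assembly))
        recs = classify_hits(hits, ds.frame_offset)
        assert len(recs) == 2
        assert all(r.is_c5_star for r in recs)
        assert sorted(round(r.divergence) for r in recs) == [5, 10]

    def test_low_divergence_not_c5_star(self, mito):
        h = self._planted_hit(mito, 658, 0.015, seed=13)
        rec = classify(h, mito.frame_offset)
        if not rec.has_ipsc:  # mutation could create a stop by chance
            assert not rec.is_c5_star  # divergence <= 2%


class TestEvaluateAgainstTruth:
    def _truth(self, pos, length, scaffold="s", **kw):
        defaults = dict(planted_divergence=0.1, indels=[],
                        has_frameshift=False, has_planted_stop=False,
                        copy_group="g", strand="+")
        defaults.update(kw)
        return GroundTruthNumt(id=f"t{pos}", scaffold_id=scaffold,
                               insert_position=pos,
                               source_interval=(0, length),
                               planted_length=length, **defaults)

    def _record(self, pos, length, scaffold="s"):
        return classify(_hit(q_span=length, identity=0.9, s_start=pos,
                             scaffold=scaffold), 0)

    def test_perfect_detection(self):
        truth = [self._truth(i * 1000, 300) for i in range(50)]
        recs = [self._record(i * 1000, 300) for i in range(50)]
        m = evaluate_against_truth(recs, truth)
        assert m.recall == 1.0 and m.precision == 1.0

    def test_one_spurious_record(self):
        truth = [self._truth(i * 1000, 300) for i in range(50)]
        recs = [self._record(i * 1000, 300) for i in range(50)]
        recs.append(self._record(90000, 200))
        m = evaluate_against_truth(recs, truth)
        assert m.precision == pytest.approx(50 / 51)
        assert m.recall == 1.0

    def test_low_overlap_not_matched(self):
        truth = [self._truth(1000, 300)]
        recs = [self._record(1200, 300)]  # 100/300 overlap
        m = evaluate_against_truth(recs, truth)
        assert m.n_matched == 0

    def test_query_cap_matches_long_insertions(self):
        truth = [self._truth(1000, 1500)]
        recs = [self._record(1400, 658)]
        assert evaluate_against_truth(recs, truth).n_matched == 0
        assert evaluate_against_truth(recs, truth,
                                      query_len=658).n_matched == 1
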