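import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from numtrisk.errors import SizingError
from numtrisk.simgen import (BARCODE_LENGTH, CopyPolicy, IndelPolicy,
                             StopPolicy, add_residual_mito_scaffolds,
                             generate_assembly, generate_mitogenome,
                             mutate_segment, plant_numts, revcomp,
                             sample_numt_length, simulate_dataset,
                             truncated_pareto_cdf, truncated_pareto_quantile,
                             uniform_divergence_sampler, _scan_premature_stop)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class TestMitogenome:
    def test_invariants(self, mito):
        b0, b1 = mito.barcode_interval
        c0, c1 = mito.coi_interval
        assert b1 - b0 == BARCODE_LENGTH
        assert c0 <= b0 and b1 <= c1
        names = [g[0] for g in mito.genes]
        assert len(names) == 15 and len(set(names)) == 15
        assert sum(n.startswith("rrn") for n in names) == 2

    def test_coi_translation_has_no_internal_stop(self, mito):
        prot = str(Seq(mito.coi).translate(table=mito.code_table))
        assert "*" not in prot[:-1]

    def test_barcode_frame_offset_phase(self, mito):
        assert (mito.barcode_interval[0] - mito.coi_interval[0]) % 3 == \
               mito.frame_offset

    def test_determinism(self):
        a = generate_mitogenome(seed=3, length=14500, coi_length=1536)
        b = generate_mitogenome(seed=3, length=14500, coi_length=1536)
        assert a.sequence == b.sequence and a.genes == b.genes

    @pytest.mark.parametrize("kwargs", [
        {"length": 11000}, {"coi_length": 1537}, {"coi_length": 600},
        {"length": 13263 - 1536 + 900 - 1, "coi_length": 900},
    ])
    def test_sizing_errors(self, kwargs):
        with pytest.raises(SizingError):
            generate_mitogenome(seed=1, **{"length": 15000,
                                           "coi_length": 1536, **kwargs})


class TestMutateSegment:
    def test_zero_divergence_is_identity(self):
        seq = "ACGT" * 165  # 660 bp
        out, pos = mutate_segment(seq, 0.0, seed=1)
        assert out == seq and len(pos) == 0

    def test_exact_substitution_count(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 658))
        out, pos = mutate_segment(seq, 0.10, seed=2)
        assert len(pos) == 66  # round(0.10 * 658)
        ham = sum(a != b for a, b in zip(seq, out))
        assert ham == 66
        assert all(seq[p] != out[p] for p in pos)

    def test_transition_fraction_binomial(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 6000))
        out, pos = mutate_segment(seq, 0.12, kappa=2.0, seed=3)
        n_sub = len(pos)
        ts = sum((seq[p], out[p]) in TRANSITIONS for p in pos)
        # 3 sigma of binomial(n_sub, 2/3)
        sd = (n_sub * (2 / 3) * (1 / 3)) ** 0.5
        assert abs(ts - n_sub * 2 / 3) <= 3 * sd

    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError):
            mutate_segment("ACGT" * 30, 0.5, seed=1)


class TestLengthSampler:
    def test_median_quantile(self):
        assert round(truncated_pareto_quantile(0.5, 100, 1600)) == 188

    def test_lower_truncation(self):
        assert truncated_pareto_quantile(0.0, 100, 1600) == 100

    def test_goodness_of_fit(self):
        rng = np.random.default_rng(7)
        draws = np.array([sample_numt_length(rng, 100, 1600)
                          for _ in range(10_000)], dtype=float)
        # KS against the truncated Pareto CDF (continuous model; integer
        # rounding adds at most ~1/188 of displacement)
        res = stats.kstest(draws, lambda x: np.clip(
            truncated_pareto_cdf(x, 100, 1600), 0, 1))
        assert res.pvalue > 0.01

    def test_precondition(self):
        with pytest.raises(ValueError):
            sample_numt_length(1, 10, 5)


class TestPlantNumts:
    def test_zero_numts_unchanged(self, mito):
        asm = generate_assembly(2, n_scaffolds=2, scaffold_length=5000)
        out, truth = plant_numts(asm, mito, 0,
                                 uniform_divergence_sampler(0.1, 0.1), seed=1)
        assert truth == []
        assert [r.sequence for r in out] == [r.sequence for r in asm]

    def test_insertions_present_verbatim_and_flags(self, small_dataset):
        ds = small_dataset
        for t in ds.truth:
            seg = ds.assembly[t.scaffold_id].sequence[
                t.insert_position:t.insert_position + t.planted_length]
            assert len(seg) == t.planted_length
            oriented = revcomp(seg) if t.strand == "-" else seg
            # gap-free plantings: observed p-distance == planted d (+-1 site)
            if not t.indels:
                src = ds.mitogenome.sequence[t.source_interval[0]:
                                             t.source_interval[1]]
                ham = sum(a != b for a, b in zip(src, oriented))
                # a forced premature stop may rewrite up to 3 extra sites
                slack = 4 if t.has_planted_stop else 1
                assert abs(ham - round(t.planted_divergence * len(src))) <= slack
            assert t.has_frameshift == any(l % 3 for _p, l, _i in t.indels)
            # for gap-free plantings the recorded stop flag matches a
            # rescan of the planted segment (indels shift the frame, so the
            # flag is recorded pre-indel there)
            if not t.indels:
                assert t.has_planted_stop == _scan_premature_stop(
                    oriented, t.source_interval[0], ds.mitogenome)

    def test_no_indel_policy_means_no_frameshifts(self, mito):
        asm = generate_assembly(3, n_scaffolds=2, scaffold_length=40000)
        _, truth = plant_numts(asm, mito, 50,
                               uniform_divergence_sampler(0.03, 0.25), seed=4)
        assert len(truth) == 50
        assert not any(t.has_frameshift for t in truth)
        assert all(t.indels == [] for t in truth)

    def test_ten_copies_share_group(self, ten_copies):
        assert len(ten_copies.truth) == 10
        assert len({t.copy_group for t in ten_copies.truth}) == 1
        segs = set()
        for t in ten_copies.truth:
            seg = ten_copies.assembly[t.scaffold_id].sequence[
                t.insert_position:t.insert_position + t.planted_length]
            segs.add(seg if t.strand == "+" else revcomp(seg))
        assert len(segs) == 1  # identical copies

    def test_determinism_byte_identical(self, tmp_path):
        from numtrisk.cli import write_dataset
        for sub in ("a", "b"):
            write_dataset(simulate_dataset(seed=99, n_numts=10),
                          tmp_path / sub)
        for name in ("assembly.fasta", "truth.tsv", "mitogenome.fasta"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()


class TestResidualScaffolds:
    def test_labelled_header_token(self, mito):
        asm = generate_assembly(2, n_scaffolds=1, scaffold_length=5000)
        out = add_residual_mito_scaffolds(asm, mito, labelled=True,
                                          length=11300, seed=1)
        new = [r for r in out if r.id not in asm.ids]
        assert len(new) == 1 and "mitochondrion" in new[0].description
        assert len(new[0]) == 11300

    def test_unlabelled_full_copy(self, mito):
        asm = generate_assembly(2, n_scaffolds=1, scaffold_length=5000)
        out = add_residual_mito_scaffolds(asm, mito, labelled=False,
                                          length=15000, seed=1)
        new = [r for r in out if r.id not in asm.ids][0]
        assert "mitochondri" not in new.description.lower()
        assert new.sequence == mito.sequence

    def test_longest_allowed(self, mito):
        asm = generate_assembly(2, n_scaffolds=1, scaffold_length=5000)
        out = add_residual_mito_scaffolds(asm, mito, labelled=True,
                                          length=45500, seed=1)
        assert max(len(r) for r in out) == 45500

    def test_length_bounds(self, mito):
        asm = generate_assembly(2, n_scaffolds=1, scaffold_length=5000)
        with pytest.raises(ValueError):
            add_residual_mito_scaffolds(asm, mito, True, 100, seed=1)
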