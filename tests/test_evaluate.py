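"""Prediction metrics, window evidence and discovery ROC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesr.evaluate import (
    auc,
    bias_slope,
    mixture_region_evidence,
    pearson_accuracy,
    predict,
    region_evidence,
    roc_curve_regions,
    single_snp_gwas,
    split_train_validation,
)
from scipy import stats


class TestPredict:
    def test_zero_effects_give_constant(self):
        W = np.random.default_rng(0).standard_normal((5, 3))
        np.testing.assert_allclose(predict(W, 2.5, np.zeros(3)), 2.5)

    def test_single_snp_identity(self):
        w = np.arange(4.0).reshape(4, 1)
        np.testing.assert_allclose(predict(w, 1.0, np.array([1.0])), 1.0 + w[:, 0])

    def test_mismatched_panel_rejected(self):
        with pytest.raises(ValueError, match="features|columns"):
            predict(np.zeros((3, 4)), 0.0, np.zeros(5))


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        y = np.array([1.0, 2.0, 4.0])
        assert pearson_accuracy(y, y) == pytest.approx(1.0)
        assert pearson_accuracy(y, -y) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert pearson_accuracy(np.array([0, 1, 2.0]), np.array([0, 2, 1.0])) == \
            pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_accuracy(np.array([1, 1, 1.0]), np.array([1, 2, 3.0]))


class TestAuc:
    def test_perfect_separation(self):
        assert auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_all_ties_is_half(self):
        assert auc(np.array([0, 1, 0, 1]), np.zeros(4)) == 0.5

    def test_three_of_four_concordant(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.4, 0.5, 0.1])
        assert auc(y, s) == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.ones(4), np.arange(4.0))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 60))
    def test_matches_brute_force_pair_count(self, seed, n):
        """AUC equals the normalized Mann-Whitney U by explicit pair counting."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = rng.choice(np.linspace(0, 1, 7), size=n)  # ties likely
        cases, controls = s[y == 1], s[y == 0]
        wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
        assert auc(y, s) == pytest.approx(wins / (len(cases) * len(controls)))


class TestBiasSlope:
    def test_identity_and_half_scale(self):
        y = np.array([0.0, 1, 2, 3])
        assert bias_slope(y, y) == pytest.approx(1.0)
        assert bias_slope(y, y / 2) == pytest.approx(2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bias_slope(np.arange(4.0), np.ones(4))


class TestSplit:
    def test_sizes_and_exhaustiveness(self):
        train, val = split_train_validation(10, rng=np.random.default_rng(0))
        assert len(train) == 8 and len(val) == 2
        assert sorted(np.concatenate([train, val]).tolist()) == list(range(10))

    def test_disjoint(self):
        train, val = split_train_validation(23, rng=np.random.default_rng(1))
        assert not set(train) & set(val)

    def test_seeds_differ(self):
        a, _ = split_train_validation(100, rng=np.random.default_rng(1))
        b, _ = split_train_validation(100, rng=np.random.default_rng(2))
        assert not np.array_equal(a, b)


class TestRegionEvidence:
    def test_single_snp_window_sums_large_class_pips(self):
        pips = np.array([[0.2, 0.3, 0.4, 0.1]])
        ev = mixture_region_evidence(pips)
        assert ev[0] == pytest.approx(0.5)  # classes 1e-3 and 1e-2
        regions = region_evidence(ev, ["1"], [100], window_bp=250_000, offsets=(0,))
        assert regions[0].table["evidence"].iloc[0] == pytest.approx(0.5)

    def test_six_snp_region_accumulates(self):
        # six SNPs whose non-null inclusion probabilities sum to 1.2
        pips = np.tile([0.8, 0.0, 0.1, 0.1], (6, 1))
        ev = mixture_region_evidence(pips)
        regions = region_evidence(ev, ["9"] * 6, np.arange(6) * 1000 + 1,
                                  window_bp=44_000, offsets=(0,))
        assert regions[0].table["evidence"].iloc[0] == pytest.approx(1.2)

    def test_windows_partition_each_offset(self):
        pos = np.arange(1, 1_000_001, 50_000)
        ev = np.ones(len(pos))
        regions = region_evidence(ev, ["1"] * len(pos), pos)
        for r in regions:
            # non-overlapping and exhaustive: evidence sums preserved
            assert r.table["evidence"].sum() == pytest.approx(len(pos))
            spans = r.table.sort_values("start")
            assert np.all(np.diff(spans["start"].to_numpy()) >= 250_000)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            region_evidence(np.ones(2), ["1", "1"], [500, 100])

    def test_min_p_aggregation_for_single_snp_gwas(self):
        logp = np.array([1.0, 3.0, 2.0])
        regions = region_evidence(logp, ["1"] * 3, [10, 20, 30],
                                  window_bp=100, offsets=(0,), aggregate="max")
        assert regions[0].table["evidence"].iloc[0] == 3.0


class TestRoc:
    def causal_top_two(self):
        ev = np.array([3.0, 2.0, 1.0, 0.0])
        causal = np.array([True, True, False, False])
        return region_evidence(ev, ["1"] * 4, [1, 300_000, 600_000, 900_000],
                               causal, window_bp=250_000, offsets=(0,))

    def test_hand_enumerated_curve(self):
        fpr, tpr = roc_curve_regions(self.causal_top_two())
        pts = set(zip(fpr.round(6), tpr.round(6)))
        assert (0.0, 0.0) in pts and (0.0, 0.5) in pts and (0.0, 1.0) in pts \
            and (1.0, 1.0) in pts

    def test_monotone_nondecreasing(self):
        fpr, tpr = roc_curve_regions(self.causal_top_two())
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_invariant_to_monotone_transform(self):
        regions = self.causal_top_two()
        fpr1, tpr1 = roc_curve_regions(regions)
        for r in regions:
            r.table["evidence"] = np.exp(r.table["evidence"])
        fpr2, tpr2 = roc_curve_regions(regions)
        np.testing.assert_allclose(fpr1, fpr2)
        np.testing.assert_allclose(tpr1, tpr2)

    def test_uniform_evidence_degenerates(self):
        regions = region_evidence(np.ones(4), ["1"] * 4,
                                  [1, 300_000, 600_000, 900_000],
                                  np.array([True, False, False, False]),
                                  window_bp=250_000, offsets=(0,))
        fpr, tpr = roc_curve_regions(regions)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)

    def test_no_causal_windows_rejected(self):
        regions = region_evidence(np.ones(2), ["1", "1"], [1, 300_000])
        with pytest.raises(ValueError):
            roc_curve_regions(regions)


class TestDiscoveryOnFittedModel:
    def test_large_effect_windows_outrank_median(self):
        """Windows holding the large-effect causal SNPs score above the
        median window evidence after a mixture-model fit at high h2."""
        from bayesr.model import ChainConfig
        from bayesr.sampler import run_chain
        from bayesr.simulate import ArchitectureSpec, simulate_dataset
        from bayesr.summarize import pips as pips_of

        rng = np.random.default_rng(606)
        spec = ArchitectureSpec(class_counts=(4, 12, 60), h2_target=0.8)
        _, std, y, truth = simulate_dataset(500, 800, spec, rng, n_chromosomes=4)
        cfg = ChainConfig(n_iter=2500, burn_in=1000, thin=3, seed=707)
        s = run_chain(std.W, y, config=cfg, chrom=std.snps.chrom)

        ev = mixture_region_evidence(pips_of(s))
        causal_mask = np.zeros(800, dtype=bool)
        causal_mask[truth.causal_indices] = True
        regions = region_evidence(ev, std.snps.chrom, std.snps.pos, causal_mask,
                                  window_bp=250_000, offsets=(0, 125_000))
        # class labels are draws: a "large-effect" class member can realize a
        # near-zero beta; rank by realized effect size instead
        top = np.argsort(-np.abs(truth.true_effects))[:3]
        large = set(truth.causal_indices[top])
        for r in regions:
            med = r.table["evidence"].median()
            # locate windows containing the large-effect SNPs
            for j in large:
                c, bp = std.snps.chrom[j], std.snps.pos[j]
                row = r.table[(r.table["chrom"] == c) & (r.table["start"] <= bp)
                              & (bp < r.table["end"])]
                assert row["evidence"].iloc[0] > med


class TestSingleSnpGwas:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        W = rng.standard_normal((200, 400))
        y = rng.standard_normal(200)
        res = single_snp_gwas(W, y)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.001

    def test_perfect_association(self):
        rng = np.random.default_rng(4)
        W = rng.standard_normal((50, 3))
        res = single_snp_gwas(W, W[:, 1])
        assert res["p"][1] < 1e-30
        assert res["slope"][1] == pytest.approx(1.0)

    def test_slope_is_least_squares(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        res = single_snp_gwas(W, y)
        Wc = W - W.mean(0)
        yc = y - y.mean()
        expect = (Wc.T @ yc) / np.einsum("ij,ij->j", Wc, Wc)
        np.testing.assert_allclose(res["slope"], expect, atol=1e-12)
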