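"""Spike-in size factors, the NB Wald test, BH adjustment, FDR classes."""

import numpy as np
import pandas as pd
import pytest

from propause import (CountMatrix, bh_adjust, classify_features, nb_wald_test,
                      run_differential, spike_size_factors)


def make_matrix(counts_by_sample, conditions, spikes):
    samples = pd.DataFrame({
        "condition": conditions,
        "replicate": [1] * len(conditions),
        "spike_total": spikes,
        "primary_total": [sum(v) for v in counts_by_sample.values()],
    }, index=list(counts_by_sample))
    return CountMatrix(pd.DataFrame(counts_by_sample), samples)


class TestSpikeSizeFactors:
    def test_equal_totals_identity(self):
        assert spike_size_factors([1000, 1000]).tolist() == [1.0, 1.0]

    def test_geometric_mean_example(self):
        s = spike_size_factors([1000, 2000])
        assert s.to_numpy() == pytest.approx([0.70711, 1.41421], abs=5e-6)
        assert np.log(s).sum() == pytest.approx(0.0, abs=1e-12)

    def test_permutation_equivariance(self):
        s = spike_size_factors(pd.Series([500, 1500, 4000], index=list("abc")))
        sp = spike_size_factors(pd.Series([4000, 500, 1500], index=list("cab")))
        assert s.sort_index().equals(sp.sort_index())

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="pseudo-count|exclude"):
            spike_size_factors([1000, 0])


class TestNbWaldTest:
    def test_exact_null_symmetry(self):
        cm = make_matrix({"a1": [10], "a2": [10], "b1": [10], "b2": [10]},
                         ["ctl", "ctl", "trt", "trt"], [100] * 4)
        res = nb_wald_test(cm, spike_size_factors(cm.samples.spike_total),
                           ("trt", "ctl"), dispersion=0.05)
        assert res["log2fc"].iloc[0] == 0.0
        assert res["wald_p"].iloc[0] == 1.0

    def test_all_zero_feature_untested(self):
        cm = make_matrix({"a1": [0, 5], "a2": [0, 6], "b1": [0, 7], "b2": [0, 8]},
                         ["ctl", "ctl", "trt", "trt"], [100] * 4)
        res = nb_wald_test(cm, spike_size_factors(cm.samples.spike_total),
                           ("trt", "ctl"), dispersion=0.05)
        assert np.isnan(res["wald_p"].iloc[0])
        assert np.isfinite(res["wald_p"].iloc[1])

    def test_poisson_limit_matches_glm_oracle(self):
        """alpha=0, (4,6) vs (18,22): log2fc exactly 2, Wald p equal to an
        independent Poisson GLM fit (statsmodels)."""
        import statsmodels.api as sm
        cm = make_matrix({"a1": [4], "a2": [6], "b1": [18], "b2": [22]},
                         ["ctl", "ctl", "trt", "trt"], [100] * 4)
        res = nb_wald_test(cm, spike_size_factors(cm.samples.spike_total),
                           ("trt", "ctl"), dispersion=0.0)
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-12)
        X = sm.add_constant(np.array([0., 0., 1., 1.]))
        fit = sm.GLM([4, 6, 18, 22], X, family=sm.families.Poisson()).fit()
        assert res["log2fc"].iloc[0] == pytest.approx(fit.params[1] / np.log(2))
        assert res["wald_p"].iloc[0] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_non_integer_counts_error(self):
        cm = make_matrix({"a1": [1.5], "a2": [2], "b1": [3], "b2": [4]},
                         ["ctl", "ctl", "trt", "trt"], [100] * 4)
        with pytest.raises(ValueError, match="integer"):
            nb_wald_test(cm, spike_size_factors(cm.samples.spike_total),
                         ("trt", "ctl"))

    def test_log2fc_invariant_to_sample_rescaling(self):
        """Multiplying one sample's counts and its spike total by k leaves
        every log2 fold change unchanged (spike normalization recovery)."""
        rng = np.random.default_rng(5)
        base = rng.poisson(50, size=(30, 4))
        spikes = [900, 1100, 1000, 950]
        conds = ["ctl", "ctl", "trt", "trt"]
        cols = ["a1", "a2", "b1", "b2"]
        cm1 = make_matrix(dict(zip(cols, base.T)), conds, spikes)
        scaled = base.copy()
        scaled[:, 0] *= 3
        spikes2 = [2700, 1100, 1000, 950]
        cm2 = make_matrix(dict(zip(cols, scaled.T)), conds, spikes2)
        r1 = nb_wald_test(cm1, spike_size_factors(pd.Series(spikes, index=cols)),
                          ("trt", "ctl"))
        r2 = nb_wald_test(cm2, spike_size_factors(pd.Series(spikes2, index=cols)),
                          ("trt", "ctl"))
        assert r1["log2fc"].to_numpy() == pytest.approx(
            r2["log2fc"].to_numpy(), abs=1e-6)


class TestBhAdjust:
    def test_step_up_worked_example(self):
        fdr = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert fdr.to_numpy() == pytest.approx([0.04] * 4)

    def test_single_p_identity(self):
        assert bh_adjust([0.2]).iloc[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_excluded_from_m(self):
        fdr = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(fdr.iloc[1])
        # m = 2 tested features, not 3
        assert fdr.iloc[0] == pytest.approx(0.02)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_hand_step_up(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        fdr = bh_adjust(p).to_numpy()
        order = np.argsort(p)
        expected = np.empty_like(p)
        m = len(p)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            expected[order[rank]] = running
        assert fdr == pytest.approx(expected)


class TestClassifyFeatures:
    @pytest.mark.parametrize("log2fc,fdr,expected", [
        (1.2, 0.05, "up"),
        (-0.8, 0.02, "down"),
        (0.1, 0.7, "unchanged"),
        (0.5, 0.3, "indeterminate"),
        (np.nan, np.nan, "untested"),
    ])
    def test_threshold_classes(self, log2fc, fdr, expected):
        res = pd.DataFrame({"log2fc": [log2fc], "fdr": [fdr]})
        assert classify_features(res).iloc[0] == expected


def test_run_differential_library_vs_spike_on_global_shift():
    """A uniform 4x treatment shift is visible under spike normalization and
    cancelled by library-size normalization."""
    rng = np.random.default_rng(9)
    base = rng.poisson(100, size=(40, 2))
    treated = rng.poisson(400, size=(40, 2))
    counts = pd.DataFrame(np.hstack([base, treated]),
                          columns=["c1", "c2", "t1", "t2"])
    samples = pd.DataFrame({
        "condition": ["ctl", "ctl", "trt", "trt"],
        "replicate": [1, 2, 1, 2],
        "spike_total": [1000] * 4,
        "primary_total": counts.sum(axis=0).tolist(),
    }, index=counts.columns)
    cm = CountMatrix(counts, samples)
    spike = run_differential(cm, ("trt", "ctl"), normalization="spike")
    lib = run_differential(cm, ("trt", "ctl"), normalization="library")
    assert spike["log2fc"].median() == pytest.approx(2.0, abs=0.2)
    assert lib["log2fc"].median() == pytest.approx(0.0, abs=0.2)
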