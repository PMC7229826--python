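"""Peak merging, blacklist filtering, peak-gene assignment, z-scores,
state overlap, enhancer classes, coupling and IP/input ratios."""

import numpy as np
import pandas as pd
import pytest

from propause import (GeneModel, Interval, assign_peaks_to_genes,
                      classify_enhancers, enrichment_zscores, fc_correlation,
                      filter_blacklist, log2_ip_over_input,
                      merge_overlapping_peaks, state_overlap_fraction,
                      threshold_gain_set)

from conftest import make_track


def brute_force_merge(intervals):
    """O(n^2) overlap-closure oracle."""
    groups = []
    for iv in intervals:
        hit = [g for g in groups
               if any(iv.chrom == o.chrom and iv.start < o.end and o.start < iv.end
                      for o in g)]
        merged = [iv] + [o for g in hit for o in g]
        groups = [g for g in groups if g not in hit] + [merged]
    return sorted((g[0].chrom, min(o.start for o in g), max(o.end for o in g))
                  for g in groups)


class TestMergeOverlappingPeaks:
    def test_simple_overlap(self):
        m = merge_overlapping_peaks([[Interval("c", 100, 200)],
                                     [Interval("c", 150, 250)]])
        assert [(r.start, r.end) for r in m] == [(100, 250)]

    def test_book_ended_not_merged(self):
        m = merge_overlapping_peaks([[Interval("c", 100, 200)],
                                     [Interval("c", 200, 300)]])
        assert [(r.start, r.end) for r in m] == [(100, 200), (200, 300)]

    def test_chained_overlaps_collapse(self):
        m = merge_overlapping_peaks([[Interval("c", 0, 50), Interval("c", 40, 90),
                                      Interval("c", 80, 120)]])
        assert [(r.start, r.end) for r in m] == [(0, 120)]

    def test_provenance_recorded(self):
        m = merge_overlapping_peaks([[Interval("c", 0, 50, name="p1")],
                                     [Interval("c", 30, 80, name="p2")]])
        assert set(m[0].sources) == {(0, "p1"), (1, "p2")}

    def test_matches_brute_force_oracle(self):
        """Exact agreement with the O(n^2) closure on 500 random sets."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(1, 15))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 120))
                ivs.append(Interval(rng.choice(["c1", "c2"]), s,
                                    s + int(rng.integers(1, 30))))
            got = sorted((r.chrom, r.start, r.end)
                         for r in merge_overlapping_peaks([ivs]))
            assert got == brute_force_merge(ivs)


class TestFilterBlacklist:
    def test_overlapping_peak_dropped(self):
        kept = filter_blacklist([Interval("c", 10, 50)], [Interval("c", 40, 60)])
        assert kept == []

    def test_book_ended_peak_retained(self):
        peaks = [Interval("c", 10, 40)]
        assert filter_blacklist(peaks, [Interval("c", 40, 60)]) == peaks

    def test_empty_blacklist_identity(self):
        peaks = [Interval("c", 10, 40), Interval("c", 100, 140)]
        assert filter_blacklist(peaks, []) == peaks


@pytest.fixture
def two_genes():
    return {
        "gA": GeneModel(gene_id="gA", chrom="c", strand="+", tss=5000, tes=8999,
                        cds_length=4000, length=4000),
        "gB": GeneModel(gene_id="gB", chrom="c", strand="-", tss=20000, tes=16001,
                        cds_length=4000, length=4000),
    }


class TestAssignPeaksToGenes:
    def test_largest_absolute_change_kept(self, two_genes):
        peaks = pd.DataFrame({
            "chrom": ["c", "c"], "start": [4500, 5200], "end": [4900, 5600],
            "peak_id": ["p1", "p2"], "log2fc": [0.5, 1.5]})
        res = assign_peaks_to_genes(peaks, {"gA": two_genes["gA"]})
        assert res.loc[0, "peak_id"] == "p2" and res.loc[0, "log2fc"] == 1.5

    def test_promoter_window_boundaries(self, two_genes):
        gA = {"gA": two_genes["gA"]}  # window [4000, 6000)
        inside = pd.DataFrame({"chrom": ["c"], "start": [3900], "end": [4100],
                               "peak_id": ["p"], "log2fc": [1.0]})
        outside = pd.DataFrame({"chrom": ["c"], "start": [2000], "end": [2500],
                                "peak_id": ["p"], "log2fc": [1.0]})
        assert len(assign_peaks_to_genes(inside, gA)) == 1
        assert len(assign_peaks_to_genes(outside, gA)) == 0

    def test_genes_without_peaks_omitted(self, two_genes):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [4500], "end": [4900],
                              "peak_id": ["p"], "log2fc": [1.0]})
        res = assign_peaks_to_genes(peaks, two_genes)
        assert res["gene_id"].tolist() == ["gA"]


class TestEnrichmentZscores:
    def test_textbook_standardization(self):
        raw = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("abc"))
        zm = enrichment_zscores(raw)
        assert zm.z["f"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_feature_zeroed_and_flagged(self):
        raw = pd.DataFrame({"f": [5.0, 5.0, 5.0], "g": [1.0, 2.0, 3.0]},
                           index=list("abc"))
        zm = enrichment_zscores(raw)
        assert (zm.z["f"] == 0).all() and zm.constant_features == ["f"]

    def test_set_mean_over_all_genes_is_zero(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame(rng.random((10, 3)), index=[f"g{i}" for i in range(10)],
                           columns=list("xyz"))
        zm = enrichment_zscores(raw)
        assert zm.set_mean(raw.index).to_numpy() == pytest.approx([0.0] * 3, abs=1e-12)


class TestStateOverlapFraction:
    def test_counting(self, two_genes):
        # gA promoter [4500,5500); gB promoter [19500,20500)
        states = {"active": [Interval("c", 4400, 4600)],
                  "silent": [Interval("c", 0, 10)]}
        frac = state_overlap_fraction(["gA", "gB"], two_genes, states)
        assert frac == {"active": 0.5, "silent": 0.0}

    def test_chromosome_wide_state(self, two_genes):
        states = {"all": [Interval("c", 0, 10_000_000)]}
        assert state_overlap_fraction(["gA", "gB"], two_genes, states)["all"] == 1.0

    def test_empty_gene_set_errors(self, two_genes):
        with pytest.raises(ValueError):
            state_overlap_fraction([], two_genes, {})


class TestClassifyEnhancers:
    @pytest.mark.parametrize("summit,expected", [
        (5050, "promoter-proximal"),   # 50 <= 100
        (5101, "enhancer"),            # 101 > 100
        (5000, "promoter-proximal"),   # exactly on the TSS
    ])
    def test_summit_distance_classes(self, two_genes, summit, expected):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [summit - 50],
                              "end": [summit + 50], "summit": [summit]})
        assert classify_enhancers(peaks, two_genes).iloc[0] == expected

    def test_no_genes_errors(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10],
                              "summit": [5]})
        with pytest.raises(ValueError):
            classify_enhancers(peaks, {})


class TestFcCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10, dtype=float)
        r, rho, n = fc_correlation(x, 2 * x)
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0) and n == 10

    def test_anticorrelation(self):
        x = np.arange(10, dtype=float)
        assert fc_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_undefined_pairs_dropped(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        y = np.array([1.0, 2.0, 3.5, 4.0, np.inf])
        assert fc_correlation(x, y)[2] == 3

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError):
            fc_correlation([1.0, np.nan], [2.0, 3.0])

    def test_independent_null_is_small(self):
        """|r| < 0.1 for independent pairs (n=1000) in >= 19/20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r, _, _ = fc_correlation(rng.normal(size=1000), rng.normal(size=1000))
            hits += abs(r) < 0.1
        assert hits >= 19


class TestThresholdGainSet:
    def test_boundary_is_strict(self):
        lfc = pd.Series({"in": 0.6, "edge": np.log2(1.5), "out": -1.0})
        assert set(threshold_gain_set(lfc)) == {"in"}


class TestLog2IpOverInput:
    def test_identical_tracks_zero(self):
        track = make_track([("c", 5, "+"), ("c", 17, "-")])
        _, vals = log2_ip_over_input(track, track, "c", 0, 30, 1.0, 1.0)
        assert (vals == 0).all()

    def test_fourfold_limit(self):
        ip = make_track([("c", 5, "+")] * 400)
        inp = make_track([("c", 5, "+")] * 100)
        _, vals = log2_ip_over_input(ip, inp, "c", 0, 10, 1.0, 1.0,
                                     pseudocount=1e-9)
        assert vals[0] == pytest.approx(2.0, abs=1e-6)

    def test_size_factor_scale_invariance(self):
        ip = make_track([("c", 5, "+")] * 8)
        ip2 = make_track([("c", 5, "+")] * 16)
        inp = make_track([("c", 5, "+")] * 4)
        _, v1 = log2_ip_over_input(ip, inp, "c", 0, 10, 1.0, 1.0)
        _, v2 = log2_ip_over_input(ip2, inp, "c", 0, 10, 2.0, 1.0)
        np.testing.assert_allclose(v1, v2)

    def test_bad_factor_errors(self):
        t = make_track([])
        with pytest.raises(ValueError):
            log2_ip_over_input(t, t, "c", 0, 10, 0.0, 1.0)
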