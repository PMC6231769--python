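import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from regmap.enrichment import (
    assign_tf_peaks,
    cluster_tissue_composition,
    cpg_density,
    fisher_p,
    odds_ratio_2x2,
    relative_tf_expression,
    scan_consensus,
    tf_enrichment,
    tissue_bias,
)


def elements_df(n, spacing=1000):
    starts = np.arange(n) * spacing
    return pd.DataFrame(
        {"chrom": "chrI", "start": starts, "end": starts + 151}
    )


def peak_row(summit, factor):
    return {"chrom": "chrI", "start": summit - 100, "end": summit + 100,
            "factor": factor, "summit": summit}


class TestAssignTfPeaks:
    def test_window_half_open_boundaries(self):
        els = elements_df(1)
        mid = (0 + 151) // 2
        inside = pd.DataFrame([peak_row(mid + 199, "tfA")])
        outside = pd.DataFrame([peak_row(mid + 200, "tfA")])
        assert assign_tf_peaks(els, inside).bound.iloc[0, 0]
        assert not assign_tf_peaks(els, outside).bound.iloc[0, 0]

    def test_hotness_thresholds(self):
        els = elements_df(3)
        rows = []
        mids = ((els["start"] + els["end"]) // 2).to_numpy()
        for i in range(19):
            rows.append(peak_row(int(mids[0]), f"tf{i:02d}"))
        for i in range(18):
            rows.append(peak_row(int(mids[1]), f"tf{i:02d}"))
        binding = assign_tf_peaks(els, pd.DataFrame(rows))
        hot = binding.hotness
        assert hot.iloc[0] == "HOT"       # 19 factors
        assert hot.iloc[1] == "cold"      # 18 factors
        assert hot.iloc[2] == "none"      # 0 factors

    def test_no_peaks(self):
        els = elements_df(2)
        peaks = pd.DataFrame(columns=["chrom", "start", "end", "factor", "summit"])
        binding = assign_tf_peaks(els, peaks)
        assert (binding.factor_count == 0).all()
        assert (binding.hotness == "none").all()


class TestOddsRatioAndFisher:
    def test_or_arithmetic_forced(self):
        assert odds_ratio_2x2(20, 80, 100, 800) == pytest.approx(2.0)

    def test_haldane_only_on_zero_cell(self):
        assert odds_ratio_2x2(0, 10, 5, 5) == pytest.approx(
            (0.5 * 5.5) / (10.5 * 5.5)
        )
        assert odds_ratio_2x2(2, 4, 8, 16) == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_oracle(self):
        # DERIVED exhaustive oracle: two-sided Fisher p as a sum of
        # hypergeometric point masses no larger than the observed one
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            a = int(rng.integers(0, n + 1))
            rest = n - a
            b = int(rng.integers(0, rest + 1))
            rest -= b
            c = int(rng.integers(0, rest + 1))
            d = rest - c
            ours = fisher_p(a, b, c, d)
            M, K, N = a + b + c + d, a + b, a + c
            support = np.arange(max(0, K + N - M), min(K, N) + 1)
            pmf = hypergeom.pmf(support, M, N, K)
            p_obs = hypergeom.pmf(a, M, N, K)
            oracle = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
            assert ours == pytest.approx(oracle, abs=1e-10)


class TestTfEnrichment:
    def _setup(self, rng, n=300, bound_p=0.2, target_boost=0.6):
        els = elements_df(n)
        clusters = pd.Series(rng.integers(1, 5, size=n), index=els.index)
        mids = ((els["start"] + els["end"]) // 2).to_numpy()
        rows = []
        for i in range(n):
            p = target_boost if clusters[i] == 1 else bound_p
            if rng.random() < p:
                rows.append(peak_row(int(mids[i]), "tf_enr"))
            if rng.random() < bound_p:
                rows.append(peak_row(int(mids[i]), "tf_bg"))
        binding = assign_tf_peaks(els, pd.DataFrame(rows))
        return els, clusters, binding

    def test_planted_enrichment_detected(self, rng):
        _, clusters, binding = self._setup(rng)
        res = tf_enrichment(clusters, binding, min_peaks=10)
        assert res.kept["tf_enr"]
        assert res.odds_ratio.loc["tf_enr"].idxmax() == 1
        assert not res.kept.get("tf_bg", False)

    def test_min_peaks_filter(self, rng):
        _, clusters, binding = self._setup(rng)
        res = tf_enrichment(clusters, binding, min_peaks=10_000)
        assert res.odds_ratio.empty

    def test_default_min_peaks_excludes_150_peak_factor(self):
        els = elements_df(400)
        mids = ((els["start"] + els["end"]) // 2).to_numpy()
        rows = [peak_row(int(mids[i]), "tf_few") for i in range(150)]
        binding = assign_tf_peaks(els, pd.DataFrame(rows))
        clusters = pd.Series(np.tile([1, 2], 200), index=els.index)
        res = tf_enrichment(clusters, binding)  # default min_peaks=200
        assert "tf_few" not in res.odds_ratio.index

    def test_hot_elements_removed_from_tables(self, rng):
        els = elements_df(60)
        mids = ((els["start"] + els["end"]) // 2).to_numpy()
        rows = []
        # elements 0..9 are HOT (19 factors each)
        for i in range(10):
            for f in range(19):
                rows.append(peak_row(int(mids[i]), f"tf{f:02d}"))
        # tf00 additionally binds everything else
        for i in range(10, 60):
            rows.append(peak_row(int(mids[i]), "tf00"))
        binding = assign_tf_peaks(els, pd.DataFrame(rows))
        clusters = pd.Series(np.tile([1, 2, 3], 20), index=els.index)
        res = tf_enrichment(clusters, binding, min_peaks=10)
        assert res.n_universe == 50


class TestTissueBias:
    def _expr(self, rows):
        cols = [f"tissue_{t}|rep{r}" for t in range(4) for r in range(2)]
        return pd.DataFrame(rows, columns=cols,
                            index=[f"g{i}" for i in range(len(rows))])

    def test_fold_arithmetic(self):
        # TPMs (30, 9, 1, 1): fold = 30.1/9.1 = 3.307 -> biased if padj ok
        many = [[30, 30, 9, 9, 1, 1, 1, 1]] * 30 + [[5, 5, 5, 5, 5, 5, 5, 5]] * 30
        bias = tissue_bias(self._expr(many))
        assert bias.iloc[0]["fold"] == pytest.approx(30.1 / 9.1)
        assert bias.iloc[0]["top_tissue"] == "tissue_0"

    def test_below_threshold_fold_never_biased(self):
        rows = [[30, 30, 15, 15, 1, 1, 1, 1]] * 20
        bias = tissue_bias(self._expr(rows))
        assert not bias["biased"].any()

    def test_equal_tissues_fold_one(self):
        rows = [[7, 7, 7, 7, 7, 7, 7, 7]] * 5
        bias = tissue_bias(self._expr(rows))
        np.testing.assert_allclose(bias["fold"], 1.0)
        assert not bias["biased"].any()

    def test_needs_two_tissues(self):
        df = pd.DataFrame({"a|rep0": [1.0], "a|rep1": [2.0]})
        with pytest.raises(ValueError):
            tissue_bias(df)


class TestClusterComposition:
    def test_percentages(self):
        clusters = pd.Series([1] * 10, index=range(10))
        gene_map = {i: f"g{i}" for i in range(10)}
        bias = pd.DataFrame(
            {
                "top_tissue": ["gonad"] * 4 + ["muscle"] * 6,
                "biased": [True] * 4 + [False] * 6,
            },
            index=[f"g{i}" for i in range(10)],
        )
        comp = cluster_tissue_composition(clusters, bias, gene_map)
        assert comp.loc[1, "gonad"] == pytest.approx(40.0)
        assert comp.loc[1, "muscle"] == pytest.approx(0.0)
        assert comp.to_numpy().sum() <= 100.0

    def test_no_biased_genes(self):
        clusters = pd.Series([1, 1], index=[0, 1])
        bias = pd.DataFrame(
            {"top_tissue": ["gonad", "gonad"], "biased": [False, False]},
            index=["g0", "g1"],
        )
        comp = cluster_tissue_composition(clusters, bias, {0: "g0", 1: "g1"})
        assert (comp.to_numpy() == 0).all()


class TestRelativeTfExpression:
    def test_equal_tissues_zero(self):
        tpm = pd.DataFrame({"a": [5.0], "b": [5.0]}, index=["tf1"])
        rel, dec = relative_tf_expression(tpm)
        np.testing.assert_allclose(rel.to_numpy(), 0.0)

    def test_pseudo_value_arithmetic(self):
        tpm = pd.DataFrame({"a": [10.0], "b": [0.0]}, index=["tf1"])
        rel, _ = relative_tf_expression(tpm)
        assert rel.loc["tf1", "a"] == pytest.approx(np.log2(10.1 / 5.1))

    def test_decile_excludes_low_tpm(self):
        vals = list(np.linspace(1, 100, 20)) + [0.5]
        tpm = pd.DataFrame({"a": vals}, index=[f"t{i}" for i in range(21)])
        _, dec = relative_tf_expression(tpm)
        assert np.isnan(dec.loc["t20", "a"])
        observed = dec["a"].dropna()
        assert observed.min() >= 1 and observed.max() <= 10


class TestScanConsensus:
    def test_tata_match(self):
        hits = scan_consensus("GGTATAAAAGG", "TATAWAW")
        assert 2 in hits["+"]

    def test_n_matches_everywhere(self):
        hits = scan_consensus("ACGT", "N")
        assert hits["+"] == [0, 1, 2, 3]

    def test_empty_sequence(self):
        hits = scan_consensus("", "TATA")
        assert hits["+"] == [] and hits["-"] == []

    def test_reverse_strand(self):
        # TTAGC on the minus strand of GCTAA
        hits = scan_consensus("GCTAA", "TTAGC")
        assert hits["-"] == [0]

    def test_overlapping_matches(self):
        hits = scan_consensus("AAAA", "AA")
        assert hits["+"] == [0, 1, 2]


class TestCpGDensity:
    def test_cg_repeat(self):
        dens = cpg_density("CGCGCG", 6)
        assert dens[2] == pytest.approx(3 / 6)

    def test_no_cg(self):
        assert cpg_density("ATATAT", 4).sum() == 0

    def test_all_n(self):
        assert cpg_density("NNNNNN", 4).sum() == 0

    def test_bad_window(self):
        with pytest.raises(ValueError):
            cpg_density("ACGT", 0)
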