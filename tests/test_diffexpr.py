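"""Normalization, dispersion, NB Wald contrast and DEG set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from peachbud import diffexpr as de
from peachbud.io import CountMatrix


def _df(data, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(len(data))]
    samples = samples or [f"s{j}" for j in range(len(data[0]))]
    return pd.DataFrame(data, index=genes, columns=samples)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        sf = de.size_factors_median_of_ratios(_df([[5, 5], [9, 9], [2, 2]]))
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_sample_hand_computation(self):
        # geometric means: sqrt(2*4)=2.83..., ratios s1: 1/sqrt2, s2: sqrt2
        sf = de.size_factors_median_of_ratios(_df([[2, 4], [4, 8], [6, 12]]))
        assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2))
        assert sf.iloc[1] == pytest.approx(np.sqrt(2))
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_scale_equivariance(self):
        base = _df([[3, 7], [10, 12], [100, 80]])
        scaled = base.copy()
        scaled["s1"] = scaled["s1"] * 5
        sf0 = de.size_factors_median_of_ratios(base)
        sf1 = de.size_factors_median_of_ratios(scaled)
        # factors are defined up to overall scale: the s1/s0 ratio gains the 5
        assert (sf1["s1"] / sf1["s0"]) / (sf0["s1"] / sf0["s0"]) == pytest.approx(5.0)

    def test_all_genes_with_zero_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            de.size_factors_median_of_ratios(_df([[0, 5], [3, 0]]))


class TestDispersion:
    def test_moment_formula_by_hand(self):
        # one gene, counts (4,7,13,16): mean 10, var 30 -> alpha 0.2
        counts = _df([[4, 7, 13, 16]])
        sf = pd.Series(1.0, index=counts.columns)
        alpha = de.estimate_dispersion(counts, sf)
        assert alpha.iloc[0] == pytest.approx(0.2)

    def test_poisson_limit_hits_floor(self):
        rng = np.random.default_rng(0)
        counts = _df([rng.poisson(100, 500)])
        sf = pd.Series(1.0, index=counts.columns)
        alpha = de.estimate_dispersion(counts, sf)
        assert alpha.iloc[0] < 0.005

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(1)
        mu, a = 100.0, 0.1
        n = 1.0 / a
        draws = rng.negative_binomial(n, n / (n + mu), 500)
        counts = _df([draws])
        sf = pd.Series(1.0, index=counts.columns)
        alpha = de.estimate_dispersion(counts, sf)
        assert alpha.iloc[0] == pytest.approx(a, rel=0.25)

    def test_pooling_removes_group_difference(self):
        # two levels with very different means: pooled-within variance must
        # not absorb the between-level shift
        rng = np.random.default_rng(2)
        low = rng.poisson(50, 10)
        high = rng.poisson(400, 10)
        counts = _df([np.concatenate([low, high])])
        sf = pd.Series(1.0, index=counts.columns)
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=counts.columns)
        pooled = de.estimate_dispersion(counts, sf, groups=groups)
        naive = de.estimate_dispersion(counts, sf)
        assert pooled.iloc[0] < 0.05 < naive.iloc[0]


class TestWaldContrast:
    @staticmethod
    def _meta(levels):
        return pd.DataFrame(
            {"grp": levels}, index=[f"s{j}" for j in range(len(levels))]
        )

    def test_identical_groups_give_exact_zero_lfc(self):
        counts = _df([[10, 20, 10, 20], [7, 7, 7, 7]])
        res = de.nb_wald_contrast(
            counts, self._meta(["A", "A", "B", "B"]), "grp", ("A", "B")
        )
        assert (res["log2fc"] == 0.0).all()
        assert (res.loc[res["tested"], "pvalue"] == 1.0).all()

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(7)
        mu, a, n = 200.0, 0.05, 20
        size = 1.0 / a
        lo = rng.negative_binomial(size, size / (size + mu), n)
        hi = rng.negative_binomial(size, size / (size + 4 * mu), n)
        # stable background so size factors are well determined
        bg = [rng.poisson(m, 2 * n) for m in (100, 300, 1000, 50, 70, 150)]
        counts = _df([np.concatenate([lo, hi]), *bg])
        res = de.nb_wald_contrast(
            counts, self._meta(["A"] * n + ["B"] * n), "grp", ("A", "B")
        )
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.2)

    def test_contrast_swap_negates_lfc_and_swaps_sets(self):
        rng = np.random.default_rng(8)
        counts = _df(rng.poisson(100, (30, 8)))
        counts.iloc[0, 4:] *= 8
        meta = self._meta(["A"] * 4 + ["B"] * 4)
        ab = de.nb_wald_contrast(counts, meta, "grp", ("A", "B"))
        ba = de.nb_wald_contrast(counts, meta, "grp", ("B", "A"))
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        up_ab, dn_ab = de.call_degs(ab)
        up_ba, dn_ba = de.call_degs(ba)
        assert up_ab == dn_ba and dn_ab == up_ba

    def test_all_zero_gene_untested(self):
        counts = _df([[0, 0, 0, 0], [10, 12, 9, 11]])
        res = de.nb_wald_contrast(
            counts, self._meta(["A", "A", "B", "B"]), "grp", ("A", "B")
        )
        assert not res["tested"].iloc[0]
        assert np.isnan(res["padj"].iloc[0])

    def test_samples_without_level_are_dropped(self):
        counts = _df(np.random.default_rng(3).poisson(50, (5, 6)))
        meta = self._meta(["A", "A", "B", "B", "", ""])
        res = de.nb_wald_contrast(counts, meta, "grp", ("A", "B"))
        assert res.shape[0] == 5  # runs on the 4 labelled samples only


class TestCallsAndBH:
    def test_threshold_arithmetic(self):
        res = pd.DataFrame(
            {"padj": [0.005, 0.005, 0.02], "log2fc": [1.2, 0.5, 3.0]},
            index=["a", "b", "c"],
        )
        up, down = de.call_degs(res)
        assert up == {"a"} and down == set()

    def test_boundary_lfc_inclusive(self):
        res = pd.DataFrame({"padj": [0.005], "log2fc": [1.0]}, index=["g"])
        up, _ = de.call_degs(res)
        assert up == {"g"}

    def test_fold_below_one_rejected(self):
        res = pd.DataFrame({"padj": [0.5], "log2fc": [0.0]})
        with pytest.raises(ValueError, match="fold"):
            de.call_degs(res, fold=0.5)

    def test_bh_step_up_by_hand(self):
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_bh_degenerate_inputs(self):
        assert de.bh_adjust([0.123]) == pytest.approx([0.123])
        assert np.allclose(de.bh_adjust([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        hst.lists(
            hst.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40
        )
    )
    def test_bh_dominates_raw_and_preserves_order(self, ps):
        adj = de.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestVenn:
    def test_two_set_regions(self):
        out = de.venn_overlaps({"X": {"a", "b"}, "Y": {"b", "c"}})
        assert out["regions"][("X", "Y")] == {"b"}
        assert out["regions"][("X",)] == {"a"}
        assert out["regions"][("Y",)] == {"c"}

    def test_disjoint_sets(self):
        out = de.venn_overlaps({"X": {"a"}, "Y": {"b"}})
        assert out["counts"][("X", "Y")] == 0

    def test_three_sets_against_brute_force(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(60)]
        sets = {
            name: set(rng.choice(universe, rng.integers(5, 40), replace=False))
            for name in ("A", "B", "C")
        }
        out = de.venn_overlaps(sets)
        # oracle: classify every gene by its exact membership pattern
        for combo, members in out["regions"].items():
            expected = {
                g
                for g in universe
                if all(g in sets[n] for n in combo)
                and all(g not in sets[n] for n in sets if n not in combo)
            }
            assert members == expected
        union = set().union(*sets.values())
        assert sum(out["counts"].values()) == len(union)

    def test_more_than_three_sets_rejected(self):
        with pytest.raises(ValueError, match="3"):
            de.venn_overlaps({k: {1} for k in "ABCD"})


def test_normalized_counts_invariant_to_library_rescale(default_dataset):
    cm = default_dataset["counts"]
    sub = cm.counts.iloc[:200].copy()
    sf0 = de.size_factors_median_of_ratios(sub)
    scaled = sub.copy()
    scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
    sf1 = de.size_factors_median_of_ratios(scaled)
    n0 = de.normalized_counts(sub, sf0)
    n1 = de.normalized_counts(scaled, sf1)
    # normalized counts are recovered up to one global constant
    ratio = (n1 / n0).to_numpy()
    ratio = ratio[np.isfinite(ratio)]
    assert np.allclose(ratio, ratio[0], rtol=1e-10)
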