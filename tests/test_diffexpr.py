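"""DE stage: size factors, dispersions, NB Wald GLM, BH, threshold filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from treghub.diffexpr import (
    CountMatrix,
    DEThresholds,
    adjust_pvalues,
    estimate_dispersions,
    estimate_size_factors,
    filter_degs,
    moderate_dispersions,
    run_de,
    wald_test,
)
from treghub.simulate import SimConfig, simulate_counts


def _cm(counts: dict, n_case: int) -> CountMatrix:
    df = pd.DataFrame(counts)
    groups = pd.Series(
        ["case"] * n_case + ["control"] * (len(df.columns) - n_case),
        index=df.columns,
    )
    return CountMatrix(counts=df, groups=groups)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm({"a": [5, 9, 2], "b": [5, 9, 2], "c": [5, 9, 2], "d": [5, 9, 2]}, 2)
        sf = estimate_size_factors(cm)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_has_double_factor(self):
        cm = _cm({"a": [10, 20, 30], "b": [20, 40, 60]}, 1)
        sf = estimate_size_factors(cm)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_three_gene_hand_computed_medians(self):
        # geometric means per gene: sqrt(4*9)=6, sqrt(10*40)=20, sqrt(2*8)=4
        # ratios col a: 4/6, 10/20, 2/4 -> median 0.5
        # ratios col b: 9/6, 40/20, 8/4 -> median 2 -> s = (0.5, 2)
        cm = _cm({"a": [4, 10, 2], "b": [9, 40, 8]}, 1)
        sf = estimate_size_factors(cm)
        assert sf["a"] == pytest.approx(0.5)
        assert sf["b"] == pytest.approx(2.0)

    def test_fallback_when_no_all_positive_gene(self):
        cm = _cm({"a": [0, 10, 8], "b": [5, 0, 8], "c": [5, 10, 8], "d": [5, 10, 8]}, 2)
        sf = estimate_size_factors(cm)
        assert (sf > 0).all()

    def test_error_when_no_usable_gene(self):
        cm = _cm({"a": [3, 0, 0, 0], "b": [0, 3, 0, 0],
                  "c": [0, 0, 3, 0], "d": [0, 0, 0, 3]}, 2)
        with pytest.raises(ValueError, match="size factors"):
            estimate_size_factors(cm)


class TestDispersions:
    def test_constant_gene_floored(self):
        cm = _cm({"a": [7, 1], "b": [7, 9], "c": [7, 4], "d": [7, 2]}, 2)
        sf = pd.Series(1.0, index=cm.samples)
        disp = estimate_dispersions(cm, sf)
        assert disp.iloc[0] == pytest.approx(1e-8)

    def test_poisson_genes_near_floor(self, rng):
        """Poisson data is NB with alpha -> 0; MoM should sit near the floor."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            counts = pd.DataFrame(
                r.poisson(100.0, size=(50, 200)),
                columns=[f"s{i}" for i in range(200)],
            )
            cm = CountMatrix(
                counts=counts,
                groups=pd.Series(["case"] * 100 + ["control"] * 100,
                                 index=counts.columns),
            )
            disp = estimate_dispersions(cm, pd.Series(1.0, index=cm.samples))
            hits += (disp < 0.05).mean() >= 0.9
        assert hits >= 18

    def test_nb_dispersion_recovery(self):
        """True alpha = 0.5 recovered within +-0.15 on average at n=500."""
        r = np.random.default_rng(77)
        alpha, mu, n = 0.5, 100.0, 500
        counts = pd.DataFrame(
            r.poisson(r.gamma(1 / alpha, alpha * mu, size=(200, n))),
            columns=[f"s{i}" for i in range(n)],
        )
        cm = CountMatrix(
            counts=counts,
            groups=pd.Series(["case"] * 250 + ["control"] * 250, index=counts.columns),
        )
        disp = estimate_dispersions(cm, pd.Series(1.0, index=cm.samples))
        assert disp.mean() == pytest.approx(alpha, abs=0.15)


class TestWald:
    def test_all_zero_gene_degenerate_output(self):
        cm = _cm({"a": [0, 10], "b": [0, 12], "c": [0, 9], "d": [0, 11]}, 2)
        sf = pd.Series(1.0, index=cm.samples)
        disp = pd.Series(0.1, index=cm.genes)
        rec = wald_test(cm, sf, disp)
        assert rec.iloc[0]["log2FoldChange"] == 0.0
        assert rec.iloc[0]["pvalue"] == 1.0

    def test_wald_stat_is_lfc_over_se(self):
        cfg = SimConfig(n_genes=100, seed=5)
        cm, _ = simulate_counts(cfg)
        rec, _ = run_de(cm)
        ok = rec["lfcSE"] > 0
        assert np.allclose(rec.loc[ok, "stat"],
                           rec.loc[ok, "log2FoldChange"] / rec.loc[ok, "lfcSE"])

    def test_group_swap_negates_lfc_and_preserves_p(self):
        cfg = SimConfig(n_genes=200, frac_de=0.2, seed=6)
        cm, _ = simulate_counts(cfg)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        rec = wald_test(cm, sf, disp)
        swapped = CountMatrix(
            counts=cm.counts,
            groups=cm.groups.map({"case": "control", "control": "case"}),
        )
        rec2 = wald_test(swapped, sf, disp)
        assert np.allclose(rec["log2FoldChange"], -rec2["log2FoldChange"], atol=1e-6)
        assert np.allclose(rec["pvalue"], rec2["pvalue"], atol=1e-8)

    def test_scale_invariance_of_lfc(self):
        """Scaling one sample's column scales its size factor relative to
        every other sample by that constant (median-of-ratios is defined up
        to a common rescaling) and leaves the fitted log2FC invariant."""
        profile = np.array([8, 40, 100])
        cols = {"a": profile * 2, "b": profile, "c": profile * 3, "d": profile}
        cm = _cm(cols, 2)
        sf = estimate_size_factors(cm)
        disp = pd.Series(0.05, index=cm.genes)
        rec = wald_test(cm, sf, disp)
        scaled = cm.counts.copy()
        scaled["a"] = scaled["a"] * 3
        cm2 = CountMatrix(counts=scaled, groups=cm.groups)
        sf2 = estimate_size_factors(cm2)
        assert (sf2["a"] / sf2["b"]) / (sf["a"] / sf["b"]) == pytest.approx(3.0)
        rec2 = wald_test(cm2, sf2, disp)
        assert np.allclose(rec["log2FoldChange"], rec2["log2FoldChange"], atol=1e-6)

    def test_planted_lfc_recovery(self):
        """Planted log2FC = +1 at mu=100, alpha=0.05, 6v6: mean bias < 0.15."""
        cfg = SimConfig(n_genes=500, group_sizes=(6, 6), frac_de=1.0,
                        lfc_magnitude=1.0, dispersion=0.05, seed=3)
        cm, truth = simulate_counts(cfg)
        rec, _ = run_de(cm)
        signed = rec["log2FoldChange"] * np.sign(truth["true_log2fc"])
        assert abs(signed.mean() - 1.0) < 0.15


class TestBH:
    def test_single_gene_unchanged(self):
        rec = pd.DataFrame({"gene": ["g"], "pvalue": [0.03]})
        assert adjust_pvalues(rec)["padj"].iloc[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        rec = pd.DataFrame({"gene": list("abcd"), "pvalue": [0.01, 0.02, 0.03, 0.04]})
        out = adjust_pvalues(rec)
        assert np.allclose(out["padj"], [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        rec = pd.DataFrame({"gene": list("abc"), "pvalue": [1.0, 1.0, 1.0]})
        assert (adjust_pvalues(rec)["padj"] == 1.0).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_bh_properties(self, pvals):
        rec = pd.DataFrame({"gene": [f"g{i}" for i in range(len(pvals))],
                            "pvalue": pvals})
        out = adjust_pvalues(rec)
        padj = out["padj"].to_numpy()
        p = out["pvalue"].to_numpy()
        assert (padj <= 1.0 + 1e-12).all()
        assert (padj >= p - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(padj[order]) >= -1e-12).all()
        # BH rejections contain Bonferroni rejections at the same level
        q = 0.05
        bonf = p <= q / len(p)
        assert (padj[bonf] <= q + 1e-12).all()


class TestFilter:
    def test_boundary_lfc_included_boundary_p_excluded(self):
        rec = pd.DataFrame(
            {
                "gene": ["at_lfc", "at_p", "below_lfc", "clean"],
                "log2FoldChange": [0.5, 1.0, 0.49, -0.8],
                "pvalue": [0.049, 0.05, 1e-10, 0.001],
            }
        )
        degs = filter_degs(rec)
        assert "at_lfc" in degs.up
        assert "at_p" not in degs.up
        assert "below_lfc" not in degs.up | degs.down
        assert "clean" in degs.down

    def test_adjusted_filter_flag(self):
        rec = pd.DataFrame(
            {"gene": ["a", "b"], "log2FoldChange": [1.0, 1.0],
             "pvalue": [0.01, 0.5], "padj": [0.2, 0.9]}
        )
        raw = filter_degs(rec, DEThresholds(use_adjusted=False))
        adj = filter_degs(rec, DEThresholds(use_adjusted=True))
        assert raw.up == {"a"}
        assert adj.up == set()

    def test_planted_core_sensitivity(self):
        """At |log2FC| = 2 and mu ~ 100 the filter recovers >= 90% of truth."""
        cfg = SimConfig(n_genes=1000, group_sizes=(6, 6), frac_de=0.1,
                        lfc_magnitude=2.0, dispersion=0.05, seed=8)
        cm, truth = simulate_counts(cfg)
        _, degs = run_de(cm)
        planted = set(truth.loc[truth["is_de"], "gene"])
        recovered = (degs.up | degs.down) & planted
        assert len(recovered) / len(planted) >= 0.9


def test_moderation_keeps_gene_wise_scale():
    cfg = SimConfig(n_genes=800, group_sizes=(6, 6), frac_de=0.0,
                    dispersion=0.1, seed=9)
    cm, _ = simulate_counts(cfg)
    sf = estimate_size_factors(cm)
    raw = estimate_dispersions(cm, sf)
    mod = moderate_dispersions(cm, sf, raw)
    assert (mod > 0).all()
    assert mod.median() == pytest.approx(raw.median(), rel=0.5)


def test_duplicate_gene_labels_rejected():
    df = pd.DataFrame([[1, 2], [3, 4]], index=["g", "g"], columns=["a", "b"])
    with pytest.raises(ValueError, match="duplicate"):
        CountMatrix(counts=df, groups=pd.Series({"a": "case", "b": "control"}))
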