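"""Generator contracts: determinism, planted structure, moment and copula
fidelity."""

import numpy as np
import pandas as pd
import pytest

from treghub.diffexpr import estimate_size_factors
from treghub.enrichment import ora_test
from treghub.network import read_string_tsv, write_string_tsv
from treghub.simulate import (
    PanelConfig,
    SimConfig,
    build_copula_correlation,
    simulate_counts,
    simulate_dataset_trio,
    simulate_gene_sets,
    simulate_pan_cancer_panel,
    simulate_ppi,
)


class TestSimulateCounts:
    def test_no_planted_effect_when_frac_de_zero(self):
        cm, truth = simulate_counts(SimConfig(n_genes=200, frac_de=0.0, seed=1))
        assert not truth["is_de"].any()
        assert (truth["true_log2fc"] == 0).all()

    def test_planted_count_follows_rounding_rule(self):
        cfg = SimConfig(n_genes=1000, frac_de=0.1, seed=2)
        _, truth = simulate_counts(cfg)
        assert truth["is_de"].sum() == 100
        assert (truth.loc[truth["is_de"], "true_log2fc"].abs() == cfg.lfc_magnitude).all()

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_genes=300, seed=7)
        cm1, t1 = simulate_counts(cfg)
        cm2, t2 = simulate_counts(cfg)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_counts_are_nonnegative_integers(self):
        cm, _ = simulate_counts(SimConfig(n_genes=100, seed=3))
        arr = cm.counts.to_numpy()
        assert np.issubdtype(arr.dtype, np.integer)
        assert (arr >= 0).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_genes": -5},
            {"dispersion": 0.0},
            {"frac_de": 1.5},
            {"group_sizes": (1, 5)},
            {"size_factor_range": (2.0, 1.0)},
            {"lfc_magnitude": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(seed=0, **kwargs)

    def test_nb_moment_relationship(self):
        """Pooled mean/variance of null counts satisfies Var ~ mu + alpha*mu^2."""
        alpha = 0.2
        cfg = SimConfig(
            n_genes=6000, group_sizes=(30, 30), frac_de=0.0, dispersion=alpha,
            sd_log_expression=0.0, size_factor_range=(1.0, 1.0), seed=5,
        )
        cm, _ = simulate_counts(cfg)
        mu = cm.counts.mean(axis=1).to_numpy()
        var = cm.counts.var(axis=1, ddof=1).to_numpy()
        implied_alpha = (var - mu) / mu**2
        assert np.mean(implied_alpha) == pytest.approx(alpha, abs=0.03)


class TestSimulateTrio:
    def test_truth_intersection_equals_shared_core(self):
        cfg = SimConfig(n_genes=1500, frac_de=0.1, seed=11)
        trio = simulate_dataset_trio(cfg, shared_core=57, shared_up=35)
        de_sets = [set(t.loc[t["is_de"], "gene"]) for _, t in trio]
        shared = set.intersection(*de_sets)
        assert len(shared) == 57
        # identical signs across datasets, with the requested up/down split
        signs = pd.DataFrame({i: trio[i][1].loc[sorted(shared), "true_log2fc"]
                              for i in range(3)})
        assert (signs.nunique(axis=1) == 1).all()
        assert (signs[0] > 0).sum() == 35
        assert (signs[0] < 0).sum() == 22

    def test_private_degs_are_disjoint(self):
        cfg = SimConfig(n_genes=1500, frac_de=0.1, seed=12)
        trio = simulate_dataset_trio(cfg, shared_core=50)
        de_sets = [set(t.loc[t["is_de"], "gene"]) for _, t in trio]
        shared = set.intersection(*de_sets)
        privates = [s - shared for s in de_sets]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not privates[i] & privates[j]

    def test_zero_shared_core(self):
        cfg = SimConfig(n_genes=1000, frac_de=0.05, seed=13)
        trio = simulate_dataset_trio(cfg, shared_core=0)
        de_sets = [set(t.loc[t["is_de"], "gene"]) for _, t in trio]
        assert not set.intersection(*de_sets)

    def test_all_shared_gives_identical_truths(self):
        cfg = SimConfig(n_genes=500, frac_de=0.1, seed=14)
        trio = simulate_dataset_trio(cfg, shared_core=50, shared_up=30)
        for i in range(1, 3):
            pd.testing.assert_frame_equal(trio[0][1], trio[i][1])

    def test_group_shapes_match_study_design(self):
        cfg = SimConfig(n_genes=200, frac_de=0.05, seed=15)
        trio = simulate_dataset_trio(cfg, shared_core=5)
        shapes = [
            ((cm.groups == "case").sum(), (cm.groups == "control").sum())
            for cm, _ in trio
        ]
        assert shapes == [(5, 5), (12, 6), (6, 6)]

    def test_shared_core_exceeding_planted_count_rejected(self):
        cfg = SimConfig(n_genes=100, frac_de=0.1, seed=16)
        with pytest.raises(ValueError, match="shared_core"):
            simulate_dataset_trio(cfg, shared_core=11)


class TestSimulateGeneSets:
    def test_spiked_set_attains_smallest_ora_p(self):
        universe = [f"G{i:04d}" for i in range(500)]
        spiked = universe[:10]
        coll = simulate_gene_sets(universe, n_sets=40, set_size_range=(10, 40),
                                  spiked_set=spiked, seed=21)
        records = ora_test(set(spiked), coll)
        assert records.iloc[0]["set_id"] == "SPIKED"
        assert records.iloc[0]["p_value"] == records["p_value"].min()

    def test_single_set_collection(self):
        universe = list("ABCDEFGH")
        coll = simulate_gene_sets(universe, 1, (2, 4), ["A", "B"], seed=1)
        assert set(coll.sets) == {"SPIKED"}

    def test_fixed_set_size(self):
        universe = [f"G{i}" for i in range(50)]
        coll = simulate_gene_sets(universe, 10, (5, 5), universe[:3], seed=2)
        assert all(len(genes) == 5 for sid, (_, genes) in coll.sets.items()
                   if sid != "SPIKED")

    def test_spiked_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_gene_sets(["A", "B"], 2, (1, 2), ["Z"], seed=0)


class TestSimulatePPI:
    def test_single_planted_hub_dominates_degree(self):
        wins = 0
        for seed in range(100):
            g = simulate_ppi(50, 3, ["IL2RA"], seed)
            deg = dict(g.degree())
            wins += max(deg, key=deg.get) == "IL2RA"
        assert wins >= 95

    def test_minimal_graph(self):
        g = simulate_ppi(2, 1, ["HUB"], seed=0)
        assert g.number_of_edges() == 1
        assert all(d == 1 for _, d in g.degree())

    def test_string_tsv_round_trip(self, tmp_path):
        g = simulate_ppi(30, 2, ["A", "B"], seed=5)
        path = tmp_path / "edges.tsv"
        write_string_tsv(g, path)
        g2 = read_string_tsv(path, min_score=0)
        assert g2.number_of_edges() == g.number_of_edges()
        assert set(g2.nodes) == set(g.nodes)
        assert set(map(frozenset, g2.edges)) == set(map(frozenset, g.edges))

    def test_simple_undirected(self):
        g = simulate_ppi(40, 3, ["H1", "H2"], seed=9)
        assert not any(u == v for u, v in g.edges)

    @pytest.mark.parametrize(
        "args", [(5, 5, ["A"]), (1, 1, ["A"]), (3, 1, ["A", "B", "C"])]
    )
    def test_invalid_ppi_args_rejected(self, args):
        n, m, hubs = args
        with pytest.raises(ValueError):
            simulate_ppi(n, m, hubs, seed=0)


class TestPanCancerPanel:
    def test_copula_recovers_requested_spearman(self):
        from scipy.stats import spearmanr

        cfg = PanelConfig(
            cancer_types=("BRCA",), n_samples=5000,
            target_rank_corr={"CTLA4": 0.758}, seed=31,
        )
        panel = simulate_pan_cancer_panel(cfg)
        rho = spearmanr(panel["CCR8"], panel["CTLA4"]).statistic
        assert rho == pytest.approx(0.758, abs=0.03)

    def test_null_setpoints_give_near_zero_correlation(self):
        from scipy.stats import spearmanr

        hits = 0
        for seed in range(20):
            cfg = PanelConfig(cancer_types=("X",), n_samples=1000, seed=seed)
            panel = simulate_pan_cancer_panel(cfg)
            rho = spearmanr(panel["CCR8"], panel["PDCD1"]).statistic
            hits += abs(rho) < 0.1
        assert hits >= 19

    def test_minimal_panel_well_formed(self):
        cfg = PanelConfig(cancer_types=("A", "B"), n_samples=3, seed=1)
        panel = simulate_pan_cancer_panel(cfg)
        assert len(panel) == 6
        assert {"sample", "cancer_type", "TMB", "MSI"} <= set(panel.columns)
        assert panel["TMB"].ge(0).all()
        assert panel["MSI"].between(0, 1).all()

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError, match="target_rank_corr"):
            PanelConfig(target_rank_corr={"PDCD1": 1.0}, seed=0)

    def test_infeasible_structure_reports_nearest(self):
        cfg = PanelConfig(
            target_rank_corr={"PDCD1": 0.95, "CD274": 0.95},
            tmb_corr={"PDCD1": 0.9, "CD274": -0.9},
            seed=0,
        )
        with pytest.raises(ValueError, match="positive definite"):
            build_copula_correlation(cfg)

    def test_deterministic_under_seed(self):
        cfg = PanelConfig(cancer_types=("A",), n_samples=50, seed=3)
        pd.testing.assert_frame_equal(
            simulate_pan_cancer_panel(cfg), simulate_pan_cancer_panel(cfg)
        )


def test_size_factors_recover_simulated_depths():
    """Size factors on simulated data vary with the planted library depths."""
    cfg = SimConfig(n_genes=2000, frac_de=0.0, size_factor_range=(0.5, 2.0), seed=41)
    cm, _ = simulate_counts(cfg)
    sf = estimate_size_factors(cm)
    assert sf.between(0.3, 3.0).all()
    assert sf.std() > 0.05
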