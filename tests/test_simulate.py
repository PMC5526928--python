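"""Synthetic-data generators: determinism and distributional sanity."""

import numpy as np
import pytest

from phylogs.karyotype import cv_ci, cv_cl, summarize_karyotype
from phylogs.simulate import (
    SimulationConfig,
    make_study_bundle,
    simulate_bm,
    simulate_flow_histogram,
    simulate_karyotype,
    simulate_lambda_trait,
    simulate_ou,
    simulate_yule_tree,
)
from phylogs.tree import bm_covariance


class TestYule:
    def test_two_tip_cherry(self):
        tree = simulate_yule_tree(2, 1.0, seed=1)
        d = tree.tip_depths()
        assert len(d) == 2 and d[0] == pytest.approx(d[1])

    def test_ultrametric_and_labels(self):
        tree = simulate_yule_tree(50, 1.0, seed=2)
        assert tree.is_ultrametric(rel_tol=1e-9)
        assert tree.tip_labels[0].startswith("sp")
        assert len(set(tree.tip_labels)) == 50

    def test_mean_depth_matches_analytic_expectation(self):
        """E[height] of a Yule tree cut at n tips = sum_{k=2..n} 1/(k b)."""
        n, rate = 50, 1.0
        expected = sum(1.0 / k for k in range(2, n + 1)) / rate
        depths = [
            simulate_yule_tree(n, rate, seed=s).max_depth for s in range(200)
        ]
        assert np.mean(depths) == pytest.approx(expected, rel=0.15)

    def test_same_seed_identical_newick(self):
        a = simulate_yule_tree(20, 1.0, seed=7).to_newick()
        b = simulate_yule_tree(20, 1.0, seed=7).to_newick()
        assert a == b


class TestTraitSimulators:
    def test_bm_zero_variance_constant(self, tree20):
        tree, _ = tree20
        y = simulate_bm(tree, 0.0, root_state=3.0, seed=1)
        assert np.allclose(y.to_numpy(), 3.0)

    def test_bm_variance_law(self):
        tree = simulate_yule_tree(10, 1.0, seed=3)
        depth = tree.max_depth
        tips = np.array(
            [simulate_bm(tree, 2.0, seed=s).to_numpy() for s in range(2000)]
        )
        assert np.var(tips[:, 0]) == pytest.approx(2.0 * depth, rel=0.10)

    def test_bm_empirical_covariance_matches_tree(self):
        tree = simulate_yule_tree(8, 1.0, seed=4)
        C = bm_covariance(tree)
        tips = np.array(
            [simulate_bm(tree, 1.0, seed=s).to_numpy() for s in range(3000)]
        )
        emp = np.cov(tips.T)
        assert np.allclose(emp, C.matrix, atol=0.25 * C.matrix.max())

    def test_lambda_trait_covariance(self):
        tree = simulate_yule_tree(8, 1.0, seed=5)
        C = bm_covariance(tree)
        tips = np.array(
            [
                simulate_lambda_trait(tree, 0.5, 1.0, seed=s).to_numpy()
                for s in range(3000)
            ]
        )
        emp = np.cov(tips.T)
        expect = 0.5 * C.matrix
        np.fill_diagonal(expect, np.diag(C.matrix))
        assert np.allclose(emp, expect, atol=0.25 * C.matrix.max())

    def test_ou_stationary_variance(self):
        tree = simulate_yule_tree(6, 0.3, seed=6)  # deep tree
        alpha, sigma2 = 2.0, 4.0
        tips = np.array(
            [
                simulate_ou(tree, alpha, 0.0, sigma2, seed=s).to_numpy()
                for s in range(2000)
            ]
        )
        assert np.var(tips[:, 0]) == pytest.approx(sigma2 / (2 * alpha), rel=0.15)

    def test_ou_strong_pull_clusters_at_theta(self, tree20):
        tree, _ = tree20
        y = simulate_ou(tree, alpha=50.0, theta=5.0, sigma2=0.01, root_state=5.0, seed=7)
        assert np.allclose(y.to_numpy(), 5.0, atol=0.2)

    def test_ou_small_alpha_approaches_bm_variance(self):
        tree = simulate_yule_tree(10, 1.0, seed=8)
        alpha = 1e-4
        tips = np.array(
            [
                simulate_ou(tree, alpha, 0.0, 1.0, seed=s).to_numpy()
                for s in range(1500)
            ]
        )
        # var(tip) ~ sigma2 * depth to first order in alpha
        assert np.var(tips[:, 0]) == pytest.approx(tree.max_depth, rel=0.15)


class TestKaryotypeSimulator:
    def test_zero_cv_targets(self):
        k = simulate_karyotype(12, 8.0, 0.0, 30.0, 0.0, seed=1)
        assert cv_cl(k) == pytest.approx(0.0, abs=1e-9)
        assert cv_ci(k) == pytest.approx(0.0, abs=1e-9)
        assert len(k.chromosomes) == 12

    def test_realized_cv_near_target(self):
        reals = [
            cv_cl(simulate_karyotype(12, 8.0, 25.0, 30.0, 20.0, seed=s))
            for s in range(200)
        ]
        assert np.mean(reals) == pytest.approx(25.0, rel=0.20)

    def test_ci_within_bounds(self):
        for s in range(10):
            k = simulate_karyotype(12, 8.0, 30.0, 35.0, 40.0, seed=s)
            m = summarize_karyotype(k)
            assert all(0 < ci <= 50 for ci in m.ci_values)
            assert 50 <= m.ask_percent <= 100


class TestHistogramSimulator:
    def test_peak_positions(self):
        h = simulate_flow_histogram(61.8, standard_2c_pg=30.9,
                                    standard_channel=120.0, seed=3)
        # sample peak should sit near channel 240 = 120 * 61.8/30.9
        window = h.counts[230:251]
        assert window.sum() > 0.2 * h.counts.sum()

    def test_event_count_and_determinism(self):
        a = simulate_flow_histogram(90.0, events=5000, seed=4)
        b = simulate_flow_histogram(90.0, events=5000, seed=4)
        assert a.counts.sum() == 5000
        assert np.array_equal(a.counts, b.counts)

    def test_out_of_range_peak_rejected(self):
        with pytest.raises(ValueError):
            simulate_flow_histogram(1000.0, n_channels=256)


class TestStudyBundle:
    def test_bundle_deterministic_and_complete(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_tips=12, histograms_per_species=1)
        b1 = make_study_bundle(cfg, out_dir=tmp_path / "b1")
        b2 = make_study_bundle(cfg, out_dir=tmp_path / "b2")
        assert b1["tree"].to_newick() == b2["tree"].to_newick()
        assert b1["traits"].equals(b2["traits"])
        t1 = (tmp_path / "b1" / "traits.tsv").read_text()
        t2 = (tmp_path / "b2" / "traits.tsv").read_text()
        assert t1 == t2
        assert (tmp_path / "b1" / "tree.nwk").exists()
        assert (tmp_path / "b1" / "karyotypes.tsv").exists()
        assert len(list((tmp_path / "b1" / "histograms").glob("*.csv"))) == 12

    def test_trait_table_schema_and_ranges(self):
        cfg = SimulationConfig(seed=10, n_tips=16, histograms_per_species=1)
        bundle = make_study_bundle(cfg)
        df = bundle["traits"]
        assert set(
            [
                "species", "two_c_pg", "one_cx_pg", "ploidy", "HCL", "AsK_pct",
                "CV_CI", "CV_CL", "x", "two_n", "elevation_m",
                "annual_mean_temp_c", "annual_precip_mm", "region", "section",
            ]
        ) <= set(df.columns)
        assert df["two_c_pg"].between(cfg.gs_low - 1e-9, cfg.gs_high + 1e-9).all()
        assert (df["two_n"] == df["x"] * df["ploidy"]).all()
        assert np.allclose(df["one_cx_pg"], df["two_c_pg"] / df["ploidy"], atol=1e-3)

    def test_truth_ledger_matches_config(self):
        cfg = SimulationConfig(seed=11, n_tips=10, histograms_per_species=1)
        bundle = make_study_bundle(cfg)
        truth = bundle["truth"]
        assert truth["lambda"] == cfg.lam
        assert truth["standard_2c_pg"] == cfg.standard_2c_pg
        assert set(truth["true_two_c"]) == set(bundle["tree"].tip_labels)
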