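"""Tree parsing, covariance construction, and alignment."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_mrca_depths
from phylogs.simulate import simulate_yule_tree
from phylogs.tree import (
    NewickError,
    TreeTraitMismatchError,
    align_tree_and_table,
    bm_covariance,
    lambda_transform,
    ou_correlation,
    parse_newick,
    patristic_distances,
)


class TestParseNewick:
    def test_smallest_tree(self, cherry):
        assert cherry.tip_labels == ["A", "B"]
        assert np.allclose(cherry.tip_depths(), [1.0, 1.0])

    def test_three_tip_depths(self, three_tip):
        assert np.allclose(three_tip.tip_depths(), [2.0, 2.0, 2.0])

    @pytest.mark.parametrize(
        "bad",
        [
            "((A:1,B:1:1,C:2);",   # unbalanced parentheses
            "(A:1,A:1);",          # duplicate tips
            "(A:1,B);",            # missing branch length
            "(A:1,B:-1);",         # negative branch length
            "",                    # empty
        ],
    )
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_internal_labels_and_bootstrap_tolerated(self):
        tree = parse_newick("((A:1,B:1)90:1,C:2)root;")
        assert tree.tip_labels == ["A", "B", "C"]

    def test_round_trip_preserves_distances(self):
        tree = simulate_yule_tree(50, 1.0, seed=1)
        again = parse_newick(tree.to_newick())
        d1 = patristic_distances(tree)
        d2 = patristic_distances(again)
        d2 = d2.loc[d1.index, d1.columns]
        assert np.allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-9)


class TestBMCovariance:
    def test_cherry(self, cherry):
        C = bm_covariance(cherry)
        assert np.allclose(C.matrix, np.eye(2))

    def test_three_tip(self, three_tip):
        C = bm_covariance(three_tip).as_dataframe()
        assert np.allclose(np.diag(C.to_numpy()), 2.0)
        assert C.loc["A", "B"] == pytest.approx(1.0)
        assert C.loc["A", "C"] == 0.0 and C.loc["B", "C"] == 0.0

    def test_matches_brute_force_oracle(self, tree20):
        tree, C = tree20
        labels, oracle = brute_force_mrca_depths(tree)
        assert labels == C.tip_order
        assert np.allclose(C.matrix, oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_psd(self, seed):
        tree = simulate_yule_tree(30, 1.0, seed=seed)
        eig = np.linalg.eigvalsh(bm_covariance(tree).matrix)
        assert eig.min() >= -1e-10

    def test_ultrametric_constant_diagonal(self, tree20):
        _, C = tree20
        assert np.allclose(np.diag(C.matrix), C.matrix[0, 0])


class TestLambdaTransform:
    def test_identity_at_one(self, tree20):
        _, C = tree20
        assert np.allclose(lambda_transform(C, 1.0).matrix, C.matrix)

    def test_diagonal_at_zero(self, tree20):
        _, C = tree20
        V = lambda_transform(C, 0.0).matrix
        assert np.allclose(V, np.diag(np.diag(C.matrix)))

    def test_half_on_three_tip(self, three_tip):
        C = bm_covariance(three_tip)
        V = lambda_transform(C, 0.5).as_dataframe()
        assert V.loc["A", "B"] == pytest.approx(0.5)
        assert np.allclose(np.diag(V.to_numpy()), 2.0)

    def test_monotone_in_lambda(self, tree20):
        _, C = tree20
        prev = lambda_transform(C, 0.0).matrix
        for lam in np.linspace(0.1, 1.0, 10):
            cur = lambda_transform(C, lam).matrix
            assert np.all(cur >= prev - 1e-12)
            prev = cur

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_domain_error(self, tree20, lam):
        _, C = tree20
        with pytest.raises(ValueError):
            lambda_transform(C, lam)


class TestPatristic:
    def test_examples(self, cherry, three_tip):
        assert patristic_distances(cherry).loc["A", "B"] == pytest.approx(2.0)
        assert patristic_distances(three_tip).loc["A", "C"] == pytest.approx(4.0)

    def test_matches_path_walk_oracle(self, tree20):
        tree, C = tree20
        D = patristic_distances(tree)
        # oracle: depth_i + depth_j - 2 * brute-force MRCA depth
        labels, mrca = brute_force_mrca_depths(tree)
        depths = np.diag(mrca)
        oracle = depths[:, None] + depths[None, :] - 2 * mrca
        np.fill_diagonal(oracle, 0)
        assert np.allclose(D.loc[labels, labels].to_numpy(), oracle, atol=1e-10)

    def test_triangle_inequality(self, tree20):
        tree, _ = tree20
        D = patristic_distances(tree).to_numpy()
        n = len(D)
        for i in range(n):
            for j in range(n):
                for k in range(0, n, 5):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestOUCorrelation:
    def test_arithmetic(self, cherry):
        D = patristic_distances(cherry)
        R = ou_correlation(D, 0.5)
        assert R.matrix[0, 1] == pytest.approx(np.exp(-1.0))
        assert np.allclose(np.diag(R.matrix), 1.0)

    def test_large_alpha_limit(self, tree20):
        tree, _ = tree20
        R = ou_correlation(patristic_distances(tree), 1e3)
        assert np.allclose(R.matrix, np.eye(tree.n_tips), atol=1e-8)

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 10.0])
    def test_psd(self, tree20, alpha):
        tree, _ = tree20
        R = ou_correlation(patristic_distances(tree), alpha)
        assert np.linalg.eigvalsh(R.matrix).min() >= -1e-10

    def test_consistency_with_depths_on_ultrametric(self, tree20):
        # exp(-alpha d_ij) == exp(-2 alpha (T - t_mrca)) for contemporaneous tips
        tree, C = tree20
        alpha = 0.7
        R = ou_correlation(patristic_distances(tree), alpha).matrix
        T = np.diag(C.matrix)
        independent = np.exp(-2 * alpha * (np.add.outer(T, T) / 2 - C.matrix))
        np.fill_diagonal(independent, 1.0)
        assert np.allclose(R, independent, atol=1e-8)

    def test_alpha_domain(self, cherry):
        with pytest.raises(ValueError):
            ou_correlation(patristic_distances(cherry), 0.0)


class TestAlign:
    def _table(self, species, **cols):
        return pd.DataFrame({"species": species, **cols})

    def test_prune_then_cov_commutes(self, tree20):
        tree, C = tree20
        keep = tree.tip_labels[::2]
        table = self._table(keep, gs=np.arange(len(keep), dtype=float))
        pruned, conformed = align_tree_and_table(
            tree, table, ["gs"], species_col="species"
        )
        sub = bm_covariance(pruned)
        direct = C.restrict_to(sub.tip_order)
        assert np.allclose(sub.matrix, direct.matrix, atol=1e-9)
        assert list(conformed.index) == sub.tip_order

    def test_missing_traits_dropped(self, tree20):
        tree, _ = tree20
        labels = tree.tip_labels
        gs = np.arange(len(labels), dtype=float)
        gs[0] = np.nan
        _, conformed = align_tree_and_table(
            tree, self._table(labels, gs=gs), ["gs"], species_col="species"
        )
        assert labels[0] not in conformed.index
        assert len(conformed) == len(labels) - 1

    def test_empty_intersection_errors(self, three_tip):
        with pytest.raises(TreeTraitMismatchError):
            align_tree_and_table(
                three_tip,
                self._table(["X", "Y"], gs=[1.0, 2.0]),
                ["gs"],
                species_col="species",
            )

    def test_duplicate_rows_error(self, three_tip):
        with pytest.raises(TreeTraitMismatchError):
            align_tree_and_table(
                three_tip,
                self._table(["A", "A", "B"], gs=[1.0, 2.0, 3.0]),
                ["gs"],
                species_col="species",
            )
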