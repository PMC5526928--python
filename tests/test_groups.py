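"""ANOVA, Tukey-HSD and compact-letter display."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from phylogs.groups import (
    GroupStatsError,
    compact_letters,
    compare_groups,
    one_way_anova,
    tukey_hsd,
)


def anova_two_pass_oracle(data):
    """Textbook two-pass ANOVA from per-group lists."""
    all_vals = np.concatenate(data)
    grand = all_vals.mean()
    ssb = sum(len(d) * (np.mean(d) - grand) ** 2 for d in data)
    ssw = sum(float(np.sum((np.asarray(d) - np.mean(d)) ** 2)) for d in data)
    df_b, df_w = len(data) - 1, len(all_vals) - len(data)
    F = (ssb / df_b) / (ssw / df_w)
    return F, float(stats.f.sf(F, df_b, df_w))


def studentized_range_sf_quadrature(q, k, df):
    """Survival function of the studentized range by direct double quadrature.

    P(Q > q) with Q = range of k iid N(0,1) divided by an independent
    chi(df)/sqrt(df) scale: integrates the classical density representation,
    independent of scipy.stats.studentized_range.
    """

    def inner(s):
        # P(range of k std normals <= q*s)
        def f(z):
            return (
                k
                * stats.norm.pdf(z)
                * (stats.norm.cdf(z) - stats.norm.cdf(z - q * s)) ** (k - 1)
            )

        val, _ = integrate.quad(f, -8.5, 8.5 + q * s, limit=200)
        return val

    # density of s = chi_df / sqrt(df)
    log_c = (df / 2) * np.log(df) - special.gammaln(df / 2) - (df / 2 - 1) * np.log(2)

    def outer(s):
        log_dens = log_c + (df - 1) * np.log(s) - df * s * s / 2
        return np.exp(log_dens) * inner(s)

    cdf, _ = integrate.quad(outer, 1e-9, 10.0, limit=200)
    return 1.0 - cdf


def flat_groups(values_by_group):
    values, groups = [], []
    for label, vals in values_by_group.items():
        values.extend(vals)
        groups.extend([label] * len(vals))
    return np.array(values), np.array(groups)


class TestAnova:
    def test_identical_groups(self):
        v, g = flat_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        res = one_way_anova(v, g)
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_shift_invariance(self):
        v, g = flat_groups({"a": [1.0, 2.0, 4.0], "b": [2.0, 5.0, 3.0]})
        res1 = one_way_anova(v, g)
        res2 = one_way_anova(v + 100.0, g)
        assert res2.F == pytest.approx(res1.F, rel=1e-10)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(17)
        data = [rng.normal(m, 1.0, size=n) for m, n in [(0, 8), (0.5, 12), (1.2, 6)]]
        v, g = flat_groups({f"g{i}": d for i, d in enumerate(data)})
        res = one_way_anova(v, g)
        F, p = anova_two_pass_oracle(data)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert (res.df_between, res.df_within) == (2, 23)

    def test_small_group_errors(self):
        v, g = flat_groups({"a": [1.0], "b": [2.0, 3.0]})
        with pytest.raises(GroupStatsError):
            one_way_anova(v, g)

    def test_zero_variance_errors(self):
        v, g = flat_groups({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        with pytest.raises(GroupStatsError):
            one_way_anova(v, g)


class TestTukey:
    def test_identical_groups_p_one(self):
        v, g = flat_groups({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        table = tukey_hsd(v, g)
        assert np.allclose(table["p_adj"], 1.0)

    def test_pair_order_symmetry(self):
        v, g = flat_groups({"a": [1.0, 2.0], "b": [4.0, 5.0], "c": [0.0, 0.5]})
        t1 = tukey_hsd(v, g)
        # reversed input order permutes pairs but must keep the same p per pair
        t2 = tukey_hsd(v[::-1], g[::-1])
        for _, row in t1.iterrows():
            pair = {row["group_i"], row["group_j"]}
            match = t2[
                t2.apply(lambda r: {r["group_i"], r["group_j"]} == pair, axis=1)
            ]
            assert match["p_adj"].iloc[0] == pytest.approx(row["p_adj"], abs=1e-12)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(23)
        data = {
            "g1": rng.normal(0.0, 1.0, 6),
            "g2": rng.normal(0.8, 1.0, 9),
            "g3": rng.normal(1.6, 1.0, 5),
            "g4": rng.normal(0.2, 1.0, 7),
        }
        v, g = flat_groups(data)
        table = tukey_hsd(v, g)
        df_w = len(v) - 4
        for _, row in table.head(3).iterrows():
            oracle = studentized_range_sf_quadrature(row["q"], 4, df_w)
            assert row["p_adj"] == pytest.approx(oracle, abs=1e-6)

    def test_unbalanced_kramer_denominator(self):
        v, g = flat_groups({"a": [0.0, 1.0, 2.0, 3.0], "b": [5.0, 6.0]})
        table = tukey_hsd(v, g)
        anova = one_way_anova(v, g)
        se = np.sqrt(anova.ms_within / 2 * (1 / 4 + 1 / 2))
        assert table["q"].iloc[0] == pytest.approx(
            abs(np.mean([0, 1, 2, 3]) - 5.5) / se
        )


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        S = np.zeros((3, 3), dtype=bool)
        assert compact_letters(S) == ["a", "a", "a"]

    def test_all_different(self):
        S = ~np.eye(4, dtype=bool)
        assert compact_letters(S) == ["a", "b", "c", "d"]

    def test_table_pattern_a_b_a_c(self):
        """Four groups where only the pair (1, 3) is NOT different -> a,b,a,c."""
        S = ~np.eye(4, dtype=bool)
        S[0, 2] = S[2, 0] = False
        assert compact_letters(S) == ["a", "b", "a", "c"]

    def test_chain_pattern(self):
        # 1~2, 2~3 but 1 != 3: letters must overlap pairwise correctly
        S = np.zeros((3, 3), dtype=bool)
        S[0, 2] = S[2, 0] = True
        letters = compact_letters(S)
        assert set(letters[0]) & set(letters[1])
        assert set(letters[1]) & set(letters[2])
        assert not set(letters[0]) & set(letters[2])

    def test_asymmetric_matrix_rejected(self):
        S = np.zeros((3, 3), dtype=bool)
        S[0, 1] = True
        with pytest.raises(GroupStatsError):
            compact_letters(S)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_patterns_audited(self, seed):
        """The built-in audit guarantees letter/significance consistency on
        arbitrary symmetric patterns (insert-and-absorb is exact)."""
        rng = np.random.default_rng(seed)
        k = 6
        S = rng.random((k, k)) < 0.4
        S = np.triu(S, 1)
        S = S | S.T
        letters = compact_letters(S)  # audit raises on inconsistency
        assert all(letters)


class TestCompareGroups:
    def test_end_to_end_partition(self):
        rng = np.random.default_rng(31)
        data = {
            "low1": rng.normal(0.0, 0.5, 10),
            "high": rng.normal(8.0, 0.5, 10),
            "low2": rng.normal(0.1, 0.5, 10),
        }
        v, g = flat_groups(data)
        comp = compare_groups(v, g)
        assert comp.anova.p < 1e-6
        # the two low groups share a letter; the high group stands alone
        assert set(comp.letters[0]) & set(comp.letters[2])
        assert not set(comp.letters[0]) & set(comp.letters[1])

    def test_permuting_groups_preserves_partition(self):
        rng = np.random.default_rng(37)
        data = {
            "a": rng.normal(0, 0.5, 8),
            "b": rng.normal(5, 0.5, 8),
            "c": rng.normal(0.2, 0.5, 8),
        }
        v, g = flat_groups(data)
        comp1 = compare_groups(v, g)

        def partition(labels, letters):
            sig = {}
            for l1, s1 in zip(labels, letters):
                for l2, s2 in zip(labels, letters):
                    sig[(l1, l2)] = bool(set(s1) & set(s2))
            return sig

        perm = np.argsort(g, kind="stable")[::-1]
        comp2 = compare_groups(v[perm], g[perm])
        assert partition(comp1.group_labels, comp1.letters) == partition(
            comp2.group_labels, comp2.letters
        )
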