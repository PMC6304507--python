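"""Permutation ANOVA, BH adjustment, fold change and the significance
filter, each checked against an independent oracle."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from cystomics import (
    QuantMatrix, bh_adjust, diff_test, fold_change, perm_anova,
    select_significant, PermutationAnova,
)


def exhaustive_p_oracle(values, groups):
    """Exact permutation p by brute-force enumeration of ALL n! label
    orderings (distinct assignments counted with multiplicity)."""
    values = np.asarray(values, float)
    f_obs = sps.f_oneway(*[values[groups == g] for g in np.unique(groups)]).statistic
    count = total = 0
    for perm in permutations(range(len(values))):
        v = values[list(perm)]
        f = sps.f_oneway(*[v[groups == g] for g in np.unique(groups)]).statistic
        total += 1
        if f >= f_obs - 1e-9:
            count += 1
    return count / total


class TestPermAnova:
    def test_two_by_two_toy_exact_third(self):
        """{1,2} vs {10,11}: 6 distinct assignments, the observed split and
        its mirror maximize F, so the exact p is 1/3."""
        values = np.array([1.0, 2.0, 10.0, 11.0])
        groups = np.array(["A", "A", "B", "B"])
        f, p = perm_anova(values, groups, exhaustive_limit=100)
        assert p == pytest.approx(1 / 3)
        assert p == pytest.approx(exhaustive_p_oracle(values, groups))

    def test_exhaustive_matches_bruteforce_three_groups(self):
        values = np.array([1.0, 2.0, 5.0, 7.0, 3.0, 3.5])
        groups = np.array(["A", "A", "B", "B", "C", "C"])
        _, p = perm_anova(values, groups, exhaustive_limit=10**6)
        assert p == pytest.approx(exhaustive_p_oracle(values, groups))

    def test_f_statistic_matches_scipy(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=12)
        groups = np.repeat(["A", "B", "C"], 4)
        f, _ = perm_anova(values, groups, exhaustive_limit=1)  # force MC, F same
        expected = sps.f_oneway(*[values[groups == g] for g in "ABC"]).statistic
        assert f == pytest.approx(expected)

    def test_degenerate_constant_data(self):
        values = np.full(6, 3.0)
        groups = np.repeat(["A", "B"], 3)
        f, p = perm_anova(values, groups)
        assert f == 0.0 and p == 1.0

    def test_monte_carlo_agrees_with_exhaustive_within_3se(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, size=8)
        values[:4] += 1.0
        groups = np.repeat(["A", "B"], 4)
        _, p_exact = perm_anova(values, groups, exhaustive_limit=10**5)
        n_perm = 9999
        _, p_mc = perm_anova(values, groups, n_perm=n_perm, seed=7, exhaustive_limit=1)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 3 * se + 2 / n_perm

    def test_null_pvalues_uniform(self):
        """On pure-noise features the permutation p-values are uniform on
        the achievable quantiles (KS test)."""
        rng = np.random.default_rng(3)
        groups = np.repeat(["A", "B", "C"], 5)
        pvals = []
        for _ in range(400):
            v = rng.normal(size=15)
            _, p = perm_anova(v, groups, n_perm=499, seed=rng, exhaustive_limit=1)
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_values_excluded(self):
        values = np.array([1.0, 2.0, np.nan, 10.0, 11.0, np.nan])
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        f, p = perm_anova(values, groups, exhaustive_limit=100)
        f2, p2 = perm_anova(
            np.array([1.0, 2.0, 10.0, 11.0]), np.array(["A", "A", "B", "B"]),
            exhaustive_limit=100,
        )
        assert f == pytest.approx(f2) and p == pytest.approx(p2)

    def test_insufficient_groups_raise(self):
        with pytest.raises(ValueError):
            perm_anova(np.array([1.0, 2.0, 3.0]), np.array(["A", "A", "A"]))
        with pytest.raises(ValueError):
            perm_anova(
                np.array([1.0, np.nan, 3.0, 4.0]),
                np.array(["A", "A", "B", "B"]),
            )


def bh_oracle(p):
    """Brute-force BH: all m rescalings + cumulative minimum from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-6, 1, size=500)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-15)


class TestFoldChange:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ({"A": 3.0, "B": 3.0}, 1.0),
            ({"A": 1.0, "B": 2.0}, 2.0),
            ({"A": 1.0, "B": 2.0, "C": 3.585}, 2 ** 2.585),
        ],
    )
    def test_values(self, means, expected):
        assert fold_change(means) == pytest.approx(expected)

    def test_fewer_than_two_means_undefined(self):
        with pytest.raises(ValueError):
            fold_change({"A": 1.0, "B": np.nan})


class TestSelection:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "p_adj", "fc"])

    def test_boundary_inclusive(self):
        res = self._frame([("f1", 0.05, 1.5)])
        assert len(select_significant(res, 0.05, 1.5)) == 1

    def test_fc_failure_excludes(self):
        res = self._frame([("f1", 0.049, 1.49)])
        assert select_significant(res, 0.05, 1.5).empty

    def test_empty_input(self):
        assert select_significant(self._frame([]), 0.05, 1.5).empty

    def test_stable_ordering(self):
        res = self._frame([("b", 0.01, 2.0), ("a", 0.01, 2.0), ("c", 0.001, 2.0)])
        assert list(select_significant(res)["feature_id"]) == ["c", "a", "b"]


class TestDiffTest:
    def _dataset(self, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(20, 0.5, size=(40, 12))
        data[:4, 6:] += 2.0  # 4 true differential features, log2FC = 2
        features = [f"f{i:02d}" for i in range(40)]
        samples = [f"s{j:02d}" for j in range(12)]
        qm = QuantMatrix(pd.DataFrame(data, index=features, columns=samples), "log2")
        groups = pd.Series(np.repeat(["A", "B"], 6), index=samples)
        return qm, groups

    def test_spiked_features_detected(self):
        qm, groups = self._dataset()
        res = diff_test(qm, groups, n_perm=999, seed=1)
        hits = set(res[res["significant"]]["feature_id"])
        assert {"f00", "f01", "f02", "f03"} <= hits
        assert len(hits) <= 6  # at most a couple of false positives

    def test_unc_samples_excluded(self):
        qm, groups = self._dataset()
        groups.iloc[0] = "UNC"
        res = diff_test(qm, groups, n_perm=99, seed=1)
        assert res["n_A"].max() == 5

    def test_untested_features_flagged(self):
        qm, groups = self._dataset()
        qm.data.iloc[0, :6] = np.nan  # group A absent for f00
        res = diff_test(qm, groups, n_perm=99, seed=1).set_index("feature_id")
        assert not res.loc["f00", "tested"]
        assert np.isnan(res.loc["f00", "p_adj"])

    def test_sklearn_wrapper_exposes_fitted_attributes(self):
        qm, groups = self._dataset()
        est = PermutationAnova(n_perm=199, seed=0).fit(
            qm.to_samples_by_features(), groups.to_numpy()
        )
        assert est.pvalues_.shape == (40,)
        assert est.significant_[:4].all()
        kept = est.transform(qm.to_samples_by_features())
        assert kept.shape[1] == est.significant_.sum()
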