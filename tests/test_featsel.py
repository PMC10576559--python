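"""Scaling and selectors: hand values, exact-enumeration oracle, recovery."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from gliomets.featsel import (
    fit_apply_scaler,
    lasso_select,
    mi_select,
    mwu_prefilter,
    pearson_matrix,
    rfe_rf_select,
)


def exact_mwu_pvalue(a, b):
    """Two-sided Mann-Whitney p by exhaustive enumeration of group splits."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                u += (xi > yi) + 0.5 * (xi == yi)
        return u

    observed = u_stat(a, b)
    mean_u = n1 * len(b) / 2.0
    count = total = 0
    idx = np.arange(len(pooled))
    for comb in combinations(idx, n1):
        comb = set(comb)
        x = pooled[[i in comb for i in idx]]
        y = pooled[[i not in comb for i in idx]]
        if abs(u_stat(x, y) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestScaler:
    def test_hand_values(self):
        table = pd.DataFrame({"f": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
        scaled, state = fit_apply_scaler(table, np.array([True, True, True]))
        np.testing.assert_allclose(
            scaled["f"].to_numpy(), [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_train_statistics_applied_to_test(self):
        table = pd.DataFrame(
            {"f": [2.0, 4.0, 6.0, 4.0, 100.0]},
            index=["t1", "t2", "t3", "v1", "v2"],
        )
        train = np.array([True, True, True, False, False])
        scaled, state = fit_apply_scaler(table, train)
        assert scaled.loc["v1", "f"] == pytest.approx(0.0)  # equals train mean
        # stored state reproduces the transform bit-exactly
        again = state.transform(table)
        np.testing.assert_array_equal(scaled.to_numpy(), again.to_numpy())

    def test_constant_features_dropped(self):
        table = pd.DataFrame({"c": [1.0, 1.0, 1.0], "f": [1.0, 2.0, 3.0]})
        scaled, state = fit_apply_scaler(table, np.array([True, True, True]))
        assert state.dropped_constant == ["c"]
        assert list(scaled.columns) == ["f"]


class TestMannWhitney:
    def test_identical_groups_dropped(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=20)
        table = pd.DataFrame({"same": np.concatenate([vals[:10], vals[:10]])})
        labels = np.array([0] * 10 + [1] * 10)
        res = mwu_prefilter(table, labels)
        assert res.kept_features == []
        assert res.params["alpha"] == 0.05

    def test_perfect_separation_kept(self):
        table = pd.DataFrame({"sep": np.r_[np.arange(10), np.arange(10) + 100.0]})
        labels = np.array([0] * 10 + [1] * 10)
        res = mwu_prefilter(table, labels)
        assert res.kept_features == ["sep"]
        assert res.scores["sep"] < 0.001

    def test_single_class_errors(self):
        table = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            mwu_prefilter(table, np.array([1, 1]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_asymptotic_close_to_exact_enumeration(self, seed):
        """Normal-approximation p within 0.02 of the exhaustive oracle, n<=8."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, 7)
        b = rng.normal(0.8, 1.0, 6)
        table = pd.DataFrame({"f": np.concatenate([a, b])})
        labels = np.array([0] * 7 + [1] * 6)
        res = mwu_prefilter(table, labels)
        assert abs(res.scores["f"] - exact_mwu_pvalue(a, b)) <= 0.02


def _planted_table(n=200, n_noise=20, n_info=1, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    cols = {}
    for i in range(n_info):
        cols[f"info{i}"] = labels * 2.0 + rng.normal(0, 0.6, n)
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(0, 1.0, n)
    table = pd.DataFrame(cols)
    scaled = (table - table.mean()) / table.std(ddof=0)
    return scaled, labels


class TestLasso:
    def test_recovers_planted_feature(self):
        table, labels = _planted_table(seed=1)
        res = lasso_select(table, labels, cv_folds=5, seed=1)
        assert "info0" in res.kept_features
        scores = [res.scores[f] for f in res.kept_features]
        assert scores == sorted(scores, reverse=True)

    def test_infinite_penalty_empty(self):
        table, labels = _planted_table(n=60, seed=2)
        with pytest.warns(UserWarning, match="zero"):
            res = lasso_select(table, labels, penalty_grid=(1e-6,), cv_folds=3, seed=0)
        assert res.kept_features == []


class TestMutualInformation:
    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 50)
        table = pd.DataFrame(
            {"copy": labels.astype(float), "noise": rng.normal(size=100)}
        )
        res = mi_select(table, labels, top_n=1, seed=0)
        assert res.kept_features == ["copy"]

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1], 250)
        table = pd.DataFrame({"indep": rng.normal(size=500)})
        res = mi_select(table, labels, top_n=1, seed=0)
        assert res.scores["indep"] < 0.05

    def test_top_n_clipped(self):
        table, labels = _planted_table(n=40, n_noise=3, seed=5)
        with pytest.warns(UserWarning, match="clip"):
            res = mi_select(table, labels, top_n=100, seed=0)
        assert len(res.kept_features) == table.shape[1]


class TestRfeRf:
    def test_recovers_two_planted_features(self):
        table, labels = _planted_table(n=300, n_noise=30, n_info=2, seed=6)
        res = rfe_rf_select(table, labels, n_keep=5, seed=6)
        assert {"info0", "info1"} <= set(res.kept_features)

    def test_identity_when_keeping_all(self):
        table, labels = _planted_table(n=60, n_noise=4, seed=7)
        res = rfe_rf_select(table, labels, n_keep=table.shape[1], seed=0)
        assert set(res.kept_features) == set(table.columns)

    def test_deterministic(self):
        table, labels = _planted_table(n=80, n_noise=6, seed=8)
        a = rfe_rf_select(table, labels, n_keep=3, seed=5)
        b = rfe_rf_select(table, labels, n_keep=3, seed=5)
        assert a.kept_features == b.kept_features


class TestPearson:
    def test_hand_values_and_structure(self):
        table = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0], "y": [3.0, 2.0, 1.0], "x2": [2.0, 4.0, 6.0]}
        )
        corr = pearson_matrix(table)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["x", "y"] == pytest.approx(-1.0)
        assert corr.loc["x", "x2"] == pytest.approx(1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_constant_column_zeroed(self):
        table = pd.DataFrame({"c": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            corr = pearson_matrix(table)
        assert corr.loc["c", "x"] == 0.0
        assert corr.loc["c", "c"] == 1.0


def test_no_test_label_leakage():
    """Shuffling test labels changes nothing fitted upstream of evaluation."""
    rng = np.random.default_rng(9)
    table = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"f{i}" for i in range(8)])
    labels = np.repeat([0, 1], 30)
    train = np.zeros(60, dtype=bool)
    train[:40] = True
    scaled_a, state_a = fit_apply_scaler(table, train)
    sel_a = mwu_prefilter(scaled_a.loc[train], labels[:40])

    shuffled = labels.copy()
    rng.shuffle(shuffled[40:])  # only test labels change
    scaled_b, state_b = fit_apply_scaler(table, train)
    sel_b = mwu_prefilter(scaled_b.loc[train], shuffled[:40])

    pd.testing.assert_series_equal(state_a.mean, state_b.mean)
    assert sel_a.kept_features == sel_b.kept_features
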