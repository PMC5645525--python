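"""Kendall tau-b ranking, selection, z-scoring, linear SVM, LOOCV, metrics,
Welch t."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

import dynfc
from dynfc.classify import kendall_tau_batch
from dynfc.errors import InvalidInputError, InvalidParameterError


def tau_b_bruteforce(x, y):
    """O(n^2) pair enumeration of tie-corrected tau-b."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (c - d) / denom if denom > 0 else 0.0


class TestKendallTau:
    def test_monotone_feature_example(self):
        labels = np.array([-1, -1, 1, 1])
        tau = dynfc.kendall_tau_b(np.array([0.1, 0.2, 0.3, 0.4]), labels)
        assert tau == pytest.approx(4.0 / np.sqrt(4 * 6), abs=1e-12)

    def test_oracle_equivalence(self, rng):
        # 1,000 random instances vs pair enumeration (and scipy as referee)
        for k in range(1000):
            n = int(rng.integers(6, 30))
            labels = np.concatenate([np.ones(n // 2 + 1), -np.ones(n - n // 2 - 1)])
            x = np.round(rng.standard_normal(n), 1)  # induce value ties
            mine = dynfc.kendall_tau_b(x, labels)
            assert abs(mine - tau_b_bruteforce(x, labels)) < 1e-12
            if k < 50:
                ref = scipy_stats.kendalltau(x, labels).statistic
                assert mine == pytest.approx(ref, abs=1e-12)

    def test_antisymmetry(self, rng):
        labels = np.concatenate([np.ones(10), -np.ones(10)])
        x = rng.standard_normal(20)
        assert dynfc.kendall_tau_b(-x, labels) == pytest.approx(
            -dynfc.kendall_tau_b(x, labels), abs=1e-14
        )

    def test_permutation_null_centred(self, rng):
        # independent features: mean tau over 10^4 draws within +/-0.02 of 0
        labels = np.concatenate([np.ones(27), -np.ones(25)])
        x = rng.standard_normal((52, 10000))
        taus = kendall_tau_batch(x, labels)
        assert abs(taus.mean()) < 0.02

    def test_constant_feature_warns_zero(self):
        labels = np.array([1, 1, -1, -1])
        with pytest.warns(UserWarning):
            assert dynfc.kendall_tau_b(np.ones(4), labels) == 0.0


def make_table(rng, n_sub=12, n_pairs=10, types=("hurst", "variance", "static_fc")):
    import pandas as pd
    from dynfc.features import _TYPE_PREFIX
    pairs = dynfc.component_pairs(5)[:n_pairs]
    rows = []
    for t in types:
        for pid, (i, j) in enumerate(pairs):
            rows.append((f"{_TYPE_PREFIX[t]}__{i}_{j}", t, int(i), int(j), pid))
    info = pd.DataFrame(rows, columns=["feature_id", "ftype", "comp_i", "comp_j", "pair_id"])
    labels = np.concatenate([np.ones(n_sub // 2, dtype=int), -np.ones(n_sub - n_sub // 2, dtype=int)])
    values = rng.standard_normal((n_sub, len(info)))
    return dynfc.FeatureTable(values=values, info=info, labels=labels)


class TestRankAndSelect:
    def test_union_counts(self, rng):
        table = make_table(rng)
        sel = dynfc.rank_and_select(table, table.labels,
                                    {"hurst": 3, "variance": 5, "static_fc": 0})
        assert sel["hurst"].size == 3 and sel["variance"].size == 5
        assert sel["__union__"].size == 8

    def test_k_too_large_rejected(self, rng):
        table = make_table(rng)
        with pytest.raises(InvalidParameterError):
            dynfc.rank_and_select(table, table.labels, {"hurst": 11})

    def test_tie_break_lowest_indices(self, rng):
        table = make_table(rng)
        table.values[:, :10] = table.values[:, [0]]  # all hurst features equal
        sel = dynfc.rank_and_select(table, table.labels, {"hurst": 4})
        np.testing.assert_array_equal(np.sort(sel["hurst"]), np.arange(4))


class TestZScore:
    def test_formula(self):
        train = np.array([[3.0], [5.0], [7.0]])  # mean 5, sd 2
        _, test_z, mean, sd = dynfc.zscore_fit_apply(train, np.array([[9.0]]))
        assert test_z[0, 0] == pytest.approx(2.0)
        assert mean[0] == 5.0 and sd[0] == 2.0

    def test_training_column_standardized(self, rng):
        train = rng.standard_normal((30, 4)) * 5 + 2
        tr_z, _, _, _ = dynfc.zscore_fit_apply(train, train[:1])
        np.testing.assert_allclose(tr_z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(tr_z.std(axis=0, ddof=1), 1.0, rtol=1e-12)

    def test_constant_column_guarded(self):
        train = np.ones((5, 1))
        with pytest.warns(UserWarning):
            tr_z, te_z, _, sd = dynfc.zscore_fit_apply(train, np.array([[1.0]]))
        assert sd[0] == 1.0
        np.testing.assert_array_equal(tr_z, 0.0)


class TestLinearSVM:
    def test_separable_data(self):
        x = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        w, b = dynfc.train_linear_svm(x, y)
        assert np.all(np.sign(x @ w + b) == y)

    def test_informative_feature_recovery(self, rng):
        x = rng.standard_normal((200, 2))
        y = np.sign(x[:, 0]).astype(int)
        y[y == 0] = 1
        w, _ = dynfc.train_linear_svm(x, y)
        assert abs(w[0]) > 5 * abs(w[1])

    def test_single_class_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            dynfc.train_linear_svm(rng.standard_normal((4, 2)), np.ones(4))


class TestLOOCV:
    def test_fold_structure(self, rng):
        table = make_table(rng, n_sub=10)
        cv = dynfc.loocv(table, {"hurst": 3, "variance": 3})
        assert len(cv.folds) == 10
        assert sorted(f.test_index for f in cv.folds) == list(range(10))

    def test_metrics_conservation(self, rng):
        table = make_table(rng, n_sub=14)
        cv = dynfc.loocv(table, {"hurst": 3})
        m = cv.metrics
        assert m.tp + m.fn == (table.labels == 1).sum()
        assert m.tn + m.fp == (table.labels == -1).sum()

    def test_no_leakage(self, rng):
        # mutating the held-out subject's features changes nothing in that
        # fold's selection, normalization statistics or weights
        table = make_table(rng, n_sub=10)
        cv = dynfc.loocv(table, {"hurst": 3, "variance": 3})
        fold = cv.folds[4]
        mutated = make_table(rng, n_sub=10)
        mutated.values[:] = table.values
        mutated.values[4] = 1e6 * rng.standard_normal(table.n_features)
        cv2 = dynfc.loocv(mutated, {"hurst": 3, "variance": 3})
        fold2 = cv2.folds[4]
        np.testing.assert_array_equal(fold.selected_union, fold2.selected_union)
        np.testing.assert_array_equal(fold.train_mean, fold2.train_mean)
        np.testing.assert_array_equal(fold.train_sd, fold2.train_sd)
        np.testing.assert_array_equal(fold.weights, fold2.weights)


class TestNestedProtocol:
    def test_inner_loop_chooses_k_per_fold(self, rng):
        table = make_table(rng, n_sub=10)
        cv = dynfc.loocv_nested(table, types=("hurst", "variance"), k_max=3)
        assert len(cv.folds) == 10
        # every fold selected between 1 and k_max features per type
        for fold in cv.folds:
            for ftype in ("hurst", "variance"):
                assert 1 <= fold.selected[ftype].size <= 3


class TestGridSearch:
    def test_accuracy_vector_shape_and_max(self, rng):
        table = make_table(rng, n_sub=12)
        gs = dynfc.grid_search_k(table, types=("hurst",), k_max=10)
        assert gs.accuracy["hurst"].shape == (10,)
        assert gs.best_accuracy >= gs.accuracy["hurst"].max() - 1e-12

    def test_best_k_ties_take_smallest(self, rng):
        table = make_table(rng, n_sub=8)
        gs = dynfc.grid_search_k(table, types=("hurst",), k_max=5)
        accs = gs.accuracy["hurst"]
        assert gs.best_k["hurst"] == int(np.argmax(accs)) + 1


class TestEvaluate:
    def test_perfect_decision_values(self):
        labels = np.array([1, 1, -1, -1])
        m = dynfc.evaluate(labels, labels, decision_values=[2.0, 1.0, -1.0, -2.0])
        assert m.auc == 1.0 and m.accuracy == 1.0

    def test_null_auc_centred(self, rng):
        labels = np.concatenate([np.ones(27), -np.ones(25)])
        aucs = []
        for _ in range(1000):
            dec = rng.standard_normal(52)
            aucs.append(dynfc.evaluate(labels, np.sign(dec), decision_values=dec).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_empty_class_rejected(self):
        with pytest.raises(InvalidInputError):
            dynfc.evaluate(np.ones(4), np.ones(4))


class TestWelchT:
    def test_identical_summaries_zero(self):
        g = dynfc.GroupSummary(10.0, 2.0, 20)
        assert dynfc.welch_t(g, g).t == 0.0

    def test_zero_scale_rejected(self):
        g = dynfc.GroupSummary(1.0, 0.0, 5)
        with pytest.raises(InvalidInputError):
            dynfc.welch_t(g, g)
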