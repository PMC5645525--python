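"""Activation-pattern transform, standard activation, component importance,
consensus connections."""

import numpy as np
import pytest

import dynfc
from dynfc.errors import InvalidInputError


class TestFoldActivation:
    def test_scalar_reduction(self, rng):
        x = rng.standard_normal((40, 1)) * 3.0
        y = np.sign(rng.standard_normal(40))
        y[y == 0] = 1
        a = dynfc.fold_activation(x, y, np.array([2.0]))
        expected = x[:, 0].var(ddof=1) * 2.0 / y.var(ddof=1)
        assert a[0] == pytest.approx(expected, rel=1e-12)

    def test_whitened_features_proportional_to_weights(self, rng):
        # identity covariance: A = W / var(S)
        n = 5000
        x = rng.standard_normal((n, 3))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        y = np.sign(rng.standard_normal(n))
        y[y == 0] = 1
        w = np.array([1.0, -2.0, 0.5])
        a = dynfc.fold_activation(x, y, w)
        np.testing.assert_allclose(a, w / y.var(ddof=1), atol=0.1)

    def test_suppressor_channel_silenced(self, rng):
        # classic suppressor: x1 = signal + noise, x2 = noise only; the
        # least-squares weight on x2 is nonzero but its activation vanishes
        n = 2000
        s = np.sign(rng.standard_normal(n))
        s[s == 0] = 1
        noise = rng.standard_normal(n)
        x = np.column_stack([s + noise, noise])
        weights = np.linalg.lstsq(x - x.mean(0), s - s.mean(), rcond=None)[0]
        assert abs(weights[1]) > 0.1  # suppressor weight is clearly nonzero
        a = dynfc.fold_activation(x, s, weights)
        assert abs(a[1]) < 0.05 * abs(a[0])

    def test_single_class_fold_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            dynfc.fold_activation(rng.standard_normal((5, 1)), np.ones(5), np.array([1.0]))

    def test_scale_covariance(self, rng):
        # scaling one feature by a > 0 and refitting least-squares weights
        # scales that feature's activation by a
        n = 3000
        s = np.sign(rng.standard_normal(n))
        s[s == 0] = 1
        noise = rng.standard_normal(n)
        x = np.column_stack([s + noise, noise])
        for scale in (1.0, 3.0):
            xs = x.copy()
            xs[:, 0] *= scale
            w = np.linalg.lstsq(xs - xs.mean(0), s - s.mean(), rcond=None)[0]
            a = dynfc.fold_activation(xs, s, w)
            if scale == 1.0:
                base = a[0]
        assert a[0] == pytest.approx(scale * base, rel=1e-6)


class TestStandardActivation:
    def test_half_selected_average(self):
        patterns = np.array([[2.0], [-2.0], [0.0], [0.0]])
        assert dynfc.standard_activation(patterns)[0] == 1.0

    def test_never_selected_zero(self):
        patterns = np.zeros((5, 3))
        np.testing.assert_array_equal(dynfc.standard_activation(patterns), 0.0)

    def test_single_fold_identity(self):
        p = np.array([[1.5, -0.5]])
        np.testing.assert_allclose(dynfc.standard_activation(p), [1.5, 0.5])


class TestComponentImportance:
    def test_incidence_sums(self):
        pairs = np.array([[0, 1], [0, 2]])
        comp, _ = dynfc.component_importance(np.array([2.0, 3.0]), pairs, 3)
        np.testing.assert_allclose(comp, [5.0, 2.0, 3.0])

    def test_threshold_rule_no_outlier_in_small_profile(self):
        # component profile (10, 1, 1, 1, 1, 0): mean + 2 sd exceeds 10,
        # so nothing is flagged -- the rule needs a genuine outlier
        pairs = np.array([[0, 5], [1, 2], [3, 4]])
        vals = np.array([10.0, 1.0, 1.0])
        comp, important = dynfc.component_importance(vals, pairs, 6)
        np.testing.assert_allclose(comp, [10.0, 1.0, 1.0, 1.0, 1.0, 10.0])
        profile = np.array([10.0, 1.0, 1.0, 1.0, 1.0])
        assert profile.max() < profile.mean() + 2 * profile.std(ddof=1)
        assert important.size == 0

    def test_flat_profile_flags_none(self):
        pairs = np.array([[0, 1], [2, 3]])
        with pytest.warns(UserWarning):
            _, important = dynfc.component_importance(np.array([1.0, 1.0]), pairs, 4)
        assert important.size == 0

    def test_clear_outlier_detected(self):
        vals = np.zeros(20)
        vals[0] = 5.0
        pairs = np.column_stack([np.arange(20), np.full(20, 20)])
        comp, important = dynfc.component_importance(vals, pairs, 21)
        assert 0 in important


class TestConsensus:
    def _cv(self, selections):
        folds = []
        for k, sel in enumerate(selections):
            folds.append(dynfc.classify.FoldResult(
                test_index=k, test_subject=f"s{k}",
                selected={"hurst": np.asarray(sel)},
                selected_union=np.asarray(sel),
                weights=np.ones(len(sel)), bias=0.0,
                train_mean=np.zeros(len(sel)), train_sd=np.ones(len(sel)),
                zscored_mask=np.ones(len(sel), bool),
                decision_value=0.0, predicted=1, true_label=1,
            ))
        return dynfc.CVResult(folds=folds, labels=np.ones(len(selections)),
                              subject_ids=[f.test_subject for f in folds],
                              k_per_type={"hurst": 2})

    def test_feature_in_all_folds_included(self):
        cv = self._cv([[1, 2], [2, 3], [2, 4]])
        np.testing.assert_array_equal(dynfc.consensus_connections(cv)["hurst"], [2])

    def test_feature_missing_once_excluded(self):
        cv = self._cv([[1, 2], [1, 3], [3, 4]])
        assert 1 not in dynfc.consensus_connections(cv)["hurst"]

    def test_disjoint_selections_empty(self):
        cv = self._cv([[1], [2], [3]])
        assert dynfc.consensus_connections(cv)["hurst"].size == 0


class TestEndToEndActivation:
    def test_analyze_activation_shapes(self, tiny_table):
        cv = dynfc.loocv(tiny_table, {"hurst": 4, "variance": 4})
        act = dynfc.analyze_activation(tiny_table, cv)
        assert act.standard_values.shape == (tiny_table.n_features,)
        assert np.all(act.standard_values >= 0)
        for ftype in ("hurst", "variance"):
            assert act.component_values[ftype].shape == (8,)
            assert set(act.important_components[ftype]) <= set(range(8))
        # unselected features carry exactly zero
        never = np.setdiff1d(
            np.arange(tiny_table.n_features),
            np.concatenate([f.selected_union for f in cv.folds]),
        )
        np.testing.assert_array_equal(act.standard_values[never], 0.0)
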