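"""Two-input classification, ROC averaging, and group contrasts."""

import numpy as np
import pandas as pd
import pytest

from bradykinet.evaluation import (
    MODEL_NAMES,
    build_feature_table,
    cross_validate,
    external_validate,
    group_compare,
    make_classifier,
    train_classifier,
)


def _tidy(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "task", "condition", "hand", "speed"]
    )


def _wide(n_pd=8, n_hs=8, pd_loc=1.8, hs_loc=2.9, sd=0.15, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pd):
        rows.append((f"PD{i}", "PD", rng.normal(pd_loc, sd), rng.normal(pd_loc, sd)))
    for i in range(n_hs):
        rows.append((f"HS{i}", "HS", rng.normal(hs_loc, sd), rng.normal(hs_loc, sd)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "left_value", "right_value"])


class TestBuildFeatureTable:
    def _table(self):
        rows = []
        for sid, grp, l, r in [("a", "PD", 1.0, 1.2), ("b", "PD", 1.1, 1.3),
                               ("c", "HS", 2.0, 2.2), ("d", "HS", 2.1, 2.3)]:
            rows.append((sid, grp, "finger_tapping", "unilateral", "left", l))
            rows.append((sid, grp, "finger_tapping", "unilateral", "right", r))
        return _tidy(rows)

    def test_pivot_puts_left_and_right_in_one_row(self):
        wide = build_feature_table(self._table(), "speed", "finger_tapping", "unilateral")
        assert len(wide) == 4
        row = wide[wide["subject_id"] == "a"].iloc[0]
        assert row["left_value"] == 1.0 and row["right_value"] == 1.2

    def test_subject_with_undefined_side_is_dropped_not_imputed(self):
        t = self._table()
        extra = _tidy([("e", "HS", "finger_tapping", "unilateral", "left", np.nan),
                       ("e", "HS", "finger_tapping", "unilateral", "right", 2.0)])
        wide = build_feature_table(pd.concat([t, extra]), "speed",
                                   "finger_tapping", "unilateral")
        assert "e" not in set(wide["subject_id"])

    def test_too_few_subjects_per_class_errors(self):
        t = self._table()
        t = t[t["subject_id"] != "a"]
        with pytest.raises(ValueError, match="at least 2"):
            build_feature_table(t, "speed", "finger_tapping", "unilateral")

    def test_unknown_feature_and_empty_selection_error(self):
        with pytest.raises(KeyError):
            build_feature_table(self._table(), "vigor", "finger_tapping", "unilateral")
        with pytest.raises(ValueError, match="no rows"):
            build_feature_table(self._table(), "speed", "hand_grasp", "unilateral")


class TestClassifiers:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_factory_covers_all_models(self, name):
        clf = make_classifier(name, seed=1)
        assert hasattr(clf, "fit") and hasattr(clf, "predict_proba")

    def test_unknown_model_errors(self):
        with pytest.raises(ValueError, match="unknown model"):
            make_classifier("svm")

    def test_train_rejects_single_class(self):
        rows = _wide(n_pd=4, n_hs=4)
        rows = rows[rows["group"] == "PD"]
        with pytest.raises(ValueError, match="single class"):
            train_classifier(rows, "logistic_regression")

    def test_random_forest_seeded(self):
        rows = _wide()
        a = train_classifier(rows, "random_forest", seed=7)
        b = train_classifier(rows, "random_forest", seed=7)
        X = rows[["left_value", "right_value"]].to_numpy()
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))


class TestCrossValidate:
    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_separable_classes_reach_ceiling(self, model):
        # The vertically averaged curve pins tpr=0 at fpr=0, so on the
        # 101-point grid a perfect separation yields exactly 1 - 0.005.
        cv = cross_validate(_wide(sd=0.05), model, k=4, seed=0)
        assert cv.fold_auc == [1.0, 1.0, 1.0, 1.0]
        assert cv.auc == pytest.approx(0.995)
        assert cv.sensitivity == 1.0 and cv.specificity >= 0.99

    def test_deterministic_for_fixed_seed(self):
        rows = _wide(pd_loc=2.2, hs_loc=2.6, sd=0.4)
        a = cross_validate(rows, "logistic_regression", seed=3)
        b = cross_validate(rows, "logistic_regression", seed=3)
        assert a.auc == b.auc and a.fold_auc == b.fold_auc

    def test_mean_curve_is_valid_roc(self):
        cv = cross_validate(_wide(pd_loc=2.2, hs_loc=2.6, sd=0.4), "gaussian_naive_bayes")
        assert cv.mean_tpr[0] == 0.0 and cv.mean_tpr[-1] == 1.0
        assert np.all(np.diff(cv.mean_tpr) >= -1e-12)
        assert 0.0 <= cv.auc <= 1.0
        assert len(cv.fold_auc) == 4

    def test_label_swap_is_relearned_under_refit(self):
        # Swapping the class labels and refitting per fold must give the
        # same discrimination: the classifier simply learns the flipped map.
        rows = _wide(pd_loc=2.0, hs_loc=2.8, sd=0.3, seed=5)
        swapped = rows.copy()
        swapped["group"] = np.where(rows["group"] == "PD", "HS", "PD")
        a = cross_validate(rows, "logistic_regression", seed=0)
        b = cross_validate(swapped, "logistic_regression", seed=0)
        assert b.auc == pytest.approx(a.auc, abs=0.02)

    def test_k_larger_than_class_errors(self):
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(_wide(n_pd=3, n_hs=8), "logistic_regression", k=4)


class _ColumnScorer:
    """Stand-in fitted model whose PD probability is the left_value column."""

    def predict_proba(self, X):
        p = np.clip(X[:, 0], 0.0, 1.0)
        return np.column_stack([1 - p, p])


class TestExternalValidate:
    def test_auc_and_threshold_accuracy(self):
        rows = pd.DataFrame({
            "subject_id": list("abcdef"),
            "group": ["PD", "PD", "PD", "HS", "HS", "HS"],
            "left_value": [0.9, 0.8, 0.4, 0.3, 0.2, 0.6],
            "right_value": [0.0] * 6,
        })
        res = external_validate(_ColumnScorer(), rows, model="column")
        # ranks: one HS (0.6) above one PD (0.4) -> AUC = 8/9
        assert res.auc == pytest.approx(8 / 9)
        # 0.5 threshold: PD 0.4 and HS 0.6 are both wrong -> 4/6 correct
        assert res.accuracy == pytest.approx(4 / 6)
        assert res.n_cases == 3 and res.n_controls == 3

    def test_label_swap_complements_auc_for_fixed_scorer(self):
        rows = pd.DataFrame({
            "subject_id": list("abcdef"),
            "group": ["PD", "PD", "PD", "HS", "HS", "HS"],
            "left_value": [0.9, 0.8, 0.4, 0.3, 0.2, 0.6],
            "right_value": [0.0] * 6,
        })
        swapped = rows.copy()
        swapped["group"] = np.where(rows["group"] == "PD", "HS", "PD")
        a = external_validate(_ColumnScorer(), rows)
        b = external_validate(_ColumnScorer(), swapped)
        assert a.auc + b.auc == pytest.approx(1.0)

    def test_fitted_model_generalizes_to_held_out_cohort(self):
        train = _wide(seed=1)
        val = _wide(n_pd=4, n_hs=4, seed=2)
        clf = train_classifier(train, "logistic_regression")
        res = external_validate(clf, val, "logistic_regression")
        assert res.auc == pytest.approx(1.0)
        assert res.accuracy == 1.0


class TestGroupCompare:
    def _inputs(self, pd_vals, hs_vals):
        rows, side = [], []
        for i, (worse, better) in enumerate(pd_vals):
            sid = f"PD{i}"
            rows.append((sid, "PD", "finger_tapping", "unilateral", "left", worse))
            rows.append((sid, "PD", "finger_tapping", "unilateral", "right", better))
            side.append((sid, "PD", "left", "right"))
        for i, (dom, nondom) in enumerate(hs_vals):
            sid = f"HS{i}"
            rows.append((sid, "HS", "finger_tapping", "unilateral", "right", dom))
            rows.append((sid, "HS", "finger_tapping", "unilateral", "left", nondom))
            side.append((sid, "HS", "none", "right"))
        features = _tidy(rows)
        meta = pd.DataFrame(
            side, columns=["subject_id", "group", "most_affected_side", "dominant_side"]
        )
        return features, meta

    def test_contrast_uses_mas_vs_ds(self):
        features, meta = self._inputs(
            pd_vals=[(1.0, 1.5), (1.1, 1.6), (0.9, 1.4), (1.2, 1.7)],
            hs_vals=[(2.9, 2.8), (3.0, 2.9), (2.8, 2.7), (3.1, 3.0)],
        )
        out = group_compare(features, meta, feature_names=("speed",))
        assert len(out) == 1
        c = out[0]
        assert c.group1_label == "PD_MAS" and c.group2_label == "HS_DS"
        assert c.group1_median == pytest.approx(np.median([1.0, 1.1, 0.9, 1.2]))
        assert c.group2_median == pytest.approx(np.median([2.9, 3.0, 2.8, 3.1]))
        assert c.p_value < 0.05
        assert set(c.side_stats) == {"MAS", "LAS", "DS", "NDS"}

    def test_identical_constant_samples_give_p_one(self):
        features, meta = self._inputs(
            pd_vals=[(2.0, 2.0)] * 3, hs_vals=[(2.0, 2.0)] * 3
        )
        out = group_compare(features, meta, feature_names=("speed",))
        assert out[0].p_value == 1.0

    def test_nan_values_are_excluded(self):
        features, meta = self._inputs(
            pd_vals=[(1.0, 1.5), (np.nan, 1.6), (0.9, 1.4)],
            hs_vals=[(2.9, 2.8), (3.0, 2.9), (2.8, 2.7)],
        )
        out = group_compare(features, meta, feature_names=("speed",))
        assert out[0].side_stats["MAS"][0] == pytest.approx(np.median([1.0, 0.9]))
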