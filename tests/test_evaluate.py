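"""SMOTE, splitting, grid search, per-class metrics and model comparison."""

import warnings

import numpy as np
import pytest
from sklearn.model_selection import ParameterGrid

import rcads_ml as r
from rcads_ml.evaluate import (
    GRIDS,
    GridSpec,
    SplitSpec,
    balance_and_split,
    compare_models,
    report_from_predictions,
    smote_balance,
    split,
)


def _three_class_data(counts=(49, 6, 34), d=46, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1, 2], counts)
    X = rng.normal(loc=y[:, None] * 1.5, scale=1.0, size=(len(y), d))
    return X, y


class TestSmote:
    def test_imbalanced_counts_equalized(self):
        X, y = _three_class_data()
        Xb, yb = smote_balance(X, y, seed=1)
        assert list(np.bincount(yb)) == [49, 49, 49]
        assert len(Xb) == 147
        # originals preserved verbatim, first
        assert np.array_equal(Xb[: len(X)], X)

    def test_balanced_input_unchanged(self):
        X, y = _three_class_data(counts=(20, 20, 20))
        Xb, yb = smote_balance(X, y, seed=2)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_interpolation_geometry(self):
        """Synthetic rows lie coordinate-wise between two same-class parents."""
        X, y = _three_class_data(counts=(30, 5, 30), d=4, seed=3)
        Xb, yb = smote_balance(X, y, k=3, seed=3)
        new = Xb[len(X):]
        new_cls = yb[len(X):]
        for row, cls in zip(new, new_cls):
            Xc = X[y == cls]
            # must be a convex combination of some pair of class members
            dists = np.abs(Xc - row)
            lo = Xc.min(axis=0) - 1e-9
            hi = Xc.max(axis=0) + 1e-9
            assert ((row >= lo) & (row <= hi)).all()
            del dists

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(0).random((5, 3))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="single member"):
            smote_balance(X, y)

    def test_k_capped_with_warning(self):
        X, y = _three_class_data(counts=(20, 3, 20), d=3, seed=4)
        with pytest.warns(UserWarning, match="capped"):
            Xb, _ = smote_balance(X, y, k=5, seed=4)
        assert len(Xb) == 60


class TestSplit:
    def test_147_gives_117_30(self):
        X, y = _three_class_data(counts=(49, 49, 49))
        X_tr, y_tr, X_te, y_te = split(X, y, SplitSpec(seed=0))
        assert X_tr.shape == (117, 46)
        assert X_te.shape == (30, 46)

    def test_small_n_ceiling(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 5)
        X = rng.random((10, 2))
        X_tr, y_tr, X_te, y_te = split(X, y, SplitSpec(seed=1))
        assert len(X_tr) == 8 and len(X_te) == 2

    def test_partition_property(self):
        X, y = _three_class_data()
        X_tr, y_tr, X_te, y_te = split(X, y, SplitSpec(seed=2))
        assert len(X_tr) + len(X_te) == len(X)
        rows = {tuple(row) for row in X}
        assert {tuple(r) for r in X_tr} | {tuple(r) for r in X_te} == rows
        assert not ({tuple(r) for r in X_tr} & {tuple(r) for r in X_te})

    def test_stratification_keeps_all_classes(self):
        X, y = _three_class_data()
        _, y_tr, _, y_te = split(X, y, SplitSpec(seed=3))
        assert set(y_te) == {0, 1, 2}

    def test_balance_first_protocol_warns_about_leakage(self):
        X, y = _three_class_data()
        with pytest.warns(UserWarning, match="leak"):
            X_tr, y_tr, X_te, y_te = balance_and_split(X, y, seed=0)
        assert len(X_tr) == 117 and len(X_te) == 30

    def test_split_first_protocol_balances_training_only(self):
        X, y = _three_class_data()
        X_tr, y_tr, X_te, y_te = balance_and_split(X, y, seed=0, order="split_first")
        counts = np.bincount(y_tr)
        assert counts.min() == counts.max()  # balanced train
        assert len(X_te) == 18  # ceil(0.2 * 89)


class TestGridSearch:
    def test_rf_grid_has_108_candidates(self):
        assert len(list(ParameterGrid(GRIDS["RF"]))) == 3 * 4 * 3 * 3 == 108

    def test_single_point_grid_returned(self):
        X, y = _three_class_data(seed=5)
        spec = GridSpec("DT", grid={"max_depth": [3]})
        model, best, acc, folds = r.grid_search_cv(X, y, spec, seed=0)
        assert best == {"max_depth": 3}
        assert len(folds) == 5

    def test_separable_data_perfect_cv(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1, 2], 30)
        X = rng.normal(loc=y[:, None] * 50.0, scale=0.1, size=(90, 5))
        for fam in ("RF", "DT"):
            spec = GridSpec(fam, grid={"max_depth": [None, 5]})
            _, _, acc, _ = r.grid_search_cv(X, y, spec, seed=0)
            assert acc == pytest.approx(1.0)

    def test_nb_has_no_grid(self):
        X, y = _three_class_data(seed=7)
        model, best, acc, folds = r.grid_search_cv(X, y, GridSpec("NB"), seed=0)
        assert best == {}
        assert 0 < acc <= 1

    def test_empty_grid_rejected_for_non_nb(self):
        X, y = _three_class_data(seed=8)
        with pytest.raises(ValueError, match="empty grid"):
            r.grid_search_cv(X, y, GridSpec("SVM", grid={}), seed=0)

    def test_small_class_rejected(self):
        X, y = _three_class_data(counts=(30, 3, 30), seed=9)
        with pytest.raises(ValueError, match="below folds"):
            r.grid_search_cv(X, y, GridSpec("NB"), seed=0)


class TestEvalReport:
    def test_perfect_predictions(self):
        y = np.repeat([0, 1, 2], 10)
        rep = report_from_predictions(y, y)
        assert rep.accuracy == 1.0
        assert all(v["f1"] == 1.0 for v in rep.per_class.values())
        assert np.array_equal(np.diag(rep.confusion), [10, 10, 10])

    def test_constant_prediction_closed_form(self):
        y = np.repeat([0, 1, 2], 10)
        with pytest.warns(UserWarning, match="no predictions"):
            rep = report_from_predictions(y, np.zeros(30, dtype=int))
        assert rep.accuracy == pytest.approx(1 / 3)
        assert rep.macro_avg["recall"] == pytest.approx(1 / 3)

    def test_hand_worked_confusion_matrix(self):
        """Confusion [[9,1,0],[0,7,0],[1,1,11]] checked by hand."""
        y_true = np.repeat([0, 1, 2], [10, 7, 13])
        y_pred = np.concatenate([
            np.repeat([0, 1], [9, 1]),        # class 0: 9 right, 1 -> borderline
            np.repeat([1], 7),                # class 1: all right
            np.repeat([0, 1, 2], [1, 1, 11]), # class 2
        ])
        rep = report_from_predictions(y_true, y_pred)
        assert rep.confusion.tolist() == [[9, 1, 0], [0, 7, 0], [1, 1, 11]]
        assert rep.per_class[0]["precision"] == pytest.approx(0.9)
        assert rep.per_class[0]["recall"] == pytest.approx(0.9)
        assert rep.per_class[1]["precision"] == pytest.approx(7 / 9)
        assert rep.per_class[2]["recall"] == pytest.approx(11 / 13)
        assert rep.accuracy == pytest.approx(27 / 30)
        # row sums = supports; accuracy = trace/total
        assert rep.confusion.sum(axis=1).tolist() == [10, 7, 13]
        f1s = [rep.per_class[c]["f1"] for c in (0, 1, 2)]
        assert rep.macro_avg["f1"] == pytest.approx(np.mean(f1s), abs=1e-12)
        w = np.array([10, 7, 13]) / 30
        assert rep.weighted_avg["f1"] == pytest.approx(np.dot(f1s, w), abs=1e-12)

    def test_labels_outside_range_rejected(self):
        with pytest.raises(ValueError, match="0, 1, 2|0 \\(Normal\\)"):
            report_from_predictions(np.array([0, 3]), np.array([0, 0]))


class TestCompareModels:
    def test_identical_folds_p_one(self):
        t, p = compare_models([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compare_models([0.9] * 5, [0.5] * 5)

    def test_hand_computed_paired_t(self):
        d = np.array([0.02, -0.01, 0.03, 0.00, 0.01])
        a = np.full(5, 0.9)
        b = a - d
        t, p = compare_models(a, b)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expected_t, abs=1e-12)


class TestExternalValidate:
    def test_training_cohort_reproduces_in_sample_metrics(self, complete_cohort,
                                                          norms, bank):
        cohort, _ = complete_cohort
        scored = r.score_cohort(cohort, bank, norms)
        y = scored["label"].to_numpy()
        X = cohort.items().to_numpy(dtype=float)
        from sklearn.ensemble import RandomForestClassifier

        rf = RandomForestClassifier(n_estimators=30, random_state=0).fit(X, y)
        in_sample = r.evaluate(rf, X, y)
        ext = r.external_validate(rf, cohort, bank, norms)
        assert ext.accuracy == in_sample.accuracy
        assert ext.confusion.tolist() == in_sample.confusion.tolist()

    def test_borderline_heavy_external_cohort(self, complete_cohort, norms, bank):
        """Shifted generator stresses the rare class; no crash, full report."""
        cohort, _ = complete_cohort
        scored = r.score_cohort(cohort, bank, norms)
        from sklearn.ensemble import RandomForestClassifier

        rf = RandomForestClassifier(n_estimators=30, random_state=0).fit(
            cohort.items().to_numpy(float), scored["label"].to_numpy()
        )
        shifted_cfg = r.GeneratorConfig(
            n=60, seed=31, class_mix=(0.2, 0.6, 0.2),
            missing_sex=0, missing_grade=0, missing_both=0,
        )
        ext_cohort, _ = r.generate_cohort(shifted_cfg, bank, with_correlations=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = r.external_validate(rf, ext_cohort, bank, norms)
        assert "recall" in rep.per_class[1]
        assert rep.confusion.sum() == 60

    def test_empty_cohort_rejected(self, complete_cohort, norms, bank):
        cohort, _ = complete_cohort
        empty = r.Cohort(cohort.df.iloc[:0].copy())
        with pytest.raises(ValueError, match="empty"):
            r.external_validate(object(), empty, bank, norms)
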