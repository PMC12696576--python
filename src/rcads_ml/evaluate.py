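"""Class balancing, splitting, grid-search model development and evaluation.

Six classifier families are tuned by exhaustive grid search with
stratified five-fold cross-validation on accuracy.  Class imbalance is
handled with SMOTE.  The historical protocol balances *before* the
80/20 split — which leaks synthetic copies of test information into
training and optimistically biases test metrics — so :func:`balance_and_split`
emits a prominent warning in that mode and offers a split-first mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import Cohort, NormTable, score_cohort
from .itembank import ItemBank

FAMILIES = ("RF", "SVM", "LR", "DT", "NB", "KNN")

#: hyperparameter grids searched for each family (NB has none)
GRIDS: dict[str, dict[str, list]] = {
    "RF": {
        "n_estimators": [50, 100, 200],
        "max_depth": [None, 10, 20, 30],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 4],
    },
    "SVM": {"C": [0.1, 1, 10, 100], "kernel": ["linear", "rbf"], "gamma": ["scale", "auto"]},
    "LR": {"C": [0.01, 0.1, 1, 10, 100], "penalty": ["l1", "l2"]},
    "DT": {
        "max_depth": [None, 10, 20, 30],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 4],
        "criterion": ["gini", "entropy"],
    },
    "NB": {},
    "KNN": {
        "n_neighbors": [3, 5, 7, 9],
        "weights": ["uniform", "distance"],
        "metric": ["euclidean", "manhattan"],
    },
}


def make_estimator(family: str, seed: int = 0):
    if family == "RF":
        return RandomForestClassifier(random_state=seed)
    if family == "SVM":
        return SVC(random_state=seed)
    if family == "LR":
        # liblinear supports both l1 and l2 penalties
        return LogisticRegression(solver="liblinear", max_iter=1000, random_state=seed)
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if family == "NB":
        return GaussianNB()
    if family == "KNN":
        return KNeighborsClassifier()
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class GridSpec:
    family: str
    grid: dict[str, list] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.grid is None:
            self.grid = GRIDS[self.family]


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(X, y, k: int = 5, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Upsample every minority class to the majority count by SMOTE.

    Each synthetic point is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)``,
    ``x`` a random minority point and ``x_nn`` one of its ``k`` nearest
    same-class neighbors (Euclidean).  Original rows are preserved
    verbatim and come first; interpolated values stay continuous.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    X_parts, y_parts = [X], [y]
    for cls, count in zip(classes, counts):
        need = majority - count
        if need == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {cls!r} has a single member; SMOTE needs >= 2"
            )
        k_eff = min(k, count - 1)
        if k_eff < k:
            warnings.warn(
                f"class {cls!r}: k capped at {k_eff} (class size {count})"
            )
        Xc = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(0, count, size=need)
        pick = rng.integers(1, k_eff + 1, size=need)
        u = rng.random((need, 1))
        x0 = Xc[base]
        x1 = Xc[idx[base, pick]]
        X_parts.append(x0 + u * (x1 - x0))
        y_parts.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(X_parts), np.concatenate(y_parts)


def split(X, y, spec: SplitSpec):
    """Stratified 80/20 split; test size = ceiling(n * (1 - train_fraction))."""
    X = np.asarray(X)
    y = np.asarray(y)
    if len(y) < 5:
        raise ValueError("need at least 5 records to split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=1.0 - spec.train_fraction,
        stratify=y if spec.stratified else None,
        random_state=spec.seed,
    )
    return X_tr, y_tr, X_te, y_te


def balance_and_split(
    X, y, k: int = 5, seed: int = 0, order: str = "balance_first"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SMOTE + 80/20 split in the requested order.

    ``balance_first`` reproduces the historical protocol (SMOTE on the
    full data, then split) and warns about the induced leakage;
    ``split_first`` is the methodologically sound alternative that
    oversamples the training portion only.
    """
    spec = SplitSpec(seed=seed)
    if order == "balance_first":
        warnings.warn(
            "SMOTE applied before the train/test split: synthetic test "
            "records interpolate training records, which leaks information "
            "and optimistically biases test metrics",
            UserWarning,
            stacklevel=2,
        )
        Xb, yb = smote_balance(X, y, k=k, seed=seed)
        return split(Xb, yb, spec)
    if order == "split_first":
        X_tr, y_tr, X_te, y_te = split(X, y, spec)
        Xb, yb = smote_balance(X_tr, y_tr, k=k, seed=seed)
        return Xb, yb, X_te, y_te
    raise ValueError(f"unknown order {order!r}")


# ---------------------------------------------------------------------------
# grid search + evaluation


def grid_search_cv(
    X_train, y_train, spec: GridSpec, folds: int = 5, seed: int = 0
):
    """Exhaustive grid search with stratified k-fold CV on accuracy.

    Ties are broken by grid order (first candidate wins).  Returns
    ``(fitted best model, best_params, cv_mean_accuracy, cv_fold_scores)``.
    The NB family has no grid and is fitted with defaults.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    _, counts = np.unique(y_train, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest training class ({counts.min()}) below folds={folds}"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    est = make_estimator(spec.family, seed)
    if not spec.grid:
        if spec.family != "NB":
            raise ValueError(f"empty grid for family {spec.family}")
        scores = cross_val_score(est, X_train, y_train, cv=cv, scoring="accuracy")
        est.fit(X_train, y_train)
        return est, {}, float(scores.mean()), [float(s) for s in scores]
    gs = GridSearchCV(est, spec.grid, scoring="accuracy", cv=cv, refit=True)
    gs.fit(X_train, y_train)
    folds_scores = [
        float(gs.cv_results_[f"split{i}_test_score"][gs.best_index_])
        for i in range(folds)
    ]
    return (
        gs.best_estimator_,
        dict(gs.best_params_),
        float(gs.best_score_),
        folds_scores,
    )


@dataclass
class EvalReport:
    """Per-class precision/recall/F1 with macro/weighted averages."""

    per_class: dict[int, dict[str, float]]
    accuracy: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    confusion: np.ndarray  # rows = truth, columns = prediction
    cv_fold_scores: list[float] = field(default_factory=list)
    best_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "confusion": self.confusion.tolist(),
            "cv_fold_scores": self.cv_fold_scores,
            "best_params": {str(k): repr(v) for k, v in self.best_params.items()},
        }


def evaluate(model, X_test, y_test, cv_fold_scores=None, best_params=None) -> EvalReport:
    """Score a fitted model on held-out data (three-class report)."""
    y_test = np.asarray(y_test)
    if not np.isin(y_test, [0, 1, 2]).all():
        raise ValueError("labels must be 0 (Normal), 1 (Borderline) or 2 (Clinical)")
    y_pred = np.asarray(model.predict(np.asarray(X_test, dtype=float)))
    return report_from_predictions(
        y_test, y_pred, cv_fold_scores=cv_fold_scores, best_params=best_params
    )


def report_from_predictions(
    y_true, y_pred, cv_fold_scores=None, best_params=None
) -> EvalReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = [0, 1, 2]
    if not np.isin(y_true, labels).all():
        raise ValueError("labels must be 0, 1, 2")
    if not np.isin(y_pred, labels).all():
        raise ValueError("predictions outside {0, 1, 2}")
    if set(np.unique(y_pred)) < set(np.unique(y_true)):
        warnings.warn("some observed classes received no predictions; "
                      "their precision reported as 0")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    per_class = {
        c: {"precision": float(prec[i]), "recall": float(rec[i]),
            "f1": float(f1[i]), "support": int(support[i])}
        for i, c in enumerate(labels)
    }
    macro = {"precision": float(prec.mean()), "recall": float(rec.mean()),
             "f1": float(f1.mean())}
    w = support / support.sum()
    weighted = {"precision": float(prec @ w), "recall": float(rec @ w),
                "f1": float(f1 @ w)}
    return EvalReport(
        per_class=per_class,
        accuracy=float(accuracy_score(y_true, y_pred)),
        macro_avg=macro,
        weighted_avg=weighted,
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
        cv_fold_scores=list(cv_fold_scores or []),
        best_params=dict(best_params or {}),
    )


def compare_models(fold_scores_a, fold_scores_b) -> tuple[float, float]:
    """Paired two-sided t-test on per-fold CV accuracies.

    All-zero differences return (0, 1) (identical performance); nonzero
    constant differences make the statistic undefined and raise.
    """
    a = np.asarray(fold_scores_a, dtype=float)
    b = np.asarray(fold_scores_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need equal-length fold vectors with >= 2 folds")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        raise ValueError(
            "fold differences are constant and nonzero; paired t undefined"
        )
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def external_validate(
    model,
    cohort: Cohort,
    bank: ItemBank,
    norms: NormTable,
    feature_items=None,
) -> EvalReport:
    """Frozen-model validation on an external cohort.

    The cohort is scored and classified for ground-truth labels, the
    model predicts from its item responses (restricted to
    ``feature_items`` when the model was trained after elimination), and
    the full three-class report incl. confusion matrix is returned.
    """
    if cohort.n == 0:
        raise ValueError("external cohort is empty")
    incomplete = cohort.df.isna().any(axis=1)
    if incomplete.any():
        rows = list(np.flatnonzero(incomplete.to_numpy())[:10] + 1)
        raise ValueError(f"unscorable (incomplete) records at rows {rows}")
    scored = score_cohort(cohort, bank, norms)
    y = scored["label"].to_numpy()
    items = cohort.items()
    if feature_items is not None:
        from .itembank import item_column

        items = items[[item_column(i) for i in feature_items]]
    return evaluate(model, items.to_numpy(dtype=float), y)
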