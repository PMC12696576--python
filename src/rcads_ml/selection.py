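"""Consensus feature screening: chi-square, Spearman and RF-RFE.

An item is eliminated only when all three methods agree it carries no
signal about the class label: the chi-square test of independence and
the Spearman rank correlation are both non-significant at the chosen
alpha, and recursive feature elimination with a random-forest ranker
leaves it out of the accuracy-optimal subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold

from .core import Cohort
from .itembank import ItemBank, item_column


def chisq_independence(item, label) -> tuple[float, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, p).  Warns when any expected cell count is below
    5 (inevitable for sparse 4 x 3 tables at small n) rather than
    switching tests silently.
    """
    item = np.asarray(item)
    label = np.asarray(label)
    if len(item) != len(label):
        raise ValueError("item and label must have equal length")
    table = pd.crosstab(item, label).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table of shape {table.shape}; "
            "need >= 2 observed levels and >= 2 classes"
        )
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell count(s) < 5; "
            "chi-square p-values may be unreliable"
        )
    return float(chi2), float(p)


def spearman_assoc(item, label) -> tuple[float, float]:
    """Spearman rank correlation (average ranks) with t-approximation p."""
    item = np.asarray(item, dtype=float)
    label = np.asarray(label, dtype=float)
    if len(item) != len(label) or len(item) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(item) == 0 or np.ptp(label) == 0:
        raise ValueError("constant input; Spearman correlation undefined")
    rho, p = stats.spearmanr(item, label)
    return float(rho), float(p)


def rf_rfe(
    X,
    y,
    cv_folds: int = 5,
    n_estimators: int = 100,
    seed: int = 0,
) -> tuple[list, float]:
    """Recursive feature elimination ranked by random-forest importance.

    One feature is removed per step; the retained subset size is the one
    maximizing mean stratified-CV accuracy (ties favor the smaller set).
    Returns (selected column indices/names, best mean CV accuracy).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class ({counts.min()}) below cv_folds={cv_folds}"
        )
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    selector = RFECV(forest, step=1, cv=cv, scoring="accuracy",
                     min_features_to_select=1)
    selector.fit(X.to_numpy(), y)
    selected = [c for c, keep in zip(X.columns, selector.support_) if keep]
    # mean_test_score is indexed by subset size starting at min_features
    acc = float(selector.cv_results_["mean_test_score"][selector.n_features_ - 1])
    return selected, acc


def consensus_eliminate(
    chisq_p: dict, spearman_p: dict, rfe_selected, alpha: float = 0.05
) -> set:
    """Items flagged uninformative by all three screens.

    Eliminated iff chi-square p > alpha AND Spearman p > alpha AND the
    item is absent from the RFE-selected subset.
    """
    rfe_selected = set(rfe_selected)
    return {
        i
        for i in chisq_p
        if chisq_p[i] > alpha and spearman_p[i] > alpha and i not in rfe_selected
    }


@dataclass
class SelectionReport:
    chisq: dict[int, tuple[float, float]]  # item -> (chi2, p)
    spearman: dict[int, tuple[float, float]]  # item -> (rho, p)
    rfe_selected: set[int]
    rfe_cv_accuracy: float
    eliminated: set[int]
    alpha_level: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha_level": self.alpha_level,
            "chisq": {str(i): {"chi2": c, "p": p} for i, (c, p) in self.chisq.items()},
            "spearman": {
                str(i): {"rho": r, "p": p} for i, (r, p) in self.spearman.items()
            },
            "rfe_selected": sorted(self.rfe_selected),
            "rfe_cv_accuracy": self.rfe_cv_accuracy,
            "eliminated": sorted(self.eliminated),
        }


def select_features(
    cohort: Cohort,
    labels,
    bank: ItemBank,
    alpha: float = 0.05,
    cv_folds: int = 5,
    n_estimators: int = 100,
    seed: int = 0,
) -> SelectionReport:
    """Run all three screens on a complete cohort and apply the consensus rule."""
    y = np.asarray(labels)
    items = cohort.items().to_numpy(dtype=np.int64)
    chisq = {}
    spear = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse-cell warnings summarized by caller
        for j, i in enumerate(bank.item_ids):
            chisq[i] = chisq_independence(items[:, j], y)
            spear[i] = spearman_assoc(items[:, j], y)
    X = pd.DataFrame(items, columns=[item_column(i) for i in bank.item_ids])
    sel_cols, acc = rf_rfe(X, y, cv_folds=cv_folds, n_estimators=n_estimators,
                           seed=seed)
    rfe_sel = {int(c.split("_")[1]) for c in sel_cols}
    eliminated = consensus_eliminate(
        {i: p for i, (_, p) in chisq.items()},
        {i: p for i, (_, p) in spear.items()},
        rfe_sel,
        alpha=alpha,
    )
    return SelectionReport(
        chisq=chisq,
        spearman=spear,
        rfe_selected=rfe_sel,
        rfe_cv_accuracy=acc,
        eliminated=eliminated,
        alpha_level=alpha,
    )
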