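"""Internal-consistency analysis: Cronbach's alpha and inter-item summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import Cohort
from .itembank import ANXIETY_SUBSCALES, ItemBank, item_column


def _as_matrix(responses, item_set=None) -> np.ndarray:
    """Coerce a records x items array; optionally select item columns."""
    if isinstance(responses, Cohort):
        responses = responses.df
    if isinstance(responses, pd.DataFrame):
        if item_set is not None:
            cols = [item_column(i) if isinstance(i, (int, np.integer)) else i
                    for i in item_set]
            responses = responses[cols]
        X = responses.to_numpy(dtype=float)
    else:
        X = np.asarray(responses, dtype=float)
        if item_set is not None:
            X = X[:, [i - 1 for i in item_set]] if X.shape[1] > len(item_set) else X
    if np.isnan(X).any():
        raise ValueError("reliability analysis requires complete responses")
    return X


def cronbach_alpha(responses, item_set=None) -> float:
    """Cronbach's alpha, ``k/(k-1) * (1 - sum(var_i) / var(total))``.

    Sample variances use the n-1 denominator.  Raises if the total score
    has zero variance (alpha undefined) or fewer than 2 items/records.
    """
    X = _as_matrix(responses, item_set)
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError(f"need >= 2 items and >= 2 records, got {n} x {k}")
    var_items = X.var(axis=0, ddof=1)
    var_total = X.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - var_items.sum() / var_total))


def alpha_if_deleted(responses, item_set=None) -> dict:
    """Alpha of the remaining items after deleting each item in turn."""
    if isinstance(responses, (Cohort, pd.DataFrame)) and item_set is not None:
        keys = list(item_set)
        X = _as_matrix(responses, item_set)
    else:
        X = _as_matrix(responses, item_set)
        keys = list(item_set) if item_set is not None else list(range(X.shape[1]))
    if X.shape[1] < 3:
        raise ValueError("alpha-if-deleted needs >= 3 items")
    out = {}
    for j, key in enumerate(keys):
        out[key] = cronbach_alpha(np.delete(X, j, axis=1))
    return out


def interitem_summary(responses, item_set=None) -> dict:
    """Mean/min/max of pairwise Spearman correlations (average ranks).

    Pairs involving a constant item are undefined; they are excluded and
    counted in ``n_undefined`` with a warning.
    """
    X = _as_matrix(responses, item_set)
    n, k = X.shape
    if k < 2:
        raise ValueError("need >= 2 items")
    ranks = np.apply_along_axis(rankdata, 0, X)
    sd = ranks.std(axis=0)
    constant = sd == 0
    n_const = int(constant.sum())
    if n_const:
        warnings.warn(
            f"{n_const} constant item(s); their pairwise correlations are excluded"
        )
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                continue
            c = np.corrcoef(ranks[:, i], ranks[:, j])[0, 1]
            vals.append(c)
    n_excluded = k * (k - 1) // 2 - len(vals)
    if not vals:
        return {"mean": float("nan"), "min": float("nan"), "max": float("nan"),
                "n_pairs": 0, "n_undefined": n_excluded}
    arr = np.asarray(vals)
    return {"mean": float(arr.mean()), "min": float(arr.min()),
            "max": float(arr.max()), "n_pairs": len(vals),
            "n_undefined": n_excluded}


@dataclass
class ReliabilityReport:
    """Scale- and subscale-level internal consistency summary."""

    alpha_overall: float
    alpha_anxiety: float
    alpha_by_scale: dict[str, float]
    alpha_if_deleted: dict[int, float]
    interitem_mean: float
    interitem_range: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "alpha": {
                "Overall Internalizing Scale": self.alpha_overall,
                "Overall Anxiety Scale": self.alpha_anxiety,
                **self.alpha_by_scale,
            },
            "alpha_if_deleted": {str(k): v for k, v in self.alpha_if_deleted.items()},
            "interitem": {
                "mean": self.interitem_mean,
                "min": self.interitem_range[0],
                "max": self.interitem_range[1],
            },
        }


def reliability_report(cohort: Cohort, bank: ItemBank) -> ReliabilityReport:
    """Full reliability analysis of a complete cohort.

    Alpha for the 47-item internalizing scale, the anxiety scale (all
    items outside the depression subscale), each of the six subscales,
    alpha-if-item-deleted for the full scale, and the pairwise Spearman
    summary over all 47 items.
    """
    all_items = list(bank.item_ids)
    anx_items = [i for s in ANXIETY_SUBSCALES for i in bank.items_of(s)]
    by_scale = {
        s: cronbach_alpha(cohort.df, bank.items_of(s)) for s in bank.subscale_items
    }
    inter = interitem_summary(cohort.df, all_items)
    return ReliabilityReport(
        alpha_overall=cronbach_alpha(cohort.df, all_items),
        alpha_anxiety=cronbach_alpha(cohort.df, anx_items),
        alpha_by_scale=by_scale,
        alpha_if_deleted=alpha_if_deleted(cohort.df, all_items),
        interitem_mean=inter["mean"],
        interitem_range=(inter["min"], inter["max"]),
    )
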