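"""Multinomial + Gaussian-copula data augmentation for small cohorts.

The augmentation model is fitted from a complete cohort: per-item
category probabilities (multinomial marginals), per-subscale target mean
Spearman correlation, and empirical sex/grade marginals.  Synthetic
records are drawn subscale-by-subscale from a calibrated Gaussian copula
(independent across subscales), demographics independently from their
marginals, and class labels assigned deterministically by scoring the
generated responses.  Hybrid datasets concatenate the original cohort
with synthetic records at ratios 1:4 through 1:20.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import copula
from .core import Cohort, GRADES, NormTable, frame_from_arrays, score_cohort
from .itembank import ITEM_COLUMNS, ItemBank, N_ITEMS, item_column

STANDARD_RATIOS = (4, 8, 12, 16, 20)


@dataclass
class AugmentationModel:
    """Fitted marginals, correlation targets and calibrated latent rho."""

    item_probs: dict[int, np.ndarray]  # item -> (p0, p1, p2, p3)
    subscale_rho: dict[str, float]  # target mean Spearman per subscale
    sex_probs: dict[str, float]
    grade_probs: dict[int, float]
    fitted_n: int
    latent_rho: dict[str, float] = field(default_factory=dict)
    rho_mode: str = "pairwise"

    def __post_init__(self) -> None:
        for i, p in self.item_probs.items():
            p = np.asarray(p, dtype=float)
            if abs(float(p.sum()) - 1.0) > 1e-12:
                raise ValueError(f"item {i}: probabilities sum to {p.sum()!r}, not 1")
            self.item_probs[i] = p
        for s, r in self.subscale_rho.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"subscale {s}: target correlation {r} outside [0,1)")

    def calibrate(self, bank: ItemBank, tol: float = 0.01) -> "AugmentationModel":
        """Fill ``latent_rho`` per subscale by inverting the attenuation map."""
        for scale in bank.subscale_items:
            probs = [self.item_probs[i] for i in bank.items_of(scale)]
            self.latent_rho[scale] = copula.calibrate_latent_rho(
                self.subscale_rho[scale], probs, tol=tol
            )
        return self

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fitted_n": self.fitted_n,
            "rho_mode": self.rho_mode,
            "item_probs": {str(i): list(map(float, p)) for i, p in self.item_probs.items()},
            "subscale_rho": self.subscale_rho,
            "latent_rho": self.latent_rho,
            "sex_probs": self.sex_probs,
            "grade_probs": {str(g): p for g, p in self.grade_probs.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "AugmentationModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            item_probs={int(i): np.asarray(p) for i, p in d["item_probs"].items()},
            subscale_rho=d["subscale_rho"],
            sex_probs=d["sex_probs"],
            grade_probs={int(g): p for g, p in d["grade_probs"].items()},
            fitted_n=int(d["fitted_n"]),
            latent_rho=d.get("latent_rho", {}),
            rho_mode=d.get("rho_mode", "pairwise"),
        )


def _pairwise_mean_spearman(X: np.ndarray) -> float:
    """Mean pairwise Spearman over columns, skipping constant-column pairs."""
    ranks = np.apply_along_axis(stats.rankdata, 0, X.astype(float))
    sd = ranks.std(axis=0)
    keep = sd > 0
    vals = []
    k = X.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            if keep[i] and keep[j]:
                vals.append(np.corrcoef(ranks[:, i], ranks[:, j])[0, 1])
    return float(np.mean(vals)) if vals else float("nan")


def fit_marginals(
    cohort: Cohort, bank: ItemBank, rho_mode: str = "pairwise"
) -> AugmentationModel:
    """Fit the augmentation model from a complete cohort.

    ``rho_mode='pairwise'`` (default) targets the mean pairwise
    inter-item Spearman within each subscale — the exchangeable reading
    that directly parameterizes an equicorrelated copula.
    ``rho_mode='item_total'`` instead averages each item's Spearman with
    its subscale total score.
    """
    if cohort.n == 0:
        raise ValueError("cannot fit an augmentation model on an empty cohort")
    if not cohort.is_complete():
        raise ValueError("augmentation model requires a complete cohort")
    if cohort.n == 1:
        warnings.warn("single-record cohort: degenerate one-hot marginals")
    items = cohort.items().to_numpy(dtype=np.int64)
    n = cohort.n
    item_probs = {}
    for j, i in enumerate(bank.item_ids):
        counts = np.bincount(items[:, j], minlength=4)[:4]
        item_probs[i] = counts / counts.sum()
    subscale_rho = {}
    for scale in bank.subscale_items:
        cols = [i - 1 for i in bank.items_of(scale)]
        block = items[:, cols]
        if rho_mode == "pairwise":
            r = _pairwise_mean_spearman(block)
        elif rho_mode == "item_total":
            total = block.sum(axis=1)
            vals = []
            for c in range(block.shape[1]):
                if np.ptp(block[:, c]) == 0 or np.ptp(total) == 0:
                    continue
                vals.append(stats.spearmanr(block[:, c], total)[0])
            r = float(np.mean(vals)) if vals else float("nan")
        else:
            raise ValueError(f"unknown rho_mode {rho_mode!r}")
        if not np.isfinite(r):
            warnings.warn(f"subscale {scale}: correlation undefined; using 0")
            r = 0.0
        subscale_rho[scale] = float(np.clip(r, 0.0, 0.99))
    sex = cohort.df["sex"]
    sex_probs = {s: float((sex == s).mean()) for s in ("boy", "girl")}
    grade = cohort.df["grade"].astype(int)
    grade_probs = {
        int(g): float((grade == g).mean()) for g in sorted(grade.unique())
    }
    return AugmentationModel(
        item_probs=item_probs,
        subscale_rho=subscale_rho,
        sex_probs=sex_probs,
        grade_probs=grade_probs,
        fitted_n=n,
        rho_mode=rho_mode,
    )


def gof_multinomial(counts, reference_probs) -> tuple[float, float]:
    """Chi-square goodness of fit of category counts against reference probs.

    Degrees of freedom are (#nonzero-reference categories - 1); a
    nonzero count in a zero-probability category is an error.
    """
    counts = np.asarray(counts, dtype=float)
    p = np.asarray(reference_probs, dtype=float)
    if counts.shape != (4,) or p.shape != (4,):
        raise ValueError("counts and reference_probs must have length 4")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("reference probabilities must sum to 1")
    bad = (p == 0) & (counts > 0)
    if bad.any():
        raise ValueError(
            f"nonzero count in zero-probability category {np.flatnonzero(bad)}"
        )
    nz = p > 0
    expected = counts.sum() * p[nz] / p[nz].sum()
    chi2, pval = stats.chisquare(counts[nz], f_exp=expected)
    return float(chi2), float(pval)


def sample_items(
    model: AugmentationModel,
    subscale: str,
    n: int,
    bank: ItemBank,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw an n x k correlated response block for one subscale."""
    if subscale not in model.latent_rho:
        raise ValueError(
            f"latent correlation for {subscale} not calibrated; call model.calibrate()"
        )
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    probs = [model.item_probs[i] for i in bank.items_of(subscale)]
    return copula.sample_discretized(model.latent_rho[subscale], probs, n, rng)


def generate_synthetic(
    model: AugmentationModel,
    ratio: int,
    seed: int,
    bank: ItemBank,
    norms: NormTable,
) -> Cohort:
    """Generate ``ratio x fitted_n`` synthetic records.

    Item blocks are sampled per subscale (independent across subscales),
    sex and grade independently from their fitted marginals, and class
    labels assigned by scoring each record against the norm table.
    """
    if norms is None:
        raise ValueError("norms are required to label synthetic records")
    if ratio not in STANDARD_RATIOS:
        warnings.warn(f"non-standard augmentation ratio 1:{ratio}")
    n = int(ratio) * model.fitted_n
    rng = np.random.default_rng(seed)
    items = np.empty((n, N_ITEMS), dtype=np.int64)
    for scale in bank.subscale_items:
        cols = [i - 1 for i in bank.items_of(scale)]
        items[:, cols] = sample_items(model, scale, n, bank, rng)
    sexes = np.array(sorted(model.sex_probs), dtype=object)
    sp = np.array([model.sex_probs[s] for s in sexes], dtype=float)
    sex = rng.choice(sexes, size=n, p=sp / sp.sum())
    grades = np.array(sorted(model.grade_probs))
    gp = np.array([model.grade_probs[g] for g in grades], dtype=float)
    grade = rng.choice(grades, size=n, p=gp / gp.sum()).astype(float)
    df = frame_from_arrays(sex, grade, items.astype(float))
    cohort = Cohort(df=df, provenance="synthetic", seed=seed, ratio=int(ratio))
    scored = score_cohort(cohort, bank, norms)
    cohort.labels = scored["label"].to_numpy()
    return cohort


def make_hybrid(original: Cohort, synthetic: Cohort) -> Cohort:
    """Concatenate original + synthetic records (original first, order-stable)."""
    if list(original.df.columns) != list(synthetic.df.columns):
        raise ValueError("schema mismatch between original and synthetic cohorts")
    df = pd.concat([original.df, synthetic.df], ignore_index=True)
    labels = None
    if original.labels is not None and synthetic.labels is not None:
        labels = np.concatenate([original.labels, synthetic.labels])
    return Cohort(
        df=df,
        provenance="hybrid",
        seed=synthetic.seed,
        ratio=synthetic.ratio,
        labels=labels,
    )


@dataclass
class FidelityReport:
    """Distributional agreement between original and synthetic cohorts."""

    mw_p: dict[int, float]  # per-item Mann-Whitney two-sided p
    marginal_tv: dict[int, float]  # per-item total-variation distance
    corr_gap: dict[str, float]  # |achieved - target| mean Spearman per subscale
    notes: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return sum(1 for p in self.mw_p.values() if p < 0.05)

    def to_dict(self) -> dict:
        return {
            "mw_p": {str(i): p for i, p in self.mw_p.items()},
            "marginal_tv": {str(i): v for i, v in self.marginal_tv.items()},
            "corr_gap": self.corr_gap,
            "n_rejected_at_0.05": self.n_rejected,
            "notes": self.notes,
        }


def fidelity(
    original: Cohort,
    synthetic: Cohort,
    bank: ItemBank,
    model: AugmentationModel | None = None,
) -> FidelityReport:
    """Per-item Mann-Whitney tests, TV distances and correlation gaps.

    The Mann-Whitney U test (tie-corrected normal approximation)
    compares each item's level distribution between cohorts; high p
    throughout indicates the synthetic data preserved the originals'
    distributions.  ``corr_gap`` compares the synthetic within-subscale
    mean Spearman to the model target (or to the original cohort's when
    no model is given).
    """
    X = original.items().to_numpy(dtype=np.int64)
    Y = synthetic.items().to_numpy(dtype=np.int64)
    mw_p: dict[int, float] = {}
    tv: dict[int, float] = {}
    notes: list[str] = []
    for j, i in enumerate(bank.item_ids):
        x, y = X[:, j], Y[:, j]
        combined = np.concatenate([x, y])
        if np.ptp(combined) == 0:
            mw_p[i] = 1.0
            notes.append(f"item {i}: constant in both groups; MW p set to 1")
        else:
            mw_p[i] = float(
                stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            )
        fx = np.bincount(x, minlength=4)[:4] / len(x)
        fy = np.bincount(y, minlength=4)[:4] / len(y)
        tv[i] = float(0.5 * np.abs(fx - fy).sum())
    corr_gap = {}
    for scale in bank.subscale_items:
        cols = [i - 1 for i in bank.items_of(scale)]
        achieved = _pairwise_mean_spearman(Y[:, cols])
        if model is not None:
            target = model.subscale_rho[scale]
        else:
            target = _pairwise_mean_spearman(X[:, cols])
        corr_gap[scale] = float(abs(achieved - target))
    return FidelityReport(mw_p=mw_p, marginal_tv=tv, corr_gap=corr_gap, notes=notes)
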