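"""Cohort I/O, missingness filtering, scoring and three-class labeling.

A *cohort* is a table of questionnaire records with columns
``sex, grade, item_01 ... item_47``; empty cells denote missing values.
Raw totals are converted to T-scores against a normative table keyed by
(grade band, sex)::

    T = 50 + 10 * (raw_total - mean) / sd

and classified as Normal (T < 65), Borderline (65 <= T < 70) or
Clinical (T >= 70); class codes 0/1/2.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .itembank import ITEM_COLUMNS, ItemBank, N_ITEMS, item_column

LABEL_NAMES = {0: "Normal", 1: "Borderline", 2: "Clinical"}
NORMAL, BORDERLINE, CLINICAL = 0, 1, 2
BORDERLINE_T, CLINICAL_T = 65.0, 70.0

GRADES = tuple(range(2, 13))
SEXES = ("boy", "girl")
#: case-insensitive synonyms accepted on input
DEFAULT_SEX_ALIASES = {
    "boy": "boy", "b": "boy", "m": "boy", "male": "boy",
    "girl": "girl", "g": "girl", "f": "girl", "female": "girl",
}

COLUMNS = ("sex", "grade") + ITEM_COLUMNS


class CohortFormatError(ValueError):
    """Malformed cohort file: bad header, level or category."""


@dataclass
class Cohort:
    """A set of response records plus provenance metadata.

    ``df`` has columns ``sex`` (object: 'boy'/'girl'/NaN), ``grade``
    (nullable Int64) and ``item_01..item_47`` (nullable Int64).
    ``labels`` optionally carries per-record class codes assigned by
    scoring (synthetic and hybrid cohorts keep them for convenience).
    """

    df: pd.DataFrame
    provenance: str = "real"
    seed: int | None = None
    ratio: int | None = None  # hybrid cohorts record the originating ratio
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("real", "synthetic", "hybrid"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort frame lacks columns {missing[:3]}...")

    @property
    def n(self) -> int:
        return len(self.df)

    def items(self) -> pd.DataFrame:
        return self.df[list(ITEM_COLUMNS)]

    def is_complete(self) -> bool:
        return bool(self.df[list(COLUMNS)].notna().all().all())


def _empty_frame(n: int = 0) -> pd.DataFrame:
    df = pd.DataFrame(index=range(n), columns=list(COLUMNS))
    df["sex"] = df["sex"].astype(object)
    for c in ("grade",) + ITEM_COLUMNS:
        df[c] = df[c].astype("Int64")
    return df


def frame_from_arrays(sex, grade, items: np.ndarray) -> pd.DataFrame:
    """Assemble a cohort frame from parallel arrays (NaN/None = missing)."""
    n = len(items)
    df = _empty_frame(n)
    df["sex"] = np.asarray(sex, dtype=object)
    df["grade"] = pd.array(grade, dtype="Int64")
    for j, col in enumerate(ITEM_COLUMNS):
        df[col] = pd.array(items[:, j], dtype="Int64")
    return df


def read_cohort(
    path: str | Path,
    bank: ItemBank,
    sex_aliases: Mapping[str, str] | None = None,
    provenance: str = "real",
) -> Cohort:
    """Read a cohort CSV, validating every cell against the item bank.

    Raises :class:`CohortFormatError` with the offending row/column for
    unknown or duplicate columns, out-of-range levels, bad sex codes or
    out-of-range grades.  1-based data row numbers (header = row 0) are
    used in diagnostics.
    """
    aliases = {k.lower(): v for k, v in (sex_aliases or DEFAULT_SEX_ALIASES).items()}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise CohortFormatError(f"duplicate columns in header: {sorted(dupes)}")
    unknown = [c for c in header if c not in COLUMNS]
    if unknown:
        raise CohortFormatError(f"unknown columns: {unknown}")
    absent = [c for c in COLUMNS if c not in header]
    if absent:
        raise CohortFormatError(f"missing required columns: {absent}")

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _empty_frame(len(raw))

    sex_out = []
    for row, val in enumerate(raw["sex"], start=1):
        val = val.strip()
        if val == "":
            sex_out.append(None)
        elif val.lower() in aliases:
            sex_out.append(aliases[val.lower()])
        else:
            raise CohortFormatError(f"row {row}, column sex: unrecognized value {val!r}")
    df["sex"] = pd.array(sex_out, dtype=object)

    def parse_int(col: str, lo: int, hi: int) -> pd.array:
        out = []
        for row, val in enumerate(raw[col], start=1):
            val = val.strip()
            if val == "":
                out.append(pd.NA)
                continue
            try:
                iv = int(val)
            except ValueError:
                raise CohortFormatError(
                    f"row {row}, column {col}: non-integer value {val!r}"
                ) from None
            if not lo <= iv <= hi:
                raise CohortFormatError(
                    f"row {row}, column {col}: value {iv} outside [{lo}, {hi}]"
                )
            out.append(iv)
        return pd.array(out, dtype="Int64")

    df["grade"] = parse_int("grade", GRADES[0], GRADES[-1])
    lo, hi = min(bank.levels), max(bank.levels)
    for col in ITEM_COLUMNS:
        df[col] = parse_int(col, lo, hi)
    return Cohort(df=df, provenance=provenance)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV (empty cells for missing); round-trips exactly."""
    cohort.df[list(COLUMNS)].to_csv(path, index=False, na_rep="")


def filter_complete(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Listwise deletion: split into fully observed and incomplete records.

    A record is retained only when sex, grade and all 47 items are
    present.  Idempotent; ``retained.n + dropped.n == cohort.n``.
    """
    mask = cohort.df[list(COLUMNS)].notna().all(axis=1).to_numpy()
    retained = Cohort(cohort.df.loc[mask].reset_index(drop=True),
                      provenance=cohort.provenance, seed=cohort.seed)
    dropped = Cohort(cohort.df.loc[~mask].reset_index(drop=True),
                     provenance=cohort.provenance, seed=cohort.seed)
    return retained, dropped


# ---------------------------------------------------------------------------
# normative table


@dataclass
class NormTable:
    """Per (grade band, sex) normative mean/SD of the raw total score.

    ``band_of`` maps each grade to a band key; the default identity map
    uses single-grade bands.  A single pooled entry can be expressed by
    mapping every grade to one band.
    """

    entries: dict[tuple[str, str], tuple[float, float]]
    band_of: dict[int, str] = field(default_factory=lambda: {g: str(g) for g in GRADES})

    def __post_init__(self) -> None:
        for key, (mean, sd) in self.entries.items():
            if not sd > 0:
                raise ValueError(f"norm entry {key}: sd must be > 0, got {sd}")
        for g in GRADES:
            for s in SEXES:
                self.lookup(g, s)

    def lookup(self, grade: int, sex: str) -> tuple[float, float]:
        band = self.band_of.get(int(grade))
        if band is None or (band, sex) not in self.entries:
            raise KeyError(f"no norm entry for grade {grade}, sex {sex}")
        return self.entries[(band, sex)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "entries": [
                {"band": b, "sex": s, "mean": m, "sd": sd}
                for (b, s), (m, sd) in sorted(self.entries.items())
            ],
            "band_of": {str(g): b for g, b in self.band_of.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "NormTable":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        entries = {
            (e["band"], e["sex"]): (float(e["mean"]), float(e["sd"]))
            for e in payload["entries"]
        }
        band_of = {int(g): b for g, b in payload["band_of"].items()}
        return cls(entries=entries, band_of=band_of)


def label_from_t(t: float) -> int:
    """Classify a T-score: <65 Normal, [65, 70) Borderline, >=70 Clinical."""
    if t < BORDERLINE_T:
        return NORMAL
    if t < CLINICAL_T:
        return BORDERLINE
    return CLINICAL


def score_cohort(cohort: Cohort, bank: ItemBank, norms: NormTable) -> pd.DataFrame:
    """Score every record: raw totals, subscale sums, T-score and label.

    Requires a complete cohort (no missing sex/grade/items).  Returns a
    frame with ``raw_total``, one ``raw_<subscale>`` per subscale,
    ``t_score`` and ``label`` aligned with ``cohort.df``.
    """
    if norms is None:
        raise ValueError("a NormTable is required for scoring")
    df = cohort.df
    incomplete = df[list(COLUMNS)].isna().any(axis=1)
    if incomplete.any():
        rows = list(np.flatnonzero(incomplete.to_numpy())[:5] + 1)
        raise ValueError(f"cannot score records with missing values (rows {rows}...)")
    items = df[list(ITEM_COLUMNS)].to_numpy(dtype=np.int64)
    out = pd.DataFrame(index=df.index)
    out["raw_total"] = items.sum(axis=1)
    for scale, ids in bank.subscale_items.items():
        cols = [i - 1 for i in ids]
        out[f"raw_{scale}"] = items[:, cols].sum(axis=1)
    t = np.empty(len(df))
    for i, (g, s, raw) in enumerate(zip(df["grade"], df["sex"], out["raw_total"])):
        mean, sd = norms.lookup(int(g), str(s))
        t[i] = 50.0 + 10.0 * (float(raw) - mean) / sd
    out["t_score"] = t
    out["label"] = [label_from_t(x) for x in t]
    return out


def score_record(
    sex: str, grade: int, responses: Mapping[int, int], bank: ItemBank, norms: NormTable
) -> dict:
    """Score a single complete record; see :func:`score_cohort`."""
    missing = [i for i in bank.item_ids if responses.get(i) is None]
    if missing:
        raise ValueError(f"missing responses for items {missing[:5]}")
    row = _empty_frame(1)
    row.loc[0, "sex"] = sex
    row.loc[0, "grade"] = grade
    for i, v in responses.items():
        row.loc[0, item_column(i)] = v
    scored = score_cohort(Cohort(row), bank, norms).iloc[0]
    return {
        "raw_total": int(scored["raw_total"]),
        "subscale_raws": {s: int(scored[f"raw_{s}"]) for s in bank.subscale_items},
        "t_score": float(scored["t_score"]),
        "label": int(scored["label"]),
    }


def write_scored(cohort: Cohort, scored: pd.DataFrame, path: str | Path) -> None:
    """Write cohort CSV extended with raw_total, t_score and label."""
    out = cohort.df[list(COLUMNS)].copy()
    out["raw_total"] = scored["raw_total"].to_numpy()
    out["t_score"] = scored["t_score"].to_numpy()
    out["label"] = scored["label"].to_numpy()
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# retained-vs-dropped bias check


def raw_totals_available(cohort: Cohort) -> np.ndarray:
    """Raw totals of records whose 47 items are all present.

    Records dropped for missing demographics usually still have full item
    responses, so their symptom burden remains comparable.
    """
    items = cohort.items()
    ok = items.notna().all(axis=1).to_numpy()
    return items.loc[ok].to_numpy(dtype=np.int64).sum(axis=1)


def compare_retained_dropped(retained: Cohort, dropped: Cohort) -> tuple[float, float]:
    """Welch two-sample t-test of raw totals, retained vs dropped.

    Guards against attrition bias after listwise deletion: a small p
    would suggest the excluded records had different symptom levels.
    """
    a = raw_totals_available(retained)
    b = raw_totals_available(dropped)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 usable totals per group, got {len(a)} and {len(b)}"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# class-distribution summaries


def percent_int(num: int, den: int) -> int:
    """Whole-number percentage, half rounded up (sex-table style)."""
    return int(math.floor(100.0 * num / den + 0.5))


def percent_1dp(num: int, den: int) -> float:
    """Percentage truncated to one decimal place (grade-table style)."""
    return math.floor(1000.0 * num / den) / 10.0


def class_counts(labels: Iterable[int]) -> dict[str, int]:
    arr = np.asarray(list(labels), dtype=int)
    return {LABEL_NAMES[k]: int((arr == k).sum()) for k in (0, 1, 2)}


def summarize_by(
    group: Iterable, labels: Iterable[int], style: str = "sex"
) -> dict:
    """Cross-tabulated class distribution with table-style percentages.

    ``style='sex'`` formats percentages as integers; ``style='grade'``
    keeps one decimal (truncated).  Row percentages are within-group;
    the group's Total percentage is its share of the cohort.
    """
    pct = percent_int if style == "sex" else percent_1dp
    group = pd.Series(list(group))
    labels = np.asarray(list(labels), dtype=int)
    total_n = len(labels)
    out: dict = {"groups": {}, "total": {}}
    for g in sorted(group.unique(), key=str):
        mask = (group == g).to_numpy()
        n = int(mask.sum())
        row = {}
        for k in (0, 1, 2):
            c = int((labels[mask] == k).sum())
            row[LABEL_NAMES[k]] = {"n": c, "pct": pct(c, n)}
        row["Total"] = {"n": n, "pct": pct(n, total_n)}
        out["groups"][str(g)] = row
    for k in (0, 1, 2):
        c = int((labels == k).sum())
        out["total"][LABEL_NAMES[k]] = {"n": c, "pct": pct(c, total_n)}
    out["total"]["Total"] = {"n": total_n}
    return out
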