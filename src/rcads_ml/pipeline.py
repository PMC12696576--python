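"""End-to-end pipeline: simulate/load -> filter -> score -> reliability ->
select -> augment -> train/evaluate -> compare, with one master seed,
per-stage derived seeds and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import sklearn
import yaml

from . import __version__
from .augment import fidelity, fit_marginals, generate_synthetic, make_hybrid
from .core import (
    Cohort,
    NormTable,
    compare_retained_dropped,
    filter_complete,
    read_cohort,
    score_cohort,
    summarize_by,
    write_cohort,
    write_scored,
)
from .evaluate import GridSpec, balance_and_split, compare_models, evaluate, grid_search_cv
from .itembank import ItemBank, default_bank
from .selection import select_features
from .reliability import reliability_report
from .simulate import GeneratorConfig, build_norms, generate_cohort

log = logging.getLogger("rcads_ml")

STAGES = ("input", "filter", "score", "reliability", "select", "augment", "model")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Structured configuration for :func:`run_pipeline`."""

    out_dir: str = "rcads_out"
    input_csv: str | None = None  # None -> simulate a cohort
    master_seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    alpha: float = 0.05
    ratios: tuple[int, ...] = (4, 8, 12, 16, 20)
    families: tuple[str, ...] = ("RF", "SVM", "LR", "DT", "NB", "KNN")
    smote_order: str = "balance_first"
    rfe_trees: int = 100
    generator: GeneratorConfig | None = None
    norms_json: str | None = None  # external norm table; None -> synthetic default
    norms_reference_n: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if gen:
            if "class_mix" in gen:
                gen["class_mix"] = tuple(gen["class_mix"])
            if "grade_probs" in gen:
                gen["grade_probs"] = {int(k): v for k, v in gen["grade_probs"].items()}
            cfg.generator = GeneratorConfig(**gen)
        if isinstance(cfg.ratios, list):
            cfg.ratios = tuple(cfg.ratios)
        if isinstance(cfg.families, list):
            cfg.families = tuple(cfg.families)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, bank: ItemBank | None = None) -> dict:
    """Execute the enabled stages in order and write a manifest.

    Any stage failure aborts with the stage name; outputs of completed
    stages are left on disk.  Returns the manifest dict.
    """
    bank = bank or default_bank()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {
            "rcads_ml": __version__,
            "numpy": np.__version__,
            "sklearn": sklearn.__version__,
        },
        "master_seed": cfg.master_seed,
        "stages": [],
    }

    def record(stage: str, seed: int | None, outputs: list[Path], **extra) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": seed,
                "outputs": {p.name: _sha256(p) for p in outputs},
                **extra,
            }
        )

    stage = "input"
    try:
        if cfg.input_csv:
            cohort = read_cohort(cfg.input_csv, bank)
            seed_in = None
            gen_cfg = cfg.generator or GeneratorConfig()
        else:
            seed_in = derive_seed(cfg.master_seed, "input")
            from dataclasses import replace

            gen_cfg = replace(cfg.generator or GeneratorConfig(), seed=seed_in)
            cohort, _truth = generate_cohort(gen_cfg, bank)
        raw_csv = out / "cohort_raw.csv"
        write_cohort(cohort, raw_csv)
        record(stage, seed_in, [raw_csv], n=cohort.n)

        stage = "filter"
        retained, dropped = filter_complete(cohort)
        ret_csv = out / "cohort_retained.csv"
        write_cohort(retained, ret_csv)
        bias = None
        if dropped.n >= 2 and retained.n >= 2:
            t, p = compare_retained_dropped(retained, dropped)
            bias = {"t": t, "p": p}
        record(stage, None, [ret_csv],
               retained=retained.n, dropped=dropped.n, bias_check=bias)

        stage = "score"
        if cfg.norms_json:
            norms = NormTable.from_json(cfg.norms_json)
        else:
            norms = build_norms(
                gen_cfg,
                reference_n=cfg.norms_reference_n,
                seed=derive_seed(cfg.master_seed, "norms"),
                bank=bank,
            )
        norms_path = out / "norms.json"
        norms.to_json(norms_path)
        scored = score_cohort(retained, bank, norms)
        scored_csv = out / "cohort_scored.csv"
        write_scored(retained, scored, scored_csv)
        labels = scored["label"].to_numpy()
        retained.labels = labels
        summary = {
            "by_sex": summarize_by(retained.df["sex"], labels, style="sex"),
            "by_grade": summarize_by(
                retained.df["grade"].astype(int), labels, style="grade"
            ),
        }
        summary_path = out / "class_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2))
        record(stage, None, [norms_path, scored_csv, summary_path])

        if cfg.stages.get("reliability", True):
            stage = "reliability"
            rel = reliability_report(retained, bank)
            rel_path = out / "reliability.json"
            rel_path.write_text(json.dumps(rel.to_dict(), indent=2))
            record(stage, None, [rel_path], alpha_overall=rel.alpha_overall)

        eliminated: set[int] = set()
        if cfg.stages.get("select", True):
            stage = "select"
            seed_sel = derive_seed(cfg.master_seed, "select")
            report = select_features(
                retained, labels, bank, alpha=cfg.alpha,
                n_estimators=cfg.rfe_trees, seed=seed_sel,
            )
            eliminated = report.eliminated
            sel_path = out / "selection.json"
            sel_path.write_text(json.dumps(report.to_dict(), indent=2))
            record(stage, seed_sel, [sel_path], eliminated=sorted(eliminated))

        feature_items = [i for i in bank.item_ids if i not in eliminated]
        hybrids: dict[int, Cohort] = {}
        if cfg.stages.get("augment", True):
            stage = "augment"
            model = fit_marginals(retained, bank).calibrate(bank)
            model_path = out / "augmentation_model.json"
            model.to_json(model_path)
            outputs = [model_path]
            for ratio in cfg.ratios:
                seed_aug = derive_seed(cfg.master_seed, f"augment:{ratio}")
                synth = generate_synthetic(model, ratio, seed_aug, bank, norms)
                hybrid = make_hybrid(retained, synth)
                hybrids[ratio] = hybrid
                s_csv = out / f"synthetic_1to{ratio}.csv"
                h_csv = out / f"hybrid_1to{ratio}.csv"
                write_cohort(synth, s_csv)
                write_cohort(hybrid, h_csv)
                fid = fidelity(retained, synth, bank, model)
                f_json = out / f"fidelity_1to{ratio}.json"
                f_json.write_text(json.dumps(fid.to_dict(), indent=2))
                outputs += [s_csv, h_csv, f_json]
            record(stage, None, outputs, ratios=list(cfg.ratios))

        if cfg.stages.get("model", True):
            stage = "model"
            seed_mod = derive_seed(cfg.master_seed, "model")
            datasets = {"original": retained}
            datasets.update({f"hybrid_1to{r}": h for r, h in hybrids.items()})
            results: dict = {}
            fold_scores: dict = {}
            for name, data in datasets.items():
                data_scored = score_cohort(data, bank, norms)
                X = data.items()[
                    [f"item_{i:02d}" for i in feature_items]
                ].to_numpy(dtype=float)
                y = data_scored["label"].to_numpy()
                if np.bincount(y, minlength=3).min() < 2:
                    log.warning("%s: a class has < 2 records; skipping", name)
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    X_tr, y_tr, X_te, y_te = balance_and_split(
                        X, y, seed=seed_mod, order=cfg.smote_order
                    )
                results[name] = {}
                for fam in cfg.families:
                    model_fit, best, cv_acc, folds = grid_search_cv(
                        X_tr, y_tr, GridSpec(fam), seed=seed_mod
                    )
                    rep = evaluate(model_fit, X_te, y_te,
                                   cv_fold_scores=folds, best_params=best)
                    results[name][fam] = rep.to_dict()
                    fold_scores[(name, fam)] = folds
            comparisons = {}
            for (na, fa), sa in fold_scores.items():
                for (nb, fb), sb in fold_scores.items():
                    if na == nb and fa < fb:
                        try:
                            t, p = compare_models(sa, sb)
                        except ValueError:
                            t, p = float("nan"), float("nan")
                        comparisons[f"{na}:{fa}-vs-{fb}"] = {"t": t, "p": p}
            eval_path = out / "evaluation.json"
            eval_path.write_text(
                json.dumps({"results": results, "paired_t": comparisons}, indent=2)
            )
            record(stage, seed_mod, [eval_path], smote_order=cfg.smote_order)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
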