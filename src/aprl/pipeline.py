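"""End-to-end orchestration: phantom (or real volumes) -> labelling ->
features -> training -> evaluation, plus cohort-level summaries."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (
    SmoteConfig,
    evaluate,
    evaluate_nonconfluent,
    permutation_importance,
    predict_proba,
    resample_ci,
    split_by_subject,
    train_classifier,
)
from .lesion_labelling import DEFAULT_THRESHOLDS, label_lesions
from .phantom import PhantomSpec, generate_cohort
from .radiomics import extract_feature_table
from .volume_io import Grid, read_volume, write_volume

logger = logging.getLogger("aprl")

__all__ = ["RunConfig", "run_pipeline", "count_correlation", "cohort_feature_table"]

_KNOWN_KEYS = {
    "schema_version", "seed", "output_dir",
    "phantom", "subjects",
    "thresholds", "smooth_sigma_vox", "fixed_threshold", "connectivity",
    "include_size",
    "n_train_subjects", "min_lesions", "smote_k", "oversample_factor",
    "n_folds", "n_trees", "max_features_grid", "n_iter_ci",
}

_PHANTOM_KEYS = {
    "grid_shape", "voxel_size_mm", "n_subjects", "n_lesions", "rim_fraction",
    "lesion_radius_range_vox", "rim_thickness_vox", "rim_contrast",
    "background_sd", "confluence_rate", "prob_blur_sigma_vox",
    "rim_radius_scale", "interior_offset_max",
}


@dataclass
class RunConfig:
    """One run's full configuration; exactly one of phantom / real subjects."""

    seed: int = 0
    output_dir: str = "aprl_run"
    phantom: dict | None = None
    subjects: list[dict] | None = None  # real-data mode: per-subject file paths
    thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    smooth_sigma_vox: float = 1.0
    fixed_threshold: float | None = None
    connectivity: int = 26
    include_size: bool = False
    n_train_subjects: int = 16
    min_lesions: int = 100
    smote_k: int = 5
    oversample_factor: float | str = "auto"
    n_folds: int = 10
    n_trees: int = 500
    max_features_grid: tuple = ("sqrt", "third", "half")
    n_iter_ci: int = 0  # 0 disables the resampling-CI stage

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.subjects is None):
            raise ValueError("exactly one of phantom spec / real-data subjects required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "phantom" in raw and raw["phantom"]:
            bad = set(raw["phantom"]) - _PHANTOM_KEYS
            if bad:
                raise ValueError(f"unknown phantom keys: {sorted(bad)}")
        raw.pop("schema_version", None)
        if "max_features_grid" in raw:
            raw["max_features_grid"] = tuple(raw["max_features_grid"])
        return cls(**raw)

    def phantom_spec(self) -> tuple[PhantomSpec, int]:
        ph = dict(self.phantom or {})
        n_subjects = int(ph.pop("n_subjects", 20))
        shape = tuple(ph.pop("grid_shape", (96, 96, 96)))
        vox = float(ph.pop("voxel_size_mm", 0.65))
        if "lesion_radius_range_vox" in ph:
            ph["lesion_radius_range_vox"] = tuple(ph["lesion_radius_range_vox"])
        spec = PhantomSpec(grid=Grid(shape, vox), seed=self.seed, **ph)
        return spec, n_subjects


def count_correlation(
    predicted_counts, reference_counts
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation between per-subject counts, with a Fisher-z 95% CI."""
    x = np.asarray(predicted_counts, dtype=np.float64)
    y = np.asarray(reference_counts, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired subject counts")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in counts")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return r, (float(lo), float(hi))


def _label_subject(cfg: RunConfig, subject_id, prob, gold, csf, gm, annot):
    return label_lesions(
        prob, gold, csf, gm, annot,
        thresholds=cfg.thresholds,
        smooth_sigma_vox=cfg.smooth_sigma_vox,
        subject_id=subject_id,
        fixed_threshold=cfg.fixed_threshold,
        connectivity=cfg.connectivity,
    )


def cohort_feature_table(cfg: RunConfig, cases=None):
    """Label every subject and extract the pooled feature table.

    Returns (table, per-subject summary DataFrame, label maps dict).
    Phantom mode generates the cohort; real-data mode reads the configured
    NIfTI paths per subject.
    """
    tables, summaries, label_maps = [], [], {}
    if cfg.phantom is not None:
        if cases is None:
            spec, n_subjects = cfg.phantom_spec()
            cases = generate_cohort(n_subjects, spec, seed=cfg.seed)
        for case in cases:
            labels, records = _label_subject(
                cfg, case.subject_id, case.prob_map, case.gold_mask,
                case.csf_mask, case.gm_mask, case.prl_annotation,
            )
            tab = extract_feature_table(case.phase, labels, records, cfg.include_size)
            tables.append(tab)
            label_maps[case.subject_id] = labels
            summaries.append({
                "subject_id": case.subject_id,
                "n_lesions": len(records),
                "n_prl": int(sum(r.is_prl_truth for r in records)),
                "n_prl_truth": case.n_rim,
            })
    else:
        for sub in cfg.subjects:
            sid = sub["subject_id"]
            phase = read_volume(sub["phase"], "phase")
            prob = read_volume(sub["prob"], "prob")
            gold = read_volume(sub["gold"], "mask")
            csf = read_volume(sub["csf"], "mask")
            gm = read_volume(sub["gm"], "mask")
            annot = read_volume(sub["annotation"], "mask")
            labels, records = _label_subject(cfg, sid, prob, gold, csf, gm, annot)
            tab = extract_feature_table(phase, labels, records, cfg.include_size)
            tables.append(tab)
            label_maps[sid] = labels
            summaries.append({
                "subject_id": sid,
                "n_lesions": len(records),
                "n_prl": int(sum(r.is_prl_truth for r in records)),
                "n_prl_truth": np.nan,
            })
    return pd.concat(tables, ignore_index=True), pd.DataFrame(summaries), label_maps


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, write_volumes: bool = False) -> dict:
    """Run every stage and persist artifacts + manifest under cfg.output_dir.

    Returns the result dictionary that is also written as ``report.json``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    try:
        logger.info("aprl %s starting; seed=%d", __version__, cfg.seed)
        logger.info(
            "parameters: thresholds=%s sigma=%.3g smote_k=%d factor=%s folds=%d "
            "trees=%d grid=%s n_iter_ci=%d",
            f"[{cfg.thresholds[0]}..{cfg.thresholds[-1]}]", cfg.smooth_sigma_vox,
            cfg.smote_k, cfg.oversample_factor, cfg.n_folds, cfg.n_trees,
            cfg.max_features_grid, cfg.n_iter_ci,
        )
        table, summary, label_maps = cohort_feature_table(cfg)
        table.to_csv(out / "features.csv", index=False)
        summary.to_csv(out / "subject_summary.csv", index=False)
        if write_volumes:
            for sid, labels in label_maps.items():
                write_volume(labels, out / "labels" / f"{sid}_labels.nii.gz")

        split = split_by_subject(table, cfg.n_train_subjects, cfg.min_lesions,
                                 seed=cfg.seed)
        train = table[table["subject_id"].isin(split.train_subjects)]
        test = table[table["subject_id"].isin(split.test_subjects)]
        smote_cfg = SmoteConfig(cfg.smote_k, cfg.oversample_factor, seed=cfg.seed)
        fitted = train_classifier(
            train, smote_cfg, n_folds=cfg.n_folds, seed=cfg.seed,
            n_trees=cfg.n_trees, max_features_grid=cfg.max_features_grid,
        )
        report = evaluate(fitted, test, "youden")
        sub_report = None
        subset = test.loc[~test["is_confluent"].astype(bool)]
        if subset["is_prl_truth"].nunique() == 2:
            sub_report = evaluate_nonconfluent(fitted, test)
        importance = permutation_importance(fitted, test, seed=cfg.seed)
        importance.to_csv(out / "importance.csv", index=False)

        r, r_ci = np.nan, (np.nan, np.nan)
        if summary["n_prl_truth"].notna().all() and len(summary) >= 3:
            if summary["n_prl"].std() > 0 and summary["n_prl_truth"].std() > 0:
                r, r_ci = count_correlation(summary["n_prl"], summary["n_prl_truth"])

        ci = None
        if cfg.n_iter_ci >= 2:
            ci, reps = resample_ci(
                table, n_iter=cfg.n_iter_ci, n_train_subjects=cfg.n_train_subjects,
                min_lesions=cfg.min_lesions, smote_cfg=smote_cfg,
                n_folds=cfg.n_folds, n_trees=cfg.n_trees,
                max_features_grid=cfg.max_features_grid, seed=cfg.seed,
            )
            reps.to_csv(out / "ci_replicates.csv", index=False)
            report.ci = ci

        result = {
            "n_lesions": int(len(table)),
            "n_prl": int(table["is_prl_truth"].sum()),
            "prevalence": float(table["is_prl_truth"].mean()),
            "split": {"train": list(split.train_subjects),
                      "test": list(split.test_subjects)},
            "report": report.as_dict(),
            "report_nonconfluent": sub_report.as_dict() if sub_report else None,
            "count_correlation_r": r,
            "count_correlation_ci": list(r_ci),
            "top_features": importance["feature"].head(10).tolist(),
        }
        with open(out / "report.json", "w") as f:
            json.dump(result, f, indent=2)

        manifest = {
            "aprl_version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "artifacts": {
                p.name: _sha256(p)
                for p in sorted(out.glob("*.csv")) + [out / "report.json"]
            },
        }
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
        logger.info("run complete: AUC=%.3f", report.auc)
        return result
    finally:
        logger.removeHandler(fh)
        fh.close()
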