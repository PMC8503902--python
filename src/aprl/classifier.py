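"""Rim-lesion classification: SMOTE rebalancing, random forest with 10-fold
CV tuning, Youden-J operating point, resampled empirical CIs, and
permutation variable importance.

The minority class (rim-positive lesions, ~12% prevalence in the kind of
cohort this targets) is oversampled by the reciprocal of its prevalence;
the majority class is never undersampled and passes through unchanged.
Splits are always by subject, so no lesion's subject contributes to both
sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .radiomics import FEATURE_NAMES

__all__ = [
    "SmoteConfig",
    "SplitSpec",
    "PerformanceReport",
    "FittedModel",
    "feature_columns",
    "split_by_subject",
    "smote_oversample",
    "train_classifier",
    "predict_proba",
    "youden_threshold",
    "auc_rank",
    "confusion_at",
    "measures_from_confusion",
    "evaluate",
    "evaluate_nonconfluent",
    "evaluate_scores",
    "resample_ci",
    "permutation_importance",
]

LABEL_COL = "is_prl_truth"
MEASURE_NAMES = (
    "auc",
    "accuracy",
    "ppv",
    "npv",
    "fpr",
    "fnr",
    "sensitivity",
    "specificity",
)


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE parameters. ``oversample_factor="auto"`` resolves to the
    reciprocal of the minority prevalence in the training rows."""

    k_neighbors: int = 5
    oversample_factor: float | str = "auto"
    seed: int = 0


@dataclass(frozen=True)
class SplitSpec:
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]


@dataclass
class PerformanceReport:
    """AUC, operating threshold, confusion counts and the eight derived
    measures; optionally per-measure empirical CIs."""

    auc: float
    threshold: float
    confusion: tuple[int, int, int, int]  # (TN, FP, FN, TP)
    accuracy: float
    ppv: float
    npv: float
    fpr: float
    fnr: float
    sensitivity: float
    specificity: float
    n_test: int = 0
    ci: dict[str, tuple[float, float]] | None = None

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in MEASURE_NAMES}
        d["threshold"] = self.threshold
        d["confusion"] = {"TN": self.confusion[0], "FP": self.confusion[1],
                          "FN": self.confusion[2], "TP": self.confusion[3]}
        d["n_test"] = self.n_test
        if self.ci is not None:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


@dataclass
class FittedModel:
    model: RandomForestClassifier
    feature_cols: tuple[str, ...]
    best_max_features: object = "sqrt"
    cv_auc: dict = field(default_factory=dict)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The predictor columns present in a feature table (44 features plus
    size_vox when it was extracted)."""
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    if "size_vox" in table.columns:
        cols.append("size_vox")
    return cols


# --------------------------------------------------------------------------
# splitting & SMOTE
# --------------------------------------------------------------------------

def split_by_subject(
    table: pd.DataFrame,
    n_train_subjects: int = 16,
    min_lesions: int = 100,
    seed: int = 0,
    max_retries: int = 200,
) -> SplitSpec:
    """Randomly assign whole subjects to train/test, redrawing until both
    sides hold at least ``min_lesions`` lesions."""
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) <= n_train_subjects:
        raise ValueError(
            f"need more than {n_train_subjects} subjects, have {len(subjects)}"
        )
    counts = table.groupby("subject_id").size()
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(subjects)
        train = tuple(sorted(perm[:n_train_subjects]))
        test = tuple(sorted(perm[n_train_subjects:]))
        if counts.loc[list(train)].sum() >= min_lesions and counts.loc[list(test)].sum() >= min_lesions:
            return SplitSpec(train, test)
    raise ValueError(
        f"could not satisfy min_lesions={min_lesions} per side after {max_retries} draws"
    )


def smote_oversample(
    table: pd.DataFrame,
    cfg: SmoteConfig,
    feature_cols: Sequence[str] | None = None,
    label_col: str = LABEL_COL,
) -> pd.DataFrame:
    """Append SMOTE-synthesized minority rows; majority rows pass through
    unchanged.

    Each synthetic row is row + u * (neighbor - row) for a uniformly chosen
    minority row, one of its ``k_neighbors`` nearest minority neighbours
    (Euclidean in feature space) and u ~ Uniform(0,1). The number of
    synthetic rows is round((factor - 1) * n_minority).
    """
    if feature_cols is None:
        feature_cols = feature_columns(table)
    y = table[label_col].to_numpy(dtype=bool)
    n_min = int(y.sum())
    n_maj = int((~y).sum())
    minority_is_pos = n_min <= n_maj
    if not minority_is_pos:
        n_min, n_maj = n_maj, n_min
    if n_min <= cfg.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={cfg.k_neighbors}"
        )
    factor = cfg.oversample_factor
    if factor == "auto":
        factor = (n_min + n_maj) / n_min  # reciprocal of minority prevalence
    factor = float(factor)
    if factor < 1.0:
        raise ValueError("oversample_factor must be >= 1")
    n_synth = int(round((factor - 1.0) * n_min))
    if n_synth == 0:
        return table.copy()

    min_mask = y if minority_is_pos else ~y
    X_min = table.loc[min_mask, feature_cols].to_numpy(dtype=np.float64)
    # exhaustive pairwise distances; minority classes here are small
    d2 = np.sum((X_min[:, None, :] - X_min[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, : cfg.k_neighbors]

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, X_min.shape[0], size=n_synth)
    pick = rng.integers(0, cfg.k_neighbors, size=n_synth)
    u = rng.random(n_synth)
    nbr = nn_idx[base, pick]
    X_new = X_min[base] + u[:, None] * (X_min[nbr] - X_min[base])

    synth = pd.DataFrame(X_new, columns=list(feature_cols))
    synth[label_col] = bool(minority_is_pos)
    if "subject_id" in table.columns:
        synth["subject_id"] = "synthetic"
    if "lesion_id" in table.columns:
        synth["lesion_id"] = -1
    if "is_confluent" in table.columns:
        synth["is_confluent"] = False
    out = pd.concat([table, synth], ignore_index=True)
    return out


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _resolve_max_features(name, p: int):
    if name == "sqrt":
        return "sqrt"
    if name == "third":
        return max(1, p // 3)
    if name == "half":
        return max(1, p // 2)
    return name


def train_classifier(
    train: pd.DataFrame,
    cfg: SmoteConfig,
    n_folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    max_features_grid: Sequence = ("sqrt", "third", "half"),
    label_col: str = LABEL_COL,
) -> FittedModel:
    """Fit the random-forest rim classifier.

    The forest's main complexity parameter (candidate features per split)
    is tuned by stratified 10-fold CV on the training lesions, with SMOTE
    applied inside each fold's training part only (no synthetic rows leak
    into fold validation). The final model is refit on the SMOTE-augmented
    full training set with the winning setting.
    """
    cols = feature_columns(train)
    y = train[label_col].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    p = len(cols)
    rng = np.random.default_rng(seed)

    cv_auc: dict = {}
    if len(max_features_grid) > 1:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        folds = list(skf.split(np.zeros(len(train)), y))
        for mf in max_features_grid:
            aucs = []
            for fi, (tr_idx, va_idx) in enumerate(folds):
                tr = train.iloc[tr_idx]
                va = train.iloc[va_idx]
                if va[label_col].nunique() < 2:
                    continue
                fold_cfg = SmoteConfig(cfg.k_neighbors, cfg.oversample_factor,
                                       seed=cfg.seed + 1000 * fi + 1)
                aug = smote_oversample(tr, fold_cfg, cols, label_col)
                rf = RandomForestClassifier(
                    n_estimators=n_trees,
                    max_features=_resolve_max_features(mf, p),
                    random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                )
                rf.fit(aug[cols].to_numpy(), aug[label_col].to_numpy(dtype=bool))
                scores = rf.predict_proba(va[cols].to_numpy())[:, 1]
                aucs.append(auc_rank(scores, va[label_col].to_numpy(dtype=bool)))
            cv_auc[mf] = float(np.mean(aucs)) if aucs else np.nan
        best = max(
            max_features_grid,
            key=lambda m: cv_auc[m] if np.isfinite(cv_auc[m]) else -np.inf,
        )
    else:
        best = max_features_grid[0]

    aug = smote_oversample(train, cfg, cols, label_col)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=_resolve_max_features(best, p),
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    rf.fit(aug[cols].to_numpy(), aug[label_col].to_numpy(dtype=bool))
    return FittedModel(model=rf, feature_cols=tuple(cols),
                       best_max_features=best, cv_auc=cv_auc)


def predict_proba(fitted: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Per-lesion rim probability scores."""
    return fitted.model.predict_proba(table[list(fitted.feature_cols)].to_numpy())[:, 1]


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the rank statistic: P(random positive outscores a random
    negative), ties counting 1/2 (Mann-Whitney with midranks)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    from scipy.stats import rankdata

    r = rankdata(scores, method="average")
    u = float(r[labels].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    J is evaluated at every distinct score under the rule "positive iff
    score >= t"; ties break toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("Youden threshold needs both classes present")
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        sens = float((pred & labels).sum()) / labels.sum()
        spec = float((~pred & ~labels).sum()) / (~labels).sum()
        j = sens + spec - 1.0
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def confusion_at(scores, labels, t: float) -> tuple[int, int, int, int]:
    """(TN, FP, FN, TP) under the rule positive iff score >= t."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= t
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    return tn, fp, fn, tp


def measures_from_confusion(tn: int, fp: int, fn: int, tp: int) -> dict[str, float]:
    """The eight derived measures; any 0/0 ratio is reported as NaN."""

    def ratio(a, b):
        return a / b if b > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    return {
        "accuracy": ratio(tp + tn, tn + fp + fn + tp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "fpr": 1.0 - spec,
        "fnr": 1.0 - sens,
        "sensitivity": sens,
        "specificity": spec,
    }


def evaluate_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float | str = "youden"
) -> PerformanceReport:
    """Build a full performance report from scores and truth labels."""
    labels = np.asarray(labels, dtype=bool)
    t = youden_threshold(scores, labels) if threshold == "youden" else float(threshold)
    tn, fp, fn, tp = confusion_at(scores, labels, t)
    meas = measures_from_confusion(tn, fp, fn, tp)
    return PerformanceReport(
        auc=auc_rank(scores, labels),
        threshold=t,
        confusion=(tn, fp, fn, tp),
        n_test=int(labels.size),
        **meas,
    )


def evaluate(
    fitted: FittedModel,
    test: pd.DataFrame,
    threshold: float | str = "youden",
    label_col: str = LABEL_COL,
) -> PerformanceReport:
    """Score the test lesions and report AUC plus the eight threshold-based
    measures at the Youden-J (or fixed) operating point."""
    if len(test) == 0:
        raise ValueError("empty test set")
    scores = predict_proba(fitted, test)
    return evaluate_scores(scores, test[label_col].to_numpy(dtype=bool), threshold)


def evaluate_nonconfluent(
    fitted: FittedModel, test: pd.DataFrame, label_col: str = LABEL_COL
) -> PerformanceReport:
    """Re-run the evaluation on non-confluent lesions only, with its own
    subset-specific Youden threshold."""
    subset = test.loc[~test["is_confluent"].astype(bool)]
    return evaluate(fitted, subset, "youden", label_col)


# --------------------------------------------------------------------------
# resampling CIs & importance
# --------------------------------------------------------------------------

def resample_ci(
    table: pd.DataFrame,
    n_iter: int = 1000,
    n_train_subjects: int = 16,
    min_lesions: int = 100,
    smote_cfg: SmoteConfig | None = None,
    n_folds: int = 10,
    n_trees: int = 500,
    max_features_grid: Sequence = ("sqrt", "third", "half"),
    seed: int = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> tuple[dict[str, tuple[float, float]], pd.DataFrame]:
    """Empirical CIs by re-drawing the subject-level split ``n_iter`` times.

    Each iteration repeats the whole chain (split -> SMOTE -> train ->
    Youden -> evaluate) with a seed derived from the master seed by a
    simple counter, so any single iteration is reproducible in isolation.
    Returns the per-measure (2.5, 97.5) percentile interval plus the
    replicate-level measure table.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    smote_cfg = smote_cfg or SmoteConfig()
    rows = []
    for it in range(n_iter):
        s = (seed + 1) * 100_000 + it
        split = split_by_subject(table, n_train_subjects, min_lesions, seed=s)
        tr = table[table["subject_id"].isin(split.train_subjects)]
        te = table[table["subject_id"].isin(split.test_subjects)]
        cfg = SmoteConfig(smote_cfg.k_neighbors, smote_cfg.oversample_factor, seed=s)
        fitted = train_classifier(tr, cfg, n_folds=n_folds, seed=s,
                                  n_trees=n_trees, max_features_grid=max_features_grid)
        rep = evaluate(fitted, te, "youden")
        row = {m: getattr(rep, m) for m in MEASURE_NAMES}
        row["threshold"] = rep.threshold
        row["iteration"] = it
        rows.append(row)
    reps = pd.DataFrame(rows)
    ci = {}
    for m in MEASURE_NAMES:
        vals = reps[m].to_numpy(dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        lo, hi = np.percentile(vals, percentiles)
        ci[m] = (float(lo), float(hi))
    return ci, reps


def permutation_importance(
    fitted: FittedModel,
    data: pd.DataFrame,
    seed: int = 0,
    n_repeats: int = 5,
    label_col: str = LABEL_COL,
) -> pd.DataFrame:
    """Permutation variable importance on predicted-probability MSE.

    For each feature the column is permuted and the percent increase in
    mean-squared error (of the predicted rim probability against the 0/1
    label) over the unpermuted model is recorded; the raw importance is the
    mean over repeats and the scaled importance divides by the repeat-level
    standard deviation for comparability across variables.
    """
    cols = list(fitted.feature_cols)
    X = data[cols].to_numpy(dtype=np.float64)
    y = data[label_col].to_numpy(dtype=bool).astype(float)
    base = fitted.model.predict_proba(X)[:, 1]
    # floor keeps percent increases finite when the model predicts perfectly
    mse0 = max(float(np.mean((base - y) ** 2)), 1e-12)
    rng = np.random.default_rng(seed)
    rows = []
    for j, c in enumerate(cols):
        incr = []
        for _ in range(max(3, n_repeats)):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            pred = fitted.model.predict_proba(Xp)[:, 1]
            mse = float(np.mean((pred - y) ** 2))
            incr.append(100.0 * (mse - mse0) / mse0)
        incr = np.asarray(incr)
        raw = float(incr.mean())
        sd = float(incr.std(ddof=1))
        rows.append({"feature": c, "raw_pct_incr_mse": raw,
                     "scaled_importance": raw / sd if sd > 0 else raw})
    out = pd.DataFrame(rows).sort_values("raw_pct_incr_mse", ascending=False)
    return out.reset_index(drop=True)
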