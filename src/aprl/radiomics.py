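"""First-order radiomic features of a lesion's phase intensities.

Exactly 44 features summarizing the intensity sample of one lesion in three
ways: location/average, spread and distribution shape, and diversity of
intensities. Conventions, fixed across the package:

* moments use population normalization (1/n), sd = sqrt(variance);
* the interquartile range is |p75 - p25|;
* skew and kurtosis of a constant sample are 0; kurtosis is excess
  (Gaussian -> 0);
* the empirical probability p(v) of a distinct value v is its relative
  frequency among the lesion's n voxels with NO intensity binning, so
  entropy (base 2) and uniformity are computed over exact floating-point
  value equality — for a sample of n all-distinct values entropy = log2(n)
  and uniformity = 1/n;
* percentiles use linear interpolation between order statistics;
* total energy multiplies energy by the voxel volume in mm^3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .volume_io import LesionLabelMap, PhaseVolume, require_same_grid
from .lesion_labelling import LesionRecord

__all__ = ["FEATURE_NAMES", "extract_features", "extract_feature_table"]

FEATURE_NAMES: tuple[str, ...] = (
    # location / average
    "mean",
    "median",
    "mode",
    "p5",
    "p10",
    "p20",
    "p25",
    "p75",
    "p80",
    "p90",
    "p95",
    "midrange",
    "midhinge",
    "trimean",
    "trimmed_mean_10",
    "winsorized_mean_10",
    # spread
    "min",
    "max",
    "range",
    "iqr",
    "decile_range",
    "quintile_range",
    "quartile_dispersion",
    # dispersion / shape
    "variance",
    "sd",
    "std_error",
    "mean_abs_dev",
    "robust_mean_abs_dev",
    "median_abs_dev",
    "mean_abs_dev_median",
    "coeff_variation",
    "skewness",
    "kurtosis",
    "quartile_skew",
    "nonparametric_skew",
    # magnitude
    "energy",
    "total_energy",
    "rms",
    "intensity_sum",
    "abs_intensity_sum",
    "mean_abs",
    "geometric_mean_abs",
    # diversity of intensities
    "uniformity",
    "entropy",
)

assert len(FEATURE_NAMES) == 44


def extract_features(
    values: np.ndarray, voxel_volume_mm3: float = 1.0, n_bins: int | None = None
) -> dict[str, float]:
    """Compute the 44 first-order features of one intensity sample.

    Parameters
    ----------
    values
        The lesion's voxel intensities (n >= 1, all finite); ordering is
        irrelevant.
    voxel_volume_mm3
        Volume of one voxel, used only by ``total_energy``.
    n_bins
        Off (None) by default: the empirical probabilities behind
        uniformity and entropy use exact value equality. When set, those
        two features are instead computed over ``n_bins`` equal-width bins
        spanning [min, max] — a sensitivity-analysis option only.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    if n == 0:
        raise ValueError("empty intensity sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("intensity sample contains non-finite values")
    # canonical ascending order makes every reduction, and hence every
    # feature, exactly independent of voxel ordering
    x = np.sort(x)

    mean = float(np.mean(x))
    median = float(np.median(x))
    mn, mx = float(np.min(x)), float(np.max(x))
    p5, p10, p20, p25, p75, p80, p90, p95 = (
        float(v) for v in np.percentile(x, [5, 10, 20, 25, 75, 80, 90, 95])
    )

    uniq, counts = np.unique(x, return_counts=True)
    # mode: most frequent distinct value, ties toward the smallest value
    mode = float(uniq[np.argmax(counts)])

    k_trim = int(np.floor(0.1 * n))
    xs = np.sort(x)
    trimmed = float(np.mean(xs[k_trim : n - k_trim])) if n - 2 * k_trim > 0 else mean
    winsor = float(np.mean(np.clip(x, p10, p90)))

    dev = x - mean
    variance = float(np.mean(dev**2))
    sd = float(np.sqrt(variance))
    mad = float(np.mean(np.abs(dev)))
    sub = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(sub - np.mean(sub)))) if sub.size else 0.0
    medad = float(np.median(np.abs(x - median)))
    madm = float(np.mean(np.abs(x - median)))
    cv = sd / abs(mean) if mean != 0.0 else 0.0
    if sd > 0:
        skew = float(np.mean(dev**3)) / sd**3
        kurt = float(np.mean(dev**4)) / sd**4 - 3.0
        npskew = (mean - median) / sd
    else:
        skew = kurt = npskew = 0.0
    qskew = ((p75 + p25 - 2.0 * median) / (p75 - p25)) if p75 > p25 else 0.0

    energy = float(np.sum(x**2))
    rms = float(np.sqrt(energy / n))

    if n_bins is not None:
        if n_bins < 1:
            raise ValueError("n_bins must be a positive integer")
        if mx > mn:
            bin_counts = np.histogram(x, bins=n_bins, range=(mn, mx))[0]
            bin_counts = bin_counts[bin_counts > 0]
        else:
            bin_counts = np.array([n])
        p = bin_counts / n
    else:
        p = counts / n
    uniformity = float(np.sum(p**2))
    entropy = float(-np.sum(p * np.log2(p))) + 0.0  # +0.0 folds -0.0 to 0.0
    qdisp = (p75 - p25) / (abs(p75) + abs(p25)) if abs(p75) + abs(p25) > 0 else 0.0
    gmean_abs = float(np.exp(np.mean(np.log(np.abs(x))))) if np.all(x != 0) else 0.0

    out = {
        "mean": mean,
        "median": median,
        "mode": mode,
        "p5": p5,
        "p10": p10,
        "p20": p20,
        "p25": p25,
        "p75": p75,
        "p80": p80,
        "p90": p90,
        "p95": p95,
        "midrange": 0.5 * (mn + mx),
        "midhinge": 0.5 * (p25 + p75),
        "trimean": 0.25 * (p25 + 2.0 * median + p75),
        "trimmed_mean_10": trimmed,
        "winsorized_mean_10": winsor,
        "min": mn,
        "max": mx,
        "range": mx - mn,
        "iqr": abs(p75 - p25),
        "decile_range": p90 - p10,
        "quintile_range": p80 - p20,
        "quartile_dispersion": qdisp,
        "variance": variance,
        "sd": sd,
        "std_error": sd / np.sqrt(n),
        "mean_abs_dev": mad,
        "robust_mean_abs_dev": rmad,
        "median_abs_dev": medad,
        "mean_abs_dev_median": madm,
        "coeff_variation": cv,
        "skewness": skew,
        "kurtosis": kurt,
        "quartile_skew": qskew,
        "nonparametric_skew": npskew,
        "energy": energy,
        "total_energy": energy * float(voxel_volume_mm3),
        "rms": rms,
        "intensity_sum": float(np.sum(x)),
        "abs_intensity_sum": float(np.sum(np.abs(x))),
        "mean_abs": float(np.mean(np.abs(x))),
        "geometric_mean_abs": gmean_abs,
        "uniformity": uniformity,
        "entropy": entropy,
    }
    return out


def extract_feature_table(
    phase: PhaseVolume,
    labels: LesionLabelMap,
    records: list[LesionRecord],
    include_size: bool = False,
) -> pd.DataFrame:
    """One feature row per lesion over its (dilated, tissue-excluded) voxels.

    Columns: subject_id, lesion_id, the 44 features, optional size_vox,
    then is_confluent and the is_prl_truth label.
    """
    require_same_grid(phase, labels)
    lab = labels.values
    present = set(labels.lesion_ids())
    rows = []
    for rec in records:
        if rec.lesion_id not in present:
            raise ValueError(f"lesion id {rec.lesion_id} absent from label map")
        sample = phase.values[lab == rec.lesion_id]
        feats = extract_features(sample, phase.grid.voxel_volume_mm3)
        row = {"subject_id": rec.subject_id, "lesion_id": rec.lesion_id}
        row.update({k: feats[k] for k in FEATURE_NAMES})
        if include_size:
            row["size_vox"] = rec.size_vox
        row["is_confluent"] = rec.is_confluent
        row["is_prl_truth"] = rec.is_prl_truth
        rows.append(row)
    cols = ["subject_id", "lesion_id", *FEATURE_NAMES]
    if include_size:
        cols.append("size_vox")
    cols += ["is_confluent", "is_prl_truth"]
    return pd.DataFrame(rows, columns=cols)
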