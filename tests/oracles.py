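"""Independent reference implementations used only as test oracles.

Everything here is written straight from the defining formulas in plain
Python (loops, ``math``), deliberately not sharing code paths with the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math


def percentile(values, q):
    """Linear-interpolation percentile between order statistics."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q / 100.0
    f = math.floor(h)
    c = math.ceil(h)
    return xs[f] + (h - f) * (xs[c] - xs[f])


def feature_oracle(values, voxel_volume_mm3=1.0):
    """All 44 first-order features, straight from their formulas."""
    x = list(map(float, values))
    n = len(x)
    xs = sorted(x)
    mean = sum(x) / n
    if n % 2:
        median = xs[n // 2]
    else:
        median = 0.5 * (xs[n // 2 - 1] + xs[n // 2])
    counts: dict[float, int] = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    best_c = max(counts.values())
    mode = min(v for v, c in counts.items() if c == best_c)

    p = {q: percentile(x, q) for q in (5, 10, 20, 25, 75, 80, 90, 95)}
    mn, mx = xs[0], xs[-1]

    k = math.floor(0.1 * n)
    trimmed = sum(xs[k : n - k]) / (n - 2 * k) if n - 2 * k > 0 else mean
    wins = [min(max(v, p[10]), p[90]) for v in x]
    winsorized = sum(wins) / n

    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    mad = sum(abs(v - mean) for v in x) / n
    sub = [v for v in x if p[10] <= v <= p[90]]
    if sub:
        sub_mean = sum(sub) / len(sub)
        rmad = sum(abs(v - sub_mean) for v in sub) / len(sub)
    else:
        rmad = 0.0
    medad = percentile([abs(v - median) for v in x], 50)
    madm = sum(abs(v - median) for v in x) / n
    cv = sd / abs(mean) if mean != 0 else 0.0
    if sd > 0:
        skew = sum((v - mean) ** 3 for v in x) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in x) / n / sd**4 - 3.0
        npskew = (mean - median) / sd
    else:
        skew = kurt = npskew = 0.0
    iqr_span = p[75] - p[25]
    qskew = (p[75] + p[25] - 2 * median) / iqr_span if iqr_span > 0 else 0.0
    qdisp = iqr_span / (abs(p[75]) + abs(p[25])) if abs(p[75]) + abs(p[25]) > 0 else 0.0

    energy = sum(v * v for v in x)
    probs = [c / n for c in counts.values()]
    uniformity = sum(q * q for q in probs)
    entropy = -sum(q * math.log2(q) for q in probs)
    entropy = entropy if entropy != 0 else 0.0
    gmean = math.exp(sum(math.log(abs(v)) for v in x) / n) if all(v != 0 for v in x) else 0.0

    return {
        "mean": mean,
        "median": median,
        "mode": mode,
        "p5": p[5],
        "p10": p[10],
        "p20": p[20],
        "p25": p[25],
        "p75": p[75],
        "p80": p[80],
        "p90": p[90],
        "p95": p[95],
        "midrange": 0.5 * (mn + mx),
        "midhinge": 0.5 * (p[25] + p[75]),
        "trimean": 0.25 * (p[25] + 2 * median + p[75]),
        "trimmed_mean_10": trimmed,
        "winsorized_mean_10": winsorized,
        "min": mn,
        "max": mx,
        "range": mx - mn,
        "iqr": abs(p[75] - p[25]),
        "decile_range": p[90] - p[10],
        "quintile_range": p[80] - p[20],
        "quartile_dispersion": qdisp,
        "variance": var,
        "sd": sd,
        "std_error": sd / math.sqrt(n),
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
        "total_energy": energy * voxel_volume_mm3,
        "rms": math.sqrt(energy / n),
        "intensity_sum": sum(x),
        "abs_intensity_sum": sum(abs(v) for v in x),
        "mean_abs": sum(abs(v) for v in x) / n,
        "geometric_mean_abs": gmean,
        "uniformity": uniformity,
        "entropy": entropy,
    }


def nn_labels_oracle(mask_coords, center_coords_by_label):
    """Exhaustive nearest-centre assignment: all voxel-to-centre-voxel
    distances, ties toward the smaller label id."""
    out = []
    labels = sorted(center_coords_by_label)
    for vx in mask_coords:
        best_label, best_d2 = None, None
        for lab in labels:
            for cv in center_coords_by_label[lab]:
                d2 = sum((a - b) ** 2 for a, b in zip(vx, cv))
                if best_d2 is None or d2 < best_d2:
                    best_d2, best_label = d2, lab
        out.append(best_label)
    return out


def auc_oracle(scores, labels):
    """O(n^2) pairwise AUC with ties counting one half."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_oracle(scores, labels):
    """Exhaustive J scan over all distinct scores (positive iff >= t)."""
    n_pos = sum(1 for y in labels if y)
    n_neg = len(labels) - n_pos
    best_t, best_j = None, -math.inf
    for t in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if y and s >= t)
        tn = sum(1 for s, y in zip(scores, labels) if not y and s < t)
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return best_t


def local_maxima_count(field, mask):
    """Count 26-neighbourhood strict local maxima of a 3D field inside a
    mask by exhaustive comparison."""
    import itertools

    sx, sy, sz = field.shape
    count = 0
    for x in range(sx):
        for y in range(sy):
            for z in range(sz):
                if not mask[x, y, z]:
                    continue
                v = field[x, y, z]
                is_max = True
                for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
                    if dx == dy == dz == 0:
                        continue
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if 0 <= nx < sx and 0 <= ny < sy and 0 <= nz < sz:
                        if field[nx, ny, nz] >= v:
                            is_max = False
                            break
                if is_max:
                    count += 1
    return count
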