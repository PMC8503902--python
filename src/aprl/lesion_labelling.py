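"""Lesion instance labelling from a voxel-wise probability map.

Stage order: Dice-optimal binarization threshold -> binarize -> one-voxel
box dilation -> CSF/GM exclusion of the newly added ring -> texture-based
centre detection on the smoothed probability map -> nearest-neighbour
assignment of the remaining mask voxels to centres -> confluence flags via
connected components -> rim status by any overlap with the manual rim
annotation.

Connectivity is 26 throughout (switchable to 6); distances are Euclidean in
voxel units, which on an isometric grid equals mm distance up to a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import (
    BinaryMask,
    LesionLabelMap,
    ProbabilityMap,
    require_same_grid,
)

__all__ = [
    "LesionRecord",
    "dice",
    "binarize",
    "select_threshold",
    "dilate_one_voxel",
    "exclude_tissue",
    "detect_centers",
    "assign_labels_nn",
    "flag_confluent",
    "assign_prl_status",
    "label_lesions",
    "DEFAULT_THRESHOLDS",
]

#: default binarization threshold grid: 0.05 .. 0.95 step 0.05
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


@dataclass
class LesionRecord:
    """Summary of one labelled lesion instance."""

    lesion_id: int
    size_vox: int
    is_confluent: bool
    is_prl_truth: bool
    subject_id: str = "subj"


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Sorensen-Dice overlap 2|A∩B|/(|A|+|B|); 0 when both masks are empty."""
    require_same_grid(a, b)
    av, bv = a.as_bool(), b.as_bool()
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((av & bv).sum()) / denom


def binarize(prob: ProbabilityMap, t: float) -> BinaryMask:
    """Threshold the probability map at t (voxel kept iff prob >= t)."""
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold must lie in (0,1), got {t}")
    return BinaryMask(prob.grid, (prob.values >= t).astype(np.uint8))


def select_threshold(
    prob: ProbabilityMap, gold: BinaryMask, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> float:
    """Scan the full threshold grid and return the Dice-maximizing value.

    Ties break toward the smallest threshold for reproducibility.
    """
    require_same_grid(prob, gold)
    ts = list(thresholds)
    if not ts:
        raise ValueError("threshold grid is empty")
    if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
        raise ValueError("threshold grid must be strictly increasing")
    best_t, best_d = ts[0], -1.0
    for t in ts:
        d = dice(binarize(prob, t), gold)
        if d > best_d:
            best_t, best_d = t, d
    return float(best_t)


def dilate_one_voxel(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Dilate by one voxel in each direction (3x3x3 box for 26-connectivity)."""
    out = ndimage.binary_dilation(mask.as_bool(), structure=_structure(connectivity))
    return BinaryMask(mask.grid, out.astype(np.uint8))


def exclude_tissue(
    dilated: BinaryMask, original: BinaryMask, csf: BinaryMask, gm: BinaryMask
) -> BinaryMask:
    """Remove CSF/GM from the ring added by dilation.

    Only newly added voxels are subject to exclusion; original lesion
    voxels are never removed.
    """
    require_same_grid(dilated, original, csf, gm)
    d, o = dilated.as_bool(), original.as_bool()
    if np.any(o & ~d):
        raise ValueError("original mask is not a subset of the dilated mask")
    ring = d & ~o
    kept_ring = ring & ~csf.as_bool() & ~gm.as_bool()
    return BinaryMask(dilated.grid, (o | kept_ring).astype(np.uint8))


def _renumber_by_min_index(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels 1..K by lexicographic order of each
    component's minimum voxel index (C-order flat index)."""
    out = np.zeros_like(labels)
    ids = [int(i) for i in np.unique(labels) if i > 0]
    if not ids:
        return out
    flat = labels.ravel(order="C")
    firsts = []
    for i in ids:
        firsts.append((int(np.flatnonzero(flat == i)[0]), i))
    firsts.sort()
    for new_id, (_, old_id) in enumerate(firsts, start=1):
        out[labels == old_id] = new_id
    return out


def detect_centers(
    prob: ProbabilityMap,
    mask: BinaryMask,
    smooth_sigma_vox: float = 1.0,
    connectivity: int = 26,
) -> LesionLabelMap:
    """Detect distinct lesion centres from the texture of the probability map.

    The map is Gaussian-smoothed; voxels whose 3x3 Hessian (central
    differences) has three strictly negative eigenvalues — locally peaked in
    every direction — are marked, and the 26-connected components of marked
    voxels inside the mask become the centres, numbered 1..K by the
    lexicographic order of their minimum voxel index. If no voxel qualifies,
    the masked voxel with maximal smoothed probability is the single centre.
    """
    require_same_grid(prob, mask)
    m = mask.as_bool()
    if not m.any():
        raise ValueError("mask is empty")
    sm = ndimage.gaussian_filter(prob.values.astype(np.float64), smooth_sigma_vox)
    g = np.gradient(sm)
    midx = np.argwhere(m)
    hess = np.empty((len(midx), 3, 3))
    for i in range(3):
        gi = np.gradient(g[i])
        for j in range(3):
            hess[:, i, j] = gi[j][m]
    # symmetrize against floating asymmetry of mixed partials
    hess = 0.5 * (hess + np.swapaxes(hess, 1, 2))
    marked = np.zeros(sm.shape, dtype=bool)
    eig = np.linalg.eigvalsh(hess)
    neg = np.all(eig < 0.0, axis=1)
    marked[tuple(midx[neg].T)] = True

    lab, k = ndimage.label(marked, structure=_structure(connectivity))
    if k == 0:
        vals = np.where(m, sm, -np.inf)
        peak = np.unravel_index(int(np.argmax(vals)), sm.shape)
        lab = np.zeros(sm.shape, dtype=np.int32)
        lab[peak] = 1
    else:
        lab = _renumber_by_min_index(lab)
    return LesionLabelMap(prob.grid, lab)


def assign_labels_nn(mask: BinaryMask, centers: LesionLabelMap) -> LesionLabelMap:
    """Assign every masked voxel to the nearest centre component.

    Distance is Euclidean (voxel units) to the nearest *member voxel* of
    each centre component, not to its centroid; ties break toward the
    smaller label id. Output support equals the mask exactly.
    """
    require_same_grid(mask, centers)
    m = mask.as_bool()
    cvals = centers.values
    ids = centers.lesion_ids()
    if not ids:
        raise ValueError("no centers to assign from")
    allowed = m | dilate_one_voxel(mask).as_bool()
    if np.any((cvals > 0) & ~allowed):
        raise ValueError("center voxels lie outside the mask and its 1-voxel dilation")
    pts = np.argwhere(m).astype(np.float64)
    dists = np.empty((len(ids), len(pts)))
    for row, k in enumerate(ids):
        tree = cKDTree(np.argwhere(cvals == k).astype(np.float64))
        dists[row], _ = tree.query(pts, k=1)
    # argmin returns the first (smallest-id) row on exact ties
    winner = np.argmin(dists, axis=0)
    out = np.zeros(m.shape, dtype=np.int32)
    out[tuple(np.argwhere(m).T)] = np.asarray(ids)[winner]
    return LesionLabelMap(mask.grid, out)


def flag_confluent(labels: LesionLabelMap, connectivity: int = 26) -> dict[int, bool]:
    """Flag lesions whose connected component holds >= 2 distinct labels.

    Connected components of the nonzero support merge touching lesions into
    one cluster; every lesion inside a multi-label cluster is confluent.
    """
    lab = labels.values
    comp, k = ndimage.label(lab > 0, structure=_structure(connectivity))
    flags = {i: False for i in labels.lesion_ids()}
    for c in range(1, k + 1):
        members = np.unique(lab[comp == c])
        members = [int(i) for i in members if i > 0]
        if len(members) >= 2:
            for i in members:
                flags[i] = True
    return flags


def assign_prl_status(labels: LesionLabelMap, annotation: BinaryMask) -> dict[int, bool]:
    """Rim status per lesion: positive iff any overlap with the annotation."""
    require_same_grid(labels, annotation)
    ann = annotation.as_bool()
    overlapped = np.unique(labels.values[ann])
    overlapped = {int(i) for i in overlapped if i > 0}
    return {i: (i in overlapped) for i in labels.lesion_ids()}


def label_lesions(
    prob: ProbabilityMap,
    gold: BinaryMask,
    csf: BinaryMask,
    gm: BinaryMask,
    annotation: BinaryMask,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    smooth_sigma_vox: float = 1.0,
    subject_id: str = "subj",
    fixed_threshold: float | None = None,
    connectivity: int = 26,
) -> tuple[LesionLabelMap, list[LesionRecord]]:
    """Run the full labelling stage for one subject.

    The gold mask is used only to select the binarization threshold; pass
    ``fixed_threshold`` to bypass it for fully unsupervised runs. Returns
    the final label map plus one record per lesion (size, confluence flag,
    rim truth by annotation overlap), sorted by lesion id.
    """
    require_same_grid(prob, gold, csf, gm, annotation)
    if fixed_threshold is None:
        t = select_threshold(prob, gold, thresholds)
    else:
        t = float(fixed_threshold)
    seg = binarize(prob, t)
    dil = dilate_one_voxel(seg, connectivity)
    final_mask = exclude_tissue(dil, seg, csf, gm)
    centers = detect_centers(prob, final_mask, smooth_sigma_vox, connectivity)
    labels = assign_labels_nn(final_mask, centers)
    confluent = flag_confluent(labels, connectivity)
    prl = assign_prl_status(labels, annotation)
    counts = np.bincount(labels.values.ravel())
    records = [
        LesionRecord(
            lesion_id=i,
            size_vox=int(counts[i]),
            is_confluent=confluent[i],
            is_prl_truth=prl[i],
            subject_id=subject_id,
        )
        for i in labels.lesion_ids()
    ]
    records.sort(key=lambda r: r.lesion_id)
    return labels, records
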