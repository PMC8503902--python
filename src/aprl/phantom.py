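"""Synthetic T2*-phase phantom: seedable subjects with known lesion truth.

Each phantom subject emulates the inputs the pipeline consumes from a real
study: a zero-centred normalized phase volume with ellipsoidal white-matter
lesions, a gold-standard binary lesion mask, a smoothed "probability map"
standing in for an automated segmenter's output, CSF and gray-matter slabs
adjacent to a subset of lesions, and a manual rim annotation drawn as a
1-voxel line through each rim lesion's centre along its longest in-plane
axis on a single axial slice.

The rim model is purely additive: rim-positive lesions carry a hypointense
shell (negative mean offset) around an iso/hyperintense interior, matching
how paramagnetic rims present on phase contrast. No attempt is made to
simulate veins, phase wrapping, or susceptibility physics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import (
    BinaryMask,
    Grid,
    PhaseVolume,
    ProbabilityMap,
    write_volume,
)

__all__ = [
    "PhantomSpec",
    "TruthLesion",
    "PhantomCase",
    "PlacementError",
    "generate_case",
    "generate_cohort",
    "write_case",
]


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    Defaults mirror the study conditions the pipeline is meant for: ~50
    supratentorial lesions per subject of which ~12% carry a paramagnetic
    rim, on a 0.65 mm isometric grid, with rim contrast set to two
    background standard deviations below normal-appearing tissue. Rim
    lesions are drawn systematically larger (``rim_radius_scale``) because
    rim-positive lesions tend to be larger than rim-negative ones.
    """

    grid: Grid = Grid((96, 96, 96), 0.65)
    n_lesions: int = 50
    rim_fraction: float = 0.12
    lesion_radius_range_vox: tuple[float, float] = (2.0, 4.0)
    rim_thickness_vox: float = 1.5
    rim_contrast: float = -2.0  # additive shell offset, normalized units
    background_sd: float = 1.0
    confluence_rate: float = 0.1
    prob_blur_sigma_vox: float = 1.0
    rim_radius_scale: float = 1.25
    interior_offset_max: float = 0.5  # lesion interiors iso- to hyper-intense
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rim_fraction <= 1.0):
            raise ValueError("rim_fraction must lie in [0,1]")
        if not (0.0 <= self.confluence_rate <= 1.0):
            raise ValueError("confluence_rate must lie in [0,1]")
        lo, hi = self.lesion_radius_range_vox
        if not (0 < lo <= hi):
            raise ValueError("lesion radius range must satisfy 0 < min <= max")
        if not self.rim_contrast < 0:
            raise ValueError("rim_contrast must be negative (hypointense shell)")
        if self.background_sd <= 0 or self.prob_blur_sigma_vox <= 0:
            raise ValueError("background_sd and prob_blur_sigma_vox must be positive")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        max_r = hi * max(self.rim_radius_scale, 1.0)
        if min(self.grid.shape) < 4 * max_r:
            raise ValueError(
                f"grid {self.grid.shape} too small for max lesion radius {max_r:.1f} "
                "(need >= 4x max radius per axis)"
            )


@dataclass
class TruthLesion:
    """Ground truth for one generated lesion."""

    index: int
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    axes: np.ndarray = field(repr=False)  # rows are principal directions
    is_rim: bool = False
    is_confluent_pair: bool = False
    partner: int | None = None


@dataclass
class PhantomCase:
    """One synthetic subject: all pipeline inputs plus the generating truth."""

    subject_id: str
    spec: PhantomSpec
    phase: PhaseVolume
    gold_mask: BinaryMask
    prob_map: ProbabilityMap
    csf_mask: BinaryMask
    gm_mask: BinaryMask
    prl_annotation: BinaryMask
    truth: list[TruthLesion]
    # per-lesion boolean support arrays, kept for tests and direct checks
    lesion_supports: list[np.ndarray] = field(default_factory=list, repr=False)
    lesion_shells: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_rim(self) -> int:
        return sum(t.is_rim for t in self.truth)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _ellipsoid_rho(grid_shape, center, radii, axes) -> tuple[np.ndarray, tuple]:
    """Normalized ellipsoid radius field over the lesion's bounding box.

    Returns (rho array over the box, box slices). rho <= 1 is the support.
    """
    rmax = float(np.max(radii))
    lo = [max(0, int(np.floor(c - rmax - 1))) for c in center]
    hi = [min(s, int(np.ceil(c + rmax + 2))) for c, s in zip(center, grid_shape)]
    slices = tuple(slice(a, b) for a, b in zip(lo, hi))
    coords = np.stack(
        np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"),
        axis=-1,
    ).astype(float)
    rel = coords - np.asarray(center)
    # project onto principal directions, scale by radii
    proj = rel @ axes.T
    rho = np.sqrt(np.sum((proj / np.asarray(radii)) ** 2, axis=-1))
    return rho, slices


def _direction_radius(radii, axes, u) -> float:
    """Radius of the ellipsoid along unit direction u (support function of
    the quadric): r(u) = 1/sqrt(u' A u), A = R' diag(1/r^2) R."""
    a = axes @ u
    return 1.0 / np.sqrt(float(np.sum((a / np.asarray(radii)) ** 2)))


def generate_case(spec: PhantomSpec, subject_id: str = "sub-001") -> PhantomCase:
    """Generate one phantom subject, fully deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid.shape
    n = spec.n_lesions
    lo_r, hi_r = spec.lesion_radius_range_vox

    is_rim = rng.random(n) < spec.rim_fraction
    # confluent pairs: a fraction of lesions touches a designated partner
    n_paired = int(round(spec.confluence_rate * n))
    n_pairs = n_paired // 2
    pair_members: dict[int, int] = {}
    order = rng.permutation(n)
    for p in range(n_pairs):
        a, b = int(order[2 * p]), int(order[2 * p + 1])
        pair_members[a] = b
        pair_members[b] = a
        if is_rim[a] and is_rim[b]:  # at most one rim lesion per pair
            is_rim[b] = False

    max_r = hi_r * max(spec.rim_radius_scale, 1.0)
    margin = max_r + 2.0
    truth: list[TruthLesion] = []
    placed_centers: list[np.ndarray] = []
    placed_maxr: list[float] = []

    def radius_draw(rim: bool) -> np.ndarray:
        r = rng.uniform(lo_r, hi_r, size=3)
        if rim:
            r = r * spec.rim_radius_scale
        return r

    for i in range(n):
        partner = pair_members.get(i)
        if partner is not None and partner < i:
            # second member of a pair: place touching its partner
            t0 = truth[partner]
            radii = radius_draw(bool(is_rim[i]))
            axes = _random_rotation(rng)
            # prefer touching along the pair's long axes: the centre-detection
            # stage can only resolve the two instances when their peaks are
            # several voxels apart
            cand = rng.normal(size=(64, 3))
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            sums = np.array(
                [
                    _direction_radius(t0.radii, t0.axes, u)
                    + _direction_radius(radii, axes, u)
                    for u in cand
                ]
            )
            placed = False
            for ci in np.argsort(-sums):
                u = cand[ci]
                d = sums[ci] - 2.0
                center = np.asarray(t0.center) + d * u
                if np.any(center < margin) or np.any(center > np.asarray(shape) - margin):
                    continue
                ok = True
                for j, (c, r) in enumerate(zip(placed_centers, placed_maxr)):
                    if j == partner:
                        continue
                    if np.linalg.norm(center - c) < r + float(np.max(radii)) + 4.0:
                        ok = False
                        break
                if ok:
                    placed = True
                    break
            if not placed:
                raise PlacementError(f"could not place confluent partner lesion {i}")
        else:
            radii = radius_draw(bool(is_rim[i]))
            axes = _random_rotation(rng)
            placed = False
            for _ in range(500):
                center = rng.uniform(margin, np.asarray(shape) - margin)
                ok = True
                for c, r in zip(placed_centers, placed_maxr):
                    if np.linalg.norm(center - c) < r + float(np.max(radii)) + 4.0:
                        ok = False
                        break
                if ok:
                    placed = True
                    break
            if not placed:
                raise PlacementError(f"could not place lesion {i} after 500 tries")
        placed_centers.append(np.asarray(center))
        placed_maxr.append(float(np.max(radii)))
        truth.append(
            TruthLesion(
                index=i,
                center=tuple(float(c) for c in center),
                radii=tuple(float(r) for r in radii),
                axes=axes,
                is_rim=bool(is_rim[i]),
                is_confluent_pair=partner is not None,
                partner=partner,
            )
        )

    # --- rasterize ---------------------------------------------------------
    phase = rng.normal(0.0, spec.background_sd, size=shape)
    gold = np.zeros(shape, dtype=bool)
    supports: list[np.ndarray] = []
    shells: list[np.ndarray] = []

    for t in truth:
        rho, box = _ellipsoid_rho(shape, t.center, t.radii, t.axes)
        support_box = rho <= 1.0
        shell_frac = spec.rim_thickness_vox / float(np.mean(t.radii))
        shell_box = support_box & (rho > max(0.0, 1.0 - shell_frac))
        interior_box = support_box & ~shell_box
        offset = rng.uniform(0.0, spec.interior_offset_max)
        sub = phase[box]
        if t.is_rim:
            sub[interior_box] += offset
            sub[shell_box] += spec.rim_contrast
        else:
            sub[support_box] += offset
        phase[box] = sub
        gold[box] |= support_box
        full_support = np.zeros(shape, dtype=bool)
        full_support[box] = support_box
        supports.append(full_support)
        full_shell = np.zeros(shape, dtype=bool)
        full_shell[box] = shell_box
        shells.append(full_shell)

    # --- probability map: smoothed truth -----------------------------------
    prob = ndimage.gaussian_filter(gold.astype(np.float64), spec.prob_blur_sigma_vox)
    prob = np.clip(prob, 0.0, 1.0)

    # --- rim annotation: axial line through centre, longest in-plane axis --
    annot = np.zeros(shape, dtype=bool)
    for t, supp in zip(truth, supports):
        if not t.is_rim:
            continue
        z0 = int(round(t.center[2]))
        z0 = min(max(z0, 0), shape[2] - 1)
        # longest in-plane (axial, i.e. constant-z) extent among principal axes
        best_len, best_dir = -1.0, None
        for k in range(3):
            v = t.axes[k] * t.radii[k]
            inplane = np.array([v[0], v[1]])
            ln = float(np.linalg.norm(inplane))
            if ln > best_len:
                best_len, best_dir = ln, inplane
        if best_len < 0.5 or best_dir is None:
            annot[int(round(t.center[0])), int(round(t.center[1])), z0] = True
            continue
        d = best_dir / np.linalg.norm(best_dir)
        for s in np.arange(-best_len, best_len + 0.25, 0.5):
            x = int(round(t.center[0] + s * d[0]))
            y = int(round(t.center[1] + s * d[1]))
            if 0 <= x < shape[0] and 0 <= y < shape[1] and supp[x, y, z0]:
                annot[x, y, z0] = True
        if not annot[:, :, z0].any():
            xi = int(round(t.center[0]))
            yi = int(round(t.center[1]))
            if supp[xi, yi, z0]:
                annot[xi, yi, z0] = True

    # --- CSF / GM slabs adjacent to a subset of lesions ---------------------
    csf = np.zeros(shape, dtype=bool)
    gm = np.zeros(shape, dtype=bool)
    for k, (t, supp) in enumerate(zip(truth, supports)):
        if k % 3 != 0:
            continue
        idx = np.argwhere(supp)
        if idx.size == 0:
            continue
        x_hi = int(idx[:, 0].max())
        y_lo, y_hi = int(idx[:, 1].min()), int(idx[:, 1].max())
        z_lo, z_hi = int(idx[:, 2].min()), int(idx[:, 2].max())
        slab = (
            slice(x_hi + 1, min(x_hi + 3, shape[0])),
            slice(y_lo, y_hi + 1),
            slice(z_lo, z_hi + 1),
        )
        target = csf if (k // 3) % 2 == 0 else gm
        target[slab] = True
    csf &= ~gold
    gm &= ~gold & ~csf

    grid = spec.grid
    return PhantomCase(
        subject_id=subject_id,
        spec=spec,
        phase=PhaseVolume(grid, phase.astype(np.float32)),
        gold_mask=BinaryMask(grid, gold.astype(np.uint8)),
        prob_map=ProbabilityMap(grid, prob.astype(np.float32)),
        csf_mask=BinaryMask(grid, csf.astype(np.uint8)),
        gm_mask=BinaryMask(grid, gm.astype(np.uint8)),
        prl_annotation=BinaryMask(grid, annot.astype(np.uint8)),
        truth=truth,
        lesion_supports=supports,
        lesion_shells=shells,
    )


def generate_cohort(
    n_subjects: int, spec: PhantomSpec, seed: int | None = None
) -> list[PhantomCase]:
    """Generate a cohort of independent subjects.

    Per-subject lesion counts are drawn uniformly within +/-30% of
    ``spec.n_lesions``; each subject gets a derived seed so the cohort is
    reproducible as a whole and any single subject in isolation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(spec.seed if seed is None else seed)
    lo = max(1, int(round(0.7 * spec.n_lesions)))
    hi = int(round(1.3 * spec.n_lesions))
    cases = []
    for i in range(n_subjects):
        n_i = int(master.integers(lo, hi + 1))
        sub_seed = int(master.integers(0, 2**31 - 1))
        sub_spec = replace(spec, n_lesions=n_i, seed=sub_seed)
        cases.append(generate_case(sub_spec, subject_id=f"sub-{i + 1:03d}"))
    return cases


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Write one subject's six NIfTI volumes plus truth.csv."""
    out = Path(out_dir) / case.subject_id
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.phase, out / "phase.nii.gz")
    write_volume(case.gold_mask, out / "gold_mask.nii.gz")
    write_volume(case.prob_map, out / "prob_map.nii.gz")
    write_volume(case.csf_mask, out / "csf_mask.nii.gz")
    write_volume(case.gm_mask, out / "gm_mask.nii.gz")
    write_volume(case.prl_annotation, out / "prl_annotation.nii.gz")
    with open(out / "truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["index", "cx", "cy", "cz", "rx", "ry", "rz", "is_rim", "is_confluent_pair"]
        )
        for t in case.truth:
            w.writerow(
                [t.index, *[f"{c:.3f}" for c in t.center], *[f"{r:.3f}" for r in t.radii],
                 int(t.is_rim), int(t.is_confluent_pair)]
            )
    return out
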