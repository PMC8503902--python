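"""NIfTI I/O and the gridded volume types the pipeline passes between stages.

All geometry is done in 0-based voxel coordinates. Volumes are single 3D
NIfTI-1 images on an isometric grid; masks are stored as uint8, label maps
as uint16 and intensity volumes as float32.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "Volume",
    "PhaseVolume",
    "ProbabilityMap",
    "BinaryMask",
    "LesionLabelMap",
    "check_same_grid",
    "require_same_grid",
    "read_volume",
    "write_volume",
]

#: tolerance (mm) below which two voxel sizes count as equal
VOXEL_SIZE_TOL_MM = 1e-6
#: relative anisotropy above which a warning is emitted on read
ANISOTROPY_WARN_TOL = 0.01


@dataclass(frozen=True)
class Grid:
    """An isometric voxel grid: array shape plus one voxel edge length in mm."""

    shape: tuple[int, int, int]
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_mm}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3


def check_same_grid(a, b, tol_mm: float = VOXEL_SIZE_TOL_MM) -> bool:
    """True iff the two gridded objects share shape and voxel size (within tol)."""
    ga = a.grid if hasattr(a, "grid") else a
    gb = b.grid if hasattr(b, "grid") else b
    return ga.shape == gb.shape and abs(ga.voxel_size_mm - gb.voxel_size_mm) <= tol_mm


def require_same_grid(*objs) -> None:
    first = objs[0]
    for other in objs[1:]:
        if not check_same_grid(first, other):
            raise ValueError(
                f"grid mismatch: {first.grid} vs {other.grid}"
            )


@dataclass
class Volume:
    """A scalar field on a :class:`Grid`."""

    grid: Grid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        self._validate()

    def _validate(self) -> None:  # overridden by subtypes
        pass


class PhaseVolume(Volume):
    """Normalized T2*-phase intensities (unitless; zero-centred after
    intensity normalization upstream)."""

    def _validate(self) -> None:
        self.values = self.values.astype(np.float32, copy=False)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase volume contains non-finite values")


class ProbabilityMap(Volume):
    """Voxel-wise lesion probabilities in [0, 1]."""

    def _validate(self) -> None:
        self.values = self.values.astype(np.float32, copy=False)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("probability map contains non-finite values")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"values outside [0,1]: range [{lo}, {hi}]")


class BinaryMask(Volume):
    """A {0,1} mask."""

    def _validate(self) -> None:
        vals = self.values
        if vals.dtype == bool:
            vals = vals.astype(np.uint8)
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be exactly 0 or 1, found {uniq[:10]}")
        self.values = vals.astype(np.uint8, copy=False)

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


class LesionLabelMap(Volume):
    """Integer lesion-instance labels: 0 background, 1..K distinct lesions."""

    def _validate(self) -> None:
        vals = np.asarray(self.values)
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("label map values must be integers")
            vals = np.round(vals).astype(np.int64)
        if vals.min() < 0:
            raise ValueError("label map values must be non-negative")
        self.values = vals.astype(np.uint16, copy=False)

    @property
    def n_lesions(self) -> int:
        return int(self.values.max())

    def lesion_ids(self) -> list[int]:
        ids = np.unique(self.values)
        return [int(i) for i in ids if i > 0]


_KIND_TO_TYPE = {
    "phase": PhaseVolume,
    "prob": ProbabilityMap,
    "mask": BinaryMask,
    "labels": LesionLabelMap,
    "volume": Volume,
}

_TYPE_TO_DTYPE = {
    PhaseVolume: np.float32,
    ProbabilityMap: np.float32,
    BinaryMask: np.uint8,
    LesionLabelMap: np.uint16,
    Volume: np.float32,
}


def _grid_from_header(img) -> Grid:
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        shape = shape[:3]
    if len(shape) != 3:
        raise ValueError(f"expected a 3D single volume, got shape {img.shape}")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    mean = float(zooms.mean())
    if mean <= 0:
        raise ValueError(f"non-positive voxel sizes in header: {zooms}")
    if np.max(np.abs(zooms - mean)) / mean > ANISOTROPY_WARN_TOL:
        warnings.warn(
            f"anisotropic voxels {tuple(zooms)}; proceeding with mean edge {mean:.4g} mm",
            stacklevel=3,
        )
    return Grid(tuple(int(s) for s in shape), mean)


def read_volume(path: str | Path, kind: str = "volume") -> Volume:
    """Read one 3D NIfTI volume as the requested type.

    Parameters
    ----------
    path
        A ``.nii`` or ``.nii.gz`` file.
    kind
        One of ``phase``, ``prob``, ``mask``, ``labels`` or ``volume``
        (no invariant checking beyond shape).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind not in _KIND_TO_TYPE:
        raise ValueError(f"unknown volume kind {kind!r}")
    img = nib.load(str(path))
    grid = _grid_from_header(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        data = data[..., 0]
    return _KIND_TO_TYPE[kind](grid, data)


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal affine from its voxel size."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = _TYPE_TO_DTYPE.get(type(vol), np.float32)
    data = np.asarray(vol.values, dtype=dtype)
    affine = np.diag([vol.grid.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((vol.grid.voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return path
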