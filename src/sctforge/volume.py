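"""Scalar 3D volumes on axis-aligned grids, with NIfTI and SimpleITK bridges.

Conventions used throughout the package:

* arrays are indexed ``[ix, iy, iz]`` (x fastest-varying axis first);
* voxel indices are 0-based and world position = ``origin + index * spacing``
  (axis-aligned grids only — no direction matrix);
* CT-like volumes carry Hounsfield units (air = -1000, water = 0), MR volumes
  carry arbitrary scanner units, DOSE volumes carry Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

MODALITIES = ("CT", "MR", "CBCT", "DOSE")


@dataclass(frozen=True)
class Grid3D:
    """Geometry of an axis-aligned voxel grid."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple(
            o + (n - 1) * s / 2.0
            for o, n, s in zip(self.origin_mm, self.shape, self.spacing_mm)
        )

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinate arrays broadcastable over the grid."""
        axes = [
            (self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a])
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for an array of world points (..., 3)."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def approx_equal(self, other: "Grid3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )


@dataclass
class Volume3D:
    """A scalar field on a :class:`Grid3D` with intensity semantics."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if self.modality == "DOSE" and np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def grid(self) -> Grid3D:
        return Grid3D(self.values.shape, self.spacing_mm, self.origin_mm)

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "Volume3D":
        return Volume3D(
            values,
            self.spacing_mm,
            self.origin_mm,
            modality or self.modality,
            dict(self.meta),
        )

    # ---- NIfTI -----------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float64), affine)
        img.header.set_xyzt_units("mm")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, modality: str = "CT") -> "Volume3D":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        data = np.asarray(img.get_fdata(), dtype=float)
        return cls(data, spacing, origin, modality)

    # ---- SimpleITK -------------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        # SimpleITK array layout is (z, y, x)
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T.astype(np.float64)))
        img.SetSpacing(self.spacing_mm)
        img.SetOrigin(self.origin_mm)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, modality: str = "CT") -> "Volume3D":
        arr = sitk.GetArrayFromImage(img).T
        return cls(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()), modality)


def require_same_grid(a: Volume3D | Grid3D, b: Volume3D | Grid3D, what: str = "volumes") -> None:
    ga = a.grid if isinstance(a, Volume3D) else a
    gb = b.grid if isinstance(b, Volume3D) else b
    if not ga.approx_equal(gb):
        raise ValueError(f"{what} must share one grid: {ga} vs {gb}")
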