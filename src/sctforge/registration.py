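"""Deformable and rigid registration, displacement fields, and resampling.

The displacement-vector-field (DVF) convention is *pull/backward*: a DVF is
defined on the fixed grid and, for each fixed-grid voxel at world position
``p``, the warped output samples the moving volume at ``p + d(p)`` (mm).
Warping a moving volume with the DVF therefore lands it on the fixed grid.

Rigid transforms are parameterized by three translations (mm) and three
rotations (degrees) applied fixed-axis X, then Y, then Z, about a stated
center point — the convention daily-setup corrections are reported in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import Grid3D, Volume3D

RIGID_CONVENTION = "fixed-axis XYZ (R = Rz @ Ry @ Rx), degrees, about center_mm"


# ---------------------------------------------------------------------------
# Displacement vector fields
# ---------------------------------------------------------------------------

@dataclass
class DVF:
    """Per-voxel 3-vector displacements (mm) on a fixed-image grid."""

    vectors: np.ndarray  # (nx, ny, nz, 3), mm
    fixed_grid: Grid3D
    moving_grid: Grid3D

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"DVF vectors must have shape (nx,ny,nz,3), got {self.vectors.shape}")
        if tuple(self.vectors.shape[:3]) != tuple(self.fixed_grid.shape):
            raise ValueError("DVF array shape does not match fixed_grid")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("DVF components must be finite")

    @property
    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.vectors ** 2).sum(axis=-1)).max())

    @classmethod
    def zero(cls, fixed_grid: Grid3D, moving_grid: Grid3D | None = None) -> "DVF":
        return cls(
            np.zeros(tuple(fixed_grid.shape) + (3,)),
            fixed_grid,
            moving_grid or fixed_grid,
        )

    def save(self, path: str | Path) -> None:
        """Write as a 4D (x,y,z,3) NIfTI in mm plus a JSON grid sidecar."""
        path = Path(path)
        affine = np.diag(list(self.fixed_grid.spacing_mm) + [1.0])
        affine[:3, 3] = self.fixed_grid.origin_mm
        nib.save(nib.Nifti1Image(self.vectors.astype(np.float32), affine), str(path))
        sidecar = {
            "fixed_grid": _grid_to_dict(self.fixed_grid),
            "moving_grid": _grid_to_dict(self.moving_grid),
            "units": "mm",
            "convention": "pull: output(p) = moving(p + d(p))",
        }
        path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DVF":
        path = Path(path)
        img = nib.load(str(path))
        vectors = np.asarray(img.get_fdata(), dtype=float)
        sidecar_path = path.with_suffix("").with_suffix(".json")
        if sidecar_path.exists():
            sc = json.loads(sidecar_path.read_text())
            fixed = _grid_from_dict(sc["fixed_grid"])
            moving = _grid_from_dict(sc["moving_grid"])
        else:
            affine = img.affine
            fixed = Grid3D(
                vectors.shape[:3],
                tuple(abs(affine[i, i]) for i in range(3)),
                tuple(affine[i, 3] for i in range(3)),
            )
            moving = fixed
        return cls(vectors, fixed, moving)


def _grid_to_dict(g: Grid3D) -> dict:
    return {"shape": list(g.shape), "spacing_mm": list(g.spacing_mm), "origin_mm": list(g.origin_mm)}


def _grid_from_dict(d: dict) -> Grid3D:
    return Grid3D(tuple(d["shape"]), tuple(d["spacing_mm"]), tuple(d["origin_mm"]))


def apply_dvf(
    volume: Volume3D,
    dvf: DVF,
    interpolation: str = "linear",
    fill_value: float | None = None,
    return_valid_mask: bool = False,
):
    """Warp ``volume`` onto the DVF's fixed grid: ``out(p) = volume(p + d(p))``.

    Out-of-domain samples receive ``fill_value`` (-1000 for CT/CBCT, 0
    otherwise). With ``return_valid_mask=True`` a boolean in-domain mask is
    returned alongside, so downstream consumers can exclude extrapolated
    voxels.
    """
    if not dvf.moving_grid.approx_equal(volume.grid):
        raise ValueError("dvf.moving_grid does not match the volume grid")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if fill_value is None:
        fill_value = -1000.0 if volume.modality in ("CT", "CBCT") else 0.0

    wx, wy, wz = dvf.fixed_grid.world_coordinates()
    sample_world = np.stack(
        [wx + dvf.vectors[..., 0], wy + dvf.vectors[..., 1], wz + dvf.vectors[..., 2]],
        axis=-1,
    )
    idx = volume.grid.world_to_index(sample_world)
    coords = [idx[..., a] for a in range(3)]
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float),
        coords,
        order=order,
        mode="constant",
        cval=fill_value,
    )
    result = Volume3D(
        out,
        dvf.fixed_grid.spacing_mm,
        dvf.fixed_grid.origin_mm,
        volume.modality,
        dict(volume.meta),
    )
    if not return_valid_mask:
        return result
    shape = np.asarray(volume.values.shape, dtype=float)
    valid = np.ones(idx.shape[:3], dtype=bool)
    for a in range(3):
        valid &= (idx[..., a] >= -0.5) & (idx[..., a] <= shape[a] - 0.5)
    return result, valid


def apply_dvf_mask(mask: np.ndarray, dvf: DVF) -> np.ndarray:
    """Warp a binary mask with nearest-neighbor sampling; output is binary."""
    vol = Volume3D(np.asarray(mask, dtype=float), dvf.moving_grid.spacing_mm,
                   dvf.moving_grid.origin_mm, "MR")
    warped = apply_dvf(vol, dvf, interpolation="nearest", fill_value=0.0)
    return warped.values > 0.5


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """6-DOF rigid transform: translation (mm) + fixed-axis XYZ rotation (deg)."""

    translation_mm: tuple[float, float, float]
    rotation_deg: tuple[float, float, float]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    convention: str = RIGID_CONVENTION

    def __post_init__(self):
        self.translation_mm = tuple(float(t) for t in self.translation_mm)
        self.rotation_deg = tuple(float(r) for r in self.rotation_deg)
        self.center_mm = tuple(float(c) for c in self.center_mm)
        if any(not (-180.0 < r <= 180.0) for r in self.rotation_deg):
            raise ValueError(f"rotation angles must lie in (-180, 180], got {self.rotation_deg}")

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix_xyz(self.rotation_deg)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map world points (..., 3): R @ (p - c) + c + t."""
        pts = np.asarray(pts, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts - c) @ self.matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        r_inv = self.matrix.T
        t_inv = -r_inv @ np.asarray(self.translation_mm)
        return RigidTransform(tuple(t_inv), angles_from_matrix(r_inv), self.center_mm)

    def to_json(self) -> dict:
        return {
            "translation_mm": list(self.translation_mm),
            "rotation_deg": list(self.rotation_deg),
            "center_mm": list(self.center_mm),
            "convention": self.convention,
        }

    @classmethod
    def from_json(cls, d: dict) -> "RigidTransform":
        return cls(
            tuple(d["translation_mm"]),
            tuple(d["rotation_deg"]),
            tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
            d.get("convention", RIGID_CONVENTION),
        )


def rotation_matrix_xyz(rotation_deg) -> np.ndarray:
    """R = Rz @ Ry @ Rx: rotations applied about fixed axes x, then y, then z."""
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rmx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rmy = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rmz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rmz @ rmy @ rmx


def angles_from_matrix(r: np.ndarray) -> tuple[float, float, float]:
    """Invert :func:`rotation_matrix_xyz` (non-degenerate |ry| < 90 deg branch)."""
    ry = -np.arcsin(np.clip(r[2, 0], -1.0, 1.0))
    rx = np.arctan2(r[2, 1], r[2, 2])
    rz = np.arctan2(r[1, 0], r[0, 0])
    return tuple(np.rad2deg([rx, ry, rz]))


def resample_rigid(
    volume: Volume3D,
    transform: RigidTransform,
    interpolation: str = "linear",
    fill_value: float | None = None,
) -> Volume3D:
    """Resample on the same grid: ``out(p) = volume(T(p))`` (pull convention)."""
    if fill_value is None:
        fill_value = -1000.0 if volume.modality in ("CT", "CBCT") else 0.0
    wx, wy, wz = volume.grid.world_coordinates()
    pts = np.stack([wx, wy, wz], axis=-1)
    sample = transform.apply_points(pts)
    idx = volume.grid.world_to_index(sample)
    out = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float),
        [idx[..., a] for a in range(3)],
        order=1 if interpolation == "linear" else 0,
        mode="constant",
        cval=fill_value,
    )
    return volume.with_values(out)


# ---------------------------------------------------------------------------
# Deformable registration
# ---------------------------------------------------------------------------

@dataclass
class DeformableParams:
    """Knobs for the deformable backend.

    method: ``"demons"`` (intra-modality, mean-squares forces; the default for
    MR-to-MR atlas matching), ``"bspline_mi"`` (Mattes mutual information
    B-spline FFD for cross-modality MR-to-CT pairing), or ``"precomputed"``
    (load a DVF from ``precomputed_path`` untouched).
    """

    method: str = "demons"
    iterations_per_level: tuple[int, ...] = (40, 30, 20)
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigma_mm: float = 4.0
    bspline_grid_spacing_mm: float = 40.0
    bspline_iterations: int = 40
    precomputed_path: str | None = None


def register_deformable(
    fixed: Volume3D,
    moving: Volume3D,
    params: DeformableParams | None = None,
) -> DVF:
    """Estimate the DVF aligning ``moving`` onto ``fixed``'s grid.

    Returns the field on the fixed grid in the pull convention, so
    :func:`apply_dvf` of the moving volume reproduces the fixed anatomy. A
    non-improving optimization emits a warning and returns the best field
    found (never raises).
    """
    params = params or DeformableParams()
    if params.method == "precomputed":
        if not params.precomputed_path:
            raise ValueError("precomputed method requires precomputed_path")
        return DVF.load(params.precomputed_path)

    fixed_img = fixed.to_sitk()
    moving_img = moving.to_sitk()

    if params.method == "demons":
        field_img = _multiscale_demons(fixed_img, moving_img, params)
    elif params.method == "bspline_mi":
        field_img = _bspline_mi(fixed_img, moving_img, params)
    else:
        raise ValueError(f"unknown deformable method {params.method!r}")

    vectors = sitk.GetArrayFromImage(field_img)  # (z, y, x, 3) in physical mm
    vectors = np.transpose(vectors, (2, 1, 0, 3))
    dvf = DVF(vectors, fixed.grid, moving.grid)

    # Contract check: similarity of (fixed, moving o DVF) must not degrade.
    warped = apply_dvf(moving, dvf, interpolation="linear")
    before = float(np.mean((fixed.values - _resample_like(moving, fixed)) ** 2))
    after = float(np.mean((fixed.values - warped.values) ** 2))
    if after > before:
        warnings.warn(
            f"deformable registration did not improve similarity "
            f"(MSE {before:.1f} -> {after:.1f}); returning best-found field",
            stacklevel=2,
        )
    return dvf


def _resample_like(moving: Volume3D, fixed: Volume3D) -> np.ndarray:
    if moving.grid.approx_equal(fixed.grid):
        return np.asarray(moving.values, dtype=float)
    return apply_dvf(moving, DVF.zero(fixed.grid, moving.grid)).values


def _multiscale_demons(fixed_img, moving_img, params: DeformableParams):
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(params.smoothing_sigma_mm / fixed_img.GetSpacing()[0])
    field = None
    levels = list(zip(params.shrink_factors, params.iterations_per_level))
    for shrink, iters in levels:
        f = sitk.Shrink(fixed_img, [shrink] * 3) if shrink > 1 else fixed_img
        m = sitk.Shrink(moving_img, [shrink] * 3) if shrink > 1 else moving_img
        if field is None:
            field = sitk.Image(f.GetSize(), sitk.sitkVectorFloat64)
            field.CopyInformation(f)
        else:
            field = sitk.Resample(field, f, sitk.Transform(), sitk.sitkLinear)
            field = sitk.Cast(field, sitk.sitkVectorFloat64)
        demons.SetNumberOfIterations(iters)
        field = demons.Execute(f, m, field)
    if field.GetSize() != fixed_img.GetSize():
        field = sitk.Resample(field, fixed_img, sitk.Transform(), sitk.sitkLinear)
        field = sitk.Cast(field, sitk.sitkVectorFloat64)
    return field


def _bspline_mi(fixed_img, moving_img, params: DeformableParams):
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(0.3, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    physical_size = [
        sz * sp for sz, sp in zip(fixed_img.GetSize(), fixed_img.GetSpacing())
    ]
    mesh = [max(1, int(round(ps / params.bspline_grid_spacing_mm))) for ps in physical_size]
    tx = sitk.BSplineTransformInitializer(fixed_img, mesh)
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetOptimizerAsLBFGSB(numberOfIterations=params.bspline_iterations)
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1, 0])
    final = reg.Execute(fixed_img, moving_img)
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetReferenceImage(fixed_img)
    filt.SetOutputPixelType(sitk.sitkVectorFloat64)
    return filt.Execute(final)


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

@dataclass
class RigidParams:
    iterations: int = 150
    learning_rate: float = 1.0
    restarts_translation_mm: tuple = ((0.0, 0.0, 0.0), (4.0, 4.0, 0.0), (-4.0, -4.0, 0.0))


def register_rigid(
    reference: Volume3D,
    daily: Volume3D,
    clipbox_mask: np.ndarray,
    params: RigidParams | None = None,
) -> RigidTransform:
    """6-DOF bone match of a daily (CBCT) image to a reference CT.

    The similarity (negative correlation) is evaluated inside ``clipbox_mask``
    (pelvic-bone region on the reference grid). The returned transform is the
    setup error in the pull convention of :func:`resample_rigid`: resampling
    the reference under it reproduces the daily image, so a daily image
    simulated with offset ``T`` is recovered as ``T`` itself. Optimization
    restarts from a fixed set of initial translations; the best final metric
    wins, making the result deterministic.
    """
    clipbox_mask = np.asarray(clipbox_mask, dtype=bool)
    if clipbox_mask.shape != reference.values.shape:
        raise ValueError("clipbox mask must be on the reference grid")
    if not clipbox_mask.any():
        raise ValueError("clipbox mask is empty")
    params = params or RigidParams()

    fixed_img = reference.to_sitk()
    moving_img = daily.to_sitk()
    mask_img = Volume3D(clipbox_mask.astype(float), reference.spacing_mm,
                        reference.origin_mm, "MR").to_sitk()
    mask_img = sitk.Cast(mask_img, sitk.sitkUInt8)
    center = reference.grid.center_mm

    best = None
    for t0 in params.restarts_translation_mm:
        tx = sitk.Euler3DTransform()
        tx.SetCenter(center)
        tx.SetTranslation(tuple(float(v) for v in t0))
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsCorrelation()
        reg.SetMetricFixedMask(mask_img)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetInitialTransform(tx, inPlace=True)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=params.learning_rate,
            minStep=1e-4,
            numberOfIterations=params.iterations,
            relaxationFactor=0.6,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([2, 1])
        reg.SetSmoothingSigmasPerLevel([1, 0])
        try:
            final = reg.Execute(fixed_img, moving_img)
            metric = reg.GetMetricValue()
        except RuntimeError as exc:  # optimizer failure on this start
            warnings.warn(f"rigid restart failed: {exc}", stacklevel=2)
            continue
        if best is None or metric < best[0]:
            best = (metric, final)

    if best is None:
        warnings.warn("rigid registration failed from every restart; returning identity",
                      stacklevel=2)
        return RigidTransform((0, 0, 0), (0, 0, 0), center)

    euler = sitk.Euler3DTransform(best[1])
    # sitk maps fixed->moving points: daily(T_reg(p)) ~ reference(p). The
    # setup-error convention resamples the *reference*, i.e. daily(p) =
    # reference(T(p)); hence T = T_reg^{-1} recentred at the volume center.
    r_reg = np.array(euler.GetMatrix()).reshape(3, 3)
    c_reg = np.array(euler.GetCenter())
    t_reg = np.array(euler.GetTranslation())
    # forward: q = R (p - c) + c + t ; invert and re-express about `center`
    r_inv = r_reg.T
    c = np.array(center)
    # inverse map: p = R^T (q - c - t) + c = R^T (q - cc) + cc + t'
    t_prime = r_inv @ (c - c_reg - t_reg) + c_reg - c
    return RigidTransform(tuple(t_prime), angles_from_matrix(r_inv), tuple(c))
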