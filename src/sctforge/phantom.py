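"""Deterministic digital pelvis cohort generator.

Emulates a cohort of prostate-radiotherapy subjects, each with a
voxel-matched MR/CT pair, six ROI masks (air, bone, bladder, prostate,
rectum, skin) and ground-truth geometry, so the whole synthesis and
evaluation chain can be exercised without patient data.

Anatomy is parametric: the body and soft organs are ellipsoids, the rectum a
vertical tube with a tissue wall enclosing an air pocket, and bone a
posterior sacrum plus two lateral femoral cylinders. Inter-subject variation
combines seeded jitter of the organ parameters with one smooth random
displacement field per subject; both are recorded in ``truth_meta`` so
registration accuracy is measurable against ground truth.

The MR tissue map is deliberately non-monotone versus HU (bone is dark and
the urine-filled bladder bright on T2-like contrast) so no global intensity
transform can substitute for the atlas-based method. A configurable subset
of subjects receives elevated bladder HU, emulating intravenous contrast —
the confound that separates selection-based synthesis from plain averaging.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .atlaslib import ROIMaskSet, masks_from_labels
from .registration import DVF, RigidTransform, resample_rigid
from .volume import Grid3D, Volume3D

LABEL_CODES = {
    "exterior": 0,
    "soft": 1,
    "pelvic_bone": 2,
    "bladder": 3,
    "prostate": 4,
    "rectum_wall": 5,
    "air_lumen": 6,
    "femoral_bone": 7,
}

# roi name -> label codes it comprises; the rectum ROI is the whole tube
# (wall + lumen) so the air pocket is a subset of it, and skin is the body
ROI_CODE_TABLE = {
    "air": [6],
    "bone": [2, 7],
    "bladder": [3],
    "prostate": [4],
    "rectum": [5, 6],
    "skin": [1, 2, 3, 4, 5, 6, 7],
}
FEMORAL_CODES = [7]

# label code -> tissue class used for intensity lookup
CODE_TISSUE = {
    0: "air",
    1: "soft",
    2: "bone",
    3: "bladder",
    4: "prostate",
    5: "rectum_wall",
    6: "air",
    7: "bone",
}

DEFAULT_TISSUE_HU = {
    "air": (-1000.0, 5.0),
    "soft": (30.0, 15.0),
    "bone": (700.0, 40.0),
    "bladder": (10.0, 12.0),
    "prostate": (40.0, 12.0),
    "rectum_wall": (45.0, 12.0),
}

DEFAULT_TISSUE_MR = {
    "air": (30.0, 12.0),
    "soft": (400.0, 25.0),
    "bone": (120.0, 20.0),
    "bladder": (850.0, 30.0),
    "prostate": (480.0, 25.0),
    "rectum_wall": (330.0, 25.0),
}


def default_organ_geometry() -> dict:
    """Base organ geometry in mm, relative to the grid center (+y posterior)."""
    return {
        "body": {"center": [0.0, 0.0, 0.0], "radii": [110.0, 85.0, 92.0]},
        "sacrum": {"center": [0.0, 55.0, 0.0], "radii": [30.0, 14.0, 60.0]},
        "femoral": {"centers_x": [-65.0, 65.0], "y": 0.0, "radius": 16.0,
                    "half_length": 70.0},
        "bladder": {"center": [0.0, -25.0, 25.0], "radii": [26.0, 22.0, 20.0]},
        "prostate": {"center": [0.0, -5.0, -15.0], "radii": [18.0, 16.0, 15.0]},
        "rectum": {"center_xy": [0.0, 25.0], "z_range": [-60.0, 50.0],
                   "outer_radius": 15.0, "lumen_radius": 8.0,
                   "air_z_range": [-10.0, 30.0]},
    }


@dataclass
class PhantomSpec:
    """Study conditions for cohort generation. Same seed + spec => identical cohort."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    organ_geometry: dict = field(default_factory=default_organ_geometry)
    tissue_hu: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_TISSUE_HU))
    tissue_mr: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_TISSUE_MR))
    deform_amplitude_mm: float = 8.0
    center_jitter_mm: float = 6.0
    radius_jitter_frac: float = 0.12
    bladder_radius_jitter_frac: float = 0.25
    body_radius_jitter_frac: float = 0.05
    air_z_jitter_mm: float = 8.0
    contrast_subjects: tuple[int, ...] = (3, 7)  # elevated bladder HU
    contrast_hu_boost: float = 300.0
    texture_frac_mr: float = 0.06
    texture_hu_ct: float = 10.0
    dvf_smoothing_mm: float = 30.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def grid(self) -> Grid3D:
        # centered grid: origin so that the domain center is at world 0
        origin = tuple(
            -(n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)
        )
        return Grid3D(self.grid_shape, self.spacing_mm, origin)

    def validate(self) -> None:
        g = self.organ_geometry
        for organ in ("body", "sacrum", "bladder", "prostate"):
            if any(r <= 0 for r in g[organ]["radii"]):
                raise ValueError(f"{organ} radii must be positive: {g[organ]['radii']}")
        rect = g["rectum"]
        if rect["outer_radius"] <= 0 or rect["lumen_radius"] <= 0:
            raise ValueError("rectum radii must be positive")
        if rect["lumen_radius"] >= rect["outer_radius"]:
            raise ValueError("rectal wall thickness must be positive "
                             "(lumen radius < outer radius)")
        if g["femoral"]["radius"] <= 0 or g["femoral"]["half_length"] <= 0:
            raise ValueError("femoral cylinder dimensions must be positive")
        body_r = np.asarray(g["body"]["radii"])
        body_c = np.asarray(g["body"]["center"])
        for organ in ("sacrum", "bladder", "prostate"):
            c = np.asarray(g[organ]["center"])
            r = np.asarray(g[organ]["radii"])
            if np.any(np.abs(c - body_c) + r > body_r):
                raise ValueError(f"{organ} does not fit inside the body contour")
        if abs(self.tissue_hu["air"][0] - (-1000.0)) > 1e-9:
            raise ValueError("air mean HU must be -1000")


@dataclass
class PhantomSubject:
    """One cohort member with ground truth."""

    subject_id: str
    mr: Volume3D
    ct: Volume3D
    label_map: np.ndarray
    roi_masks: ROIMaskSet
    femoral_mask: np.ndarray
    truth_dvf: DVF
    truth_meta: dict


# ---------------------------------------------------------------------------
# Geometry evaluation
# ---------------------------------------------------------------------------

def _labels_at(geom: dict, x, y, z) -> np.ndarray:
    """Integer label codes at (possibly warped) world coordinates (mm)."""
    labels = np.zeros(np.broadcast(x, y, z).shape, dtype=np.int16)

    def ellipsoid(p):
        c, r = np.asarray(p["center"]), np.asarray(p["radii"])
        return (((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2
                + ((z - c[2]) / r[2]) ** 2) <= 1.0

    labels[ellipsoid(geom["body"])] = LABEL_CODES["soft"]
    inside_body = labels > 0

    labels[ellipsoid(geom["sacrum"]) & inside_body] = LABEL_CODES["pelvic_bone"]

    fem = geom["femoral"]
    for cx in fem["centers_x"]:
        cyl = (((x - cx) ** 2 + (y - fem["y"]) ** 2) <= fem["radius"] ** 2) & (
            np.abs(z) <= fem["half_length"]
        )
        labels[cyl & inside_body] = LABEL_CODES["femoral_bone"]

    rect = geom["rectum"]
    cx, cy = rect["center_xy"]
    rad2 = (x - cx) ** 2 + (y - cy) ** 2
    in_z = (z >= rect["z_range"][0]) & (z <= rect["z_range"][1])
    tube = (rad2 <= rect["outer_radius"] ** 2) & in_z & inside_body
    labels[tube] = LABEL_CODES["rectum_wall"]
    air = (
        (rad2 <= rect["lumen_radius"] ** 2)
        & (z >= rect["air_z_range"][0])
        & (z <= rect["air_z_range"][1])
        & inside_body
    )
    labels[air] = LABEL_CODES["air_lumen"]

    labels[ellipsoid(geom["bladder"]) & inside_body] = LABEL_CODES["bladder"]
    labels[ellipsoid(geom["prostate"]) & inside_body] = LABEL_CODES["prostate"]
    return labels


def _perturb_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    geom = copy.deepcopy(spec.organ_geometry)
    cj = spec.center_jitter_mm

    def scale(rel):
        return float(rng.uniform(1.0 - rel, 1.0 + rel))

    for organ in ("sacrum", "bladder", "prostate"):
        rel = spec.bladder_radius_jitter_frac if organ == "bladder" else spec.radius_jitter_frac
        geom[organ]["center"] = [
            c + rng.uniform(-cj, cj) for c in geom[organ]["center"]
        ]
        s = scale(rel)
        geom[organ]["radii"] = [r * s for r in geom[organ]["radii"]]
    geom["body"]["radii"] = [r * scale(spec.body_radius_jitter_frac)
                             for r in geom["body"]["radii"]]
    rect = geom["rectum"]
    rect["center_xy"] = [c + rng.uniform(-cj / 2, cj / 2) for c in rect["center_xy"]]
    s = scale(spec.radius_jitter_frac)
    rect["outer_radius"] *= s
    rect["lumen_radius"] *= s
    aj = spec.air_z_jitter_mm
    rect["air_z_range"] = [v + rng.uniform(-aj, aj) for v in rect["air_z_range"]]
    fem = geom["femoral"]
    fem["centers_x"] = [c + rng.uniform(-cj / 2, cj / 2) for c in fem["centers_x"]]
    fem["radius"] *= scale(spec.radius_jitter_frac)
    return geom


# ---------------------------------------------------------------------------
# Smooth displacement fields
# ---------------------------------------------------------------------------

def generate_smooth_dvf(
    spec: PhantomSpec,
    seed: int,
    grid: Grid3D | None = None,
    amplitude_mm: float | None = None,
    boundary_margin_voxels: int = 4,
) -> DVF:
    """Band-limited random displacement field, zero at the grid boundary.

    Gaussian-filtered white noise per component, tapered to zero over a
    boundary margin, then rescaled so the maximum displacement magnitude
    equals ``amplitude_mm`` exactly (and is therefore never exceeded).
    """
    grid = grid or spec.grid
    amplitude = spec.deform_amplitude_mm if amplitude_mm is None else float(amplitude_mm)
    if amplitude < 0:
        raise ValueError("deformation amplitude must be non-negative")
    shape = tuple(grid.shape)
    if amplitude == 0.0:
        return DVF.zero(grid)
    rng = np.random.default_rng(seed)
    sigma_vox = [spec.dvf_smoothing_mm / s for s in grid.spacing_mm]
    vectors = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox) for _ in range(3)],
        axis=-1,
    )
    taper = np.ones(shape)
    m = boundary_margin_voxels
    for a in range(3):
        n = shape[a]
        ramp = np.ones(n)
        if m > 0 and n > 2 * m:
            edge = np.linspace(0.0, 1.0, m + 1)[:-1]  # exactly 0 on the boundary plane
            ramp[:m] = edge
            ramp[-m:] = edge[::-1]
        sl = [None] * 3
        sl[a] = slice(None)
        taper *= ramp[tuple(sl)]
    vectors *= taper[..., None]
    mag = np.sqrt((vectors ** 2).sum(axis=-1))
    peak = mag.max()
    if peak > 0:
        vectors *= amplitude / peak
    return DVF(vectors, grid, grid)


def _smooth_field(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


# ---------------------------------------------------------------------------
# Subject / cohort generation
# ---------------------------------------------------------------------------

def generate_subject(spec: PhantomSpec, subject_index: int) -> PhantomSubject:
    """One cohort member: paired MR/CT, label map, ROI masks, ground truth.

    MR and CT derive from a single label map evaluated at warped coordinates
    ``p + d(p)`` (the subject's smooth truth DVF on top of jittered organ
    geometry), so the pair is anatomically consistent voxel by voxel.
    """
    rng = np.random.default_rng([spec.seed, subject_index])
    geom = _perturb_geometry(spec, rng)
    dvf_seed = int(rng.integers(0, 2**31 - 1))
    truth_dvf = generate_smooth_dvf(spec, dvf_seed)

    grid = spec.grid
    wx, wy, wz = grid.world_coordinates()
    x = wx + truth_dvf.vectors[..., 0]
    y = wy + truth_dvf.vectors[..., 1]
    z = wz + truth_dvf.vectors[..., 2]
    labels = _labels_at(geom, x, y, z)

    has_contrast = subject_index in tuple(spec.contrast_subjects)
    tissue_hu = copy.deepcopy(spec.tissue_hu)
    if has_contrast:
        mean, sd = tissue_hu["bladder"]
        tissue_hu["bladder"] = (mean + spec.contrast_hu_boost, sd)

    sigma_vox = [40.0 / s for s in grid.spacing_mm]
    texture = _smooth_field(rng, grid.shape, sigma_vox)
    # texture lives in material coordinates: sample it at the warped positions
    idx = grid.world_to_index(np.stack([x, y, z], axis=-1))
    texture_w = ndimage.map_coordinates(
        texture, [idx[..., a] for a in range(3)], order=1, mode="nearest"
    )

    ct = np.zeros(grid.shape)
    mr = np.zeros(grid.shape)
    for code, tissue in CODE_TISSUE.items():
        sel = labels == code
        if not sel.any():
            continue
        hu_mean, hu_sd = tissue_hu[tissue]
        mr_mean, mr_sd = spec.tissue_mr[tissue]
        ct[sel] = hu_mean + hu_sd * rng.standard_normal(int(sel.sum()))
        mr[sel] = mr_mean + mr_sd * rng.standard_normal(int(sel.sum()))
    body = labels > 0
    solid = body & (labels != LABEL_CODES["air_lumen"])
    ct[solid] += spec.texture_hu_ct * texture_w[solid]
    mr[solid] *= 1.0 + spec.texture_frac_mr * texture_w[solid]

    roi_masks = masks_from_labels(labels, ROI_CODE_TABLE)
    truth_meta = {
        "subject_index": subject_index,
        "geometry": geom,
        "dvf_seed": dvf_seed,
        "has_bladder_contrast": has_contrast,
        "tissue_hu": {k: list(v) for k, v in tissue_hu.items()},
    }
    sid = f"sub-{subject_index:02d}"
    return PhantomSubject(
        subject_id=sid,
        mr=Volume3D(mr, grid.spacing_mm, grid.origin_mm, "MR"),
        ct=Volume3D(ct, grid.spacing_mm, grid.origin_mm, "CT"),
        label_map=labels,
        roi_masks=roi_masks,
        femoral_mask=np.isin(labels, FEMORAL_CODES),
        truth_dvf=truth_dvf,
        truth_meta=truth_meta,
    )


def generate_cohort(spec: PhantomSpec, n_subjects: int) -> list[PhantomSubject]:
    """A deterministic cohort; leave-one-out needs at least one atlas, so n >= 2."""
    if n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects (1 subject + 1 atlas)")
    return [generate_subject(spec, i) for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# CBCT simulation
# ---------------------------------------------------------------------------

def simulate_cbct(
    ct: Volume3D,
    seed: int,
    noise_sd_hu: float = 20.0,
    shading_amplitude_hu: float = 30.0,
    rigid_offset: RigidTransform | None = None,
) -> Volume3D:
    """Degraded daily image: rigidly offset CT + noise + low-frequency shading.

    The true offset is stored in ``meta['true_offset']`` so registration
    recovery is verifiable. The offset follows the pull convention of
    :func:`sctforge.registration.resample_rigid`.
    """
    if ct.modality not in ("CT", "CBCT"):
        raise ValueError("simulate_cbct expects a CT volume")
    rigid_offset = rigid_offset or RigidTransform((0, 0, 0), (0, 0, 0), ct.grid.center_mm)
    moved = resample_rigid(ct, rigid_offset, "linear", fill_value=-1000.0)
    rng = np.random.default_rng(seed)
    values = moved.values.copy()
    if shading_amplitude_hu > 0:
        sigma_vox = [60.0 / s for s in ct.spacing_mm]
        values += shading_amplitude_hu * _smooth_field(rng, ct.values.shape, sigma_vox)
    if noise_sd_hu > 0:
        values += noise_sd_hu * rng.standard_normal(ct.values.shape)
    out = Volume3D(values, ct.spacing_mm, ct.origin_mm, "CBCT")
    out.meta["true_offset"] = rigid_offset.to_json()
    return out


# ---------------------------------------------------------------------------
# On-disk cohort layout
# ---------------------------------------------------------------------------

def write_subject(subject: PhantomSubject, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    subject.mr.save(out_dir / f"{sid}_mr.nii.gz")
    subject.ct.save(out_dir / f"{sid}_ct.nii.gz")
    lab = Volume3D(subject.label_map.astype(np.int16), subject.mr.spacing_mm,
                   subject.mr.origin_mm, "MR")
    lab.save(out_dir / f"{sid}_labels.nii.gz")
    (out_dir / f"{sid}_labels.json").write_text(
        json.dumps({"label_codes": LABEL_CODES, "roi_code_table": ROI_CODE_TABLE}, indent=2)
    )
    (out_dir / f"{sid}_truth.json").write_text(json.dumps(subject.truth_meta, indent=2))


def write_cohort(cohort: list[PhantomSubject], out_dir: str | Path) -> None:
    for subject in cohort:
        write_subject(subject, out_dir)
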