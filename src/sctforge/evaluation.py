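"""Evaluation battery: HU error, dose proxy, 2D local gamma, DVH, localization.

The leave-one-out driver treats each cohort member in turn as the subject
whose MR-only synthetic CT is built from the remaining members, then scores
the result four ways: per-ROI HU error against the ground-truth CT, a
primary-attenuation dose proxy compared via 2D local gamma and DVH
parameters, Dice of the autosegmentation, and 6-DOF bone localization to
simulated daily CBCTs with the synthetic CT versus the true CT as reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlaslib import AtlasEntry, AtlasLibrary, ROIMaskSet
from .phantom import PhantomSubject, simulate_cbct
from .registration import (
    DVF,
    DeformableParams,
    RigidParams,
    RigidTransform,
    register_rigid,
)
from .sct import SelectionInput, direct_mean_sct, synthesize_sct
from .segmentation import (
    FusionConfig,
    body_contour,
    dice,
    fuse_labels,
    propagate_atlases,
    threshold_air,
)
from .volume import Volume3D, require_same_grid


# ---------------------------------------------------------------------------
# HU error statistics
# ---------------------------------------------------------------------------

@dataclass
class HUErrorReport:
    per_roi: dict[str, tuple[float, float, int]]  # roi -> (mean, sd, n_voxels)
    cumulative_abs_histogram: tuple[np.ndarray, np.ndarray]  # (abs_error, cum_fraction)
    quantiles: dict[float, float]  # fraction -> abs error at that fraction

    def abs_error_at(self, fraction: float) -> float:
        return self.quantiles[fraction]


SOFT_TISSUE_EXCLUDES = ("bone", "bladder", "prostate", "rectum", "air")


def soft_tissue_mask(rois: ROIMaskSet) -> np.ndarray:
    """Body voxels outside every organ ROI (the 'soft tissue outside all ROIs')."""
    soft = rois["skin"].copy()
    for name in SOFT_TISSUE_EXCLUDES:
        if name in rois:
            soft &= ~rois[name]
    return soft


def hu_error_report(
    sct: Volume3D,
    reference_ct: Volume3D,
    rois: ROIMaskSet,
    quantile_fractions=(0.5, 0.8, 0.9),
    roi_names=("prostate", "bladder", "rectum", "bone", "air"),
) -> HUErrorReport:
    """Signed per-ROI HU error (sct - reference) and body-wide error histogram."""
    require_same_grid(sct, reference_ct, "synthetic and reference CT")
    err = np.asarray(sct.values, dtype=float) - np.asarray(reference_ct.values, dtype=float)
    per_roi: dict[str, tuple[float, float, int]] = {}
    regions = {name: rois[name] for name in roi_names if name in rois}
    regions["soft_tissue"] = soft_tissue_mask(rois)
    for name, mask in regions.items():
        n = int(mask.sum())
        if n == 0:
            per_roi[name] = (float("nan"), float("nan"), 0)
        else:
            per_roi[name] = (float(err[mask].mean()), float(err[mask].std()), n)
    body = rois["skin"]
    abs_err = np.sort(np.abs(err[body]))
    cum = np.arange(1, abs_err.size + 1) / abs_err.size
    quantiles = {float(q): float(np.quantile(np.abs(err[body]), q)) for q in quantile_fractions}
    return HUErrorReport(per_roi, (abs_err, cum), quantiles)


# ---------------------------------------------------------------------------
# Dose proxy
# ---------------------------------------------------------------------------

@dataclass
class Beam:
    gantry_angle_deg: float
    field_mask: np.ndarray  # 3D bool: rays intersecting it are irradiated
    weight: float = 1.0


def dose_proxy(
    ct: Volume3D,
    beams: list[Beam],
    ptv_mask: np.ndarray,
    mu_water_per_mm: float = 0.005,
    prescription_gy: float = 79.2,
) -> Volume3D:
    """Primary-attenuation dose stand-in for a treatment-planning system.

    Each beam is a parallel-ray field in the axial plane at its gantry
    angle; voxel attenuation is ``mu_water * (1 + HU/1000)`` clipped at
    zero, the per-ray dose decays as ``exp(-integral mu ds)``, and the
    weighted beam sum is scaled so the PTV mean equals ``prescription_gy``.
    HU-sensitivity is what matters here: it exercises the downstream gamma
    and DVH comparisons, not clinical beam physics.
    """
    if not beams:
        raise ValueError("need at least one beam")
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("PTV mask is empty")
    sx, sy, _ = ct.spacing_mm
    if abs(sx - sy) > 1e-9 and any(b.gantry_angle_deg % 180 != 0 for b in beams):
        raise ValueError("oblique beams require isotropic in-plane spacing")
    hu = np.asarray(ct.values, dtype=float)
    mu = np.clip(mu_water_per_mm * (1.0 + hu / 1000.0), 0.0, None)

    total = np.zeros_like(mu)
    for beam in beams:
        fmask = np.asarray(beam.field_mask, dtype=bool)
        if not fmask.any():
            raise ValueError("beam field mask is empty")
        angle = beam.gantry_angle_deg
        mu_rot = ndimage.rotate(mu, angle, axes=(0, 1), reshape=False, order=1,
                                mode="constant", cval=0.0)
        mask_rot = ndimage.rotate(fmask.astype(float), angle, axes=(0, 1),
                                  reshape=False, order=0, mode="constant", cval=0.0) > 0.5
        # rays travel along +y in the rotated frame
        path = np.cumsum(mu_rot, axis=1) * sy
        primary = np.exp(-path)
        aperture = mask_rot.any(axis=1)[:, None, :]
        dose_rot = primary * aperture
        dose = ndimage.rotate(dose_rot, -angle, axes=(0, 1), reshape=False, order=1,
                              mode="constant", cval=0.0)
        total += beam.weight * dose

    total = np.clip(total, 0.0, None)
    ptv_mean = total[ptv_mask].mean()
    if ptv_mean <= 0:
        raise ValueError("no dose reaches the PTV; check beam geometry")
    total *= prescription_gy / ptv_mean
    return Volume3D(total, ct.spacing_mm, ct.origin_mm, "DOSE")


def default_beams(ptv_mask: np.ndarray, n_beams: int = 7, margin_voxels: int = 2) -> list[Beam]:
    """Evenly spaced coplanar beams with a common dilated-PTV aperture."""
    fmask = ndimage.binary_dilation(np.asarray(ptv_mask, dtype=bool),
                                    iterations=margin_voxels)
    angles = np.arange(n_beams) * 360.0 / n_beams
    return [Beam(float(a), fmask, 1.0) for a in angles]


# ---------------------------------------------------------------------------
# 2D local gamma index
# ---------------------------------------------------------------------------

@dataclass
class GammaResult:
    gamma_map: np.ndarray  # per-pixel gamma on the evaluated slice
    pass_rate: float  # fraction with gamma <= 1 among evaluated pixels
    criteria: tuple[float, float]  # (dose_percent, distance_mm)
    low_dose_threshold_fraction: float
    evaluated: np.ndarray  # pixels included in the pass rate

    def pass_rate_in(self, mask2d: np.ndarray) -> float:
        sel = self.evaluated & np.asarray(mask2d, dtype=bool)
        if not sel.any():
            return float("nan")
        return float((self.gamma_map[sel] <= 1.0).mean())


def gamma_2d_local(
    reference_dose: np.ndarray,
    evaluated_dose: np.ndarray,
    dose_percent: float,
    distance_mm: float,
    spacing_mm: tuple[float, float] = (1.0, 1.0),
    low_dose_cutoff_fraction: float = 0.1,
) -> GammaResult:
    """2D gamma with local dose normalization.

    For each evaluated pixel, searches reference positions within a disc of
    radius 3x ``distance_mm`` at ~``distance_mm/10`` sub-pixel steps
    (reference dose linearly interpolated) and takes

    ``gamma = min sqrt((D_eval - D_ref(r))^2 / (delta * D_ref(r))^2
                        + |r|^2 / distance_mm^2)``,

    with ``delta = dose_percent/100`` applied to the *local* reference dose
    at the search point. Pixels whose reference dose falls below
    ``low_dose_cutoff_fraction`` of the reference maximum are excluded from
    the pass rate (but still carry a gamma value).
    """
    ref = np.asarray(reference_dose, dtype=float)
    ev = np.asarray(evaluated_dose, dtype=float)
    if ref.shape != ev.shape:
        raise ValueError("dose slices must share one grid")
    ref_max = ref.max()
    if ref_max <= 0:
        raise ValueError("reference dose is zero everywhere")

    # fine grid with an integer number of substeps per pixel so every pixel
    # center lands exactly on a fine-grid node
    target_step = distance_mm / 10.0
    factors = [max(1, int(round(s / target_step))) for s in spacing_mm]
    fine_steps = [s / f for s, f in zip(spacing_mm, factors)]
    h, w = ref.shape
    fi = np.arange((h - 1) * factors[0] + 1) / factors[0]
    fj = np.arange((w - 1) * factors[1] + 1) / factors[1]
    fine = ndimage.map_coordinates(
        ref, np.meshgrid(fi, fj, indexing="ij"), order=1, mode="nearest"
    )

    radius = 3.0 * distance_mm
    oi_max = int(radius / fine_steps[0])
    oj_max = int(radius / fine_steps[1])
    oi, oj = np.meshgrid(np.arange(-oi_max, oi_max + 1), np.arange(-oj_max, oj_max + 1),
                         indexing="ij")
    dist2 = (oi * fine_steps[0]) ** 2 + (oj * fine_steps[1]) ** 2
    keep = dist2 <= radius ** 2
    offsets = np.stack([oi[keep], oj[keep]], axis=1)
    dist2 = dist2[keep] / distance_mm ** 2

    base_i = (np.arange(h) * factors[0])[:, None] * np.ones(w, dtype=int)[None, :]
    base_j = np.ones(h, dtype=int)[:, None] * (np.arange(w) * factors[1])[None, :]
    delta = dose_percent / 100.0

    gamma2 = np.full(ref.shape, np.inf)
    fh, fw = fine.shape
    for (doi, doj), d2 in zip(offsets, dist2):
        ii = base_i + doi
        jj = base_j + doj
        inb = (ii >= 0) & (ii < fh) & (jj >= 0) & (jj < fw)
        refs = fine[np.clip(ii, 0, fh - 1), np.clip(jj, 0, fw - 1)]
        denom = delta * refs
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (ev - refs) ** 2 / denom ** 2 + d2
        term = np.where(inb & (denom > 0), term, np.inf)
        np.minimum(gamma2, term, out=gamma2)

    gamma_map = np.sqrt(gamma2)
    evaluated = ref >= low_dose_cutoff_fraction * ref_max
    finite = np.isfinite(gamma_map) & evaluated
    pass_rate = float((gamma_map[finite] <= 1.0).mean()) if finite.any() else float("nan")
    return GammaResult(gamma_map, pass_rate, (dose_percent, distance_mm),
                       low_dose_cutoff_fraction, finite)


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    dose_bins: np.ndarray  # ascending dose values (Gy)
    volume_fraction: np.ndarray  # fraction of ROI receiving >= dose
    roi_name: str = ""


def dvh_curve(dose: Volume3D, roi: np.ndarray, n_bins: int = 200, roi_name: str = "") -> DVHCurve:
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    doses = np.asarray(dose.values, dtype=float)[roi]
    bins = np.linspace(0.0, doses.max(), n_bins)
    frac = np.array([(doses >= b).mean() for b in bins])
    return DVHCurve(bins, frac, roi_name)


def dvh_parameters(dose: Volume3D, roi: np.ndarray, query_percents) -> dict[float, float]:
    """Dx values: minimum dose received by the hottest x% of the ROI volume.

    Computed as the (1 - x/100) quantile of the ROI dose distribution with
    linear interpolation between order statistics.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    doses = np.asarray(dose.values, dtype=float)[roi]
    return {
        float(x): float(np.quantile(doses, 1.0 - x / 100.0, method="linear"))
        for x in query_percents
    }


def dvh_discrepancy(
    dose_eval: Volume3D,
    dose_ref: Volume3D,
    roi: np.ndarray,
    query_percents,
    prescription_gy: float,
) -> dict[float, float]:
    """Relative Dx discrepancy (eval - ref) / prescription, per query."""
    de = dvh_parameters(dose_eval, roi, query_percents)
    dr = dvh_parameters(dose_ref, roi, query_percents)
    return {x: (de[x] - dr[x]) / prescription_gy for x in de}


# ---------------------------------------------------------------------------
# Localization comparison
# ---------------------------------------------------------------------------

def compare_localization(
    t_sct: RigidTransform, t_pct: RigidTransform
) -> tuple[float, tuple[float, float, float]]:
    """Setup-correction difference when the synthetic CT replaces the true CT.

    Returns the Euclidean norm of the translation difference (mm) and the
    per-axis absolute rotation differences (deg).
    """
    if t_sct.convention != t_pct.convention:
        raise ValueError("rigid transforms use different rotation conventions")
    dt = np.asarray(t_sct.translation_mm) - np.asarray(t_pct.translation_mm)
    dr = np.abs(np.asarray(t_sct.rotation_deg) - np.asarray(t_pct.rotation_deg))
    return float(np.linalg.norm(dt)), tuple(float(v) for v in dr)


# ---------------------------------------------------------------------------
# Leave-one-out orchestration
# ---------------------------------------------------------------------------

@dataclass
class LOOConfig:
    """Study conditions for the leave-one-out evaluation."""

    fusion: FusionConfig = field(default_factory=FusionConfig)
    reg_params: DeformableParams = field(default_factory=DeformableParams)
    roi_selection_set: tuple[str, ...] = ("air", "bone", "bladder", "prostate",
                                          "rectum", "skin")
    use_truth_masks: tuple[str, ...] = ()  # ROIs substituted by ground truth
    ptv_margin_mm: float = 5.0
    n_beams: int = 7
    prescription_gy: float = 79.2
    mu_water_per_mm: float = 0.005
    gamma_criteria: tuple = ((1.0, 1.0), (2.0, 2.0))
    gamma_slices: int = 3
    dvh_queries: dict = field(default_factory=lambda: {
        "ptv": (99, 95), "rectum": (40, 5), "bladder": (50,), "femoral": (1,)})
    n_cbct_per_subject: int = 2
    cbct_offset_mm: float = 5.0
    cbct_offset_deg: float = 2.0
    atlas_counts: tuple[int, ...] = ()  # e.g. (5,...,9) for the sweep
    include_dose: bool = True
    include_localization: bool = True
    rigid_params: RigidParams = field(default_factory=RigidParams)


@dataclass
class LOOReport:
    hu: pd.DataFrame  # per subject x roi x method signed errors
    soft_p90: pd.DataFrame  # per subject 90th-pct abs soft-tissue error, both methods
    dice: pd.DataFrame  # per subject x roi autosegmentation Dice
    dice_sweep: pd.DataFrame  # per subject x roi x n_atlases Dice
    gamma: pd.DataFrame  # per subject x roi x criterion pass rate
    dvh: pd.DataFrame  # per subject x roi x Dx relative discrepancy
    localization: pd.DataFrame  # per subject x cbct transform differences
    config_echo: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.hu.to_csv(out_dir / "summary_hu.csv", index=False)
        self.soft_p90.to_csv(out_dir / "summary_soft_p90.csv", index=False)
        self.dice.to_csv(out_dir / "summary_dice.csv", index=False)
        self.dice_sweep.to_csv(out_dir / "summary_dice_sweep.csv", index=False)
        self.gamma.to_csv(out_dir / "summary_gamma.csv", index=False)
        self.dvh.to_csv(out_dir / "summary_dvh.csv", index=False)
        self.localization.to_csv(out_dir / "summary_localization.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(self.config_echo, indent=2, default=str))


def _roi_slices(mask: np.ndarray, n: int, allowed_z=None) -> list[int]:
    """Up to n axial slice indices through the ROI, centered on its z-centroid.

    ``allowed_z`` restricts to slices that actually receive dose.
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        return []
    zs = np.unique(idx[:, 2])
    if allowed_z is not None:
        zs = np.array([z for z in zs if int(z) in allowed_z], dtype=int)
    if zs.size == 0:
        return []
    zc = int(np.mean(idx[:, 2]))
    return sorted(zs, key=lambda z: abs(z - zc))[:n]


def ptv_from_prostate(prostate: np.ndarray, margin_mm: float, spacing_mm) -> np.ndarray:
    iters = max(1, int(round(margin_mm / min(spacing_mm[:2]))))
    return ndimage.binary_dilation(np.asarray(prostate, dtype=bool), iterations=iters)


def make_library(cohort: list[PhantomSubject], exclude_index: int | None = None,
                 max_entries: int | None = None) -> AtlasLibrary:
    """Phantom subjects as atlas entries (MR/CT already voxel-matched)."""
    entries = []
    for i, s in enumerate(cohort):
        if i == exclude_index:
            continue
        entries.append(AtlasEntry(s.mr, s.ct, s.roi_masks,
                                  DVF.zero(s.mr.grid), s.subject_id))
    if max_entries is not None:
        entries = entries[:max_entries]
    return AtlasLibrary(entries, {"source": "phantom cohort"})


def _subject_masks(subject, propagated, cfg: LOOConfig) -> ROIMaskSet:
    fused = fuse_labels(subject.mr, propagated, cfg.fusion)
    masks = dict(fused.masks)
    for roi in cfg.use_truth_masks:
        masks[roi] = subject.roi_masks[roi]
    vals = np.asarray(subject.mr.values, dtype=float)
    if "skin" not in masks:
        masks["skin"] = body_contour(subject.mr, 0.5 * float(np.percentile(vals, 75)))
    if "air" not in masks:
        body_median = float(np.median(vals[masks["skin"]]))
        masks["air"] = threshold_air(subject.mr, masks["rectum"], 0.25 * body_median)
    return ROIMaskSet(masks)


def evaluate_subject(
    cohort: list[PhantomSubject],
    index: int,
    cfg: LOOConfig,
    rng: np.random.Generator,
    records: dict,
) -> None:
    subject = cohort[index]
    lib = make_library(cohort, exclude_index=index)
    propagated = propagate_atlases(subject.mr, lib, cfg.reg_params)
    subj_masks = _subject_masks(subject, propagated, cfg)

    # --- autosegmentation Dice against phantom truth
    for roi in ("bone", "bladder", "prostate", "rectum"):
        records["dice"].append({
            "subject": subject.subject_id, "roi": roi,
            "dice": dice(subj_masks[roi], subject.roi_masks[roi]),
        })
    for k in cfg.atlas_counts:
        k = min(k, len(propagated))
        fused_k = fuse_labels(subject.mr, propagated[:k], cfg.fusion)
        for roi in ("bone", "bladder", "prostate", "rectum"):
            records["dice_sweep"].append({
                "subject": subject.subject_id, "roi": roi, "n_atlases": k,
                "dice": dice(fused_k[roi], subject.roi_masks[roi]),
            })

    # --- synthesis, both methods
    sel_input = SelectionInput(
        subject_masks=subj_masks,
        deformed_atlas_cts=[p.def_atlas_ct for p in propagated],
        deformed_atlas_masks=[p.def_atlas_masks for p in propagated],
        roi_selection_set=cfg.roi_selection_set,
        air_mask=subj_masks["air"] if "air" in subj_masks else None,
        valid_masks=[p.valid for p in propagated],
    )
    sct_vol, diag = synthesize_sct(sel_input)
    dm_vol = direct_mean_sct(sel_input.deformed_atlas_cts, sel_input.air_mask,
                             sel_input.valid_masks)

    # --- HU error against ground-truth CT, scored inside the truth ROIs
    for method, vol in (("selection", sct_vol), ("direct_mean", dm_vol)):
        report = hu_error_report(vol, subject.ct, subject.roi_masks)
        for roi, (mean, sd, n) in report.per_roi.items():
            records["hu"].append({
                "subject": subject.subject_id, "method": method, "roi": roi,
                "mean_error_hu": mean, "sd_hu": sd, "n_voxels": n,
            })
        soft = soft_tissue_mask(subject.roi_masks)
        abs_soft = np.abs(vol.values - subject.ct.values)[soft]
        records["soft_p90"].append({
            "subject": subject.subject_id, "method": method,
            "p90_abs_error_hu": float(np.percentile(abs_soft, 90)),
            "fallback_fraction": diag.fallback_fraction if method == "selection" else 1.0,
        })

    # --- dose proxy + gamma + DVH
    if cfg.include_dose:
        ptv = ptv_from_prostate(subject.roi_masks["prostate"], cfg.ptv_margin_mm,
                                subject.ct.spacing_mm)
        beams = default_beams(ptv, cfg.n_beams)
        dose_ref = dose_proxy(subject.ct, beams, ptv, cfg.mu_water_per_mm,
                              cfg.prescription_gy)
        dose_eval = dose_proxy(sct_vol, beams, ptv, cfg.mu_water_per_mm,
                               cfg.prescription_gy)
        roi_for_dose = {
            "ptv": ptv,
            "bladder": subject.roi_masks["bladder"],
            "rectum": subject.roi_masks["rectum"],
            "femoral": subject.femoral_mask,
        }
        dosed_z = {int(z) for z in range(dose_ref.values.shape[2])
                   if dose_ref.values[:, :, z].max() > 0}
        for dose_pct, dist_mm in cfg.gamma_criteria:
            for roi_name, roi_mask in roi_for_dose.items():
                rates = []
                for z in _roi_slices(roi_mask, cfg.gamma_slices, allowed_z=dosed_z):
                    res = gamma_2d_local(
                        dose_ref.values[:, :, z], dose_eval.values[:, :, z],
                        dose_pct, dist_mm, subject.ct.spacing_mm[:2],
                    )
                    r = res.pass_rate_in(roi_mask[:, :, z])
                    if np.isfinite(r):
                        rates.append(r)
                records["gamma"].append({
                    "subject": subject.subject_id, "roi": roi_name,
                    "dose_percent": dose_pct, "distance_mm": dist_mm,
                    "pass_rate": float(np.mean(rates)) if rates else float("nan"),
                })
        for roi_name, queries in cfg.dvh_queries.items():
            disc = dvh_discrepancy(dose_eval, dose_ref, roi_for_dose[roi_name],
                                   queries, cfg.prescription_gy)
            for x, v in disc.items():
                records["dvh"].append({
                    "subject": subject.subject_id, "roi": roi_name,
                    "dx_percent": x, "relative_discrepancy": v,
                })

    # --- CBCT localization: synthetic-CT reference vs true-CT reference
    if cfg.include_localization:
        clipbox = ndimage.binary_dilation(subject.roi_masks["bone"], iterations=2)
        for c in range(cfg.n_cbct_per_subject):
            offset = RigidTransform(
                tuple(rng.uniform(-cfg.cbct_offset_mm, cfg.cbct_offset_mm, 3)),
                tuple(rng.uniform(-cfg.cbct_offset_deg, cfg.cbct_offset_deg, 3)),
                subject.ct.grid.center_mm,
            )
            cbct = simulate_cbct(subject.ct, int(rng.integers(0, 2**31 - 1)),
                                 rigid_offset=offset)
            t_sct = register_rigid(sct_vol, cbct, clipbox, cfg.rigid_params)
            t_pct = register_rigid(subject.ct, cbct, clipbox, cfg.rigid_params)
            dt, drot = compare_localization(t_sct, t_pct)
            records["localization"].append({
                "subject": subject.subject_id, "cbct": c,
                "translation_diff_mm": dt,
                "rotation_diff_x_deg": drot[0],
                "rotation_diff_y_deg": drot[1],
                "rotation_diff_z_deg": drot[2],
            })


def run_leave_one_out(
    cohort: list[PhantomSubject],
    cfg: LOOConfig | None = None,
    seed: int = 0,
) -> LOOReport:
    """Evaluate every cohort member against a library of the others.

    Per-subject failures are recorded and the run continues; an empty run
    raises.
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    cfg = cfg or LOOConfig()
    rng = np.random.default_rng(seed)
    records: dict[str, list] = {k: [] for k in
                                ("hu", "soft_p90", "dice", "dice_sweep",
                                 "gamma", "dvh", "localization")}
    errors = []
    for i in range(len(cohort)):
        sub_rng = np.random.default_rng([seed, i])
        try:
            evaluate_subject(cohort, i, cfg, sub_rng, records)
        except Exception as exc:
            errors.append({"subject": cohort[i].subject_id, "error": str(exc)})
    if not records["hu"]:
        raise RuntimeError(f"every subject failed: {errors}")
    return LOOReport(
        hu=pd.DataFrame(records["hu"]),
        soft_p90=pd.DataFrame(records["soft_p90"]),
        dice=pd.DataFrame(records["dice"]),
        dice_sweep=pd.DataFrame(records["dice_sweep"]),
        gamma=pd.DataFrame(records["gamma"]),
        dvh=pd.DataFrame(records["dvh"]),
        localization=pd.DataFrame(records["localization"]),
        config_echo={"seed": seed, "n_subjects": len(cohort),
                     "errors": errors, "config": str(cfg)},
    )
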