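"""Multi-atlas autosegmentation of a subject MR and Dice evaluation.

Every atlas MR is deformably registered to the subject MR; the resulting
fields carry the atlas CTs (linear) and ROI masks (nearest) onto the subject
grid, and the propagated masks are fused per ROI by majority or
intensity-weighted voting. Air in the rectum and the body (skin) contour are
generated separately by thresholding, mirroring the usual clinical split
between fused soft-tissue ROIs and semi-automatic air/skin contours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .atlaslib import AtlasLibrary, ROIMaskSet
from .registration import DVF, DeformableParams, apply_dvf, apply_dvf_mask, register_deformable
from .volume import Volume3D, require_same_grid


@dataclass
class FusionConfig:
    """Label-fusion settings.

    ``intensity_weighted`` weights each atlas vote at voxel p by
    ``1 / (epsilon + patch-mean |subject_mr - deformed_atlas_mr|)`` over a
    cubic patch of radius ``patch_radius_voxels`` — atlases that locally
    resemble the subject count more. ``majority`` is the unweighted mean
    vote. A voxel is labeled when its vote reaches ``decision_threshold``
    (ties at the threshold are included).
    """

    method: str = "intensity_weighted"
    patch_radius_voxels: int = 2
    epsilon: float = 1.0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.method not in ("majority", "intensity_weighted"):
            raise ValueError(f"unknown fusion method {self.method!r}")
        if self.patch_radius_voxels < 0:
            raise ValueError("patch radius must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not (0.0 < self.decision_threshold <= 1.0):
            raise ValueError("decision threshold must lie in (0, 1]")


@dataclass
class PropagatedAtlas:
    """One atlas carried onto the subject grid."""

    def_atlas_ct: Volume3D
    def_atlas_masks: ROIMaskSet
    def_atlas_mr: Volume3D
    dvf: DVF
    valid: np.ndarray  # in-domain sample mask
    entry_id: str = ""


def propagate_atlases(
    subject_mr: Volume3D,
    lib: AtlasLibrary,
    params: DeformableParams | None = None,
) -> list[PropagatedAtlas]:
    """Register every atlas MR to the subject MR and warp CT + masks across.

    A failing entry is skipped with a warning; if every entry fails the
    error propagates.
    """
    if len(lib) == 0:
        raise ValueError("atlas library is empty")
    out: list[PropagatedAtlas] = []
    failures = []
    for entry in lib:
        try:
            dvf = register_deformable(subject_mr, entry.atlas_mr, params)
            def_ct, valid = apply_dvf(entry.atlas_ct, dvf, "linear", return_valid_mask=True)
            def_mr = apply_dvf(entry.atlas_mr, dvf, "linear")
            def_masks = entry.roi_masks.warp(dvf)
            out.append(PropagatedAtlas(def_ct, def_masks, def_mr, dvf, valid, entry.entry_id))
        except Exception as exc:  # pragma: no cover - defensive per-entry isolation
            failures.append((entry.entry_id, exc))
            warnings.warn(f"atlas {entry.entry_id!r} failed to propagate: {exc}",
                          stacklevel=2)
    if not out:
        raise RuntimeError(f"all atlas propagations failed: {failures}")
    return out


def fuse_labels(
    subject_mr: Volume3D,
    propagated: list[PropagatedAtlas],
    cfg: FusionConfig | None = None,
    roi_names=("bone", "bladder", "prostate", "rectum"),
) -> ROIMaskSet:
    """Consensus ROI masks on the subject grid from propagated atlas masks."""
    if not propagated:
        raise ValueError("no propagated atlases to fuse")
    cfg = cfg or FusionConfig()

    if cfg.method == "intensity_weighted":
        size = 2 * cfg.patch_radius_voxels + 1
        weights = []
        subj = np.asarray(subject_mr.values, dtype=float)
        for prop in propagated:
            diff = np.abs(subj - np.asarray(prop.def_atlas_mr.values, dtype=float))
            patch_mad = ndimage.uniform_filter(diff, size=size, mode="nearest")
            weights.append(1.0 / (cfg.epsilon + patch_mad))
        weights = np.stack(weights)
    else:
        weights = np.ones((len(propagated),) + subject_mr.values.shape)

    wsum = weights.sum(axis=0)
    fused = {}
    for roi in roi_names:
        votes = np.stack([p.def_atlas_masks[roi].astype(float) for p in propagated])
        vote = (weights * votes).sum(axis=0) / wsum
        fused[roi] = vote >= cfg.decision_threshold
    return ROIMaskSet(fused)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 1.0 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"masks must share one grid: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def threshold_air(
    subject_mr: Volume3D,
    rectum_hint: np.ndarray,
    threshold: float,
    hint_dilation_voxels: int = 2,
) -> np.ndarray:
    """Air-in-rectum mask: low-MR voxels inside the (dilated) rectum region.

    Keeps the largest connected component; may be empty.
    """
    rectum_hint = np.asarray(rectum_hint, dtype=bool)
    if hint_dilation_voxels > 0 and rectum_hint.any():
        rectum_hint = ndimage.binary_dilation(rectum_hint, iterations=hint_dilation_voxels)
    candidate = (np.asarray(subject_mr.values) < threshold) & rectum_hint
    if not candidate.any():
        return candidate
    labeled, n = ndimage.label(candidate)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def body_contour(volume: Volume3D, background_threshold: float) -> np.ndarray:
    """Body (skin) mask: largest connected foreground component, holes filled."""
    fg = np.asarray(volume.values) > background_threshold
    if not fg.any():
        return fg
    labeled, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    body = labeled == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(body)


def segment_subject(
    subject_mr: Volume3D,
    lib: AtlasLibrary,
    cfg: FusionConfig | None = None,
    reg_params: DeformableParams | None = None,
    air_threshold: float | None = None,
    body_threshold: float | None = None,
) -> tuple[ROIMaskSet, list[PropagatedAtlas]]:
    """Full subject segmentation: fused soft ROIs + thresholded air and skin.

    Thresholds default to fractions of the subject MR intensity range
    (air: 20th percentile of the in-body histogram is usually far above the
    air signal, so 0.25x the body median; skin: halfway between the exterior
    and body intensity levels).
    """
    propagated = propagate_atlases(subject_mr, lib, reg_params)
    fused = fuse_labels(subject_mr, propagated, cfg)
    vals = np.asarray(subject_mr.values, dtype=float)
    if body_threshold is None:
        body_threshold = 0.5 * float(np.percentile(vals, 75))
    skin = body_contour(subject_mr, body_threshold)
    if air_threshold is None:
        body_median = float(np.median(vals[skin])) if skin.any() else float(np.median(vals))
        air_threshold = 0.25 * body_median
    air = threshold_air(subject_mr, fused["rectum"], air_threshold)
    masks = dict(fused.masks)
    masks["air"] = air
    masks["skin"] = skin
    return ROIMaskSet(masks), propagated


def dice_report(predicted: ROIMaskSet, truth: ROIMaskSet, roi_names=None) -> dict[str, float]:
    names = roi_names or [n for n in predicted.roi_names if n in truth.roi_names]
    require_same = predicted.shape == truth.shape
    if not require_same:
        raise ValueError("mask sets must share one grid")
    return {name: dice(predicted[name], truth[name]) for name in names}
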