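"""Atlas library: voxel-matched MR-CT pairs with ROI masks.

Each library entry donates Hounsfield-unit information during synthesis: its
MR is the registration target, its CT (the planning CT deformed onto the MR
grid by the pairing DVF) is the HU donor, and its six binary ROI masks (air,
bone, bladder, prostate, rectum, skin) drive the voxel selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .registration import DVF, DeformableParams, apply_dvf, apply_dvf_mask, register_deformable
from .volume import Volume3D, require_same_grid

STANDARD_ROI_NAMES = ("air", "bone", "bladder", "prostate", "rectum", "skin")


@dataclass
class ROIMaskSet:
    """Named binary masks sharing one grid."""

    masks: dict[str, np.ndarray]

    def __post_init__(self):
        if not self.masks:
            raise ValueError("ROIMaskSet needs at least one mask")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"all masks must share one grid, got shapes {shapes}")
        self.masks = {name: np.asarray(m, dtype=bool) for name, m in self.masks.items()}

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.masks]
        if missing:
            raise KeyError(f"missing ROI masks: {missing}")

    def warp(self, dvf: DVF) -> "ROIMaskSet":
        return ROIMaskSet({name: apply_dvf_mask(m, dvf) for name, m in self.masks.items()})


def make_roi_mask(label_volume: np.ndarray, roi_code: int) -> np.ndarray:
    """Binary mask of one integer code: mask(p)=1 iff label(p)=roi_code."""
    label_volume = np.asarray(label_volume)
    mask = label_volume == roi_code
    if not mask.any():
        import warnings

        warnings.warn(f"ROI code {roi_code} not present in label volume; empty mask",
                      stacklevel=2)
    return mask


def masks_from_labels(label_volume: np.ndarray, code_table: dict[str, list[int]]) -> ROIMaskSet:
    """Build an ROIMaskSet from an integer label map.

    ``code_table`` maps roi name -> list of label codes it comprises (a single
    anatomical ROI may span several codes, e.g. bone = pelvic + femoral).
    """
    label_volume = np.asarray(label_volume)
    return ROIMaskSet(
        {name: np.isin(label_volume, codes) for name, codes in code_table.items()}
    )


@dataclass
class AtlasEntry:
    atlas_mr: Volume3D
    atlas_ct: Volume3D
    roi_masks: ROIMaskSet
    atlas_dvf: DVF | None = None
    entry_id: str = ""

    def __post_init__(self):
        require_same_grid(self.atlas_mr, self.atlas_ct, "atlas MR and CT")
        if self.roi_masks.shape != self.atlas_mr.values.shape:
            raise ValueError("ROI masks must live on the atlas MR grid")


@dataclass
class AtlasLibrary:
    entries: list[AtlasEntry]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.entries:
            raise ValueError("atlas library needs at least one entry")
        name_sets = {e.roi_masks.roi_names for e in self.entries}
        if len({frozenset(s) for s in name_sets}) > 1:
            raise ValueError(f"entries expose different ROI name sets: {name_sets}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def roi_names(self) -> tuple[str, ...]:
        return self.entries[0].roi_masks.roi_names


def build_atlas_entry(
    mr: Volume3D,
    p_ct: Volume3D,
    rois: ROIMaskSet,
    dvf: DVF | None = None,
    entry_id: str = "",
    required_rois=STANDARD_ROI_NAMES,
    pairing_params: DeformableParams | None = None,
) -> AtlasEntry:
    """Pair a planning CT with its MR: deform the CT onto the MR grid.

    If no pairing DVF is supplied, one is estimated with the cross-modality
    deformable backend. ROI masks are resampled (nearest) to the MR grid when
    they live elsewhere.
    """
    rois.require(required_rois)
    if dvf is None:
        params = pairing_params or DeformableParams(method="bspline_mi")
        dvf = register_deformable(mr, p_ct, params)
    atlas_ct = apply_dvf(p_ct, dvf, interpolation="linear")
    if rois.shape != mr.values.shape:
        raise ValueError("ROI masks must be provided on the MR grid")
    return AtlasEntry(mr, atlas_ct, rois, dvf, entry_id)


# ---------------------------------------------------------------------------
# Persistence: library/manifest.json + library/<id>/{mr,ct,labels,dvf}
# ---------------------------------------------------------------------------

def save_library(lib: AtlasLibrary, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    roi_names = list(lib.roi_names)
    entries_meta = []
    for e in lib.entries:
        entry_dir = path / e.entry_id
        entry_dir.mkdir(exist_ok=True)
        e.atlas_mr.save(entry_dir / "mr.nii.gz")
        e.atlas_ct.save(entry_dir / "ct.nii.gz")
        # masks as one integer bitfield-free label volume is lossy when ROIs
        # overlap (air inside rectum), so each mask is stored separately
        for name in roi_names:
            Volume3D(
                e.roi_masks[name].astype(np.uint8),
                e.atlas_mr.spacing_mm,
                e.atlas_mr.origin_mm,
                "MR",
            ).save(entry_dir / f"mask_{name}.nii.gz")
        if e.atlas_dvf is not None:
            e.atlas_dvf.save(entry_dir / "dvf.nii.gz")
        entries_meta.append({"id": e.entry_id, "has_dvf": e.atlas_dvf is not None})
    manifest = {
        "roi_names": roi_names,
        "entries": entries_meta,
        "meta": lib.manifest,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_library(path: str | Path) -> AtlasLibrary:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
        roi_names = manifest["roi_names"]
        entries_meta = manifest["entries"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"corrupt library manifest {manifest_path}: {exc}") from exc
    entries = []
    for em in entries_meta:
        entry_dir = path / em["id"]
        for fname in ["mr.nii.gz", "ct.nii.gz"]:
            if not (entry_dir / fname).exists():
                raise FileNotFoundError(f"library entry file missing: {entry_dir / fname}")
        mr = Volume3D.load(entry_dir / "mr.nii.gz", "MR")
        ct = Volume3D.load(entry_dir / "ct.nii.gz", "CT")
        masks = {}
        for name in roi_names:
            mpath = entry_dir / f"mask_{name}.nii.gz"
            if not mpath.exists():
                raise FileNotFoundError(f"library entry file missing: {mpath}")
            masks[name] = Volume3D.load(mpath, "MR").values > 0.5
        dvf = DVF.load(entry_dir / "dvf.nii.gz") if em.get("has_dvf") else None
        entries.append(AtlasEntry(mr, ct, ROIMaskSet(masks), dvf, em["id"]))
    return AtlasLibrary(entries, manifest.get("meta", {}))
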