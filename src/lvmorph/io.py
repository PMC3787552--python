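"""Readers and writers for the package's on-disk formats.

Images travel as NIfTI (.nii / .nii.gz) with the axial spacing
(thickness + gap) in the header zooms, plus a small JSON sidecar
(``<stem>.json``) carrying what NIfTI cannot: the thickness/gap split,
venc and cardiac period for flow series, seeds and free-form metadata.
Cohort tables are plain CSV with columns ``group,lva_cm2,lvv_ml``; flow
curves are CSV with ``phase,time_s,flow_ml_s``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .flowquant import FlowCurve, FlowSeries
from .image import ImageVolume, VoiMask

__all__ = [
    "sidecar_path",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_flow_series",
    "read_flow_series",
    "write_flow_curve",
    "read_flow_curve",
    "write_cohort",
    "read_cohort",
]


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _affine(dx: float, dy: float, dz: float) -> np.ndarray:
    return np.diag([dx, dy, dz, 1.0])


def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file: {p}")
    try:
        img = nib.load(str(p))
        img.get_fdata()  # force the read so corruption surfaces here
    except Exception as exc:  # nibabel raises a zoo of types on corrupt input
        raise IOError(f"cannot read NIfTI {p}: {exc}") from exc
    return img


def write_image(vol: ImageVolume, path: str | Path, extra_meta: dict | None = None) -> None:
    """Write an :class:`ImageVolume` as NIfTI plus its JSON sidecar."""
    dx, dy = vol.pixel_size
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(dx, dy, vol.slice_spacing))
    img.header.set_zooms((dx, dy, vol.slice_spacing))
    nib.save(img, str(path))
    meta = {
        "pixel_size_mm": [dx, dy],
        "slice_thickness_mm": vol.thickness,
        "slice_gap_mm": vol.gap,
        **vol.meta,
        **(extra_meta or {}),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_image(path: str | Path) -> ImageVolume:
    """Read a NIfTI volume; geometry from the sidecar when present, else the header.

    Without a sidecar the axial zoom is taken as the slice thickness with a
    zero gap.  Missing or nonpositive zooms are a hard error — isotropy is
    never silently assumed.
    """
    img = _load_nifti(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(f"expected a 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise IOError(f"invalid voxel spacing in header: {zooms}")
    sp = sidecar_path(path)
    meta: dict = {}
    if sp.exists():
        meta = json.loads(sp.read_text())
        dx, dy = meta.get("pixel_size_mm", zooms[:2])
        thickness = meta["slice_thickness_mm"]
        gap = meta.get("slice_gap_mm", 0.0)
        if abs((thickness + gap) - zooms[2]) > 1e-3:
            raise IOError(
                f"sidecar thickness+gap {thickness + gap} disagrees with header zoom {zooms[2]}"
            )
    else:
        dx, dy, thickness, gap = zooms[0], zooms[1], zooms[2], 0.0
    extra = {
        k: v for k, v in meta.items()
        if k not in ("pixel_size_mm", "slice_thickness_mm", "slice_gap_mm")
    }
    return ImageVolume(data, (float(dx), float(dy)), float(thickness), float(gap), meta=extra)


def write_mask(mask: VoiMask, vol: ImageVolume, path: str | Path) -> None:
    """Write a binary mask as uint8 NIfTI on its image's grid."""
    if mask.data.shape != vol.shape:
        raise ValidationError("mask and image are not congruent")
    dx, dy = vol.pixel_size
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(dx, dy, vol.slice_spacing))
    nib.save(img, str(path))
    sidecar_path(path).write_text(json.dumps({"provenance": mask.provenance}, indent=2) + "\n")


def read_mask(path: str | Path) -> VoiMask:
    img = _load_nifti(path)
    provenance = "levelset"
    sp = sidecar_path(path)
    if sp.exists():
        provenance = json.loads(sp.read_text()).get("provenance", provenance)
    return VoiMask(np.asarray(img.dataobj) > 0, provenance=provenance)


def write_flow_series(series: FlowSeries, path: str | Path) -> None:
    """Phase stack as 3D NIfTI (phase axis third) + sidecar (venc, period)."""
    dx, dy = series.pixel_size
    img = nib.Nifti1Image(series.phases.astype(np.float32), _affine(dx, dy, 1.0))
    nib.save(img, str(path))
    meta = {
        "venc_cm_s": series.venc,
        "cardiac_period_s": series.period,
        "pixel_size_mm": [dx, dy],
        **series.meta,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_flow_series(path: str | Path) -> FlowSeries:
    img = _load_nifti(path)
    sp = sidecar_path(path)
    if not sp.exists():
        raise IOError(f"flow series {path} has no JSON sidecar (venc and period required)")
    meta = json.loads(sp.read_text())
    try:
        venc = meta["venc_cm_s"]
        period = meta["cardiac_period_s"]
        dx, dy = meta["pixel_size_mm"]
    except KeyError as exc:
        raise IOError(f"flow sidecar {sp} is missing {exc}") from exc
    extra = {
        k: v for k, v in meta.items()
        if k not in ("venc_cm_s", "cardiac_period_s", "pixel_size_mm")
    }
    return FlowSeries(
        np.asarray(img.dataobj, dtype=np.float64), venc=venc,
        pixel_size=(float(dx), float(dy)), period=period, meta=extra,
    )


def write_flow_curve(curve: FlowCurve, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "phase": np.arange(curve.n_phases),
            "time_s": curve.times,
            "flow_ml_s": curve.q_ml_s,
        }
    )
    df.to_csv(path, index=False)


def read_flow_curve(path: str | Path, level: str = "aqueduct") -> FlowCurve:
    df = pd.read_csv(path)
    for col in ("time_s", "flow_ml_s"):
        if col not in df.columns:
            raise IOError(f"flow-curve CSV {path} lacks column {col!r}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise IOError("flow-curve CSV needs >= 2 phases")
    dt = float(np.diff(t).mean())
    return FlowCurve(df["flow_ml_s"].to_numpy(), dt=dt, level=level)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=["group", "lva_cm2", "lvv_ml"])


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"group", "lva_cm2", "lvv_ml"} - set(df.columns)
    if missing:
        raise IOError(f"cohort CSV {path} lacks columns {sorted(missing)}")
    return df
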