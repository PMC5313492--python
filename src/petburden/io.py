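"""File I/O: NIfTI volumes, hotspot/label/cohort CSV, result JSON.

NIfTI headers carry the voxel spacing (zooms) and origin (affine
translation).  Only axis-aligned affines are supported — a rotated or
sheared affine raises — because the in-memory model is an axis-aligned
lattice.  Masks are written as unsigned 8-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .imaging import BoneMask, ImageVolume, IndexResult, PetburdenError, SUVMap


def _geometry_from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, tuple]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise PetburdenError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-6):
        raise PetburdenError("only axis-aligned NIfTI affines are supported")
    spacing = tuple(float(abs(d)) for d in np.diag(rot))
    origin = tuple(float(o) for o in affine[:3, 3])
    return data, spacing, origin


def _affine(spacing_mm: tuple, origin_mm: tuple) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing_mm)
    aff[:3, 3] = origin_mm
    return aff


def load_suv(path: str | Path) -> SUVMap:
    data, spacing, origin = _geometry_from_nifti(nib.load(str(path)))
    return SUVMap(np.asarray(data, dtype=np.float64), spacing, origin)


def load_bone_mask(path: str | Path) -> BoneMask:
    data, spacing, origin = _geometry_from_nifti(nib.load(str(path)))
    return BoneMask(np.asarray(data), spacing, origin)


def load_ct(path: str | Path) -> ImageVolume:
    data, spacing, origin = _geometry_from_nifti(nib.load(str(path)))
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; masks as uint8, everything else float32."""
    if isinstance(volume, BoneMask):
        data = volume.values.astype(np.uint8)
    else:
        data = volume.values.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(volume.spacing_mm, volume.origin_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_labels_csv(path: str | Path) -> dict[int, str]:
    """Manual-classification file: columns hotspot_id, label."""
    df = pd.read_csv(path)
    for col in ("hotspot_id", "label"):
        if col not in df.columns:
            raise PetburdenError(f"labels file missing column {col!r}")
    if df["hotspot_id"].duplicated().any():
        dupes = df.loc[df["hotspot_id"].duplicated(), "hotspot_id"].tolist()
        raise PetburdenError(f"duplicate hotspot_id in labels file: {dupes}")
    return {int(r.hotspot_id): str(r.label) for r in df.itertuples()}


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Cohort table: patient_id, biomarker columns, time_years, event."""
    from .survival import validate_cohort

    df = pd.read_csv(path)
    return validate_cohort(df)


def write_index_json(
    result: IndexResult,
    path: str | Path,
    *,
    inputs: dict[str, str | Path] | None = None,
    config: dict | None = None,
) -> None:
    """IndexResult JSON with tool version and input checksums (provenance)."""
    payload = result.to_dict()
    payload["tool_version"] = __version__
    if inputs:
        payload["input_checksums"] = {
            name: sha256_of(p) for name, p in inputs.items() if Path(p).exists()
        }
    if config:
        payload["config"] = config
    Path(path).write_text(json.dumps(payload, indent=2))
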