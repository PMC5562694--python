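"""Reading and writing volumes, masks, feature tables, score reports and ROI images.

NIfTI is the canonical on-disk volume format. In memory the package indexes
arrays ``(z, y, x)``; on disk NIfTI stores ``(x, y, z)``, so arrays are
transposed at the boundary and spacing is carried in the affine. A DICOM
series directory can be read as an import path and is converted immediately.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .types import CTVolume, FeatureVector, RegionBox, SegmentationMask


# ---------------------------------------------------------------- volumes

def read_volume(path: str) -> CTVolume:
    """Read a NIfTI file (or a DICOM series directory) into a CTVolume.

    Intensities are returned with the header scale slope/intercept applied
    and no further rescaling.
    """
    if os.path.isdir(path):
        return _read_dicom_series(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D: {path}")
    # on disk (x, y, z) -> memory (z, y, x)
    intensities = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return CTVolume(intensities=intensities, spacing_mm=spacing, origin_mm=origin)


def write_volume(vol: CTVolume, path: str) -> None:
    """Write a CTVolume as NIfTI with header spacing equal to ``vol.spacing_mm``."""
    data = np.transpose(vol.intensities, (2, 1, 0))  # (z,y,x) -> (x,y,z)
    sz, sy, sx = vol.spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    if vol.origin_mm is not None:
        affine[:3, 3] = np.asarray(vol.origin_mm)[::-1]
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, path)


def _read_dicom_series(dirpath: str) -> CTVolume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(dirpath)
    if not files:
        raise FileNotFoundError(f"no DICOM series found in {dirpath}")
    reader.SetFileNames(files)
    img = reader.Execute()
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D series, got {arr.ndim}D")
    sx, sy, sz = img.GetSpacing()
    return CTVolume(intensities=arr, spacing_mm=(float(sz), float(sy), float(sx)))


def write_mask(mask: SegmentationMask, grid_shape: Sequence[int],
               spacing_mm: Sequence[float], path: str) -> None:
    """Write a box-local mask embedded in its full grid as a 0/1 NIfTI."""
    full = mask.to_full_grid(grid_shape).astype(np.uint8)
    write_volume(CTVolume(full, tuple(spacing_mm)), path)


def read_mask(path: str, box: RegionBox) -> SegmentationMask:
    vol = read_volume(path)
    return SegmentationMask.from_full_grid(vol.intensities > 0, box)


# ---------------------------------------------------------------- feature tables

def write_feature_table(rows: Sequence[Tuple[str, FeatureVector]], path: str,
                        feature_names: Sequence[str] | None = None) -> None:
    """Write (id, FeatureVector) rows as CSV with one header row of names.

    All vectors must share the same ordered feature names. An empty row list
    writes a header-only file (``feature_names`` then supplies the header;
    without it only the id column is written).
    """
    if rows:
        names = rows[0][1].names
        for rid, fv in rows:
            if fv.names != names:
                raise ValueError(f"inconsistent feature names in row {rid!r}")
        df = pd.DataFrame([fv.values for _, fv in rows],
                          index=[rid for rid, _ in rows], columns=list(names))
    else:
        df = pd.DataFrame(columns=list(feature_names or []))
    df.index.name = "id"
    df.to_csv(path, float_format="%.12g")


def read_feature_table(path: str, bank_id: str = "SL") -> List[Tuple[str, FeatureVector]]:
    df = pd.read_csv(path, index_col=0)
    names = tuple(df.columns)
    return [(str(idx), FeatureVector(names, row.to_numpy(dtype=float), bank_id))
            for idx, row in df.iterrows()]


# ---------------------------------------------------------------- score reports

def write_scores(scores: Dict[str, float], path: str, meta: Dict | None = None) -> None:
    """Per-lesion score report: JSON mapping lesion id -> likelihood of T0."""
    payload = {"scores": {k: float(v) for k, v in scores.items()}}
    if meta:
        payload["meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_scores(path: str) -> Dict[str, float]:
    with open(path) as fh:
        payload = json.load(fh)
    return {k: float(v) for k, v in payload["scores"].items()}


# ---------------------------------------------------------------- ROI images

def write_roi_png(patch: np.ndarray, path: str) -> None:
    """Export a paired ROI as an 8-bit window-scaled PNG (inspection only)."""
    import imageio.v3 as iio

    patch = np.asarray(patch, dtype=float)
    lo, hi = patch.min(), patch.max()
    scaled = np.zeros_like(patch) if hi <= lo else (patch - lo) / (hi - lo)
    iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
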