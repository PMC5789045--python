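"""Reading and writing knee ROIs: 16-bit PNG/TIFF with JSON sidecars, DICOM.

Conventions
-----------
* ``<stem>.png`` / ``<stem>.tif`` holds 16-bit pixels; ``<stem>.json`` holds
  ``{"spacing_mm": float, "side": "left"|"right", "kl_grade": int|null}``.
* A bounding-box table for real radiographs is a CSV with one row per knee:
  ``image, side, x, y, width, height`` in pixels, 0-based, half-open.
* DICOM files are read with pydicom; the physical spacing comes from the
  ImagerPixelSpacing tag (PixelSpacing as fallback).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import KneeROI

__all__ = ["write_roi", "read_roi", "read_dicom_roi", "load_bbox_table",
           "crop_bbox", "load_roi_dir"]


def write_roi(roi: KneeROI, path: str | Path) -> Path:
    """Write pixels as a 16-bit image plus a JSON metadata sidecar."""
    path = Path(path)
    iio.imwrite(path, np.asarray(roi.pixels, dtype=np.uint16))
    sidecar = {
        "spacing_mm": roi.spacing_mm,
        "side": roi.side,
        "kl_grade": roi.kl_grade,
        "source_id": roi.source_id or path.stem,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_roi(path: str | Path) -> KneeROI:
    """Read a 16-bit image and its ``.json`` sidecar back into a ROI."""
    path = Path(path)
    pixels = np.asarray(iio.imread(path)).astype(np.uint16)
    meta = json.loads(path.with_suffix(".json").read_text())
    return KneeROI(pixels=pixels, spacing_mm=float(meta["spacing_mm"]),
                   side=meta["side"], kl_grade=meta.get("kl_grade"),
                   source_id=meta.get("source_id", path.stem))


def read_dicom_roi(path: str | Path, side: str,
                   kl_grade: int | None = None) -> KneeROI:
    """Read a DICOM knee image; spacing from ImagerPixelSpacing."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    spacing = getattr(ds, "ImagerPixelSpacing", None) or getattr(
        ds, "PixelSpacing", None)
    if spacing is None:
        raise ValueError(f"{path}: no ImagerPixelSpacing/PixelSpacing tag")
    return KneeROI(pixels=np.asarray(ds.pixel_array), spacing_mm=float(spacing[0]),
                   side=side, kl_grade=kl_grade, source_id=Path(path).stem)


def load_bbox_table(path: str | Path) -> pd.DataFrame:
    """Load the knee bounding-box CSV (image, side, x, y, width, height)."""
    df = pd.read_csv(path)
    required = {"image", "side", "x", "y", "width", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bounding-box table lacks columns: {sorted(missing)}")
    return df


def crop_bbox(full_image: np.ndarray, row: pd.Series, spacing_mm: float,
              kl_grade: int | None = None) -> KneeROI:
    """Cut one knee ROI out of a full radiograph using a bbox table row."""
    x, y, w, h = (int(row[k]) for k in ("x", "y", "width", "height"))
    crop = np.asarray(full_image)[y : y + h, x : x + w]
    return KneeROI(pixels=crop, spacing_mm=spacing_mm, side=row["side"],
                   kl_grade=kl_grade, source_id=str(row.get("image", "")))


def load_roi_dir(directory: str | Path,
                 manifest: str | Path | None = None) -> list[KneeROI]:
    """Load every ROI in a directory, optionally ordered by a manifest CSV."""
    directory = Path(directory)
    if manifest is not None:
        ids = pd.read_csv(manifest)["source_id"].tolist()
        paths = []
        for sid in ids:
            for ext in (".png", ".tif", ".tiff"):
                p = directory / f"{sid}{ext}"
                if p.exists():
                    paths.append(p)
                    break
            else:
                raise FileNotFoundError(f"no image for manifest id {sid}")
    else:
        paths = sorted(p for p in directory.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
    return [read_roi(p) for p in paths]
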