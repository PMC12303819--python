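"""Reading and writing intensity images, label masks and per-nucleus catalogs.

Images and masks travel as TIFF files or Zarr arrays; catalogs as Parquet or
CSV.  Labels are preserved exactly on I/O — no relabeling or compaction ever
happens here.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
import zarr
from skimage import measure

from .types import NucleusRecord, validate_image, validate_mask

Kind = Literal["tiff", "zarr"]

CATALOG_BASE_COLUMNS = [
    "method",
    "label",
    "centroid_row",
    "centroid_col",
    "area_px",
    "orientation_rad",
]


def _infer_kind(path: str | os.PathLike, kind: Kind | None) -> Kind:
    if kind is not None:
        if kind not in ("tiff", "zarr"):
            raise ValueError(f"unknown kind {kind!r}; expected 'tiff' or 'zarr'")
        return kind
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".zarr", ""):
        return "zarr"
    raise ValueError(f"cannot infer format from {path!r}; pass kind explicitly")


def _load_array(path: str | os.PathLike, kind: Kind) -> np.ndarray:
    if kind == "tiff":
        if not Path(path).exists():
            raise FileNotFoundError(str(path))
        return np.asarray(tifffile.imread(path))
    if not Path(path).exists():
        raise FileNotFoundError(str(path))
    return np.asarray(zarr.open_array(str(path), mode="r")[...])


def _select_plane(arr: np.ndarray, channel: int | None) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"array has shape {arr.shape}: a channel index is required "
                "to select a single 2D plane"
            )
        # channel axis is whichever is smallest -- (C, H, W) or (H, W, C)
        axis = int(np.argmin(arr.shape))
        return np.take(arr, channel, axis=axis)
    raise ValueError(f"cannot interpret array of shape {arr.shape} as a 2D plane")


def read_image(
    path: str | os.PathLike,
    kind: Kind | None = None,
    channel: int | None = None,
) -> np.ndarray:
    """Read a single-channel 2D intensity image from TIFF or Zarr.

    Multi-channel sources require an explicit ``channel`` index; the result
    is always a finite 2D float array.
    """
    arr = _select_plane(_load_array(path, _infer_kind(path, kind)), channel)
    return validate_image(np.asarray(arr, dtype=np.float64))


def read_mask(
    path: str | os.PathLike,
    kind: Kind | None = None,
    channel: int | None = None,
) -> np.ndarray:
    """Read a 2D integer instance label mask from TIFF or Zarr."""
    arr = _select_plane(_load_array(path, _infer_kind(path, kind)), channel)
    return validate_mask(arr)


def write_image(
    img: np.ndarray, path: str | os.PathLike, kind: Kind | None = None
) -> Path:
    """Write a 2D intensity image as TIFF or a Zarr array."""
    img = validate_image(img)
    return _write_array(np.asarray(img, dtype=np.float32), path, kind)


def write_mask(
    mask: np.ndarray, path: str | os.PathLike, kind: Kind | None = None
) -> Path:
    """Write a label mask; a read round trip is integer-exact."""
    mask = validate_mask(mask)
    return _write_array(np.asarray(mask, dtype=np.int32), path, kind)


def _write_array(arr: np.ndarray, path: str | os.PathLike, kind: Kind | None) -> Path:
    path = Path(path)
    kind = _infer_kind(path, kind)
    path.parent.mkdir(parents=True, exist_ok=True)
    if kind == "tiff":
        tifffile.imwrite(path, arr)
    else:
        z = zarr.create_array(
            store=str(path), shape=arr.shape, dtype=arr.dtype, overwrite=True
        )
        z[...] = arr
    return path


def extract_records(mask: np.ndarray, method: str = "") -> list[NucleusRecord]:
    """One :class:`NucleusRecord` per distinct positive label in the mask.

    Centroid is the mean of member pixel coordinates, area the member pixel
    count; an empty mask yields an empty list.
    """
    mask = validate_mask(mask)
    records = []
    for rp in measure.regionprops(mask):
        records.append(
            NucleusRecord(
                label=int(rp.label),
                method=method,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area=int(rp.area),
                bbox=tuple(int(b) for b in rp.bbox),
            )
        )
    return records


def build_catalog(
    mask: np.ndarray,
    method: str,
    channels: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-nucleus property table: centroid, area, orientation and the mean
    intensity over member pixels in each named channel."""
    mask = validate_mask(mask)
    channels = channels or {}
    for name, ch in channels.items():
        if np.asarray(ch).shape != mask.shape:
            raise ValueError(f"channel {name!r} shape differs from mask shape")
    rows = []
    for rp in measure.regionprops(mask):
        row = {
            "method": method,
            "label": int(rp.label),
            "centroid_row": float(rp.centroid[0]),
            "centroid_col": float(rp.centroid[1]),
            "area_px": int(rp.area),
            "orientation_rad": float(rp.orientation),
        }
        rr, cc = rp.coords[:, 0], rp.coords[:, 1]
        for name, ch in channels.items():
            row[f"mean_intensity_{name}"] = float(np.mean(np.asarray(ch)[rr, cc]))
        rows.append(row)
    columns = CATALOG_BASE_COLUMNS + [f"mean_intensity_{n}" for n in channels]
    return pd.DataFrame(rows, columns=columns)


def write_catalog(catalog: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a catalog as Parquet (default) or CSV, by file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".csv":
        catalog.to_csv(path, index=False)
    else:
        catalog.to_parquet(path, index=False)
    return path


def read_catalog(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    return pd.read_parquet(path)


def records_to_frame(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (one row per nucleus)."""
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "label": r.label,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "area_px": r.area,
                "equivalent_radius_px": r.equivalent_radius,
            }
            for r in records
        ]
    )
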