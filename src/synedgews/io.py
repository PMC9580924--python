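"""TIFF and table I/O.

Images come in as single- or multi-page grayscale TIFF (8/16-bit integer or
float) and are handled internally as float arrays; label maps go out as
16-bit single-page TIFF; tables go out as CSV and XLSX with identical
content and a deterministic column order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
import tifffile

from .config import ParameterError
from .imgsegrout import ImageStack

__all__ = ["read_image", "read_stack", "write_image", "write_label_map",
           "export_tables"]


class ImageIOError(IOError):
    pass


def _load(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise ImageIOError(f"cannot read TIFF {path}: {exc}") from exc
    return np.asarray(arr)


def read_image(path) -> np.ndarray:
    """Read one single-page grayscale TIFF as a float 2D array."""
    arr = _load(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ImageIOError(f"{path}: RGB(A) images are not supported; "
                           "provide single-channel grayscale TIFF")
    if arr.ndim != 2:
        raise ImageIOError(f"{path}: expected a single-page 2D image, got shape {arr.shape}")
    return arr.astype(float)


def read_stack(path, frame_interval_s: float = 1.0) -> ImageStack:
    """Read a multi-page grayscale TIFF as an ImageStack (frame order kept)."""
    arr = _load(path)
    if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2])):
        raise ImageIOError(f"{path}: RGB stacks are not supported")
    if arr.ndim != 3:
        raise ImageIOError(f"{path}: expected a multi-page stack, got shape {arr.shape}")
    return ImageStack(frames=arr.astype(float), frame_interval_s=frame_interval_s)


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image))


def write_label_map(path, label_map: np.ndarray) -> None:
    """Write a label map as 16-bit single-page TIFF."""
    arr = np.asarray(label_map)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ParameterError("label map does not fit into 16-bit")
    tifffile.imwrite(Path(path), arr.astype(np.uint16))


def export_tables(tables: Dict[str, pd.DataFrame], out_dir, stem: str,
                  formats=("csv", "xlsx")) -> list:
    """Write each table as ``<stem>_<name>.csv`` and one ``<stem>.xlsx``
    workbook with one sheet per table; contents are identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        for name, df in tables.items():
            p = out / f"{stem}_{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
    if "xlsx" in formats:
        p = out / f"{stem}.xlsx"
        with pd.ExcelWriter(p, engine="openpyxl") as xl:
            for name, df in tables.items():
                df.to_excel(xl, sheet_name=name[:31], index=False)
        written.append(p)
    return written
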