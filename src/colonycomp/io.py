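"""Readers and writers for the pipeline's on-disk formats.

Label maps are integer rasters, one lineage id per pixel: plain-text
matrices (``.txt``/``.dat``, whitespace separated) or 16-bit PGM/PNG images.
Founder tables are CSV with 0-based, row-major lattice coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

_TEXT_SUFFIXES = {".txt", ".dat"}
_IMAGE_SUFFIXES = {".pgm", ".png"}


def write_label_map(label_map: np.ndarray, path) -> None:
    """Write an integer label map as plain text or a 16-bit image."""
    path = Path(path)
    arr = np.asarray(label_map)
    if path.suffix in _TEXT_SUFFIXES:
        np.savetxt(path, arr, fmt="%d")
    elif path.suffix in _IMAGE_SUFFIXES:
        if arr.min() < 0 or arr.max() > 65535:
            raise ValueError("label ids must fit in 16 bits for image output")
        Image.fromarray(arr.astype(np.uint16)).save(path)
    else:
        raise ValueError(f"unsupported label-map format {path.suffix!r}")


def read_label_map(path) -> np.ndarray:
    """Read a label map written by :func:`write_label_map`."""
    path = Path(path)
    if path.suffix in _TEXT_SUFFIXES:
        return np.loadtxt(path, dtype=np.int32, ndmin=2)
    if path.suffix in _IMAGE_SUFFIXES:
        return np.asarray(Image.open(path), dtype=np.int32)
    raise ValueError(f"unsupported label-map format {path.suffix!r}")


def write_founders(founders: pd.DataFrame, path) -> None:
    founders.to_csv(path, index=False)


def read_founders(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "lineage_id" not in df.columns:
        raise ValueError("founder table must have a lineage_id column")
    if not ({"x", "y"} <= set(df.columns) or {"row", "col"} <= set(df.columns)):
        raise ValueError("founder table needs x/y or row/col columns")
    return df


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_dissimilarity(ids, values: np.ndarray, path) -> None:
    """Square distance matrix as CSV, header and index = item ids."""
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path)


def read_dissimilarity(path) -> tuple[list, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return list(df.columns), df.to_numpy(dtype=float)
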