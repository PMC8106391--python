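"""Raster stack I/O: multiband TIFF with a time-index sidecar.

A :class:`~ecosens.stacks.MonthlyStack` is stored as one multiband TIFF
(one band per month, float64, nodata encoded as NaN) whose
ImageDescription tag carries a JSON payload (geotransform, variable tag,
time index). A CSV sidecar ``<stem>_time_index.csv`` with ``band, year,
month`` columns accompanies every stack and takes precedence on read, so
stacks remain usable from tools that drop TIFF description tags.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stacks import IDENTITY_TRANSFORM, MonthlyStack

logger = logging.getLogger(__name__)

__all__ = ["read_stack", "write_stack", "weights_rgb", "sidecar_path"]


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_time_index.csv")


def write_stack(stack: MonthlyStack, path: str | Path) -> Path:
    """Write a stack as multiband TIFF + time-index CSV sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.masked()  # nodata as NaN
    meta = {
        "geotransform": list(stack.geotransform),
        "variable_tag": stack.variable_tag,
        "time_index": [[y, m] for y, m in stack.time_index],
    }
    tifffile.imwrite(path, data, description=json.dumps(meta))
    pd.DataFrame(
        {
            "band": np.arange(1, stack.n_time + 1),
            "year": [y for y, _ in stack.time_index],
            "month": [m for _, m in stack.time_index],
        }
    ).to_csv(sidecar_path(path), index=False)
    return path


def read_stack(path: str | Path) -> MonthlyStack:
    """Read a stack written by :func:`write_stack`.

    The sidecar CSV pairs band k with its (year, month); bands are
    reordered chronologically if the sidecar rows are shuffled. A stack
    without georeferencing metadata gets the identity transform with a
    warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None, :, :]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    side = sidecar_path(path)
    if side.exists():
        df = pd.read_csv(side)
        if len(df) != data.shape[0]:
            raise ValueError(
                f"sidecar has {len(df)} rows but TIFF has {data.shape[0]} bands"
            )
        pairs = [
            (int(b) - 1, (int(y), int(m)))
            for b, y, m in zip(df["band"], df["year"], df["month"])
        ]
    elif "time_index" in meta:
        if len(meta["time_index"]) != data.shape[0]:
            raise ValueError("time_index length does not match band count")
        pairs = [(i, (int(y), int(m))) for i, (y, m) in enumerate(meta["time_index"])]
    else:
        raise ValueError(f"no time index found for {path}")
    # chronological order, band pairing preserved
    pairs.sort(key=lambda p: p[1][0] * 12 + p[1][1])
    order = [b for b, _ in pairs]
    time_index = [ym for _, ym in pairs]
    gt = tuple(meta.get("geotransform", ()))
    if len(gt) != 6:
        warnings.warn(f"{path}: missing georeferencing; using identity transform")
        gt = IDENTITY_TRANSFORM
    return MonthlyStack(
        values=np.asarray(data[order], dtype=float),
        time_index=time_index,
        geotransform=gt,
        variable_tag=str(meta.get("variable_tag", "")),
    )


def weights_rgb(weights) -> np.ndarray:
    """Climate weights as a 3-band byte composite.

    Channel convention: temperature red, TVDI green, precipitation blue;
    each normalized weight scaled by 255 and rounded. Nodata maps to 0.
    """
    norm = weights.normalized  # order (tem, pre, tvdi)
    rgb = np.stack([norm[0], norm[2], norm[1]])
    out = np.zeros(rgb.shape, dtype=np.uint8)
    ok = np.isfinite(rgb)
    out[ok] = np.rint(rgb[ok] * 255).astype(np.uint8)
    return out
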