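"""Minimal tiled-raster I/O: TIFF payload plus a JSON bounds sidecar.

Rasters are written as plain (optionally multi-band) TIFFs with a
``<name>.tif.json`` sidecar recording the lon/lat bounds and band names,
which keeps every artifact a text-inspectable pair without a heavyweight
geospatial dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_raster", "read_raster"]


def write_raster(path, array: np.ndarray, bounds, band_names=None) -> Path:
    path = Path(path)
    arr = np.asarray(array)
    tifffile.imwrite(path, arr.astype(np.float32), photometric="minisblack")
    meta = {
        "bounds": list(map(float, bounds)),
        "shape": list(arr.shape),
        "band_names": list(band_names) if band_names else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_raster(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return np.asarray(arr), meta
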