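"""Reading and writing of B-scans, masks and boundary curves.

Grayscale inputs (PNG/TIFF, 8/16-bit or float) are normalized to [0, 1] on
load; masks are written as 8-bit binary PNG (255 = fluid); float planes (T/I)
as float32 TIFF; curves as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from ._exceptions import InvalidInputError

#: minimum image extent required by the 3x9 oriented filter footprint
MIN_ROWS, MIN_COLS = 3, 9


def validate_gray(g: np.ndarray) -> np.ndarray:
    """Check a normalized grayscale B-scan and return it as float64."""
    g = np.asarray(g, dtype=np.float64)
    if g.ndim != 2:
        raise InvalidInputError(f"expected a 2D grayscale image, got ndim={g.ndim}")
    if g.shape[0] < MIN_ROWS or g.shape[1] < MIN_COLS:
        raise InvalidInputError(
            f"image {g.shape} is smaller than the {MIN_ROWS}x{MIN_COLS} filter footprint")
    if not np.all(np.isfinite(g)):
        raise InvalidInputError("image contains non-finite values")
    if g.min() < 0.0 or g.max() > 1.0:
        raise InvalidInputError("image values must lie in [0, 1]; use load_gray()")
    return g


def load_gray(path: str | Path) -> np.ndarray:
    """Load a grayscale image and normalize it to [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse trivial color/alpha axes
        arr = arr[..., :3].mean(axis=-1)
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        g = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        g = arr.astype(np.float64) / 65535.0
    else:
        g = arr.astype(np.float64)
        if g.max() > 1.0:  # float image saved on an 8-bit scale
            g = g / max(g.max(), 1.0)
    return validate_gray(np.clip(g, 0.0, 1.0))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def save_float_plane(path: str | Path, plane: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(plane, dtype=np.float32))


def save_curves(path: str | Path, curves: dict) -> None:
    """Serialize {name: BoundaryCurve-or-array} as JSON arrays of row indices."""
    payload = {}
    for name, c in curves.items():
        rows = getattr(c, "rows", c)
        payload[name] = {"rows": np.asarray(rows, dtype=float).tolist(),
                         "kind": getattr(c, "kind", name)}
    Path(path).write_text(json.dumps(payload))


def load_curves(path: str | Path) -> dict:
    from .layers import BoundaryCurve

    payload = json.loads(Path(path).read_text())
    return {name: BoundaryCurve(np.asarray(d["rows"], dtype=float), d.get("kind", name))
            for name, d in payload.items()}
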