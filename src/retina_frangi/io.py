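"""Raster I/O for fundus images, masks and response maps.

Readers accept the raster formats used by the public fundus sets (TIFF,
PNG, GIF, PPM).  Integer images are rescaled to [0, 1] by their dtype range
(8-bit / 255, 16-bit / 65535); masks are any single-channel raster where a
value above half-range means foreground.
"""

from __future__ import annotations

import numpy as np
import imageio.v2 as imageio


def _to_unit(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    return np.clip(arr.astype(float), 0.0, 1.0)


def load_rgb(path) -> np.ndarray:
    """Load an RGB image as an H×W×3 float array in [0, 1]."""
    arr = imageio.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path}: expected an RGB image, got single channel")
    if arr.shape[2] == 4:      # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 channels, got {arr.shape[2]}")
    return _to_unit(arr)


def load_mask(path) -> np.ndarray:
    """Load a binary mask: foreground where the value exceeds half-range."""
    arr = imageio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return _to_unit(arr) > 0.5


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    imageio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def save_response(path, resp: np.ndarray) -> None:
    """Write a [0, 1] response map as a 16-bit PNG (round(f × 65535))."""
    arr = np.round(np.clip(resp, 0.0, 1.0) * 65535).astype(np.uint16)
    imageio.imwrite(path, arr)
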