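"""Fundus image preprocessing.

Vessels have their highest contrast against the background in the green
channel of an RGB fundus photograph, so the pipeline works on that channel
alone.  Contrast-limited adaptive histogram equalization (CLAHE) then
stretches local contrast while the clip limit keeps noise amplification
bounded.  The field of view (FOV) — the illuminated retinal disc — is either
supplied as a mask file or estimated from the red channel, which is bright
inside the disc and dark on the surrounding frame.

All images are float arrays with intensities in [0, 1], indexed (row, col).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def _check_gray(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains NaN or Inf")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return img


def extract_green(rgb: np.ndarray) -> np.ndarray:
    """Return the green channel of an H×W×3 image, verbatim.

    No rescaling is applied: the channel is already in [0, 1].
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(
            f"expected an H×W×3 RGB image, got shape {rgb.shape}"
        )
    return rgb[:, :, 1].copy()


def _tile_geometry(shape, tile_grid):
    rows, cols = tile_grid
    if rows < 1 or cols < 1:
        raise ValueError("tile_grid dimensions must be >= 1")
    h, w = shape
    th = -(-h // rows)  # ceil
    tw = -(-w // cols)
    if th < 8 or tw < 8:
        raise ValueError(
            f"image of shape {shape} too small for a {rows}×{cols} tile grid: "
            f"each tile must be at least 8×8 px, so the image must be at "
            f"least {8 * rows}×{8 * cols}"
        )
    return th, tw


def _clahe_tile_histograms(img, clip_limit=0.01, tile_grid=(8, 8), nbins=256):
    """Per-tile raw and clipped histograms (clipped = before redistribution).

    Returns (raw, clipped, quantized_padded, (th, tw)).  Exposed so the
    clip-limit contract — no clipped bin exceeds clip_limit × tile pixel
    count — can be asserted directly.
    """
    img = _check_gray(img)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    rows, cols = tile_grid
    th, tw = _tile_geometry(img.shape, tile_grid)
    h, w = img.shape
    pad = np.pad(img, ((0, rows * th - h), (0, cols * tw - w)), mode="reflect")
    q = np.minimum((pad * nbins).astype(np.int64), nbins - 1)
    tiles = q.reshape(rows, th, cols, tw).transpose(0, 2, 1, 3)
    tile_ids = np.arange(rows * cols).repeat(th * tw)
    flat = tiles.reshape(rows * cols, th * tw).ravel()
    raw = np.bincount(tile_ids * nbins + flat, minlength=rows * cols * nbins)
    raw = raw.reshape(rows, cols, nbins).astype(float)
    npix = th * tw
    clipval = max(clip_limit * npix, 1.0)
    clipped = np.minimum(raw, clipval)
    return raw, clipped, q, (th, tw)


def clahe(img: np.ndarray, clip_limit: float = 0.01,
          tile_grid: tuple[int, int] = (8, 8), nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into a ``tile_grid`` of tiles; each tile's
    histogram (``nbins`` bins over [0, 1]) is clipped at
    ``clip_limit`` × (tile pixel count), the excess is redistributed
    uniformly over all bins, and the per-tile cumulative mappings are
    bilinearly interpolated between tile centers.  A tile with at most one
    populated bin has no contrast to stretch and keeps the identity mapping.

    Output intensities lie in [0, 1].
    """
    raw, clipped, q, (th, tw) = _clahe_tile_histograms(
        img, clip_limit, tile_grid, nbins
    )
    rows, cols = raw.shape[:2]
    npix = th * tw

    hist = clipped.copy()
    excess = npix - hist.sum(axis=-1)
    hist += excess[..., None] / nbins
    cdf = np.cumsum(hist, axis=-1)
    mapping = cdf / npix

    # Degenerate tiles: single gray level -> identity (bin-center) mapping.
    identity = (np.arange(nbins) + 0.5) / nbins
    degenerate = (raw > 0).sum(axis=-1) <= 1
    mapping[degenerate] = identity

    ph, pw = q.shape
    yy = (np.arange(ph) - (th - 1) / 2.0) / th
    xx = (np.arange(pw) - (tw - 1) / 2.0) / tw
    iy0 = np.floor(yy).astype(int)
    ix0 = np.floor(xx).astype(int)
    fy = yy - iy0
    fx = xx - ix0
    iy0c = np.clip(iy0, 0, rows - 1)
    iy1c = np.clip(iy0 + 1, 0, rows - 1)
    ix0c = np.clip(ix0, 0, cols - 1)
    ix1c = np.clip(ix0 + 1, 0, cols - 1)

    fy2 = fy[:, None]
    fx2 = fx[None, :]
    out = (
        (1 - fy2) * (1 - fx2) * mapping[iy0c[:, None], ix0c[None, :], q]
        + (1 - fy2) * fx2 * mapping[iy0c[:, None], ix1c[None, :], q]
        + fy2 * (1 - fx2) * mapping[iy1c[:, None], ix0c[None, :], q]
        + fy2 * fx2 * mapping[iy1c[:, None], ix1c[None, :], q]
    )
    h, w = np.asarray(img).shape
    return np.clip(out[:h, :w], 0.0, 1.0)


def fov_from_image(rgb: np.ndarray) -> np.ndarray:
    """Estimate the field-of-view mask from the red channel.

    The retinal disc is the brightest region of the red channel; Otsu
    thresholding separates it from the dark frame, the largest connected
    component is kept and its holes are filled.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {rgb.shape}")
    red = rgb[:, :, 0]
    # Local import: segmentation depends on this module's clahe.
    from .segmentation import otsu_threshold

    full = np.ones(red.shape, dtype=bool)
    try:
        t = otsu_threshold(red, full)
    except ValueError as e:
        raise ValueError(f"cannot derive FOV mask: {e}") from e
    mask = red > t
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("cannot derive FOV mask: threshold left no foreground")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    if mask.sum() < 0.01 * mask.size:
        raise ValueError("cannot derive FOV mask: mask covers <1% of the image")
    return mask
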