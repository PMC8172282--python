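"""Oriented linear structuring elements and the improved opening.

Vessels are curvilinear, so a single fixed line element cannot match every
segment.  A bank of flat line elements is enumerated over all pixel lengths
from the minimum vessel diameter (2 px) to the maximum (12 px) and all
angles from 0° to 170° in 10° steps — 198 templates.  The improved opening
applies the grayscale opening with every template and keeps, at each pixel,
the maximum of the 198 results: bright structure that fits *some* oriented
line survives, while small bright noise that fits none is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LENGTHS = range(2, 13)
ANGLES = range(0, 180, 10)


@dataclass(frozen=True)
class StructuringElement:
    """Flat line element: Bresenham segment of ``length`` set pixels,
    centered on the origin, at ``angle`` degrees counterclockwise from the
    +x (column) axis."""

    length: int
    angle: float
    mask: np.ndarray          # 2-D bool, origin at the center pixel
    offsets: tuple            # ((dr, dc), ...) relative to the origin

    @property
    def origin(self) -> tuple[int, int]:
        return (self.mask.shape[0] // 2, self.mask.shape[1] // 2)


def make_line_se(length: int, angle: float) -> StructuringElement:
    """Rasterize a centered line segment with exactly ``length`` set pixels.

    Stepping runs along the dominant axis with the other coordinate rounded
    (half away from zero), which reproduces Bresenham's selection for lines
    through the origin.  For even lengths the extra pixel lies on the
    positive-direction side.
    """
    if not (2 <= length <= 12):
        raise ValueError(f"length must be in [2, 12], got {length}")
    if not (0 <= angle < 180):
        raise ValueError(f"angle must be in [0, 180), got {angle}")
    theta = np.deg2rad(angle)
    c, s = np.cos(theta), np.sin(theta)
    if length % 2:
        ks = np.arange(-(length // 2), length // 2 + 1)
    else:
        ks = np.arange(-(length // 2) + 1, length // 2 + 1)

    def rnd(v):
        return int(np.floor(v + 0.5))

    if abs(c) >= abs(s):                     # x-dominant (0–45°, 135–180°)
        # k is the arc index along the +direction; dx steps by sign(cosθ)
        sgn = 1 if c > 0 else -1
        pts = [(rnd(k * s / abs(c)), sgn * k) for k in ks]
    else:                                    # y-dominant (45–135°)
        pts = [(k, rnd(k * (c / s))) for k in ks]
    offsets = tuple(sorted(set((int(dy), int(dx)) for dy, dx in pts)))
    if len(offsets) != length:
        raise AssertionError("rasterization produced duplicate pixels")
    hy = max(abs(dy) for dy, _ in offsets)
    hx = max(abs(dx) for _, dx in offsets)
    mask = np.zeros((2 * hy + 1, 2 * hx + 1), dtype=bool)
    for dy, dx in offsets:
        mask[hy + dy, hx + dx] = True
    return StructuringElement(length=int(length), angle=float(angle),
                              mask=mask, offsets=offsets)


@dataclass(frozen=True)
class TemplateBank:
    """Ordered bank of line elements: lengths 2..12 × angles 0..170° step 10
    (length-major order), 198 elements in total."""

    elements: tuple

    def __len__(self):
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def dump_text(self) -> str:
        """Plain-text audit listing: length,angle,rows,cols,origin,rle-mask."""
        lines = []
        for se in self.elements:
            r, c = se.mask.shape
            flat = se.mask.ravel().astype(int)
            rle, run, cur = [], 0, flat[0]
            for v in flat:
                if v == cur:
                    run += 1
                else:
                    rle.append(f"{cur}x{run}")
                    cur, run = v, 1
            rle.append(f"{cur}x{run}")
            oy, ox = se.origin
            lines.append(
                f"{se.length},{se.angle:g},{r},{c},{oy}:{ox},{'|'.join(rle)}"
            )
        return "\n".join(lines) + "\n"


def build_template_bank() -> TemplateBank:
    """All 198 (length, angle) line elements in deterministic order."""
    return TemplateBank(elements=tuple(
        make_line_se(l, a) for l in LENGTHS for a in ANGLES
    ))


def _pad_margin(offsets):
    hy = max(abs(dy) for dy, _ in offsets)
    hx = max(abs(dx) for _, dx in offsets)
    return hy, hx


def _erode(img, offsets):
    """Flat erosion: windowed minimum over the in-bounds SE support.

    Out-of-bounds pixels are treated as +inf (domain-restriction border
    convention), which keeps erosion/dilation an adjunction so the opening
    is exactly anti-extensive and idempotent.
    """
    hy, hx = _pad_margin(offsets)
    pad = np.pad(img, ((hy, hy), (hx, hx)), mode="constant",
                 constant_values=np.inf)
    h, w = img.shape
    out = None
    for dy, dx in offsets:
        view = pad[hy + dy:hy + dy + h, hx + dx:hx + dx + w]
        out = view.copy() if out is None else np.minimum(out, view)
    return out


def _dilate(img, offsets):
    """Flat dilation: windowed maximum over the reflected in-bounds SE
    support (out-of-bounds treated as -inf)."""
    hy, hx = _pad_margin(offsets)
    pad = np.pad(img, ((hy, hy), (hx, hx)), mode="constant",
                 constant_values=-np.inf)
    h, w = img.shape
    out = None
    for dy, dx in offsets:
        view = pad[hy - dy:hy - dy + h, hx - dx:hx - dx + w]
        out = view.copy() if out is None else np.maximum(out, view)
    return out


def grayscale_open(img: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Flat grayscale opening: erosion by the element, then dilation."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if se.mask.shape[0] > img.shape[0] or se.mask.shape[1] > img.shape[1]:
        raise ValueError(
            f"structuring element {se.mask.shape} larger than image {img.shape}"
        )
    return _dilate(_erode(img, se.offsets), se.offsets)


def improved_open(img: np.ndarray, bank: TemplateBank) -> np.ndarray:
    """Pixelwise maximum of the opening over every template in the bank."""
    if len(bank) == 0:
        raise ValueError("template bank is empty")
    img = np.asarray(img, dtype=float)
    out = None
    for se in bank:
        o = grayscale_open(img, se)
        out = o if out is None else np.maximum(out, o)
    return out
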