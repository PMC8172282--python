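"""Multiscale Hessian vesselness filtering.

Vessels appear as dark curvilinear tubes on a brighter background.  At a
scale ``s`` (matched to the vessel radius, in px) the image is smoothed with
a Gaussian of standard deviation ``s`` and its second derivatives are taken
with scale-normalized derivative-of-Gaussian kernels (factor ``s²``).  The
2×2 Hessian at a vessel pixel has one large positive eigenvalue ``λ1``
(curvature across the dark tube) and one near-zero eigenvalue ``λ2``
(along the tube).  The improved vesselness response used here is

    f(p, s) = exp( − arctan(λ2/λ1)² · λ1 / d ),   d = 2s,   for λ1 > λ_floor
    f(p, s) = 0                                     otherwise,

and the multiscale output is the per-pixel maximum of f over the sampled
scales.  ``arctan(λ2/λ1)`` is the direction angle of the eigenvector pair:
it vanishes on a clean tube (response → 1) and approaches π/4 on isotropic
blobs, where the factor λ1/d then suppresses the response.  The exponent is
balanced for intensities expressed in 8-bit gray levels; images here live in
[0, 1], so the pipeline multiplies eigenvalues by a gain (default 255)
before evaluating the response.

The classic two-term vesselness (eigenvalue-ratio blobness term plus
Frobenius-norm structureness term) is provided as a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ScaleSet:
    """Sampled vessel radii ``{s_min, s_min+step, ..., s_max}`` in px."""

    s_min: float = 1.0
    s_max: float = 6.0
    step: float = 0.5

    def __post_init__(self):
        if not (0 < self.s_min <= self.s_max):
            raise ValueError("require 0 < s_min <= s_max")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    def values(self) -> np.ndarray:
        v = np.arange(self.s_min, self.s_max + self.step * 0.5, self.step)
        if v.size == 0:
            raise ValueError("empty scale set")
        return v


@dataclass
class HessianField:
    """Scale-normalized second derivatives at one scale (x = column axis)."""

    ixx: np.ndarray
    ixy: np.ndarray
    iyy: np.ndarray
    scale: float


@dataclass
class EigenField:
    """Per-pixel Hessian eigenvalues ordered by magnitude, |lam1| >= |lam2|."""

    lam1: np.ndarray
    lam2: np.ndarray


def _gauss_kernels(s: float):
    """Sampled 1-D Gaussian and its first/second derivative kernels.

    Truncated at ±4s (odd length).  The Gaussian is normalized to unit sum;
    the second-derivative kernel is mean-subtracted so it annihilates
    constants exactly and responds with exactly the analytic value on
    quadratics (up to truncation tails).
    """
    if s <= 0:
        raise ValueError("scale s must be > 0")
    r = max(1, int(round(4.0 * s)))
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(x ** 2) / (2.0 * s * s))
    g /= g.sum()
    g1 = -x / (s * s) * g
    g2 = (x ** 2 - s * s) / (s ** 4) * g
    g2 -= g2.mean()
    return g, g1, g2


def _conv_sep(img, kx, ky):
    out = ndimage.convolve1d(img, ky, axis=0, mode="reflect")
    return ndimage.convolve1d(out, kx, axis=1, mode="reflect")


def gaussian_smooth(img: np.ndarray, s: float) -> np.ndarray:
    """Convolve with an isotropic Gaussian of standard deviation ``s`` px.

    Separable convolution, reflective boundary, kernel truncated at ±4s.
    """
    img = np.asarray(img, dtype=float)
    g, _, _ = _gauss_kernels(s)
    return _conv_sep(img, g, g)


def hessian_at_scale(img: np.ndarray, s: float) -> HessianField:
    """Scale-normalized Hessian: each entry is ``s² · (∂²G_s ⊛ I)``."""
    img = np.asarray(img, dtype=float)
    g, g1, g2 = _gauss_kernels(s)
    n = s * s
    ixx = n * _conv_sep(img, g2, g)
    iyy = n * _conv_sep(img, g, g2)
    ixy = n * _conv_sep(img, g1, g1)
    return HessianField(ixx=ixx, ixy=ixy, iyy=iyy, scale=float(s))


def eigen2x2(h: HessianField) -> EigenField:
    """Closed-form eigenvalues of the symmetric 2×2 Hessian at each pixel.

    Ordered so |lam1| >= |lam2|; on magnitude ties lam1 is the larger
    signed value (a dark ridge keeps its positive eigenvalue first).
    """
    half_tr = 0.5 * (h.ixx + h.iyy)
    half_diff = 0.5 * (h.ixx - h.iyy)
    root = np.sqrt(half_diff ** 2 + h.ixy ** 2)
    hi = half_tr + root   # larger signed eigenvalue
    lo = half_tr - root
    take_hi = np.abs(hi) >= np.abs(lo)
    lam1 = np.where(take_hi, hi, lo)
    lam2 = np.where(take_hi, lo, hi)
    return EigenField(lam1=lam1, lam2=lam2)


def improved_response(e: EigenField, s: float,
                      lam_floor: float = 1e-10) -> np.ndarray:
    """Improved vesselness at one scale; output in [0, 1].

    ``f = exp(−arctan(λ2/λ1)² · λ1/(2s))`` where λ1 exceeds ``lam_floor``,
    else 0.  The floor excludes non-positive λ1 (bright ridges) and
    negligible curvature, where the formula would otherwise assign a
    response of ≈1 to flat regions.
    """
    if s <= 0:
        raise ValueError("scale s must be > 0")
    lam1 = np.asarray(e.lam1, dtype=float)
    lam2 = np.asarray(e.lam2, dtype=float)
    out = np.zeros_like(lam1)
    m = lam1 > lam_floor
    angle = np.arctan(lam2[m] / lam1[m])
    out[m] = np.exp(-(angle ** 2) * lam1[m] / (2.0 * s))
    return np.clip(out, 0.0, 1.0)


def _minmax_normalize(resp, region):
    vals = resp[region] if region is not None else resp
    lo = vals.min()
    hi = vals.max()
    if hi <= lo:
        return np.zeros_like(resp)
    return np.clip((resp - lo) / (hi - lo), 0.0, 1.0)


def multiscale_response(img: np.ndarray, scales: ScaleSet,
                        fov: np.ndarray | None = None,
                        gain: float = 255.0,
                        lam_floor: float = 1e-10,
                        normalize: bool = True,
                        return_scales: bool = False):
    """Per-pixel maximum of the improved response over the sampled scales.

    ``gain`` converts eigenvalues from [0, 1] intensity units to the 8-bit
    gray-level units the response exponent is balanced for.  ``lam_floor``
    is applied in those gained units.  With ``normalize`` the map is min–max
    rescaled to [0, 1] over the FOV (or the whole image if no FOV is given).

    With ``return_scales`` also returns the per-pixel scale attaining the
    maximum.  The response saturates at 1.0 on ideal straight tubes, so
    maxima are frequently tied across scales; ties are attributed to the
    scale with the largest λ1 (the strongest scale-normalized ridge).
    """
    img = np.asarray(img, dtype=float)
    svals = scales.values()
    best = np.full(img.shape, -np.inf)
    best_lam1 = np.full(img.shape, -np.inf)
    best_scale = np.zeros(img.shape)
    for s in svals:
        h = hessian_at_scale(img, s)
        e = eigen2x2(h)
        lam1 = gain * e.lam1
        lam2 = gain * e.lam2
        f = improved_response(EigenField(lam1, lam2), s, lam_floor=lam_floor)
        upd = (f > best) | ((f == best) & (lam1 > best_lam1))
        best = np.where(upd, f, best)
        best_lam1 = np.where(upd, lam1, best_lam1)
        best_scale = np.where(upd, s, best_scale)
    if normalize:
        region = np.asarray(fov, dtype=bool) if fov is not None else None
        best = _minmax_normalize(best, region)
    if return_scales:
        return best, best_scale
    return best


def traditional_vesselness(img: np.ndarray, scales: ScaleSet,
                           beta: float = 0.5,
                           fov: np.ndarray | None = None,
                           normalize: bool = True) -> np.ndarray:
    """Classic two-term vesselness baseline (dark-ridge convention).

    ``V = exp(−R_b²/2β²) · (1 − exp(−S²/2c²))`` for λ1 > 0, where
    ``R_b = |λ2|/|λ1|`` is the blobness ratio, ``S`` the Frobenius norm of
    the Hessian, and ``c`` half the maximum Frobenius norm at that scale.
    Multiscale maximum, then min–max normalization as for the improved map.
    """
    img = np.asarray(img, dtype=float)
    best = np.zeros(img.shape)
    for s in scales.values():
        h = hessian_at_scale(img, s)
        e = eigen2x2(h)
        frob = np.sqrt(e.lam1 ** 2 + e.lam2 ** 2)
        c = 0.5 * frob.max()
        v = np.zeros(img.shape)
        m = e.lam1 > 0
        if c > 0 and np.any(m):
            rb = np.abs(e.lam2[m]) / np.abs(e.lam1[m])
            v[m] = np.exp(-(rb ** 2) / (2.0 * beta ** 2)) * (
                1.0 - np.exp(-(frob[m] ** 2) / (2.0 * c ** 2))
            )
        best = np.maximum(best, v)
    if normalize:
        region = np.asarray(fov, dtype=bool) if fov is not None else None
        best = _minmax_normalize(best, region)
    return np.clip(best, 0.0, 1.0)
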