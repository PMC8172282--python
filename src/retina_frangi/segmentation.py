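"""Otsu thresholding and end-to-end pipeline orchestration.

The pipeline follows the method's four stages: green-channel CLAHE
enhancement, improved multiscale Hessian vesselness, improved morphological
opening, and Otsu binarization, with the result restricted to the field of
view.  Otsu's threshold maximizes the between-class variance

    g(t) = ω0 ω1 (μ0 − μ1)²

over all histogram split points t, where ω0/ω1 are the class proportions
and μ0/μ1 the class mean gray levels; the overall mean always satisfies
μ = ω0μ0 + ω1μ1.  The histogram is restricted to FOV pixels so the dark
surround cannot dominate the split.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .preprocess import extract_green, clahe, fov_from_image
from .frangi import ScaleSet, multiscale_response, traditional_vesselness
from .morphology import build_template_bank, improved_open

log = logging.getLogger(__name__)


def otsu_threshold(img: np.ndarray, region: np.ndarray,
                   bins: int = 256) -> float:
    """Between-class-variance-maximizing threshold on [0, 1] intensities.

    Exhaustive scan over the ``bins`` uniform histogram bins restricted to
    ``region``; returns the smallest maximizing threshold, placed at the
    upper edge of the last background bin.  A pixel is foreground iff its
    value is strictly greater than the returned threshold.
    """
    img = np.asarray(img, dtype=float)
    region = np.asarray(region, dtype=bool)
    if img.shape != region.shape:
        raise ValueError("image and region shapes differ")
    vals = img[region]
    if vals.size == 0:
        raise ValueError("region is empty")
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    if np.count_nonzero(counts) < 2:
        raise ValueError(
            "cannot threshold: intensities occupy fewer than 2 bins "
            "(constant image within region)"
        )
    n = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / n
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mu = cum_m[-1]
    # Split after bin k: class0 = bins 0..k, class1 = bins k+1..end.
    w0 = cum_w[:-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cum_m[:-1] / w0
        mu1 = (mu - cum_m[:-1]) / w1
    g = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(g))  # np.argmax returns the first (smallest) maximizer
    return float(edges[k + 1])


@dataclass
class PipelineConfig:
    """Tunable parameters of the segmentation pipeline.

    ``lam_floor`` and ``response_gain`` are in 8-bit gray-level units: the
    vesselness exponent is balanced for 0–255 intensities, so eigenvalues of
    the [0, 1]-ranged image are multiplied by ``response_gain`` and ridges
    with scale-normalized contrast below ``lam_floor`` gray levels are
    treated as background.
    """

    clip_limit: float = 0.01
    tile_grid: tuple[int, int] = (8, 8)
    s_min: float = 1.0
    s_max: float = 6.0
    s_step: float = 0.5
    lam_floor: float = 20.0
    response_gain: float = 255.0
    morphology: bool = True
    otsu_bins: int = 256
    fov_mode: str = "auto"      # "auto": derive from image when no mask given
    baseline: bool = False      # use the classic two-term vesselness instead

    def scales(self) -> ScaleSet:
        return ScaleSet(self.s_min, self.s_max, self.s_step)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.tile_grid, list):
            cfg.tile_grid = tuple(cfg.tile_grid)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["tile_grid"] = list(self.tile_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class SegmentationResult:
    mask: np.ndarray
    threshold: float | None
    response: np.ndarray
    enhanced: np.ndarray
    fov: np.ndarray
    timings: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage(name, timings, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(name, e) from e
    dt = time.perf_counter() - t0
    timings[name] = dt
    log.info("stage %-12s %.3f s", name, dt)
    return out


def segment_detailed(rgb: np.ndarray, fov: np.ndarray | None = None,
                     cfg: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full pipeline and keep intermediates.

    Order: green → CLAHE → vesselness (improved, or classic baseline) →
    improved opening → Otsu → binarize (value > t) → zero outside FOV.
    Outside-FOV pixels are replaced with the mean in-FOV intensity before
    filtering so the disc rim does not produce a false-positive ring.  A
    vesselness map that is constant within the FOV means no ridge exceeded
    the floor: the result is then an empty mask rather than an Otsu error.
    """
    cfg = cfg or PipelineConfig()
    timings: dict = {}

    green = _stage("green", timings, extract_green, rgb)
    if fov is None:
        fov = _stage("fov", timings, fov_from_image, rgb)
    else:
        fov = np.asarray(fov, dtype=bool)
        if fov.shape != green.shape:
            raise PipelineError(
                "fov", ValueError("FOV mask shape differs from image"))
    enhanced = _stage("clahe", timings, clahe, green,
                      cfg.clip_limit, cfg.tile_grid)

    work = enhanced.copy()
    work[~fov] = enhanced[fov].mean()
    if cfg.baseline:
        resp = _stage("vesselness", timings, traditional_vesselness,
                      work, cfg.scales(), fov=fov)
    else:
        resp = _stage("vesselness", timings, multiscale_response,
                      work, cfg.scales(), fov=fov,
                      gain=cfg.response_gain, lam_floor=cfg.lam_floor)
    if cfg.morphology:
        bank = build_template_bank()
        resp = _stage("morphology", timings, improved_open, resp, bank)

    in_fov = resp[fov]
    if in_fov.size == 0 or in_fov.max() <= in_fov.min():
        log.info("vesselness map constant within FOV: no vessels found")
        mask = np.zeros_like(fov)
        return SegmentationResult(mask=mask, threshold=None, response=resp,
                                  enhanced=enhanced, fov=fov, timings=timings)
    t = _stage("otsu", timings, otsu_threshold, resp, fov, cfg.otsu_bins)
    log.info("otsu threshold: %.6f", t)
    mask = (resp > t) & fov
    return SegmentationResult(mask=mask, threshold=t, response=resp,
                              enhanced=enhanced, fov=fov, timings=timings)


def segment(rgb: np.ndarray, fov: np.ndarray | None = None,
            cfg: PipelineConfig | None = None) -> np.ndarray:
    """Segment vessels; returns the binary vessel mask (True = vessel)."""
    return segment_detailed(rgb, fov, cfg).mask
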