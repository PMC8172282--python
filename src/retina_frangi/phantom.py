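"""Synthetic fundus phantoms with known vessel ground truth.

The generator emulates the image model the segmentation method assumes:
dark curvilinear vessels (Gaussian cross-section, diameters within the
2–12 px range) on a brighter, radially shaded background inside a circular
field of view, with additive white noise.  Vessels are rendered in the
green channel; red and blue are scaled copies so channel extraction behaves
as on real fundus photographs.  Everything is reproducible from the seed.

It is a phantom, not a fundus simulator: there is no optic disc, fovea,
lesion, or vessel-caliber taper, and noise is white rather than
sensor-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import splprep, splev
from scipy.spatial import cKDTree

#: σ of the Gaussian cross-section for a vessel of full width w (FWHM = w).
WIDTH_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    size: int = 256
    fov_radius: float | None = None   # default: 0.46 × size
    vessel_count: int = 7
    width_range: tuple[float, float] = (3.0, 9.0)
    contrast: float = 0.35
    background_amplitude: float = 0.12
    noise_sigma: float = 0.01
    curliness: float = 0.35     # std (rad) of direction jitter per segment

    def __post_init__(self):
        if self.fov_radius is None:
            object.__setattr__(self, "fov_radius", 0.46 * self.size)
        lo, hi = self.width_range
        if not (2.0 <= lo <= hi <= 12.0):
            raise ValueError("vessel widths must lie within [2, 12] px")
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0 (vessels darker than "
                             "background)")
        if self.fov_radius <= 0 or self.fov_radius > self.size / 2:
            raise ValueError("fov_radius must be in (0, size/2]")
        if hi >= 2 * self.fov_radius:
            raise ValueError("vessels wider than the field of view")
        if self.noise_sigma < 0 or self.background_amplitude < 0:
            raise ValueError("noise_sigma and background_amplitude must be "
                             ">= 0")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")


@dataclass
class VesselMeta:
    centerline: np.ndarray     # N×2 (row, col) dense samples
    width: float


@dataclass
class Phantom:
    rgb: np.ndarray
    truth: np.ndarray
    fov: np.ndarray
    vessels: list
    spec: PhantomSpec


def _centerline(rng, spec) -> np.ndarray:
    """Smooth random curve: cubic spline through jittered walk points."""
    R = spec.fov_radius
    c = (spec.size - 1) / 2.0
    r0 = R * 0.6 * np.sqrt(rng.uniform())
    a0 = rng.uniform(0, 2 * np.pi)
    p = np.array([c + r0 * np.sin(a0), c + r0 * np.cos(a0)])
    phi = rng.uniform(0, 2 * np.pi)
    pts = [p.copy()]
    step = 0.55 * R
    for _ in range(4):
        phi += rng.normal(0.0, spec.curliness)
        p = p + step * np.array([np.sin(phi), np.cos(phi)])
        pts.append(p.copy())
    pts = np.array(pts)
    k = min(3, len(pts) - 1)
    tck, _ = splprep([pts[:, 0], pts[:, 1]], s=0, k=k)
    u = np.linspace(0, 1, 600)
    rr, cc = splev(u, tck)
    return np.column_stack([rr, cc])


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Render a seeded phantom with ground-truth vessel and FOV masks."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    r = np.hypot(yy - c, xx - c)
    fov = r <= spec.fov_radius

    # Radial illumination: brightest at the disc center.
    bg = 0.66 + spec.background_amplitude * (1.0 - (r / spec.fov_radius) ** 2)

    pix = np.column_stack([yy.ravel(), xx.ravel()])
    depth = np.zeros(n * n)
    truth = np.zeros(n * n, dtype=bool)
    vessels = []
    for _ in range(spec.vessel_count):
        line = _centerline(rng, spec)
        width = rng.uniform(*spec.width_range)
        sigma = width * WIDTH_TO_SIGMA
        d, _ = cKDTree(line).query(pix)
        depth = np.maximum(depth, spec.contrast * np.exp(-d ** 2 /
                                                         (2 * sigma ** 2)))
        truth |= d <= width / 2.0
        vessels.append(VesselMeta(centerline=line, width=float(width)))
    depth = depth.reshape(n, n)
    truth = truth.reshape(n, n) & fov

    green = np.where(fov, bg - depth, 0.03)
    if spec.noise_sigma > 0:
        green = green + rng.normal(0.0, spec.noise_sigma, green.shape)
    green = np.clip(green, 0.0, 1.0)

    rgb = np.stack([
        np.clip(0.15 + 0.95 * green, 0.0, 1.0),
        green,
        np.clip(0.50 * green, 0.0, 1.0),
    ], axis=-1)
    return Phantom(rgb=rgb, truth=truth, fov=fov, vessels=vessels, spec=spec)
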