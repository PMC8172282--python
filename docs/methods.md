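# Methods

This note records the model, the parameter defaults and why they are what
they are, the numerical conventions, and what the synthetic phantoms do and
do not demonstrate.

## Image model and assumptions

All images are float arrays in [0, 1], indexed (row, col); 8-bit input is
divided by 255 on load, 16-bit by 65535. The method assumes vessels are
*dark* tubes of diameter 2–12 px on a brighter background inside a circular
field of view (FOV). Everything downstream — the sign convention on λ₁, the
scale range, the structuring-element lengths — encodes that assumption.

## Preprocessing

- Green channel extracted verbatim (no rescaling).
- CLAHE defaults: `clip_limit = 0.01` (fraction of tile pixel count),
  `tile_grid = (8, 8)`, 256 bins — the de-facto community defaults; all are
  config-exposed. Tiles must be at least 8×8 px.
- Mapping: clipped-histogram CDF divided by the tile pixel count, excess
  redistributed uniformly over all bins, bilinear interpolation between
  tile-center mappings. A tile whose raw histogram occupies at most one bin
  keeps the identity mapping: a zero-contrast tile has nothing to equalize,
  and uniform redistribution would otherwise shift a constant tile by
  several gray levels.
- FOV precedence: a supplied mask file wins; otherwise the mask is derived
  from the red channel (bright inside the retinal disc) by Otsu
  thresholding, largest connected component, and hole filling.

## Vesselness response

The per-scale response `f = exp(−arctan(λ₂/λ₁)²·λ₁/2s)` for λ₁ above a
floor, else 0. Three numerical choices matter:

1. **Intensity units (`response_gain`, default 255).** The exponent
   λ₁/2s is not invariant to intensity scaling. With intensities in [0, 1],
   λ₁ is O(10⁻²) everywhere and f ≈ 1 for *any* pixel with λ₁ > 0: the
   filter cannot discriminate. The formula is balanced for 8-bit gray
   levels, so the pipeline multiplies eigenvalues by 255 before evaluating
   the response. The pure `improved_response` operation applies no gain;
   callers pass eigenvalues in whatever units they mean.

2. **Ridge floor (`lam_floor`).** f → 1 as λ₁ → 0⁺, so without a floor
   every weakly concave background pixel scores ≈1. The *operation*
   default is 1e-10 (exclude non-positive λ₁ only). The *pipeline* default
   is 20 gray-level units, chosen from two a-priori calibrations: (a) a
   CLAHE-enhanced vessel of contrast ≈0.47 has peak scale-normalized
   curvature λ₁ ≈ 0.385 × 0.47 × 255 ≈ 50 gray units, independent of its
   width; (b) the λ₁ cross-profile of a Gaussian tube falls to 0.43 of its
   centerline value exactly at the half-width edge, so a floor ≈ 0.4 × peak
   makes the recovered width match the true width at the matched scale.
   Because the response saturates at 1 across the entire λ₁ > floor
   support, the floor — not the Otsu threshold — is what controls both
   background rejection and recovered vessel width. It is the parameter to
   adjust for low-contrast imagery.

3. **Scale attribution.** On an ideal straight tube λ₂ = 0 exactly, so
   f = 1.0 (in float64) at every scale above the floor and the multiscale
   max is attained with ties. Among tied scales the pixel is attributed to
   the scale with the largest λ₁, the canonical scale-selection quantity;
   continuous theory places that maximizer at s = √2·σ for a tube of
   Gaussian cross-section σ.

Other conventions: Gaussian kernels truncated at ±4s (odd length),
separable convolution with reflective borders; the second-derivative kernel
is mean-subtracted so constants map exactly to zero and quadratics to their
analytic curvature; eigenvalues ordered |λ₁| ≥ |λ₂| with magnitude ties
resolved toward the larger signed value (a dark ridge keeps its positive
eigenvalue first); scale set default s_min = 1, s_max = 6, step = 0.5 px
(radii of the 2–12 px diameters); the multiscale map is min–max normalized
over the FOV only, so the dark surround cannot stretch the histogram;
before filtering, outside-FOV pixels are replaced by the mean in-FOV
intensity — otherwise the disc rim is a ~0.7-amplitude edge whose λ₁
(≈40 gray units) would paint a false-positive ring, while the residual
edge after mean-filling (≈0.24·Δ·255 ≈ 4 gray units) stays below the floor.

## Morphology

Flat line elements, rasterized as centered Bresenham segments with exactly
`length` set pixels ("length" counts pixels, matching the pixel-denominated
vessel diameters); for even lengths the extra pixel lies on the
positive-direction side. Grayscale erosion/dilation use the
domain-restriction border convention (windowed min/max over in-bounds
pixels only): unlike reflective re-padding between the two passes, it
preserves the erosion/dilation adjunction, so each opening is exactly
anti-extensive and idempotent. The improved opening is the pixelwise max
of all 198 openings; note that because the bank contains length-2 elements
it is a gentle filter — only structures that fit *no* 2-px line (isolated
single pixels) are guaranteed to vanish.

## Otsu and binarization

256 uniform bins over [0, 1], restricted to FOV pixels; exhaustive scan;
smallest maximizing split; threshold placed at the upper edge of the last
background bin; vessels are pixels strictly above it. A response map that
is constant within the FOV (nothing above the ridge floor) yields an empty
vessel mask rather than an error: a flat map *means* no vessels.

## Phantoms

`make_phantom` draws smooth random curves (cubic splines through a
direction-jittered walk), renders each as a dark Gaussian-profile tube
(FWHM = vessel width) via a distance transform to the sampled centerline,
on a radially shaded disc (center 0.78, rim 0.66, surround 0.03), plus
optional white noise; truth = pixels within half-width of a centerline.
Defaults: 256×256 px, FOV radius 0.46 × size, 7 vessels, widths 3–9 px,
contrast 0.35, illumination amplitude 0.12, noise σ = 0.01.

The phantom reproduces exactly the features the method relies on — dark
tubes in a known width range, uneven illumination, a bright disc on a dark
frame — and nothing else: no optic disc, fovea, lesions, central vessel
reflex, caliber taper, or correlated sensor noise. Passing phantom tests
therefore demonstrates correctness of the implementation under the method's
own assumptions, not clinical-grade performance; on real fundus data the
optic disc in particular is a known confounder.

## Problem sizes and determinism

Tests and the acceptance script run on 256×256 phantoms (≈44k FOV pixels),
11 scales, and the full 198-template bank — the full pipeline completes in
about a second, and the whole suite in a few seconds. All randomness flows
from explicit seeds (`numpy.random.default_rng`); the pipeline itself is
deterministic, and identical inputs give bit-identical masks.

## Known limitations

- The saturating response makes the map near-binary, so the Otsu stage has
  little to do on clean phantoms; its value shows on noisy, low-contrast
  imagery where the response is graded.
- A single global ridge floor trades fine-vessel sensitivity against halo
  width; very low-contrast vessels below ~8% intensity contrast are lost
  at the default.
- The improved opening barely suppresses blob-like noise larger than one
  pixel (see above); it mainly serves to clean isolated speckle.
- Vessel widths recovered at large mismatched scales can exceed truth by
  ~1–2 px per side; the floor calibration bounds but does not remove this.
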