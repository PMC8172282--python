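# retina-frangi

Unsupervised blood-vessel segmentation for color fundus (retinal)
photographs, for researchers who need a fast, training-free vessel map —
e.g. as a preprocessing step for vessel morphometry or as a classical
baseline against learned segmenters. The package also ships a seeded
synthetic-phantom generator so every stage is testable without downloading
clinical datasets.

## Method

Vessels are dark, curvilinear tubes of diameter ≈2–12 px on a brighter,
unevenly illuminated background inside a circular field of view (FOV).
The pipeline has four stages:

1. **Preprocessing.** The green channel (highest vessel contrast) is
   enhanced with contrast-limited adaptive histogram equalization (CLAHE):
   per-tile histogram equalization whose histograms are clipped at a
   fraction of the tile pixel count, with bilinear interpolation between
   tile mappings.

2. **Improved multiscale Hessian vesselness.** At each scale *s* (matched
   to vessel radius) the scale-normalized Hessian is computed by
   convolution with *s*²·∂²G(x, y; s). Its eigenvalues, ordered
   |λ₁| ≥ |λ₂|, describe the local geometry: a dark tube has λ₁ large and
   positive (curvature across the vessel) and λ₂ ≈ 0 (along it). The
   per-scale response is

   f(p, s) = exp( − arctan(λ₂/λ₁)² · λ₁ / d ),  d = 2s,  for λ₁ > λ_floor,

   and 0 otherwise; the output map is max over s ∈ {s_min, …, s_max}
   followed by min–max normalization over the FOV. `arctan(λ₂/λ₁)` is the
   eigenvector direction angle — zero along a clean tube — and *d* equalizes
   response across scales.

3. **Improved morphological opening.** A bank of 198 flat line structuring
   elements (lengths 2–12 px × angles 0–170° in 10° steps) probes the
   response map; the output is the pixelwise **maximum** of the 198
   grayscale openings, so bright structure aligned with *some* oriented
   line survives while small bright noise is removed.

4. **Otsu thresholding.** The binary vessel mask is obtained by maximizing
   the between-class variance g(t) = ω₀ω₁(μ₀−μ₁)² over a 256-bin histogram
   restricted to the FOV, then keeping pixels strictly above the threshold.

Evaluation follows the standard pixelwise protocol over the FOV:
Acc = (TP+TN)/(TP+FP+TN+FN), Se = TP/(TP+FN), Sp = TN/(TN+FP).

## Worked example

```python
from retina_frangi import (PhantomSpec, make_phantom, segment_detailed,
                           confusion, metrics)
from retina_frangi.evaluation import dice

ph = make_phantom(PhantomSpec(seed=1, noise_sigma=0.0))   # 256×256 phantom
res = segment_detailed(ph.rgb, ph.fov)                    # default config
m = metrics(confusion(res.mask, ph.truth, ph.fov))
print(f"dice={dice(res.mask, ph.truth, ph.fov):.4f}  "
      f"acc={m.acc:.4f} se={m.se:.4f} sp={m.sp:.4f}  "
      f"otsu threshold={res.threshold:.4f}")
```

prints

```
dice=0.8366  acc=0.9599 se=0.9920 sp=0.9562  otsu threshold=0.4844
```

i.e. on a noise-free seven-vessel phantom the pipeline recovers the vessel
tree with Dice 0.84 against the generated ground truth, detecting 99% of
vessel pixels while keeping 96% of background pixels clean; the Otsu split
of the near-bimodal vesselness map lands at ≈0.48.

The same pipeline is available from the shell:

```bash
retina-frangi phantom --seed 1 --out ph/
retina-frangi segment ph/image.png --fov ph/fov.png --out mask.png
retina-frangi evaluate mask.png ph/truth.png --fov ph/fov.png
```

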