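# quadcover

Automated vegetation cover estimation from top-down quadrat photographs.

Visual cover estimation — an ecologist judging what fraction of a 1 m × 1 m
quadrat is covered by grasses, forbs, or any vegetation — is a standard but
expensive and observer-dependent survey technique. `quadcover` implements an
automated alternative that works from ordinary RGB photographs of the
quadrat:

1. **Vegetation detection.** Each pixel is mapped to a 6-D chromaticity
   feature *z* = (a, b, u, v, H, S): the chromatic components of CIELAB,
   CIELUV, and HSV, with the intensity components (L and V) discarded for
   illumination robustness. Green vegetation color is modelled by a
   multivariate Gaussian with diagonal covariance,

   p(z; μ, Σ) = (2π)^(−D/2) det(Σ)^(−1/2) exp(−½ (z−μ)ᵀ Σ⁻¹ (z−μ)), D = 6,

   with μ the mean and Σ the population variances of annotated vegetation
   pixels. A pixel is declared vegetation iff p(z) > τ, where τ is
   calibrated on a held-out labelled set at the operating point where
   precision equals recall (there, F1 equals both).

2. **Grass / forb classification.** Around each vegetation pixel, a W × W
   window is summarized by the 256-bin histogram of local binary patterns
   (LBP₈,₁ = Σₙ h(Pₙ − P_c)·2ⁿ with h(x) = 1 iff x ≥ 0), and assigned the
   label of the most similar annotated class template under cosine
   similarity — a nearest-neighbour classifier designed to work from a
   handful of annotated windows.

3. **Cover estimates.** Per quadrat: A_veg (fraction of quadrat pixels that
   are vegetation) and the normalized class covers
   A\*_grass = A_grass · A_veg and A\*_forb = A_forb · A_veg, where A_grass,
   A_forb are the grass/forb shares of the vegetation pixels.

4. **Agreement and inference.** To compare automated estimates against
   field (ecologist) estimates: Pearson correlations per year; Cohen's
   kappa on the *direction* (increase/decrease) of year-to-year cover
   change; and a treatment-effect linear mixed model
   `Coverage ~ Treatment + (1|Year) + (1|Year:Plot)` over the ten
   nutrient-addition treatments (Control, Fence, K, N, NK, NP, NPK,
   NPK+Fence, P, PK), with a treatment declared significant iff its Wald
   95% CI excludes zero, and a count of treatments on which the automated
   and field fits reach the same conclusion.

Because no photograph dataset ships with the package, a first-class
synthetic generator (`quadcover.synthetic`) renders quadrat scenes with
known per-pixel ground truth (speckled soil, striped grass strokes,
smooth-shaded forb blobs) and simulates multi-year, multi-treatment cover
surveys from the same mixed model the inference layer fits.

## Worked example

```python
import numpy as np
from quadcover import (
    GaussianVegetationDetector, TemplateTextureClassifier,
    SceneSpec, generate_quadrat, generate_annotation_fixtures, estimate_cover,
)

fx = generate_annotation_fixtures(seed=1)
det = GaussianVegetationDetector().fit(fx.train.features, fx.train.labels)
f1 = det.calibrate(fx.eval.features, fx.eval.labels)
print(f"calibrated threshold tau = {det.tau_:.3g}  (F1 on eval split = {f1:.3f})")

clf = TemplateTextureClassifier(window_size=fx.window_size, stride=2).fit(
    np.array([h for _, h in fx.templates]),
    np.array([label for label, _ in fx.templates]),
)

scene = generate_quadrat(SceneSpec(size=256, f_grass=0.4, f_forb=0.2, seed=7))
est = estimate_cover(scene.image, np.ones((256, 256), bool), det, clf)
print(f"A_veg  = {est.A_veg:.3f}   (true {scene.realized['f_veg']:.3f})")
print(f"A*_grass = {est.A_grass_star:.3f} (true {scene.realized['f_grass']:.3f})")
print(f"A*_forb  = {est.A_forb_star:.3f} (true {scene.realized['f_forb']:.3f})")
```

prints

```
calibrated threshold tau = 3.21e-09  (F1 on eval split = 1.000)
A_veg  = 0.601   (true 0.601)
A*_grass = 0.400 (true 0.400)
A*_forb  = 0.201 (true 0.200)
```

i.e. on a scene generated with 40% grass / 20% forb / 40% soil, the
detector recovers total vegetation cover to three decimals and the texture
classifier splits it into grass and forb within ±0.001.

The same workflow is available from the shell — `quadcover simulate`,
`train-detector`, `calibrate`, `detect`, `make-templates`, `classify`,
`estimate-cover`, `evaluate` — see `quadcover --help`.

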