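# Methods

## Vegetation detection

Each 8-bit RGB pixel is converted (sRGB transfer, D65 white) to CIELAB,
CIELUV and HSV; the intensity components (L, L, V) are discarded and the
remainder concatenated as z = (a, b, u, v, H, S). Scaling: a/b/u/v on their
native scales (≈ ±100), H = hue angle / 360° ∈ [0, 1), S ∈ [0, 1].
Achromatic pixels get H = 0 by convention so the mapping is deterministic.
H is treated as a plain scalar, not a circular variable; greens sit around
H ≈ 1/3, far from the wrap-around, so the diagonal-Gaussian treatment is
benign there. The component order is fixed and stored with every
serialized model; a model is only valid for features produced with the
same order and scaling.

Green-vegetation color follows a multivariate Gaussian with diagonal Σ.
μ is the arithmetic mean and diag(Σ) the population (divide-by-N)
per-component variances of the vegetation-labelled training pixels, floored
at ε = 1e−8 — degenerate annotation (identical pixels) would otherwise
produce a zero variance and an undefined density. Densities are computed in
log space throughout and exponentiated only on demand.

The decision threshold τ is swept over candidate cuts at midpoints between
consecutive distinct sorted log-densities of a labelled calibration set;
the cut minimizing |precision − recall| is chosen, ties broken toward
higher recall. At precision = recall the F1 score equals both, which makes
the achieved F1 the natural summary of the operating point. The decision
rule is strict: a pixel with density exactly τ is *not* vegetation.

## Grass/forb classification

LBP codes use the 8-connected unit ring (N = 8, R = 1) — the only
configuration consistent with a 256-bin histogram and a 3×3 patch. The
comparison function h(x) = 1 iff x ≥ 0 (ties count as "not below centre"),
bit significance starts at the east neighbour and proceeds
counter-clockwise, and border neighbours are mirror-reflected
(`numpy.pad(mode="symmetric")`). Any fixed ordering yields an equivalent
classifier as long as templates and queries share it. Grayscale is ITU-R
BT.601 luma. The code is invariant to adding a constant to all
intensities, which is the illumination robustness the feature is chosen
for.

Window histograms are stored as raw counts; cosine similarity is invariant
to positive rescaling, so normalization is irrelevant (tested). A window is
assigned the label of the single most similar template (nearest neighbour;
exact ties go to the earliest template and are logged). Per-pixel labelling
slides windows over a stride-spaced grid restricted to vegetation pixels
and gives every vegetation pixel the label of its nearest classified
window centre — with stride 1 this degenerates to the literal
one-window-per-pixel rule, at stride W/4 (the default) it is ~16× cheaper
with near-identical label maps. Windows include all W² pixels, vegetation
or not; excluding background pixels from histograms is a plausible variant
that we deliberately did not adopt (the simpler inclusive reading), noted
here for sensitivity analysis.

Defaults for real imagery are W = 100 px and stride 25 on ~2,600 px-wide
photographs. On the 192–256 px synthetic scenes the package uses W = 8 and
stride 2, preserving the window-to-image ratio (~3–4% of image width).

## Cover estimates

A_veg = vegetation pixels / quadrat-mask pixels; A_grass and A_forb are the
class shares of the vegetation pixels (summing to 1 whenever vegetation
exists); the quadrat-level class covers are A\*_grass = A_grass · A_veg and
A\*_forb = A_forb · A_veg, so A\*_grass + A\*_forb = A_veg holds exactly.
Covers are fractions in [0, 1] internally; a pixel-counting estimator
cannot exceed 1.0, unlike a field ecologist who can score overlapping
canopies above 100% — this ceiling is an inherent property of the method,
retained deliberately. The quadrat interior mask is an input (marked
manually in the field workflow); a convenience routine rasterizes a
polygon.

## Agreement and inference

*Correlation.* Pearson's r between automated and field covers, per year and
variable; requires ≥ 3 pairs and non-constant inputs.

*Directional kappa.* For each plot and consecutive-year pair, the change in
cover is binarized to increase/decrease for both raters; transitions where
either rater's change is exactly zero are dropped (and counted) rather than
inventing a third category. Cohen's κ = (p_o − p_e)/(1 − p_e) on the pooled
2×2 table, with the conventional interpretation bands (≤0 none, 0.01–0.20
slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
0.81–1.00 almost perfect). Degenerate marginals (p_e = 1) are reported as
undefined.

*Treatment effects.* For each coverage variable, a linear mixed model with
fixed treatment effects (Control as the reference intercept) and random
intercepts for plots nested in years. "Nested" is under-determined; the
default encoding is a year intercept plus a (year, plot) intercept
(`statsmodels` MixedLM: `groups=year, re_formula="1",
vc_formula={"plot": "0 + C(plot)"}`), with a (year, plot)-only variant
available (`nesting="year_plot"`). Estimation is REML; intervals are Wald
95% (estimate ± 1.96·SE) — the reproducible default when no CI method is
otherwise pinned down. Coverage is modelled on the fraction scale,
untransformed, with no multiple-testing correction across treatments. A
treatment's change is *significant* iff its CI excludes zero; two fits
*agree* on a treatment when they reach the same conclusion, and the
agreement count over the nine non-control treatments is the headline
consistency measure. Boundary variance components or non-convergence set a
`singular` flag on the fit rather than being silently dropped.

## Synthetic study conditions

The scene generator renders what the pipeline can observe: mutually
exclusive per-pixel classes (no canopy overlap), soil far from green in
chromaticity, and three textures chosen to be distinct under LBP —
i.i.d. speckled soil (near-uniform code histogram), striped grass strokes
(edge-dominated codes), smooth radially-shaded forb blobs
(gradient-dominated codes). Shapes are added until each class reaches its
target pixel count, with the last shape shrunk to limit overshoot; the
generator reports realized fractions, which are the ground truth all
recovery checks use. Scene defaults: 256² px, strokes 20–45 × 2–4 px with
a 4 px stripe period, blobs of radius 7–14 px, soil noise SD 16,
vegetation noise SD 1.5.

The survey generator mirrors one site of a ten-treatment nutrient-addition
experiment: 30 plots (three per treatment, treatment constant over years),
three years, true cover = baseline + treatment effect + year intercept
(SD 0.02) + year:plot intercept (SD 0.05) + residual (SD 0.03), clipped to
[0, 1]; automated observations add N(0, 0.02²) noise. Baselines
(grass 0.35, forb 0.25, vegetation 0.55) keep all values far from the
clipping bounds at the default effect sizes. Annotation fixtures provide
two 192² scenes per split (train/eval/test, 4,000 labelled pixels each) and
15 grass + 10 forb template windows cut from pure single-class scenes —
the same small annotation budget the method is designed around.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real imagery: non-green vegetation (flowers,
senescent material), overlapping canopies and >100% field totals,
illumination gradients and shadows, camera optics (lens distortion,
varying scale/pose), and textures any closer to each other than striped
vs speckled vs smooth. Results on the synthetic suite bound the
implementation's correctness, not field performance. A "hard mode" for the
detector (yellow-green litter) can be approximated by moving `soil_color`
toward green in a custom `SceneSpec`.

## Numerical and design notes

- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` splitting; every image, table and CLI output
  is byte-reproducible under a fixed seed.
- Threshold sweep and mask prediction compare log-densities; `exp` is
  taken only for reporting, so extremely small densities cannot underflow
  the decision.
- Model JSON stores μ, diag(Σ), τ (natural and log scale), the feature
  order and the variance floor; a save/load round trip reproduces masks
  bit for bit.
- The acceptance script scales the study to desk size (20 cover scenes at
  256², 100 LMEM replicates, 25 paired-survey replicates, 200 windows per
  class) — sizes chosen to make Monte-Carlo noise small relative to the
  tolerances being checked while the whole script finishes in well under a
  minute of compute per block.
- Estimators follow scikit-learn conventions (`fit`, `predict`,
  fitted attributes with trailing underscores), so the detector and
  texture classifier compose with sklearn tooling; the module-level
  functions are thin wrappers kept for script use.
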