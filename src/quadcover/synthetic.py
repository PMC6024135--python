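"""Synthetic quadrat scenes and survey tables with known ground truth.

Real quadrat photographs and their field survey tables are not shipped with
the package, so every stage of the pipeline is exercised on synthetic data
whose ground truth is known by construction:

* **Scenes** (:func:`generate_quadrat`): a soil-colored background with
  i.i.d. speckle noise; *grass* rendered as thin elongated green strokes
  carrying a high-contrast stripe pattern along their length; *forbs* as
  rounded green blobs with smooth radial shading.  The three textures are
  deliberately distinct under local binary patterns (speckle -> near-uniform
  code histogram, stripes -> edge codes, smooth shading -> gradient codes),
  and both vegetation classes sit far from soil in chromaticity, which is
  what the color detector relies on.  The generator reports the *realized*
  per-class pixel fractions alongside the targets.

* **Surveys** (:func:`generate_survey`): multi-year, ten-treatment cover
  tables drawn from the same random-intercept model the inference layer
  fits (year and year:plot intercepts plus residual noise), with an
  automated-observation table equal to truth plus observation noise; both
  clipped to [0, 1].

* **Annotation fixtures** (:func:`generate_annotation_fixtures`):
  train/eval/test labelled pixel sets and grass/forb template windows, all
  derived from scenes.

All randomness flows from a single seed through ``numpy`` child seeds
(``default_rng(seed).spawn``-style splitting via ``SeedSequence``), so a
fixed seed reproduces every image and table byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _sk_disk
from skimage.draw import polygon as _sk_polygon

from .stats import TREATMENTS
from .texture import lbp_image, to_gray, window_histogram

# ---------------------------------------------------------------------------
# scene generation


@dataclass
class SceneSpec:
    """Parameters of one synthetic quadrat scene.

    Fractions are *target* pixel fractions; the realized fractions reported
    by the generator differ by at most about one shape's area.  Colors are
    mean 8-bit RGB values; each stroke/blob jitters its base color, and
    per-pixel noise is added on top.
    """

    size: int = 256
    f_grass: float = 0.3
    f_forb: float = 0.2
    seed: int = 0
    # grass strokes
    stroke_length: tuple[float, float] = (20.0, 45.0)
    stroke_width: tuple[float, float] = (2.0, 4.0)
    stripe_period: int = 4  # stripe wavelength along the stroke, px
    stripe_contrast: float = 0.5  # dark band brightness = 1 - contrast
    # forb blobs
    blob_radius: tuple[float, float] = (7.0, 14.0)
    blob_shading: float = 0.45  # brightness drop from blob centre to rim
    # colors (mean RGB)
    grass_color: tuple[int, int, int] = (58, 138, 52)
    forb_color: tuple[int, int, int] = (74, 152, 82)
    soil_color: tuple[int, int, int] = (128, 96, 64)
    soil_noise_sd: float = 16.0
    vegetation_noise_sd: float = 1.5
    color_jitter_sd: float = 0.06  # relative per-shape brightness jitter

    @property
    def f_soil(self) -> float:
        return 1.0 - self.f_grass - self.f_forb

    def validate(self) -> None:
        if self.size < 8:
            raise ValueError("scene size must be at least 8 pixels")
        if min(self.f_grass, self.f_forb) < 0 or self.f_grass + self.f_forb > 1 + 1e-9:
            raise ValueError("class fractions must be non-negative and sum to at most 1")


@dataclass
class QuadratScene:
    """A rendered scene with its ground-truth masks and fractions."""

    image: np.ndarray  # H x W x 3 uint8
    vegetation_mask: np.ndarray  # bool
    class_mask: np.ndarray  # uint8: 0 soil, 1 grass, 2 forb
    realized: dict  # realized fractions: f_grass, f_forb, f_veg
    spec: SceneSpec = field(repr=False, default=None)


_GRASS, _FORB = 1, 2


def _random_free_center(rng, class_mask, cls, size):
    """A random pixel not already of class ``cls`` (rejection, then exact)."""
    for _ in range(200):
        r = int(rng.integers(0, size))
        c = int(rng.integers(0, size))
        if class_mask[r, c] != cls:
            return r, c
    free = np.flatnonzero(class_mask.ravel() != cls)
    if free.size == 0:
        return None
    idx = int(free[rng.integers(0, free.size)])
    return idx // size, idx % size


def _paint_forb(rng, img, class_mask, spec, remaining):
    size = spec.size
    center = _random_free_center(rng, class_mask, _FORB, size)
    if center is None:
        return 0
    r0, c0 = center
    radius = float(rng.uniform(*spec.blob_radius))
    # shrink the last blob so the target is not badly overshot
    radius = min(radius, max(2.0, np.sqrt(remaining / np.pi) + 1.0))
    rr, cc = _sk_disk((r0, c0), radius, shape=(size, size))
    if rr.size == 0:
        return 0
    newly = class_mask[rr, cc] != _FORB
    dist2 = ((rr - r0) ** 2 + (cc - c0) ** 2) / radius**2
    shade = 1.0 - spec.blob_shading * np.clip(dist2, 0, 1)
    base = np.asarray(spec.forb_color, dtype=np.float64)
    base = base * float(np.exp(rng.normal(0.0, spec.color_jitter_sd)))
    pix = base[None, :] * shade[:, None]
    pix += rng.normal(0.0, spec.vegetation_noise_sd, pix.shape)
    img[rr, cc] = np.clip(pix, 0, 255)
    class_mask[rr, cc] = _FORB
    return int(newly.sum())


def _paint_grass(rng, img, class_mask, spec, remaining):
    size = spec.size
    center = _random_free_center(rng, class_mask, _GRASS, size)
    if center is None:
        return 0
    r0, c0 = center
    length = float(rng.uniform(*spec.stroke_length))
    width = float(rng.uniform(*spec.stroke_width))
    length = min(length, max(3.0, remaining / width + 2.0))
    theta = float(rng.uniform(0.0, np.pi))
    d = np.array([np.cos(theta), np.sin(theta)])  # along-stroke direction
    n = np.array([-d[1], d[0]])  # across-stroke normal
    half_l, half_w = length / 2.0, width / 2.0
    corners = np.array(
        [
            [r0 + half_l * d[0] + half_w * n[0], c0 + half_l * d[1] + half_w * n[1]],
            [r0 + half_l * d[0] - half_w * n[0], c0 + half_l * d[1] - half_w * n[1]],
            [r0 - half_l * d[0] - half_w * n[0], c0 - half_l * d[1] - half_w * n[1]],
            [r0 - half_l * d[0] + half_w * n[0], c0 - half_l * d[1] + half_w * n[1]],
        ]
    )
    rr, cc = _sk_polygon(corners[:, 0], corners[:, 1], shape=(size, size))
    if rr.size == 0:
        return 0
    # forbs keep priority: strokes only paint soil or other grass
    keep = class_mask[rr, cc] != _FORB
    rr, cc = rr[keep], cc[keep]
    if rr.size == 0:
        return 0
    newly = class_mask[rr, cc] != _GRASS
    t = (rr - r0) * d[0] + (cc - c0) * d[1]  # position along the stroke
    phase = np.mod(t, spec.stripe_period) < (spec.stripe_period / 2.0)
    bright = np.where(phase, 1.0, 1.0 - spec.stripe_contrast)
    base = np.asarray(spec.grass_color, dtype=np.float64)
    base = base * float(np.exp(rng.normal(0.0, spec.color_jitter_sd)))
    pix = base[None, :] * bright[:, None]
    pix += rng.normal(0.0, spec.vegetation_noise_sd, pix.shape)
    img[rr, cc] = np.clip(pix, 0, 255)
    class_mask[rr, cc] = _GRASS
    return int(newly.sum())


def generate_quadrat(spec: SceneSpec) -> QuadratScene:
    """Render one scene; deterministic for a fixed ``spec.seed``.

    Shapes are added until each class reaches its target pixel count (forbs
    first; grass strokes then fill around them without over-painting
    forbs), so the realized fractions track the targets to within roughly
    one shape area.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    size = spec.size
    n_pix = size * size

    img = np.asarray(spec.soil_color, dtype=np.float64)[None, None, :] + rng.normal(
        0.0, spec.soil_noise_sd, (size, size, 3)
    )
    img = np.clip(img, 0, 255)
    class_mask = np.zeros((size, size), dtype=np.uint8)

    target_forb = int(round(spec.f_forb * n_pix))
    target_grass = int(round(spec.f_grass * n_pix))
    max_shapes = 50 * n_pix // 100 + 1000  # generous cap; loops always terminate

    count = 0
    for _ in range(max_shapes):
        if count >= target_forb:
            break
        count += _paint_forb(rng, img, class_mask, spec, target_forb - count)

    count = 0
    for _ in range(max_shapes):
        if count >= target_grass:
            break
        count += _paint_grass(rng, img, class_mask, spec, target_grass - count)

    veg = class_mask > 0
    realized = {
        "f_grass": float(np.mean(class_mask == _GRASS)),
        "f_forb": float(np.mean(class_mask == _FORB)),
        "f_veg": float(veg.mean()),
    }
    return QuadratScene(
        image=img.astype(np.uint8),
        vegetation_mask=veg,
        class_mask=class_mask,
        realized=realized,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# survey generation


@dataclass
class SurveySpec:
    """Parameters of a synthetic multi-year nutrient-addition survey.

    The design mirrors a single site of the grassland experiment: 30 plots,
    each permanently assigned one of the ten treatments (three plots per
    treatment), surveyed over three years.  True cover follows the same
    random-intercept model the inference layer fits; automated observations
    add independent noise.  Defaults keep all covers well inside [0, 1].
    """

    n_plots: int = 30
    years: tuple = (2009, 2010, 2011)
    site: str = "SYN"
    variables: tuple = ("V_grass", "V_forb", "V_veg")
    baseline: dict = field(
        default_factory=lambda: {"V_grass": 0.35, "V_forb": 0.25, "V_veg": 0.55}
    )
    #: variable -> {treatment: effect size on the cover fraction}
    effects: dict = field(default_factory=dict)
    year_sd: float = 0.02
    year_plot_sd: float = 0.05
    residual_sd: float = 0.03
    obs_noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < len(TREATMENTS):
            raise ValueError("need at least one plot per treatment level")
        if len(self.years) < 2:
            raise ValueError("need at least 2 survey years")
        if min(self.year_sd, self.year_plot_sd, self.residual_sd, self.obs_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")


def generate_survey(spec: SurveySpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired (truth, automated) cover tables.

    Returns ``(truth, auto)`` DataFrames with columns ``site, plot, year,
    treatment`` plus one column per coverage variable.  Cover values are
    clipped to [0, 1]; if more than 20% of records clip, the effect sizes
    are infeasible for the baseline and a warning is raised.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    plots = [f"P{i + 1:02d}" for i in range(spec.n_plots)]
    treatment_of = {p: TREATMENTS[i % len(TREATMENTS)] for i, p in enumerate(plots)}

    base_rows = [
        {"site": spec.site, "plot": p, "year": y, "treatment": treatment_of[p]}
        for p in plots
        for y in spec.years
    ]
    truth = pd.DataFrame(base_rows)
    auto = truth.copy()

    n_clip = 0
    n_val = 0
    for var in spec.variables:
        beta0 = spec.baseline.get(var, 0.5)
        betas = spec.effects.get(var, {})
        u_year = {y: rng.normal(0.0, spec.year_sd) for y in spec.years}
        u_yp = {
            (y, p): rng.normal(0.0, spec.year_plot_sd) for y in spec.years for p in plots
        }
        raw = np.array(
            [
                beta0
                + betas.get(r["treatment"], 0.0)
                + u_year[r["year"]]
                + u_yp[(r["year"], r["plot"])]
                + rng.normal(0.0, spec.residual_sd)
                for r in base_rows
            ]
        )
        true_vals = np.clip(raw, 0.0, 1.0)
        obs_raw = true_vals + rng.normal(0.0, spec.obs_noise_sd, raw.shape)
        obs_vals = np.clip(obs_raw, 0.0, 1.0)
        n_clip += int(np.sum(raw != true_vals)) + int(np.sum(obs_raw != obs_vals))
        n_val += 2 * raw.size
        truth[var] = true_vals
        auto[var] = obs_vals

    if n_val and n_clip / n_val > 0.20:
        warnings.warn(
            f"{n_clip}/{n_val} simulated cover values clipped to [0, 1]; "
            "effect sizes may be infeasible for the baseline",
            stacklevel=2,
        )
    return truth, auto


# ---------------------------------------------------------------------------
# annotation fixtures


@dataclass
class LabeledPixelSet:
    """Chromaticity features with vegetation/background labels for one split."""

    features: np.ndarray  # (n, 6)
    labels: np.ndarray  # (n,) bool, True = vegetation
    split: str

    def __post_init__(self):
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels have different lengths")


@dataclass
class AnnotationFixtures:
    train: LabeledPixelSet
    eval: LabeledPixelSet
    test: LabeledPixelSet
    templates: list  # (label, 256-bin histogram) tuples
    window_size: int
    scenes: dict = field(repr=False, default_factory=dict)


def _pixel_split(scenes, n_pixels, rng, split) -> LabeledPixelSet:
    from .color import image_to_chromaticity

    feats, labels = [], []
    per_scene = n_pixels // len(scenes)
    for scene in scenes:
        z = image_to_chromaticity(scene.image).reshape(-1, 6)
        lab = scene.vegetation_mask.ravel()
        idx = rng.choice(z.shape[0], size=per_scene, replace=False)
        feats.append(z[idx])
        labels.append(lab[idx])
    return LabeledPixelSet(
        features=np.concatenate(feats), labels=np.concatenate(labels), split=split
    )


def _template_windows(scene, label, n, window, rng):
    codes = lbp_image(to_gray(scene.image))
    out = []
    hi = scene.spec.size - window
    for _ in range(n):
        r = int(rng.integers(0, hi + 1))
        c = int(rng.integers(0, hi + 1))
        out.append((label, window_histogram(codes, (r, c), window)))
    return out


def generate_annotation_fixtures(
    seed: int = 0,
    *,
    scene_size: int = 192,
    n_pixels_per_split: int = 4000,
    n_grass_templates: int = 15,
    n_forb_templates: int = 10,
    window_size: int = 8,
) -> AnnotationFixtures:
    """Deterministic labelled pixel splits plus grass/forb templates.

    Emulates, at desk scale, the annotation workflow of the real system:
    separate mixed scenes provide the train/eval/test pixel populations
    (vegetation vs background), and pure single-class scenes provide the
    template windows (15 grass and 10 forb by default, mirroring the
    small per-site annotation effort the method is designed around).

    The default window of 8 px keeps the window-to-image ratio of the
    field configuration (100 px windows on ~2600 px photographs, about 4%
    of the image width) at the 192-256 px scale of the synthetic scenes.
    """
    root = np.random.SeedSequence(seed)
    keys = root.spawn(10)
    mixed = {
        "train": [
            generate_quadrat(SceneSpec(size=scene_size, f_grass=0.30, f_forb=0.20, seed=s))
            for s in _child_seeds(keys[0], 2)
        ],
        "eval": [
            generate_quadrat(SceneSpec(size=scene_size, f_grass=0.25, f_forb=0.25, seed=s))
            for s in _child_seeds(keys[1], 2)
        ],
        "test": [
            generate_quadrat(SceneSpec(size=scene_size, f_grass=0.35, f_forb=0.15, seed=s))
            for s in _child_seeds(keys[2], 2)
        ],
    }
    rngs = {name: np.random.default_rng(k) for name, k in
            zip(("train", "eval", "test"), keys[3:6])}
    splits = {
        name: _pixel_split(scenes, n_pixels_per_split, rngs[name], name)
        for name, scenes in mixed.items()
    }

    grass_scene = generate_quadrat(
        SceneSpec(size=scene_size, f_grass=1.0, f_forb=0.0, seed=_child_seeds(keys[6], 1)[0])
    )
    forb_scene = generate_quadrat(
        SceneSpec(size=scene_size, f_grass=0.0, f_forb=1.0, seed=_child_seeds(keys[7], 1)[0])
    )
    t_rng = np.random.default_rng(keys[8])
    templates = _template_windows(grass_scene, "grass", n_grass_templates, window_size, t_rng)
    templates += _template_windows(forb_scene, "forb", n_forb_templates, window_size, t_rng)

    return AnnotationFixtures(
        train=splits["train"],
        eval=splits["eval"],
        test=splits["test"],
        templates=templates,
        window_size=window_size,
        scenes=mixed,
    )


def _child_seeds(seedseq: np.random.SeedSequence, n: int) -> list[int]:
    """Derive ``n`` integer seeds (< 2**31) from a SeedSequence."""
    return [int(s) for s in seedseq.generate_state(n, dtype=np.uint32) % (2**31)]


def scene_spec_grid(seed: int, n_scenes: int = 20, size: int = 256) -> list[SceneSpec]:
    """Scene specs whose target fractions span the [0, 1] cover range.

    Used by the cover-recovery evaluation: grass and forb targets sweep
    from bare soil to full vegetation while remaining feasible
    (f_grass + f_forb <= 1).
    """
    seeds = _child_seeds(np.random.SeedSequence(seed), n_scenes)
    rng = np.random.default_rng(np.random.SeedSequence(seed + 1))
    specs = []
    for i, s in enumerate(seeds):
        total = i / max(n_scenes - 1, 1)  # vegetation fraction sweeps 0 -> 1
        share = float(rng.uniform(0.2, 0.8))  # grass share of the vegetation
        specs.append(
            SceneSpec(size=size, f_grass=total * share, f_forb=total * (1 - share), seed=s)
        )
    return specs
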