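"""Quadrat-level cover estimation: detection + classification orchestration.

For one quadrat photograph with its (manually marked) interior mask, the
pipeline detects green vegetation per pixel, classifies the vegetation
pixels into grass vs forb, and reports:

* ``A_veg``        -- vegetation pixels / quadrat pixels, in [0, 1];
* ``A_grass_frac`` / ``A_forb_frac`` -- fractions of the *vegetation*
  pixels labelled grass / forb (they sum to 1 when any vegetation exists);
* ``A_grass_star = A_grass_frac * A_veg`` and likewise for forbs -- the
  quadrat-level class covers comparable with field estimates.

By construction ``A_grass_star + A_forb_star == A_veg`` exactly and
``A_veg <= 1``: a pixel-counting system cannot report the >100% totals a
field ecologist can produce for overlapping canopies.

Cover values are stored as fractions in [0, 1] throughout; rendering as
percentages is left to reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.draw import polygon as _sk_polygon

from .detector import GaussianVegetationDetector
from .texture import DEFAULT_STRIDE, DEFAULT_WINDOW, TemplateTextureClassifier

#: Output CSV column order for batch estimates.
COVER_COLUMNS = [
    "site", "plot", "year", "treatment",
    "A_veg", "A_grass_frac", "A_forb_frac", "A_grass_star", "A_forb_star",
    "n_quadrat_pixels", "n_veg_pixels",
]


@dataclass
class CoverEstimate:
    """Per-quadrat cover fractions paired with survey identifiers."""

    site: str = ""
    plot: str = ""
    year: int | str = ""
    treatment: str = ""
    A_veg: float = 0.0
    A_grass_frac: float = 0.0
    A_forb_frac: float = 0.0
    A_grass_star: float = 0.0
    A_forb_star: float = 0.0
    n_quadrat_pixels: int = 0
    n_veg_pixels: int = 0
    no_vegetation: bool = field(default=False, repr=False)

    def as_row(self) -> dict:
        d = asdict(self)
        d.pop("no_vegetation")
        return d


def rasterize_quadrat_polygon(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the quadrat interior from polygon vertices.

    ``vertices`` is a sequence of (row, col) pairs (typically the 4 corners
    of the frame).  Convenience for sites that record the interior as a
    polygon rather than a mask image.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or vertices.shape[0] < 3:
        raise ValueError("need at least 3 (row, col) vertices")
    rr, cc = _sk_polygon(vertices[:, 0], vertices[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def estimate_cover(
    image: np.ndarray,
    quadrat_mask: np.ndarray,
    detector: GaussianVegetationDetector,
    classifier: TemplateTextureClassifier,
    *,
    stride: int | None = None,
    meta: dict | None = None,
) -> CoverEstimate:
    """Estimate vegetation / grass / forb cover for one quadrat image.

    ``detector`` must be calibrated (tau set) and ``classifier`` fitted with
    grass and forb templates.  ``meta`` carries the survey identifiers
    (site, plot, year, treatment) into the result.
    """
    quadrat_mask = np.asarray(quadrat_mask).astype(bool)
    n_quadrat = int(quadrat_mask.sum())
    if n_quadrat == 0:
        raise ValueError("empty quadrat mask")

    veg_mask = detector.detect(image, quadrat_mask)
    n_veg = int(veg_mask.sum())
    est = CoverEstimate(**(meta or {}))
    est.n_quadrat_pixels = n_quadrat
    est.n_veg_pixels = n_veg
    est.A_veg = n_veg / n_quadrat
    if n_veg == 0:
        est.no_vegetation = True
        return est

    labels = classifier.classify_image(image, veg_mask, stride=stride)
    veg_labels = labels[veg_mask]
    n_grass = int(np.sum(veg_labels == "grass"))
    n_forb = int(np.sum(veg_labels == "forb"))
    if n_grass + n_forb != n_veg:
        raise RuntimeError("classifier left vegetation pixels unlabelled")
    est.A_grass_frac = n_grass / n_veg
    est.A_forb_frac = n_forb / n_veg
    est.A_grass_star = est.A_grass_frac * est.A_veg
    est.A_forb_star = est.A_forb_frac * est.A_veg
    return est


def batch_estimate(
    manifest: pd.DataFrame | str,
    detector: GaussianVegetationDetector,
    classifier: TemplateTextureClassifier,
    *,
    stride: int | None = None,
    image_reader=None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run :func:`estimate_cover` over a manifest of quadrat images.

    ``manifest`` is a DataFrame (or CSV path) with columns ``image_path``,
    ``mask_path``, ``site``, ``plot``, ``year``, ``treatment``.  Rows that
    fail (unreadable files, empty masks) are logged into the returned error
    list without aborting the rest of the batch.

    Returns ``(table, errors)`` where ``table`` has :data:`COVER_COLUMNS`.
    """
    from pathlib import Path

    from .io import read_image, read_mask  # local import: io pulls in PIL

    reader_img = image_reader or read_image
    base = None
    if isinstance(manifest, (str, bytes)) or hasattr(manifest, "__fspath__"):
        base = Path(manifest).parent  # relative manifest paths resolve here
        manifest = pd.read_csv(manifest, dtype={"plot": str, "site": str, "treatment": str})
    required = {"image_path", "mask_path", "site", "plot", "year", "treatment"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")

    def _resolve(p):
        p = Path(p)
        return p if (base is None or p.is_absolute()) else base / p

    rows, errors = [], []
    for idx, rec in manifest.iterrows():
        try:
            image = reader_img(_resolve(rec["image_path"]))
            mask = read_mask(_resolve(rec["mask_path"]))
            est = estimate_cover(
                image, mask, detector, classifier, stride=stride,
                meta={
                    "site": str(rec["site"]),
                    "plot": str(rec["plot"]),
                    "year": rec["year"],
                    "treatment": str(rec["treatment"]),
                },
            )
            rows.append(est.as_row())
        except Exception as exc:  # noqa: BLE001 - per-row fault isolation
            errors.append({"row": int(idx), "image_path": str(rec.get("image_path")),
                           "error": f"{type(exc).__name__}: {exc}"})
    table = pd.DataFrame(rows, columns=COVER_COLUMNS)
    return table, errors
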