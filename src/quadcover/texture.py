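"""Local-binary-pattern texture classification of vegetation windows.

Each grayscale pixel is encoded by comparing it with its 8 ring neighbours
at radius 1 (the 8-connected ring):

    LBP = sum_{n=0..7} h(P_n - P_c) * 2^n,   h(x) = 1 iff x >= 0,

with bit significance starting at the east neighbour and proceeding
counter-clockwise (E, NE, N, NW, W, SW, S, SE).  Because only local
differences enter ``h``, the code is invariant to adding a constant to all
intensities, which makes the feature robust to illumination changes.
Out-of-bounds neighbours at the image border are obtained by mirror
reflection (the border pixel itself is mirrored).

A ``W x W`` window is summarized by the 256-bin histogram of its LBP codes;
histograms are compared with cosine similarity, so their normalization is
irrelevant (cosine is invariant to positive rescaling).  Classification is
nearest-neighbour against a small set of annotated class template
histograms (grass vs forb).

Grayscale conversion uses the ITU-R BT.601 luma: 0.299 R + 0.587 G + 0.114 B.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

#: Number of histogram bins = 2^8 neighbour bits.
N_BINS = 256

#: Default window side length, in pixels.
DEFAULT_WINDOW = 100

#: Default window-centre stride (window/4) used by the sliding classifier.
DEFAULT_STRIDE = 25

#: (drow, dcol) neighbour offsets in bit order: east, then counter-clockwise.
#: Row axis points down, so "north" is a negative row offset.
NEIGHBOR_OFFSETS = (
    (0, 1),    # E
    (-1, 1),   # NE
    (-1, 0),   # N
    (-1, -1),  # NW
    (0, -1),   # W
    (1, -1),   # SW
    (1, 0),    # S
    (1, 1),    # SE
)

_BT601 = np.array([0.299, 0.587, 0.114])


def to_gray(image: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB image (float), or pass-through for 2-D input."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.float64)
    if image.ndim == 3 and image.shape[-1] == 3:
        return image.astype(np.float64) @ _BT601
    raise ValueError(f"expected a 2-D grayscale or H x W x 3 image, got shape {image.shape}")


def lbp_code(patch: np.ndarray) -> int:
    """LBP code of a single 3x3 patch (centre compared with its 8 neighbours)."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (3, 3):
        raise ValueError(f"expected a 3x3 patch, got shape {patch.shape}")
    c = patch[1, 1]
    code = 0
    for n, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        if patch[1 + dr, 1 + dc] - c >= 0:
            code += 1 << n
    return code


def lbp_image(gray: np.ndarray) -> np.ndarray:
    """LBP code image of the same shape as ``gray`` (vectorized).

    Border neighbours are mirror-reflected (``numpy.pad`` mode
    ``symmetric``: the edge pixel is its own out-of-bounds neighbour).
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or gray.shape[0] < 2 or gray.shape[1] < 2:
        raise ValueError(f"expected a 2-D image at least 2x2, got shape {gray.shape}")
    padded = np.pad(gray, 1, mode="symmetric")
    h, w = gray.shape
    codes = np.zeros((h, w), dtype=np.int32)
    for n, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neighbor = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        codes |= (neighbor >= gray).astype(np.int32) << n
    return codes


def window_histogram(codes: np.ndarray, origin: tuple[int, int], size: int) -> np.ndarray:
    """256-bin histogram of the ``size x size`` window at ``origin`` (row, col)."""
    codes = np.asarray(codes)
    r, c = origin
    if r < 0 or c < 0 or r + size > codes.shape[0] or c + size > codes.shape[1]:
        raise ValueError(
            f"window origin {origin} with size {size} exceeds code image shape {codes.shape}"
        )
    window = codes[r : r + size, c : c + size]
    return np.bincount(window.ravel(), minlength=N_BINS).astype(np.int64)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity (a . b) / (|a| |b|); in [0, 1] for count histograms."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero histogram")
    return float(np.dot(a, b) / (na * nb))


class TemplateTextureClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-template window classifier under cosine similarity.

    ``fit`` takes the annotated class templates: ``X`` is an ``(n, 256)``
    array of LBP window histograms and ``y`` their labels (e.g. ``"grass"``
    / ``"forb"``).  ``predict`` assigns each query histogram the label of
    the single most similar template; exact ties go to the earlier template
    in ``fit`` order (and are logged).

    Parameters
    ----------
    window_size : int
        Side length W of the windows the histograms describe.
    stride : int
        Window-centre spacing used by :meth:`classify_image`.
    """

    def __init__(self, window_size: int = DEFAULT_WINDOW, stride: int = DEFAULT_STRIDE):
        self.window_size = window_size
        self.stride = stride

    def fit(self, X, y) -> "TemplateTextureClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != N_BINS:
            raise ValueError(f"expected (n, {N_BINS}) template histograms, got {X.shape}")
        if y.shape[0] != X.shape[0]:
            raise ValueError("templates and labels have different lengths")
        if np.unique(y).size < 2:
            raise ValueError("need templates for at least two classes")
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm template histogram")
        self.templates_ = X
        self.template_labels_ = y
        self.classes_ = np.unique(y)
        self._unit_templates_ = X / norms[:, None]
        self.n_features_in_ = N_BINS
        return self

    def _require_fitted(self):
        if not hasattr(self, "templates_"):
            raise RuntimeError("classifier has no templates; call fit() first")

    def similarities(self, X) -> np.ndarray:
        """Cosine similarity of each query histogram to every template."""
        self._require_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm query histogram")
        return (X / norms[:, None]) @ self._unit_templates_.T

    def predict(self, X) -> np.ndarray:
        """Label of the best-matching template for each query histogram."""
        sims = self.similarities(X)
        best = np.argmax(sims, axis=1)  # first template wins exact ties
        n_tied = int(np.sum(np.sum(sims == sims.max(axis=1, keepdims=True), axis=1) > 1))
        if n_tied:
            logger.info("nearest-template ties on %d window(s); first template kept", n_tied)
        return self.template_labels_[best]

    def best_similarity_per_class(self, X) -> dict:
        """Max similarity to any template of each class, per query."""
        sims = self.similarities(X)
        return {
            str(c): sims[:, self.template_labels_ == c].max(axis=1)
            for c in self.classes_
        }

    def classify_image(
        self, image: np.ndarray, vegetation_mask: np.ndarray, stride: int | None = None
    ) -> np.ndarray:
        """Per-pixel class labels over the vegetation pixels of an image.

        Windows of side ``window_size`` centred on a ``stride``-spaced grid
        restricted to vegetation pixels are classified; every vegetation
        pixel then takes the label of the nearest classified window centre.
        Non-vegetation pixels get the null label (empty string).  The image
        is mirror-padded so windows centred near the border stay complete;
        if the image is smaller than one window, the whole (padded) image
        is a single window.

        Returns an H x W array of labels ('' outside vegetation).
        """
        self._require_fitted()
        stride = self.stride if stride is None else int(stride)
        if stride < 1:
            raise ValueError("stride must be >= 1")
        vegetation_mask = np.asarray(vegetation_mask).astype(bool)
        gray = to_gray(image)
        if vegetation_mask.shape != gray.shape:
            raise ValueError("vegetation mask and image dimensions do not match")
        h, w = gray.shape
        labels = np.full((h, w), "", dtype=object)
        veg_rows, veg_cols = np.nonzero(vegetation_mask)
        if veg_rows.size == 0:
            return labels

        W = int(self.window_size)
        half = W // 2
        codes = lbp_image(np.pad(gray, half, mode="symmetric"))

        grid_r = np.arange(stride // 2, h, stride)
        grid_c = np.arange(stride // 2, w, stride)
        rr, cc = np.meshgrid(grid_r, grid_c, indexing="ij")
        on_veg = vegetation_mask[rr, cc]
        centers = np.column_stack([rr[on_veg], cc[on_veg]])
        if centers.shape[0] == 0:
            # no grid centre touches vegetation (tiny or sparse mask):
            # fall back to the vegetation pixels themselves
            centers = np.column_stack([veg_rows, veg_cols])

        hists = np.empty((centers.shape[0], N_BINS), dtype=np.float64)
        for i, (r, c) in enumerate(centers):
            hists[i] = window_histogram(codes, (int(r), int(c)), W)
        center_labels = self.predict(hists)

        tree = cKDTree(centers)
        _, nearest = tree.query(np.column_stack([veg_rows, veg_cols]), k=1)
        labels[veg_rows, veg_cols] = center_labels[nearest]
        return labels


# -- thin functional wrappers (module-level surface) ---------------------


def classify_window(histogram, templates: list[tuple[str, np.ndarray]]):
    """Classify one histogram against ``(label, histogram)`` templates.

    Returns ``(label, best_similarity_per_class)``.  Requires at least one
    template per class among the labels present.
    """
    labels = [t[0] for t in templates]
    if len(set(labels)) < 2:
        raise ValueError("template set must contain at least two classes")
    clf = TemplateTextureClassifier().fit(
        np.array([np.asarray(t[1], dtype=np.float64) for t in templates]), np.array(labels)
    )
    label = clf.predict(np.atleast_2d(histogram))[0]
    best = {k: float(v[0]) for k, v in clf.best_similarity_per_class(histogram).items()}
    return label, best


def classify_vegetation(
    image,
    vegetation_mask,
    templates: list[tuple[str, np.ndarray]],
    stride: int = DEFAULT_STRIDE,
    window_size: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Per-pixel grass/forb label map; see :meth:`TemplateTextureClassifier.classify_image`."""
    if not templates:
        raise ValueError("empty template set")
    clf = TemplateTextureClassifier(window_size=window_size, stride=stride).fit(
        np.array([np.asarray(t[1], dtype=np.float64) for t in templates]),
        np.array([t[0] for t in templates]),
    )
    return clf.classify_image(image, vegetation_mask)
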