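"""Gaussian color model of green vegetation.

The color of green vegetation is modelled with a multivariate Gaussian over
the 6-D chromaticity feature ``z`` (see :mod:`quadcover.color`), with a
diagonal covariance:

    p(z; mu, Sigma) = (2 pi)^(-D/2) det(Sigma)^(-1/2)
                      exp(-1/2 (z - mu)^T Sigma^-1 (z - mu)),  D = 6.

``mu`` is the arithmetic mean of vegetation-labelled training pixels and the
diagonal of ``Sigma`` holds their population (divide-by-N) variances, floored
at a small ``var_floor`` so degenerate annotation cannot produce a zero
variance.  A pixel is declared vegetation iff its density strictly exceeds a
threshold ``tau``; ``tau`` is calibrated on a held-out labelled set at the
operating point where precision equals recall (the equal-error point, at
which F1 equals both).

All density work is done in log space; densities are exponentiated only on
demand.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .color import FEATURE_ORDER, N_FEATURES, image_to_chromaticity

_LOG_2PI = float(np.log(2.0 * np.pi))


class NotCalibratedError(RuntimeError):
    """Raised when a decision threshold is required but has not been set."""


def _check_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected an (n, {N_FEATURES}) feature array, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    return X


class GaussianVegetationDetector(BaseEstimator):
    """Diagonal-Gaussian color model with an equal-error decision threshold.

    Parameters
    ----------
    var_floor : float, default 1e-8
        Lower bound applied to each per-component variance.

    Attributes
    ----------
    mu_ : (6,) ndarray
        Mean chromaticity of vegetation training pixels.
    var_ : (6,) ndarray
        Diagonal of the covariance (population variances, floored).
    log_tau_ : float
        Log of the decision threshold, set by :meth:`calibrate`.
    tau_ : float
        Decision threshold on the density scale (``exp(log_tau_)``).
    f1_ : float
        F1 score achieved on the calibration set at ``tau_``.
    meta_ : dict
        Training provenance (pixel counts, optional seed/source tags).
    """

    def __init__(self, var_floor: float = 1e-8):
        self.var_floor = var_floor

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y, meta: dict | None = None) -> "GaussianVegetationDetector":
        """Estimate ``mu_`` and ``var_`` from vegetation-labelled pixels.

        Only pixels with ``y == True`` enter the estimators; background
        pixels are used later, for threshold calibration.
        """
        X = _check_features(X)
        y = np.asarray(y, dtype=bool).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different lengths")
        veg = X[y]
        if veg.shape[0] < 2:
            raise ValueError("need at least 2 vegetation-labelled pixels to fit")
        self.mu_ = veg.mean(axis=0)
        # population variance (divide by N), per component
        self.var_ = np.maximum(veg.var(axis=0, ddof=0), self.var_floor)
        self.n_features_in_ = N_FEATURES
        self.meta_ = dict(meta or {})
        self.meta_.setdefault("n_vegetation_pixels", int(veg.shape[0]))
        self.meta_.setdefault("n_pixels", int(X.shape[0]))
        return self

    @property
    def _is_fitted(self) -> bool:
        return hasattr(self, "mu_")

    def _require_fitted(self) -> None:
        if not self._is_fitted:
            raise RuntimeError("detector is not fitted; call fit() first")

    # -- densities -------------------------------------------------------

    def score_samples(self, X) -> np.ndarray:
        """Log density of each feature row under the fitted Gaussian."""
        self._require_fitted()
        X = _check_features(X)
        d2 = ((X - self.mu_) ** 2) / self.var_
        return -0.5 * (
            N_FEATURES * _LOG_2PI + np.sum(np.log(self.var_)) + d2.sum(axis=1)
        )

    def likelihood(self, X) -> np.ndarray:
        """Density on the natural scale (exponentiated log density)."""
        return np.exp(self.score_samples(X))

    # -- threshold calibration ------------------------------------------

    def calibrate(self, X, y) -> float:
        """Set ``tau_`` at the precision = recall point of a labelled set.

        Candidate thresholds are the midpoints between consecutive distinct
        sorted log densities (plus sentinels beyond both extremes); among
        them the one minimizing ``|precision - recall|`` is chosen, ties
        broken toward higher recall.  Returns the F1 score at the chosen
        threshold (at precision = recall, F1 equals both).
        """
        self._require_fitted()
        X = _check_features(X)
        y = np.asarray(y, dtype=bool).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different lengths")
        if y.all() or not y.any():
            raise ValueError("calibration set must contain both classes")
        scores = self.score_samples(X)
        log_tau, f1, precision, recall = _equal_error_threshold(scores, y)
        self.log_tau_ = float(log_tau)
        self.tau_ = float(np.exp(log_tau))
        self.f1_ = float(f1)
        self.meta_["calibration"] = {
            "n_pixels": int(y.size),
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
        }
        return self.f1_

    @property
    def _is_calibrated(self) -> bool:
        return hasattr(self, "log_tau_")

    # -- prediction ------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Boolean vegetation call per feature row (density strictly > tau)."""
        self._require_fitted()
        if not self._is_calibrated:
            raise NotCalibratedError("threshold tau is unset; call calibrate() first")
        return self.score_samples(X) > self.log_tau_

    def detect(self, image: np.ndarray, quadrat_mask: np.ndarray) -> np.ndarray:
        """Binary vegetation mask for an RGB image, restricted to the quadrat.

        A pixel is vegetation iff it lies inside ``quadrat_mask`` and its
        density strictly exceeds ``tau_`` (density exactly equal to tau is
        not vegetation).  Pixels outside the quadrat mask never influence
        the result.
        """
        self._require_fitted()
        if not self._is_calibrated:
            raise NotCalibratedError("threshold tau is unset; call calibrate() first")
        quadrat_mask = np.asarray(quadrat_mask).astype(bool)
        feats = image_to_chromaticity(image)
        if quadrat_mask.shape != feats.shape[:2]:
            raise ValueError("quadrat mask and image dimensions do not match")
        out = np.zeros(quadrat_mask.shape, dtype=bool)
        inside = feats[quadrat_mask]
        if inside.size:
            out[quadrat_mask] = self.score_samples(inside) > self.log_tau_
        return out

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        self._require_fitted()
        d = {
            "feature_order": list(FEATURE_ORDER),
            "var_floor": float(self.var_floor),
            "mu": [float(v) for v in self.mu_],
            "sigma": [float(v) for v in self.var_],
            "meta": self.meta_,
        }
        if self._is_calibrated:
            d["log_tau"] = float(self.log_tau_)
            d["tau"] = float(self.tau_)
            d["f1"] = float(self.f1_)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianVegetationDetector":
        if tuple(d.get("feature_order", FEATURE_ORDER)) != FEATURE_ORDER:
            raise ValueError("model was fitted with an incompatible feature order")
        est = cls(var_floor=float(d.get("var_floor", 1e-8)))
        est.mu_ = np.asarray(d["mu"], dtype=np.float64)
        est.var_ = np.asarray(d["sigma"], dtype=np.float64)
        est.n_features_in_ = N_FEATURES
        est.meta_ = dict(d.get("meta", {}))
        if "log_tau" in d:
            est.log_tau_ = float(d["log_tau"])
            est.tau_ = float(d.get("tau", np.exp(est.log_tau_)))
            est.f1_ = float(d.get("f1", float("nan")))
        return est

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "GaussianVegetationDetector":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _equal_error_threshold(scores: np.ndarray, labels: np.ndarray):
    """Sweep all distinct-score cut points for the precision = recall one.

    Returns ``(threshold, f1, precision, recall)`` where ``threshold`` is a
    cut such that "score > threshold" selects the chosen positive set.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = labels[order]
    n = s.size
    n_pos = int(lab.sum())
    tp = np.cumsum(lab)  # tp[k-1] = true positives among top k
    k = np.arange(1, n + 1)
    precision = tp / k
    recall = tp / n_pos
    # a cut after position k is realizable only if s[k-1] > s[k] (strictly)
    realizable = np.empty(n, dtype=bool)
    realizable[:-1] = s[:-1] > s[1:]
    realizable[-1] = True
    gap = np.abs(precision - recall)
    gap[~realizable] = np.inf
    ties = np.flatnonzero(gap == gap.min())
    best = int(ties[-1])  # ties broken toward higher recall (larger cut)
    if best == n - 1:
        thr = s[-1] - 1.0
    else:
        thr = 0.5 * (s[best] + s[best + 1])
    p, r = precision[best], recall[best]
    f1 = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
    return thr, f1, p, r


# -- thin functional wrappers (module-level surface) ---------------------


def fit_gaussian(features, labels, var_floor: float = 1e-8, meta: dict | None = None):
    """Fit the Gaussian color model; see :meth:`GaussianVegetationDetector.fit`."""
    return GaussianVegetationDetector(var_floor=var_floor).fit(features, labels, meta=meta)


def likelihood(z, model: GaussianVegetationDetector) -> np.ndarray | float:
    """Density of feature(s) ``z`` under a fitted model (natural scale)."""
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    out = model.likelihood(z)
    return float(out[0]) if single else out


def calibrate_threshold(features, labels, model: GaussianVegetationDetector):
    """Calibrate ``tau`` at precision = recall; returns ``(model, f1)``."""
    f1 = model.calibrate(features, labels)
    return model, f1


def detect_vegetation(image, quadrat_mask, model: GaussianVegetationDetector) -> np.ndarray:
    """Binary vegetation mask; see :meth:`GaussianVegetationDetector.detect`."""
    return model.detect(image, quadrat_mask)
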