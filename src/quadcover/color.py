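"""Illumination-robust chromaticity features for vegetation detection.

Each RGB pixel is re-expressed in three standard color spaces -- CIELAB,
CIELUV and HSV -- and the intensity component of each (L, L and V) is
discarded, leaving a 6-D chromaticity vector

    z = (a, b, u, v, H, S)

in that fixed order.  Conversions use the sRGB transfer function with the
D65 reference white (the universal default of imaging libraries).  Scaling:

* a, b (CIELAB) and u, v (CIELUV) are kept on their native scales
  (roughly [-100, 100]).
* H is the hue angle divided by 360 degrees, i.e. in [0, 1); achromatic
  pixels (max channel == min channel) get H = 0.
* S is the HSV saturation in [0, 1].

The component order and scaling are part of the model contract: a detector
fitted on these features is only valid for features produced by this module.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

#: Number of chromaticity components per pixel.
N_FEATURES = 6

#: Documented component order, shared by training and inference.
FEATURE_ORDER = ("lab_a", "lab_b", "luv_u", "luv_v", "hsv_h", "hsv_s")


def _validate_rgb_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    if np.issubdtype(image.dtype, np.floating):
        raise TypeError("expected 8-bit integer RGB values in [0, 255], got floats")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return image.astype(np.uint8)


def image_to_chromaticity(image: np.ndarray) -> np.ndarray:
    """Convert an ``H x W x 3`` 8-bit RGB image to ``H x W x 6`` chromaticity.

    Vectorized core used by every other operation; see the module docstring
    for component order and scaling.
    """
    image = _validate_rgb_image(image)
    rgb = image.astype(np.float64) / 255.0
    lab = _skcolor.rgb2lab(rgb)  # D65, 2-degree observer
    luv = _skcolor.rgb2luv(rgb)
    hsv = _skcolor.rgb2hsv(rgb)  # H and S already in [0, 1]
    return np.stack(
        [lab[..., 1], lab[..., 2], luv[..., 1], luv[..., 2], hsv[..., 0], hsv[..., 1]],
        axis=-1,
    )


def rgb_to_chromaticity(pixel) -> np.ndarray:
    """Convert one RGB triple of 8-bit integers to its 6-vector ``z``.

    An achromatic pixel (R == G == B) maps to the zero vector up to the
    floating-point precision of the sRGB matrices (|a|, |b|, |u|, |v|
    below 5e-3, H = S = 0 exactly).
    """
    pixel = np.asarray(pixel)
    if pixel.shape != (3,):
        raise ValueError(f"expected an RGB triple, got shape {pixel.shape}")
    return image_to_chromaticity(pixel.reshape(1, 1, 3))[0, 0]


def image_to_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Chromaticity features of the masked pixels, in row-major pixel order.

    Parameters
    ----------
    image : H x W x 3 array of 8-bit RGB.
    mask : H x W boolean array; features are returned for True pixels only.

    Returns
    -------
    (n_true, 6) float array.  Each pixel's feature depends only on that
    pixel, so restricting the mask restricts the output accordingly.
    """
    image = _validate_rgb_image(image)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image spatial shape {image.shape[:2]}"
        )
    return image_to_chromaticity(image)[mask]
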