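"""Image and mask file handling (PNG/JPEG/TIFF via Pillow)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

#: Pixel value written for True in binary mask PNGs.
MASK_ON = 255

#: Class label <-> index mapping for label-map PNGs.
LABEL_INDEX = {"": 0, "grass": 1, "forb": 2}
INDEX_LABEL = {v: k for k, v in LABEL_INDEX.items()}


def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/JPEG/TIFF) as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("expected a uint8 image")
    Image.fromarray(image).save(Path(path))


def read_mask(path) -> np.ndarray:
    """Read a single-channel mask PNG; nonzero pixels are True."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def write_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), MASK_ON, 0).astype(np.uint8)).save(
        Path(path)
    )


def read_label_map(path) -> np.ndarray:
    """Read an indexed label-map PNG back to an object array of labels."""
    with Image.open(path) as im:
        idx = np.asarray(im.convert("L"))
    labels = np.full(idx.shape, "", dtype=object)
    for value, label in INDEX_LABEL.items():
        if value:
            labels[idx == value] = label
    return labels


def write_label_map(path, labels: np.ndarray) -> None:
    """Write a label map (strings '', 'grass', 'forb') as an indexed PNG."""
    labels = np.asarray(labels, dtype=object)
    idx = np.zeros(labels.shape, dtype=np.uint8)
    for label, value in LABEL_INDEX.items():
        if label:
            idx[labels == label] = value
    Image.fromarray(idx).save(Path(path))


def read_templates(path) -> list[tuple[str, np.ndarray]]:
    """Read class templates from JSON: a list of {label, counts, source}."""
    entries = json.loads(Path(path).read_text())
    return [(e["label"], np.asarray(e["counts"], dtype=np.float64)) for e in entries]


def write_templates(path, templates, sources=None) -> None:
    """Write ``(label, histogram)`` templates (plus provenance) as JSON."""
    sources = sources or [""] * len(templates)
    entries = [
        {"label": str(label), "counts": [int(c) for c in np.asarray(counts)], "source": src}
        for (label, counts), src in zip(templates, sources)
    ]
    Path(path).write_text(json.dumps(entries, indent=1, sort_keys=True) + "\n")
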