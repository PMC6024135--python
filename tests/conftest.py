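"""Shared fixtures: annotation fixtures and a trained detection/classification
stack, built once per session from the synthetic generator (seed 1)."""

import numpy as np
import pytest

from quadcover.detector import GaussianVegetationDetector
from quadcover.synthetic import generate_annotation_fixtures
from quadcover.texture import TemplateTextureClassifier


@pytest.fixture(scope="session")
def fixtures():
    return generate_annotation_fixtures(seed=1)


@pytest.fixture(scope="session")
def detector(fixtures):
    det = GaussianVegetationDetector().fit(fixtures.train.features, fixtures.train.labels)
    det.calibrate(fixtures.eval.features, fixtures.eval.labels)
    return det


@pytest.fixture(scope="session")
def classifier(fixtures):
    return TemplateTextureClassifier(window_size=fixtures.window_size, stride=2).fit(
        np.array([h for _, h in fixtures.templates]),
        np.array([label for label, _ in fixtures.templates]),
    )
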