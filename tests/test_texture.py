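"""Local binary patterns, window histograms, cosine similarity and the
nearest-template classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quadcover.synthetic import SceneSpec, generate_quadrat
from quadcover.texture import (
    NEIGHBOR_OFFSETS,
    TemplateTextureClassifier,
    classify_vegetation,
    classify_window,
    cosine_similarity,
    lbp_code,
    lbp_image,
    to_gray,
    window_histogram,
)

# ---------------------------------------------------------------------------
# brute-force oracle: pad explicitly, enumerate bit by bit


def _oracle_lbp(gray):
    gray = np.asarray(gray, dtype=float)
    padded = np.pad(gray, 1, mode="symmetric")
    h, w = gray.shape
    out = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            center = padded[r + 1, c + 1]
            code = 0
            for n, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                if padded[r + 1 + dr, c + 1 + dc] - center >= 0:
                    code += 2**n
            out[r, c] = code
    return out


# ---------------------------------------------------------------------------
# single-patch codes


def test_constant_patch_codes_255_equality_case():
    # h(0) = 1, so every neighbour bit is set
    assert lbp_code(np.full((3, 3), 7.0)) == 255


def test_center_strictly_greater_codes_zero():
    patch = np.zeros((3, 3))
    patch[1, 1] = 9.0
    assert lbp_code(patch) == 0


def test_lbp_code_manual_bit_enumeration():
    # centre 5; neighbours in documented order E, NE, N, NW, W, SW, S, SE
    neighbors = [7, 3, 5, 1, 9, 4, 6, 2]
    patch = np.full((3, 3), 5.0)
    for (dr, dc), value in zip(NEIGHBOR_OFFSETS, neighbors):
        patch[1 + dr, 1 + dc] = value
    # h >= 0 for neighbours 7, 5, 9, 6 -> bits 0, 2, 4, 6
    expected = sum(2**n for n, v in enumerate(neighbors) if v - 5 >= 0)
    assert expected == 2**0 + 2**2 + 2**4 + 2**6
    assert lbp_code(patch) == expected


def test_lbp_code_rejects_wrong_shape():
    with pytest.raises(ValueError):
        lbp_code(np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# full-image codes


def test_constant_image_all_255():
    assert np.all(lbp_image(np.full((5, 8), 3.0)) == 255)


def test_interior_codes_match_patchwise_definition():
    rng = np.random.default_rng(0)
    gray = rng.integers(0, 256, size=(9, 9)).astype(float)
    codes = lbp_image(gray)
    for r in range(1, 8):
        for c in range(1, 8):
            assert codes[r, c] == lbp_code(gray[r - 1 : r + 2, c - 1 : c + 2])


def test_lbp_image_matches_padded_oracle_small():
    rng = np.random.default_rng(1)
    gray = rng.integers(0, 256, size=(4, 4)).astype(float)
    assert np.array_equal(lbp_image(gray), _oracle_lbp(gray))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    h=st.integers(2, 12),
    w=st.integers(2, 12),
    seed=st.integers(0, 2**31 - 1),
)
def test_lbp_image_equals_oracle_property(h, w, seed):
    gray = np.random.default_rng(seed).integers(0, 256, size=(h, w)).astype(float)
    assert np.array_equal(lbp_image(gray), _oracle_lbp(gray))


def test_lbp_invariant_to_intensity_offset():
    rng = np.random.default_rng(3)
    gray = rng.integers(0, 200, size=(16, 16)).astype(float)
    assert np.array_equal(lbp_image(gray), lbp_image(gray + 37.0))


def test_lbp_image_rejects_degenerate_input():
    with pytest.raises(ValueError):
        lbp_image(np.zeros((1, 5)))


# ---------------------------------------------------------------------------
# histograms


def test_window_histogram_counting():
    codes = np.full((10, 10), 42)
    hist = window_histogram(codes, (0, 0), 10)
    assert hist[42] == 100 and hist.sum() == 100

    tiled = np.arange(256).reshape(16, 16)
    flat = window_histogram(tiled, (0, 0), 16)
    assert np.all(flat == 1)

    rng = np.random.default_rng(4)
    rand = rng.integers(0, 256, size=(10, 10))
    hist = window_histogram(rand, (0, 0), 10)
    values, counts = np.unique(rand, return_counts=True)  # sorting-and-counting oracle
    want = np.zeros(256, dtype=int)
    want[values] = counts
    assert np.array_equal(hist, want)


def test_window_histogram_bounds_check():
    with pytest.raises(ValueError):
        window_histogram(np.zeros((5, 5), int), (3, 3), 5)


def test_histogram_invariant_to_spatial_permutation():
    rng = np.random.default_rng(5)
    window = rng.integers(0, 256, size=(8, 8))
    shuffled = rng.permutation(window.ravel()).reshape(8, 8)
    assert np.array_equal(
        window_histogram(window, (0, 0), 8), window_histogram(shuffled, (0, 0), 8)
    )


# ---------------------------------------------------------------------------
# cosine similarity


def test_cosine_similarity_closed_forms():
    a = np.zeros(256)
    a[0] = 1
    b = np.zeros(256)
    b[0] = 1
    b[1] = 1
    assert cosine_similarity(a, a) == pytest.approx(1.0)
    assert cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))
    c = np.zeros(256)
    c[5] = 3
    assert cosine_similarity(a, c) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        cosine_similarity(a, np.zeros(256))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), scale=st.floats(0.01, 100.0))
def test_cosine_similarity_properties(seed, scale):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 50, size=256).astype(float) + 1
    b = rng.integers(0, 50, size=256).astype(float) + 1
    s = cosine_similarity(a, b)
    assert 0.0 <= s <= 1.0 + 1e-12
    assert s == pytest.approx(cosine_similarity(b, a))
    assert s == pytest.approx(cosine_similarity(a * scale, b))


# ---------------------------------------------------------------------------
# classification


def test_classify_window_exact_and_orthogonal_matches():
    g = np.zeros(256)
    g[:10] = 5
    f = np.zeros(256)
    f[100:110] = 3
    templates = [("grass", g), ("forb", f)]
    label, best = classify_window(g, templates)
    assert label == "grass" and best["grass"] == pytest.approx(1.0)
    label, _ = classify_window(f, templates)
    assert label == "forb"
    with pytest.raises(ValueError):
        classify_window(g, [("grass", g)])


def test_classify_window_matches_argmax_oracle():
    rng = np.random.default_rng(6)
    templates = [
        ("grass" if i % 2 == 0 else "forb", rng.integers(1, 30, size=256).astype(float))
        for i in range(5)
    ]
    for _ in range(20):
        h = rng.integers(0, 30, size=256).astype(float) + 1
        sims = [cosine_similarity(h, t[1]) for t in templates]
        want = templates[int(np.argmax(sims))][0]
        got, _ = classify_window(h, templates)
        assert got == want


def test_classifier_fit_validation():
    X = np.ones((3, 256))
    with pytest.raises(ValueError):
        TemplateTextureClassifier().fit(X, ["grass", "grass", "grass"])
    with pytest.raises(ValueError):
        TemplateTextureClassifier().fit(np.ones((2, 10)), ["grass", "forb"])


def test_classify_vegetation_empty_mask(classifier, fixtures):
    scene = fixtures.scenes["test"][0]
    labels = classifier.classify_image(scene.image, np.zeros(scene.image.shape[:2], bool))
    assert np.all(labels == "")


def test_window_accuracy_on_unseen_pure_scenes(classifier, fixtures):
    W = fixtures.window_size
    for label, f_grass, f_forb, seed in [("grass", 1.0, 0.0, 301), ("forb", 0.0, 1.0, 302)]:
        scene = generate_quadrat(SceneSpec(size=160, f_grass=f_grass, f_forb=f_forb, seed=seed))
        codes = lbp_image(to_gray(scene.image))
        rng = np.random.default_rng(seed)
        hists = np.array(
            [
                window_histogram(
                    codes,
                    (int(rng.integers(0, 160 - W)), int(rng.integers(0, 160 - W))),
                    W,
                )
                for _ in range(60)
            ]
        )
        acc = float(np.mean(classifier.predict(hists) == label))
        assert acc >= 0.9, f"{label} accuracy {acc}"


def test_half_grass_half_forb_scene_per_pixel_labels(fixtures, classifier, detector):
    # stitch a pure-grass and a pure-forb scene side by side
    g = generate_quadrat(SceneSpec(size=128, f_grass=1.0, f_forb=0.0, seed=311))
    f = generate_quadrat(SceneSpec(size=128, f_grass=0.0, f_forb=1.0, seed=312))
    image = np.concatenate([g.image, f.image], axis=1)
    veg = np.concatenate([g.vegetation_mask, f.vegetation_mask], axis=1)
    labels = classifier.classify_image(image, veg, stride=2)
    # score away from the seam
    cols = np.arange(image.shape[1])
    away = (np.abs(cols - 128) > 8)[None, :] & veg
    truth = np.broadcast_to(np.where(cols < 128, "grass", "forb"), veg.shape)
    acc = float(np.mean(labels[away] == truth[away]))
    assert acc >= 0.9
    assert np.all(labels[~veg] == "")


def test_classify_vegetation_functional_wrapper(fixtures):
    scene = fixtures.scenes["test"][1]
    labels = classify_vegetation(
        scene.image,
        scene.vegetation_mask,
        fixtures.templates,
        stride=4,
        window_size=fixtures.window_size,
    )
    veg_labels = labels[scene.vegetation_mask]
    assert set(np.unique(veg_labels)) <= {"grass", "forb"}
    assert np.all(labels[~scene.vegetation_mask] == "")
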