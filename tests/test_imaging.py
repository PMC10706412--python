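"""Unit and property tests for the sensor-array imaging pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.filters import threshold_otsu as sk_otsu

import cnose
from cnose.exceptions import SegmentationError
from cnose.imaging import (
    Phase,
    SensorImage,
    SpotLabelMap,
    apply_mask,
    area_open,
    difference_map,
    label_spots,
    otsu_threshold,
    refine_mask,
    rescale_for_display,
    to_grayscale,
)


def _image(arr, phase=Phase.PRE):
    return SensorImage(np.asarray(arr, dtype=np.uint8), phase=phase)


def _uniform(h, w, rgb, phase=Phase.PRE):
    return _image(np.full((h, w, 3), 0, np.uint8) + np.array(rgb, np.uint8), phase)


# ---------------------------------------------------------------------------
# Grayscale
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rgb, expected",
    [
        # the four-decimal BT.601 weights sum to 0.9999, so a uniform
        # gray is reproduced to within 0.02 of its level, not exactly
        ((200, 200, 200), 199.98),
        ((255, 0, 0), 76.2195),
        ((0, 0, 0), 0.0),
    ],
)
def test_grayscale_luminance(rgb, expected):
    g = to_grayscale(_uniform(4, 5, rgb))
    assert g.shape == (4, 5)
    assert np.allclose(g, expected)


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

def _otsu_bruteforce(gray):
    """Exhaustive 256-candidate between-class variance maximiser."""
    hist, _ = np.histogram(gray, bins=256, range=(0, 256))
    total = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def test_otsu_two_population_mask():
    # 1000 px of background-like 50 bordering 200 px of spot-like 200.
    rng = np.random.default_rng(0)
    gray = np.full((30, 40), 50.0)
    inner = [(r, c) for r in range(5, 25) for c in range(5, 35)]
    pick = rng.choice(len(inner), size=200, replace=False)
    for i in pick:
        gray[inner[i]] = 200.0
    t, mask = otsu_threshold(gray)
    assert 50 <= t < 200
    assert mask.sum() == 200  # foreground = the class unlike the border
    assert (gray[mask] == 200).all()


def test_otsu_perfectly_bimodal():
    gray = np.zeros((10, 10))
    gray[:, 5:] = 255.0
    t, mask = otsu_threshold(gray)
    assert (mask == (gray == 255)).all() or (mask == (gray == 0)).all()


def test_otsu_constant_raster_errors():
    with pytest.raises(ValueError, match="degenerate"):
        otsu_threshold(np.full((8, 8), 7.0))


@given(
    hnp.arrays(
        np.uint8,
        (16, 16),
        elements=st.integers(0, 255),
    )
)
def test_otsu_matches_exhaustive_search(arr):
    gray = arr.astype(float)
    if len(np.unique(np.floor(gray))) < 2:
        return
    t, _ = otsu_threshold(gray)
    assert t == _otsu_bruteforce(gray)


def test_otsu_partition_agrees_with_skimage_on_bimodal():
    rng = np.random.default_rng(1)
    gray = np.where(rng.random((32, 32)) < 0.7, 60.0, 190.0)
    gray += rng.integers(-5, 6, gray.shape)
    t, mask = otsu_threshold(gray)
    sk_t = sk_otsu(gray.astype(np.uint8))
    ours_high = gray > t
    theirs_high = gray > sk_t
    assert (ours_high == theirs_high).all()


# ---------------------------------------------------------------------------
# Area opening
# ---------------------------------------------------------------------------

def test_area_open_strict_threshold():
    mask = np.zeros((100, 120), bool)
    mask[5:32, 5:42] = True      # 27 x 37 = 999 px -> removed
    mask[50:80, 50:100] = True   # 30 x 50 = 1500 px -> kept
    out = area_open(mask, 1000)
    assert not out[5:32, 5:42].any()
    assert (out[50:80, 50:100]).all()
    # exactly-1000 component is preserved (strict "smaller than")
    mask2 = np.zeros((60, 60), bool)
    mask2[5:30, 5:45] = True     # 25 x 40 = 1000 px
    assert (area_open(mask2, 1000) == mask2).all()


def test_area_open_empty_and_idempotent():
    empty = np.zeros((10, 10), bool)
    assert not area_open(empty, 1000).any()
    rng = np.random.default_rng(3)
    mask = rng.random((40, 40)) < 0.4
    once = area_open(mask, 20)
    assert (area_open(once, 20) == once).all()
    with pytest.raises(ValueError):
        area_open(mask, 0)


# ---------------------------------------------------------------------------
# Refinement (erosion + hole filling)
# ---------------------------------------------------------------------------

def _erode_bruteforce(mask, radius):
    """Pixelwise definition: output on iff every disk offset stays on."""
    offs = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if np.hypot(dr, dc) <= radius
    ]
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            out[r, c] = all(
                0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
                for dr, dc in offs
            )
    return out


def test_erosion_of_square_by_disk():
    mask = np.zeros((60, 60), bool)
    mask[5:55, 5:55] = True
    out = refine_mask(mask, erosion_radius=2, max_hole=1)
    expected = np.zeros((60, 60), bool)
    expected[7:53, 7:53] = True  # 46 x 46 centred square
    assert (out == expected).all()


def test_erosion_matches_bruteforce_on_random_masks():
    rng = np.random.default_rng(7)
    for radius in (1, 2):
        for _ in range(5):
            mask = rng.random((16, 16)) < 0.6
            out = refine_mask(mask, erosion_radius=radius, max_hole=1)
            assert (out == _erode_bruteforce(mask, radius)).all()


def test_hole_filling():
    mask = np.zeros((40, 40), bool)
    rr, cc = np.mgrid[0:40, 0:40]
    mask[np.hypot(rr - 20, cc - 20) <= 15] = True
    mask[19:22, 19:22] = False  # 9-px interior hole
    out = refine_mask(mask, erosion_radius=1, max_hole=100)
    assert out[20, 20]  # hole recovered
    # hole at least max_hole px is kept
    mask[15:25, 15:25] = False  # 100-px hole
    out2 = refine_mask(mask, erosion_radius=1, max_hole=100)
    assert not out2[20, 20]


def test_hole_touching_border_not_filled():
    mask = np.ones((20, 20), bool)
    mask[0:10, 9:11] = False  # background channel reaching the border
    out = refine_mask(mask, erosion_radius=1, max_hole=400)
    assert not out[1, 10]


def test_erosion_larger_than_component_empties_mask():
    mask = np.zeros((20, 20), bool)
    mask[8:12, 8:12] = True
    assert not refine_mask(mask, erosion_radius=3, max_hole=1).any()
    with pytest.raises(ValueError):
        refine_mask(mask, erosion_radius=0, max_hole=10)
    with pytest.raises(ValueError):
        refine_mask(mask, erosion_radius=1, max_hole=0)


def test_eroded_mask_is_subset_of_input():
    rng = np.random.default_rng(11)
    mask = rng.random((30, 30)) < 0.6
    out = refine_mask(mask, erosion_radius=1, max_hole=1)
    assert not (out & ~mask).any()


# ---------------------------------------------------------------------------
# Spot labelling
# ---------------------------------------------------------------------------

def _grid_mask(centroids, half=4, shape=(80, 130)):
    mask = np.zeros(shape, bool)
    for r, c in centroids:
        mask[r - half : r + half + 1, c - half : c + half + 1] = True
    return mask


def test_label_spots_reading_order():
    cents = [(20, 20), (20, 60), (20, 100), (55, 20), (55, 60), (55, 100)]
    labels = label_spots(_grid_mask(cents), expected_k=6)
    assert labels.n_spots == 6
    for k, (r, c) in enumerate(cents, start=1):
        assert labels.labels[r, c] == k
        assert np.allclose(labels.centroids[k - 1], (r, c))


def test_label_spots_order_depends_only_on_geometry():
    # Reading order of a vertically flipped grid maps spot k -> 7 - k
    # within rows swapped: geometry alone fixes the labels.
    cents = [(20, 20), (20, 60), (20, 100), (55, 20), (55, 60), (55, 100)]
    mask = _grid_mask(cents)
    flipped = mask[::-1, :]
    lab = label_spots(mask, 6)
    lab_f = label_spots(flipped, 6)
    assert (lab_f.labels[::-1, :] == ((lab.labels + 2) % 6 + 1) * (lab.labels > 0)).all()


def test_label_spots_single_and_mismatch():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    lab = label_spots(mask, expected_k=1)
    assert lab.n_spots == 1
    with pytest.raises(SegmentationError, match="1 components, expected 6"):
        label_spots(mask, expected_k=6)


def test_label_spots_tolerates_slight_row_stagger():
    cents = [(19, 20), (21, 60), (20, 100), (54, 20), (56, 60), (55, 100)]
    labels = label_spots(_grid_mask(cents), expected_k=6)
    got = [labels.labels[r, c] for r, c in cents]
    assert got == [1, 2, 3, 4, 5, 6]


# ---------------------------------------------------------------------------
# Masking and difference maps
# ---------------------------------------------------------------------------

def _label_map_from_mask(mask, k=1):
    return label_spots(mask, expected_k=k)


def test_apply_mask_cases():
    rng = np.random.default_rng(5)
    img = _image(rng.integers(0, 256, (20, 20, 3)))
    all_bg = SpotLabelMap(np.zeros((20, 20), np.int32), centroids=())
    assert (apply_mask(img, all_bg).pixels == 0).all()
    mask = np.zeros((20, 20), bool)
    mask[:, :10] = True
    labels = _label_map_from_mask(mask)
    out = apply_mask(img, labels)
    assert (out.pixels[:, :10] == img.pixels[:, :10]).all()
    assert (out.pixels[:, 10:] == 0).all()
    # channel sums restricted to foreground
    assert out.pixels.sum(axis=(0, 1)) == pytest.approx(
        img.pixels[:, :10].sum(axis=(0, 1))
    )


def test_difference_map_identical_and_shift():
    base = np.full((30, 30, 3), 100, np.uint8)
    mask = np.zeros((30, 30), bool)
    mask[10:20, 10:20] = True
    labels = _label_map_from_mask(mask)
    pre = _image(base, Phase.PRE)
    assert difference_map(pre, _image(base, Phase.POST), labels).deltas.sum() == 0

    post = base.copy()
    post[10:20, 10:20] = [110, 80, 105]  # shift (+10, -20, +5)
    dm = difference_map(pre, _image(post, Phase.POST), labels)
    assert np.allclose(dm.deltas[15, 15], [10, 20, 5])
    assert dm.deltas[(~mask)].sum() == 0


def test_difference_map_matches_pixel_loop_and_symmetry():
    rng = np.random.default_rng(9)
    a = rng.integers(0, 256, (12, 14, 3)).astype(np.uint8)
    b = rng.integers(0, 256, (12, 14, 3)).astype(np.uint8)
    mask = rng.random((12, 14)) < 0.5
    mask[0, 0] = True
    from skimage import measure

    lab = measure.label(mask, connectivity=2)
    labels = label_spots(mask, expected_k=lab.max())
    dm = difference_map(_image(a, Phase.PRE), _image(b, Phase.POST), labels)
    for r in range(12):
        for c in range(14):
            for ch in range(3):
                want = abs(int(b[r, c, ch]) - int(a[r, c, ch])) if labels.labels[r, c] else 0
                assert dm.deltas[r, c, ch] == want
    # swapping pre and post pixel content leaves |post - pre| unchanged
    dm_swap = difference_map(_image(b, Phase.PRE), _image(a, Phase.POST), labels)
    assert (dm.deltas == dm_swap.deltas).all()


def test_difference_map_contracts():
    base = np.zeros((10, 10, 3), np.uint8)
    mask = np.zeros((10, 10), bool)
    mask[2:8, 2:8] = True
    labels = _label_map_from_mask(mask)
    with pytest.raises(ValueError, match="phase"):
        difference_map(_image(base, Phase.POST), _image(base, Phase.POST), labels)
    with pytest.raises(ValueError, match="shape"):
        difference_map(
            _image(base, Phase.PRE), _image(np.zeros((9, 10, 3), np.uint8), Phase.POST), labels
        )


def test_difference_map_registration_guard():
    base = np.zeros((30, 40, 3), np.uint8)
    m1 = np.zeros((30, 40), bool)
    m1[5:15, 5:15] = True
    m2 = np.zeros((30, 40), bool)
    m2[5:15, 25:35] = True  # centroid 20 px away
    l1, l2 = _label_map_from_mask(m1), _label_map_from_mask(m2)
    with pytest.raises(SegmentationError, match="mis-registered"):
        difference_map(_image(base, Phase.PRE), _image(base, Phase.POST), l1, post_labels=l2)


# ---------------------------------------------------------------------------
# Display rescaling
# ---------------------------------------------------------------------------

def _dm(value):
    labels = SpotLabelMap(np.ones((2, 2), np.int32), centroids=((0.5, 0.5),))
    return cnose.DifferenceMap(np.full((2, 2, 3), float(value)), labels)


@pytest.mark.parametrize(
    "value, expected", [(3.0, 0), (62.0, 255), (0.0, 0), (100.0, 255), (32.5, 128)]
)
def test_rescale_endpoints_and_rounding(value, expected):
    assert (rescale_for_display(_dm(value)) == expected).all()


@given(st.lists(st.floats(0, 255), min_size=2, max_size=20))
def test_rescale_monotone_and_saturating(values):
    out = [int(rescale_for_display(_dm(v))[0, 0, 0]) for v in values]
    order = np.argsort(values)
    sorted_out = np.array(out)[order]
    assert (np.diff(sorted_out) >= 0).all()
    assert all(0 <= o <= 255 for o in out)
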