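"""Thresholding, binary morphology, distance transform and markers."""

import numpy as np
import pytest

from accca.enhance import (
    MarkerSet,
    StructuringElement,
    binary_threshold,
    clear_borders,
    distance_transform,
    extract_markers,
    morphology,
    to_gray,
)

from _oracles import (
    border_components,
    brute_force_edt,
    minkowski_dilate,
    minkowski_erode,
    otsu_threshold_256,
    repeat,
)


def disk(shape, center, radius):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(rows - center[0], cols - center[1]) <= radius


@pytest.mark.parametrize(
    "pixel, expected",
    [((1, 1, 1), 1.0), ((0, 0, 0), 0.0), ((1, 0, 0), 0.299)],
)
def test_gray_luminance_weights(pixel, expected):
    img = np.array(pixel, dtype=float).reshape(1, 1, 3)
    assert to_gray(img)[0, 0] == pytest.approx(expected)


def test_otsu_splits_bimodal_image(rng):
    gray = np.where(rng.uniform(size=(40, 40)) < 0.6, 0.2, 0.8)
    mask = binary_threshold(gray, "otsu")
    np.testing.assert_array_equal(mask, gray == 0.2)


def test_otsu_matches_brute_force_search(rng):
    # coarsely quantized values: both thresholds then fall strictly between
    # occupied levels, so the induced masks must agree exactly
    for _ in range(5):
        gray = np.round(rng.uniform(size=(32, 32)), 1)
        t_oracle = otsu_threshold_256(gray)
        mask = binary_threshold(gray, "otsu")
        np.testing.assert_array_equal(mask, gray < t_oracle)


def test_fixed_threshold_and_constant_image():
    gray = np.array([[0.4, 0.6]])
    np.testing.assert_array_equal(
        binary_threshold(gray, "fixed", level=0.5), [[True, False]]
    )
    with pytest.warns(UserWarning):
        mask = binary_threshold(np.full((5, 5), 0.5), "otsu")
    assert not mask.any()


def test_single_pixel_dilation_and_block_erosion():
    mask = np.zeros((7, 7), dtype=bool)
    mask[3, 3] = True
    out = morphology(mask, "dilate", StructuringElement.square(3))
    assert out.sum() == 9 and out[2:5, 2:5].all()
    block = np.zeros((7, 7), dtype=bool)
    block[2:5, 2:5] = True
    out = morphology(block, "erode", StructuringElement.square(3))
    assert out.sum() == 1 and out[3, 3]


@pytest.mark.parametrize("op", ["erode", "dilate", "open", "close"])
def test_morphology_matches_minkowski_oracle(op, rng):
    fp = np.ones((3, 3), dtype=bool)
    for _ in range(10):
        mask = rng.uniform(size=(16, 16)) < 0.5
        for iters in (1, 2):
            got = morphology(mask, op, StructuringElement(fp, iters))
            if op == "erode":
                want = repeat(minkowski_erode, mask, fp, iters)
            elif op == "dilate":
                want = repeat(minkowski_dilate, mask, fp, iters)
            elif op == "open":
                want = repeat(
                    minkowski_dilate,
                    repeat(minkowski_erode, mask, fp, iters), fp, iters,
                )
            else:
                want = repeat(
                    minkowski_erode,
                    repeat(minkowski_dilate, mask, fp, iters), fp, iters,
                )
            np.testing.assert_array_equal(got, want)


def test_dilation_erosion_duality_on_interior(rng):
    # duality holds away from the frame, where the border convention is moot
    se = StructuringElement.square(3)
    for _ in range(20):
        mask = rng.uniform(size=(20, 20)) < 0.4
        mask[:2] = mask[-2:] = False
        mask[:, :2] = mask[:, -2:] = False
        dual = ~morphology(~mask, "erode", se)
        np.testing.assert_array_equal(
            morphology(mask, "dilate", se)[2:-2, 2:-2], dual[2:-2, 2:-2]
        )


def test_opening_idempotent_and_monotone(rng):
    se = StructuringElement.square(3)
    for _ in range(10):
        mask = rng.uniform(size=(24, 24)) < 0.5
        opened = morphology(mask, "open", se)
        np.testing.assert_array_equal(morphology(opened, "open", se), opened)
        eroded = morphology(mask, "erode", se)
        dilated = morphology(mask, "dilate", se)
        assert not (eroded & ~mask).any()
        assert not (mask & ~dilated).any()


def test_clear_borders_matches_flood_fill_oracle(rng):
    mask = np.zeros((10, 10), dtype=bool)
    mask[0, 3:6] = True  # touches row 0 -> removed
    mask[5:7, 5:7] = True  # interior -> kept
    out = clear_borders(mask)
    assert not out[0].any() and out[5:7, 5:7].all()
    for _ in range(20):
        mask = rng.uniform(size=(18, 18)) < 0.4
        np.testing.assert_array_equal(clear_borders(mask),
                                      border_components(mask))


def test_distance_transform_geometry_and_oracle(rng):
    mask = np.ones((3, 3), dtype=bool)
    mask[1, 1] = False
    dist = distance_transform(mask)
    assert dist[0, 1] == pytest.approx(1.0)
    assert dist[0, 0] == pytest.approx(np.sqrt(2))
    assert not distance_transform(np.zeros((4, 4), dtype=bool)).any()
    for _ in range(5):
        mask = rng.uniform(size=(24, 24)) < 0.6
        got = distance_transform(mask)
        assert np.abs(got - brute_force_edt(mask)).max() < 1e-6


def test_distance_transform_all_true_uses_virtual_border():
    dist = distance_transform(np.ones((5, 7), dtype=bool))
    assert dist[0, 0] == pytest.approx(1.0)
    assert dist[2, 3] == pytest.approx(3.0)
    np.testing.assert_allclose(dist, brute_force_edt(np.ones((5, 7), bool)))


def test_markers_on_single_disk():
    mask = disk((40, 40), (20, 20), 10)
    dist = distance_transform(mask)
    markers = extract_markers(mask, dist, fg_fraction=0.5)
    rows, cols = np.nonzero(markers.sure_fg)
    radii = np.hypot(rows - 20, cols - 20)
    assert radii.max() <= 6.0  # concentric disk of radius ~5 +- 1
    assert markers.sure_fg[20, 20]
    assert markers.sure_fg[disk((40, 40), (20, 20), 4)].all()


def test_markers_two_disks_disjoint_structure():
    from scipy import ndimage as ndi
    mask = disk((50, 90), (25, 22), 10) | disk((50, 90), (25, 65), 10)
    markers = extract_markers(mask, distance_transform(mask), 0.5)
    _, k_fg = ndi.label(markers.sure_fg, structure=np.ones((3, 3)))
    _, k_unknown = ndi.label(markers.unknown, structure=np.ones((3, 3)))
    assert k_fg == 2 and k_unknown == 2


def test_markers_partition_invariants(rng):
    for _ in range(10):
        mask = rng.uniform(size=(30, 30)) < 0.3
        markers = extract_markers(mask, distance_transform(mask), 0.5)
        assert not (markers.sure_fg & markers.unknown).any()
        assert not (markers.sure_fg & markers.sure_bg).any()
        assert not (markers.unknown & markers.sure_bg).any()
        covered = markers.sure_fg | markers.unknown | markers.sure_bg
        assert covered.all()


def test_markers_empty_mask():
    empty = np.zeros((8, 8), dtype=bool)
    markers = extract_markers(empty, distance_transform(empty), 0.5)
    assert isinstance(markers, MarkerSet)
    assert not markers.sure_fg.any() and not markers.unknown.any()
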