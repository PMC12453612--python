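"""Pixel-rule contracts: yellow/brown classification, component filtering,
head counting, mound extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volehabitat.classify import (
    BrownWindow,
    PixelMask,
    calibrate_brown_window,
    classify_brown,
    classify_yellow,
    count_flower_heads,
    extract_mound_points,
    filter_small_components,
)
from volehabitat.scene import RGBScene


def scene_from(pixels: np.ndarray) -> RGBScene:
    return RGBScene(pixels=np.asarray(pixels, dtype=np.float32), resolution=0.01)


@pytest.mark.parametrize(
    "pixel, expected",
    [
        ((0.95, 0.95, 0.05), True),  # canonical dandelion pixel
        ((0.90, 0.95, 0.05), False),  # boundary: rule is strictly >
        ((0.95, 0.90, 0.05), False),
        ((0.95, 0.95, 0.10), False),  # boundary: rule is strictly <
        ((0.35, 0.60, 0.25), False),  # green sward
    ],
)
def test_yellow_rule_pointwise(pixel, expected):
    scene = scene_from(np.array(pixel).reshape(1, 1, 3))
    assert bool(classify_yellow(scene).values[0, 0]) is expected


def test_yellow_rule_rejects_unscaled_bands():
    with pytest.raises(ValueError):
        classify_yellow(scene_from(np.full((2, 2, 3), 255.0)))


def test_brown_calibration_degenerate_training_pixels():
    scene = scene_from(np.tile([0.5, 0.3, 0.2], (4, 4, 1)))
    pts = pd.DataFrame({"x_m": np.full(12, 0.02), "y_m": np.full(12, 0.02)})
    win = calibrate_brown_window(scene, pts)
    assert (win.r_min, win.r_max) == (0.5, 0.5)
    assert (win.g_min, win.g_max) == (0.3, 0.3)
    assert (win.b_min, win.b_max) == (0.2, 0.2)


def test_brown_calibration_window_contains_true_triple_under_noise(rng):
    true = np.array([0.45, 0.30, 0.18])
    px = true + rng.normal(0, 0.01, size=(50, 50, 3))
    scene = scene_from(np.clip(px, 0, 1))
    xy = rng.uniform(0.05, 0.45, size=(40, 2))
    win = calibrate_brown_window(scene, pd.DataFrame({"x_m": xy[:, 0], "y_m": xy[:, 1]}))
    assert win.r_min <= true[0] <= win.r_max
    assert win.g_min <= true[1] <= win.g_max
    assert win.b_min <= true[2] <= win.b_max


def test_brown_calibration_disjoint_colors_warns_wide():
    px = np.tile([0.1, 0.1, 0.1], (4, 4, 1)).astype(np.float32)
    px[:, 2:] = [0.9, 0.9, 0.9]
    scene = scene_from(px)
    pts = pd.DataFrame({"x_m": [0.005] * 6 + [0.035] * 6, "y_m": [0.02] * 12})
    with pytest.warns(UserWarning, match="wide"):
        win = calibrate_brown_window(scene, pts)
    assert win.r_min <= win.r_max  # still a valid envelope


def test_brown_classification_centre_and_disjoint_pixel():
    win = BrownWindow(0.4, 0.5, 0.25, 0.35, 0.15, 0.25)
    scene = scene_from(np.array([[[0.45, 0.30, 0.20], [0.95, 0.95, 0.05]]]))
    mask = classify_brown(scene, win)
    assert bool(mask.values[0, 0]) and not bool(mask.values[0, 1])


def test_empty_training_set_is_an_error():
    scene = scene_from(np.zeros((2, 2, 3)))
    with pytest.raises(ValueError):
        calibrate_brown_window(scene, pd.DataFrame({"x_m": [], "y_m": []}))


def _mask(arr) -> PixelMask:
    return PixelMask(np.asarray(arr, dtype=bool), "yellow", 0.01)


def test_component_filter_removes_buttercup_dot_keeps_flower_disc():
    m = np.zeros((10, 10), dtype=bool)
    m[1, 1:3] = True  # 2-px buttercup dot
    m[5:8, 5:8] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]  # 5-px cross
    m[5, 6] = m[6, 5] = m[6, 6] = m[6, 7] = m[7, 6] = True
    m[4, 6] = True  # extend to 7 px
    out = filter_small_components(_mask(m), min_pixels=4)
    assert out.values[1, 1:3].sum() == 0
    assert out.values.sum() >= 6


def test_component_filter_identity_at_one_pixel(rng):
    m = _mask(rng.random((20, 20)) < 0.2)
    out = filter_small_components(m, min_pixels=1)
    assert np.array_equal(out.values, m.values)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=2**31 - 1))
def test_component_filter_is_monotone_in_min_pixels(k, seed):
    m = _mask(np.random.default_rng(seed).random((15, 15)) < 0.3)
    smaller = filter_small_components(m, min_pixels=k)
    larger = filter_small_components(m, min_pixels=k + 2)
    assert larger.values.sum() <= smaller.values.sum()
    assert not (larger.values & ~smaller.values).any()  # nested masks


@pytest.mark.parametrize(
    "n_pixels, expected_heads",
    [(7, 1.0), (0, 0.0), (70, 10.0), (10, 10 / 7)],
)
def test_head_count_from_yellow_area(n_pixels, expected_heads):
    m = np.zeros((20, 20), dtype=bool)
    m.ravel()[:n_pixels] = True
    assert count_flower_heads(_mask(m)) == pytest.approx(expected_heads)


def test_head_count_rejects_nonpositive_resolution():
    with pytest.raises(ValueError):
        count_flower_heads(_mask(np.ones((2, 2))), resolution=0.0)


def test_mound_extraction_centroid_and_area_partition():
    m = np.zeros((100, 100), dtype=bool)
    m[10:20, 10:20] = True  # 100 px at known centre
    m[60:70, 60:75] = True  # 150 px
    pts = extract_mound_points(PixelMask(m, "brown", 0.01))
    assert len(pts) == 2
    assert pts["area_m2"].sum() == pytest.approx(250 * 1e-4)
    # square block rows 10..19, cols 10..19 -> centre (0.15, 0.855) in metres
    first = pts.sort_values("x_m").iloc[0]
    assert first["x_m"] == pytest.approx(0.15, abs=0.011)
    assert first["y_m"] == pytest.approx(1.0 - 0.145, abs=0.011)


def test_mound_extraction_empty_mask():
    assert len(extract_mound_points(PixelMask(np.zeros((5, 5)), "brown", 0.01))) == 0


def test_masks_idempotent_under_refiltering(rng):
    m = _mask(rng.random((30, 30)) < 0.25)
    once = filter_small_components(m, 4)
    twice = filter_small_components(once, 4)
    assert np.array_equal(once.values, twice.values)
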