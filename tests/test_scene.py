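"""Generator contracts: point-process moments, colonization draws, thinning,
rendering geometry, series determinism."""

import numpy as np
import pandas as pd
import pytest

from volehabitat.scene import (
    SceneParams,
    apply_depletion,
    assign_colonization,
    generate_flower_pattern,
    render_scene,
    simulate_series,
)
from volehabitat.classify import classify_brown, classify_yellow, calibrate_brown_window


def test_zero_parent_intensity_gives_empty_pattern(small_params):
    p = small_params.replace(flower_parent_intensity=0.0)
    assert len(generate_flower_pattern(p, 0)) == 0


def test_thomas_process_mean_count_matches_closed_form():
    # E[N] = kappa * A * mu; Monte-Carlo mean over seeds within 3 SE
    p = SceneParams(quadrat_width=20, quadrat_height=16, flower_parent_intensity=0.1,
                    flower_mean_offspring=10.0, flower_cluster_sd=0.8)
    expected = 0.1 * 320 * 10.0
    counts = np.array([len(generate_flower_pattern(p, s)) for s in range(400)])
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - expected) < 3 * se


def test_zero_cluster_sd_collapses_offspring_onto_parents(small_params):
    p = small_params.replace(flower_cluster_sd=0.0, flower_mean_offspring=20.0)
    pts = generate_flower_pattern(p, 5)
    n_unique = len(pts[["x_m", "y_m"]].drop_duplicates())
    # offspring coincide with parents: far fewer unique locations than points
    assert n_unique < len(pts) / 2


def test_negative_parameter_rejected():
    with pytest.raises(ValueError):
        SceneParams(flower_parent_intensity=-1.0)
    with pytest.raises(ValueError):
        SceneParams(depletion_delta=1.5)
    with pytest.raises(ValueError):
        SceneParams(colonization_beta=(0.0, 1.0))


def test_saturated_negative_logit_colonizes_nothing(small_params):
    p = small_params.replace(colonization_beta=(-50.0, 0.0, 0.0, 0.0))
    gt = assign_colonization(generate_flower_pattern(p, 1), p, 2)
    assert gt.realized_colonized_tiles.sum() == 0
    assert len(gt.mound_points) == 0


def test_zero_logit_colonizes_half_the_tiles(small_params):
    p = small_params.replace(colonization_beta=(0.0, 0.0, 0.0, 0.0))
    flowers = generate_flower_pattern(p, 1)
    hits = []
    for s in range(40):
        gt = assign_colonization(flowers, p, s)
        hits.append(gt.realized_colonized_tiles.mean())
    freq = np.mean(hits)
    n = 40 * 80
    assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)


def test_positive_anomaly_effect_makes_colonization_monotone_in_anomaly():
    # empirical colonization frequency rises across anomaly deciles
    from volehabitat.experiments import simulate_tile_dataset

    df = simulate_tile_dataset(40, seed=3, beta=(-2.0, 2.0, 0.0, 0.0), n_years=1)
    df = df[df["Anom"] > -1]  # zero-flower tiles all share Anom = -1 (tied)
    df["decile"] = pd.qcut(df["Anom"].rank(method="first"), 10, labels=False)
    freq = df.groupby("decile")["Col"].mean()
    assert (np.diff(freq) > 0).all()


def test_colonized_tiles_have_positive_probability(small_params):
    gt = assign_colonization(generate_flower_pattern(small_params, 1), small_params, 2)
    assert (gt.tile_colonization_probs[gt.realized_colonized_tiles] > 0).all()
    for col in ("x_m", "y_m"):
        lim = small_params.quadrat_width if col == "x_m" else small_params.quadrat_height
        assert gt.mound_points[col].between(0, lim).all()


def test_no_depletion_is_identity(small_params, rng):
    p = small_params.replace(depletion_delta=0.0)
    flowers = generate_flower_pattern(p, 1)
    mounds = pd.DataFrame({"x_m": [5.0], "y_m": [5.0], "kind": "mound"})
    out = apply_depletion(flowers, mounds, p, rng)
    pd.testing.assert_frame_equal(out, flowers)


def test_full_depletion_removes_flowers_at_contact(small_params):
    p = small_params.replace(depletion_delta=1.0)
    flowers = pd.DataFrame({"x_m": [5.0] * 200, "y_m": [5.0] * 200, "kind": "flower"})
    mounds = pd.DataFrame({"x_m": [5.0], "y_m": [5.0]})
    out = apply_depletion(flowers, mounds, p, np.random.default_rng(0))
    assert len(out) == 0


def test_depletion_retention_matches_kernel_at_half_range(small_params):
    # r(d) = 1 - delta * (1 - d/range); at d = range/2, delta = 0.8 -> 0.6
    p = small_params.replace(depletion_delta=0.8, depletion_range=4.0)
    n = 10_000
    flowers = pd.DataFrame({"x_m": [7.0] * n, "y_m": [5.0] * n, "kind": "flower"})
    mounds = pd.DataFrame({"x_m": [5.0], "y_m": [5.0]})
    out = apply_depletion(flowers, mounds, p, np.random.default_rng(3))
    freq = len(out) / n
    assert abs(freq - 0.6) < 3 * np.sqrt(0.6 * 0.4 / n)


def test_depletion_output_is_subset_of_input(small_params, rng):
    flowers = generate_flower_pattern(small_params, 2)
    mounds = pd.DataFrame({"x_m": [5.0, 10.0], "y_m": [8.0, 4.0]})
    out = apply_depletion(flowers, mounds, small_params, rng)
    assert len(out) <= len(flowers)
    merged = out.merge(flowers, on=["x_m", "y_m"], how="left", indicator=True)
    assert (merged["_merge"] == "both").all()


def test_empty_scene_has_no_yellow_or_brown_pixels(small_params, rng):
    empty = pd.DataFrame({"x_m": [], "y_m": [], "kind": []})
    scene = render_scene(empty, empty, small_params, rng)
    assert classify_yellow(scene).values.sum() == 0
    # any plausible earth window misses the green sward
    from volehabitat.classify import BrownWindow

    win = BrownWindow(0.35, 0.55, 0.2, 0.4, 0.08, 0.28)
    assert classify_brown(scene, win).values.sum() == 0


def test_single_flower_disc_matches_pixel_centre_oracle(small_params, rng):
    empty = pd.DataFrame({"x_m": [], "y_m": [], "kind": []})
    for dx, dy in [(0.005, 0.005), (0.002, 0.007), (0.009, 0.001)]:
        flowers = pd.DataFrame({"x_m": [10 + dx], "y_m": [8 + dy], "kind": ["flower"]})
        scene = render_scene(flowers, empty, small_params, rng)
        n_yellow = int(classify_yellow(scene).values.sum())
        # oracle: count pixel centres inside the 1.5 cm-radius disc
        cx, cy = np.meshgrid(np.arange(995, 1005) + 0.5, np.arange(795, 805) + 0.5)
        inside = ((cx * 0.01 - (10 + dx)) ** 2 + (cy * 0.01 - (8 + dy)) ** 2) <= 0.015**2
        assert n_yellow == inside.sum()
        assert 5 <= n_yellow <= 9  # ~7 cm^2 disc at 1 cm/px


def test_single_mound_brown_area_matches_disc_area(small_params, rng):
    mounds = pd.DataFrame({"x_m": [10.0], "y_m": [8.0], "radius_m": [0.10], "kind": ["mound"]})
    empty = pd.DataFrame({"x_m": [], "y_m": [], "kind": []})
    scene = render_scene(empty, mounds, small_params, rng)
    win = calibrate_brown_window(scene, pd.DataFrame({"x_m": [10.0] * 10, "y_m": [8.0] * 10}))
    area = classify_brown(scene, win).area_m2
    assert abs(area - np.pi * 0.10**2) / (np.pi * 0.10**2) < 0.10


def test_series_is_deterministic_and_thins_year2(small_params):
    p = small_params.replace(initial_colonization_rate=0.1, noise_sd=0.01)
    s1 = simulate_series(p, 11, render=True)
    s2 = simulate_series(p, 11, render=True)
    for (l1, sc1, t1), (_, sc2, t2) in zip(s1, s2):
        assert np.array_equal(sc1.pixels, sc2.pixels), l1
        assert np.array_equal(t1["colonized_tiles"], t2["colonized_tiles"])
    truth = {label: t for label, _, t in s1}
    assert len(truth["may_y2"]["flowers"]) < len(truth["may_y1"]["flowers"])


def test_series_without_colonization_has_no_new_october_mounds(small_params):
    p = small_params.replace(
        colonization_beta=(-50.0, 0.0, 0.0, 0.0), initial_colonization_rate=0.0
    )
    series = simulate_series(p, 4, render=False)
    truth = {label: t for label, _, t in series}
    assert len(truth["october_y1"]["mounds"]) == 0
    assert len(truth["october_y2"]["mounds"]) == 0
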