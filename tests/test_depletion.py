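"""Distance buffers and the depletion profile: oracle equivalence,
partition conservation, null calibration, signal recovery."""

import numpy as np
import pandas as pd
import pytest

from volehabitat import depletion as dep
from volehabitat import experiments as ex


def brute_force_nearest(f: np.ndarray, m: np.ndarray) -> np.ndarray:
    return np.sqrt(((f[:, None, :] - m[None, :, :]) ** 2).sum(-1)).min(axis=1)


def test_distance_simple_cases():
    m = pd.DataFrame({"x_m": [0.0], "y_m": [0.0]})
    f = pd.DataFrame({"x_m": [0.0, 3.0], "y_m": [0.0, 4.0]})
    d = dep.distance_to_mounds(f, m)
    assert d[0] == 0.0
    assert d[1] == pytest.approx(5.0)


def test_distance_matches_brute_force_oracle(rng):
    f = rng.uniform(0, 20, size=(1000, 2))
    m = rng.uniform(0, 20, size=(1000, 2))
    assert np.array_equal(dep.distance_to_mounds(f, m), brute_force_nearest(f, m))


def test_distance_requires_mounds():
    f = pd.DataFrame({"x_m": [1.0], "y_m": [1.0]})
    with pytest.raises(ValueError):
        dep.distance_to_mounds(f, pd.DataFrame({"x_m": [], "y_m": []}))


def test_log_buffer_edges_and_ratio():
    edges = dep.make_log_buffers()
    assert len(edges) == 21
    assert edges[0] == pytest.approx(0.05)
    assert edges[-1] == pytest.approx(5.0)
    ratios = edges[1:] / edges[:-1]
    assert np.allclose(ratios, 100 ** (1 / 20))
    assert dep.make_log_buffers(n=1).tolist() == pytest.approx([0.05, 5.0])
    with pytest.raises(ValueError):
        dep.make_log_buffers(5.0, 0.05)


def test_buffer_partition_conserves_flowers(rng):
    mounds = pd.DataFrame({"x_m": rng.uniform(5, 15, 20), "y_m": rng.uniform(5, 15, 20)})
    flowers = pd.DataFrame(
        {"x_m": rng.uniform(0, 20, 3000), "y_m": rng.uniform(0, 20, 3000), "kind": "flower"}
    )
    sp = dep.SubplotData("s0", mounds, flowers)
    rec = dep.depletion_profile(sp)
    d = dep.distance_to_mounds(flowers, mounds)
    beyond = (d > 5.0).sum()
    assert rec["flower_count"].sum() + beyond == len(flowers)
    # each in-range flower in exactly one annulus: sub-5 cm ones fold into buffer 1
    assert rec["flower_count"].iloc[0] == ((d <= rec["outer_radius"].iloc[0]).sum())


def test_annulus_area_exact_single_mound_centre():
    # one central mound, bands well inside the window: plain annulus areas
    m = np.array([[10.0, 10.0]])
    edges = np.array([0.05, 0.5, 1.0, 2.0])
    areas = dep.annulus_areas(m, (0, 0, 20, 20), edges)
    assert areas[0] == pytest.approx(np.pi * 0.5**2, rel=1e-3)  # extended to d=0
    assert areas[1] == pytest.approx(np.pi * (1.0**2 - 0.5**2), rel=1e-3)
    assert areas[2] == pytest.approx(np.pi * (2.0**2 - 1.0**2), rel=1e-3)


def test_annulus_area_raster_agrees_with_exact(rng):
    m = rng.uniform(6, 14, size=(15, 2))
    edges = dep.make_log_buffers()
    exact = dep.annulus_areas(m, (0, 0, 20, 20), edges)
    raster = dep.annulus_areas(m, (0, 0, 20, 20), edges, method="raster", resolution=0.01)
    # outer bands agree to ~1 %; innermost centimetre-scale bands are why
    # the exact method is the default
    assert np.allclose(exact[8:], raster[8:], rtol=0.02)


def test_null_profile_mean_is_one_in_every_buffer():
    null = ex.depletion_null_profile(n_seeds=40, n_subplots=6, seed=2)
    z = (null["mean_DD"] - 1.0) / null["se_DD"]
    assert np.abs(z).max() < 4.0  # 20 buffers, Monte-Carlo error only
    assert null["mean_DD"].to_numpy() == pytest.approx(1.0, abs=0.08)


def test_thinned_profile_increases_from_inner_to_outer():
    subs = ex.simulate_subplots(15, seed=8, depletion_delta=1.0)
    rec = pd.concat([dep.depletion_profile(sp) for sp in subs], ignore_index=True)
    prof = rec.groupby("buffer")["DD"].mean()
    assert prof.iloc[0] < 0.2  # near-total depletion at the mounds
    assert prof.iloc[-1] > prof.iloc[0]
    assert prof.iloc[-5:].mean() > prof.iloc[:5].mean()


def test_all_flowers_beyond_range_give_zero_depletion_ratios():
    mounds = pd.DataFrame({"x_m": [1.0], "y_m": [1.0]})
    flowers = pd.DataFrame({"x_m": np.full(50, 18.0), "y_m": np.linspace(10, 19, 50), "kind": "f"})
    sp = dep.SubplotData("s0", mounds, flowers)
    rec = dep.depletion_profile(sp)
    assert (rec["flower_count"] == 0).all()
    assert (rec["DD"].dropna() == 0).all()


def test_flowerless_subplot_is_an_error():
    sp_kw = dict(
        subplot_id="s0",
        mound_points=pd.DataFrame({"x_m": [1.0], "y_m": [1.0]}),
        flower_points=pd.DataFrame({"x_m": [], "y_m": []}),
    )
    with pytest.raises(ValueError):
        dep.depletion_profile(dep.SubplotData(**sp_kw))


def test_gam_requires_enough_subplots():
    rec = ex.simulate_depletion_records(3, seed=0)
    with pytest.raises(ValueError):
        dep.fit_depletion_gam(rec)


def test_ladder_prefers_subplot_only_model_without_distance_effect():
    rng = np.random.default_rng(12)
    edges = dep.make_log_buffers()
    dm = np.sqrt(edges[:-1] * edges[1:])
    frames = []
    for i in range(20):  # strong subplot offsets, no distance signal
        frames.append(
            pd.DataFrame(
                {"subplot_id": f"s{i}", "DM": dm, "DD": 1 + rng.normal(0, 0.5) + rng.normal(0, 0.05, len(dm))}
            )
        )
    table = dep.depletion_ladder(pd.concat(frames, ignore_index=True))
    best = table.best_label
    assert "Subplot" in best
    assert table.rows["dAIC"].min() == 0.0


def test_profile_invariant_to_translation_and_relabelling(rng):
    mounds = pd.DataFrame({"x_m": rng.uniform(8, 12, 20), "y_m": rng.uniform(8, 12, 20)})
    flowers = pd.DataFrame({"x_m": rng.uniform(0, 20, 2000), "y_m": rng.uniform(0, 20, 2000)})
    rec1 = dep.depletion_profile(dep.SubplotData("a", mounds, flowers))
    shifted = dep.SubplotData(
        "b", mounds + 100.0, flowers + 100.0, (100.0, 100.0, 120.0, 120.0)
    )
    rec2 = dep.depletion_profile(shifted)
    assert np.allclose(rec1["DD"], rec2["DD"], rtol=1e-6, equal_nan=True)
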