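"""Habitat model fits: AIC identity, explained variance, stepwise selection,
parameter recovery on simulated tile tables, prediction curves."""

import numpy as np
import pandas as pd
import pytest

from volehabitat import experiments as ex
from volehabitat import models as hm


@pytest.fixture(scope="module")
def tile_df():
    return ex.simulate_tile_dataset(6, seed=42, quadrat_width=40, quadrat_height=30)


@pytest.fixture(scope="module")
def col_fit(tile_df):
    return hm.fit_colonization_model(tile_df)


def test_aic_identity_holds_exactly(col_fit):
    assert col_fit.aic == pytest.approx(-2 * col_fit.loglik + 2 * col_fit.n_params, rel=1e-12)


def test_colonization_recovers_anomaly_coefficient_within_ci():
    df = ex.simulate_tile_dataset(13, seed=7, n_years=2)  # ~60k tile-campaigns
    fit = hm.fit_colonization_model(df)
    est, se = fit.params["Anom"], fit.bse["Anom"]
    assert est - 1.96 * se <= 1.8 <= est + 1.96 * se


def test_constant_response_gives_null_slopes():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "Col": np.zeros(400, dtype=int),
            "Anom": rng.normal(size=400),
            "D_q": np.repeat(rng.uniform(2, 40, 4), 100),
            "Q": np.repeat(list("abcd"), 100),
        }
    )
    df.loc[:1, "Col"] = 1  # avoid a fully degenerate response
    with pytest.warns(UserWarning):
        fit = hm.fit_colonization_model(df)
    assert hm.explained_variance(fit) < 0.5
    assert abs(fit.params["Anom"]) < 2.0


def test_reuse_model_recovers_negative_tile_density_effect():
    fit = ex.reuse_sign_recovery(seed=5)
    assert fit.params["D_t"] < 0
    assert fit.params["D_t"] + 1.96 * fit.bse["D_t"] < 0  # significantly negative


def test_reuse_constant_dq_collinearity_flagged():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {
            "Reuse": rng.integers(0, 2, 200),
            "D_t": rng.gamma(2, 5, 200),
            "D_q": 20.0,
            "Q": np.repeat(list("ab"), 100),
        }
    )
    with pytest.warns(UserWarning, match="collinear"):
        hm.fit_reuse_model(df)


def test_dpgr_slope_recovery_is_unbiased():
    ests, ses = [], []
    for seed in range(8):
        fit, true_slope = ex.dpgr_recovery(seed=seed)
        ests.append(fit.params["np.log(Cover + 1)"])
        ses.append(fit.bse["np.log(Cover + 1)"])
    mean_est = np.mean(ests)
    se_mean = np.mean(ses) / np.sqrt(len(ests))
    assert abs(mean_est - true_slope) < 3 * se_mean


def test_dpgr_zero_cover_everywhere_is_rank_error():
    df = pd.DataFrame(
        {"DPGR": np.random.default_rng(0).normal(size=50), "Cover": 0.0, "Q": ["a"] * 25 + ["b"] * 25}
    )
    with pytest.raises(ValueError):
        hm.fit_dpgr_model(df)


def test_explained_variance_bounds_and_extremes(tile_df, col_fit):
    ev = hm.explained_variance(col_fit)
    assert 0.0 <= ev <= 1.0
    null_fit = hm.fit_glm(tile_df, "Col ~ 1", "null")
    assert hm.explained_variance(null_fit) == pytest.approx(0.0, abs=1e-10)


def test_single_candidate_ladder_has_zero_delta(tile_df):
    table = hm.aic_ladder(tile_df, [("Col ~ Anom + Q", "Col ~ Anom + C(Q)")])
    assert table.rows["dAIC"].iloc[0] == 0.0


def test_strong_effect_beats_null_by_wide_aic_margin(tile_df):
    table = hm.aic_ladder(
        tile_df,
        [("Col ~ 1 + Q", "Col ~ 1 + C(Q)"), ("Col ~ Anom + Q", "Col ~ Anom + C(Q)")],
    )
    rows = table.rows.set_index("model")
    assert rows.loc["Col ~ 1 + Q", "dAIC"] > 10


def test_forward_stepwise_reaches_full_interaction_model(tile_df):
    table = hm.forward_stepwise_aic(
        tile_df, "Col", ["Anom", "D_q", "Anom:D_q"], explicit_ladder=hm.COLONIZATION_LADDER
    )
    assert table.rows.attrs["selected"] == "Col ~ 1 + Anom + D_q + Anom:D_q + Q"
    assert table.best_label == "Col ~ Anom*D_q + Q"


def test_prediction_curve_flat_at_half_for_null_coefficients():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        {
            "Col": rng.integers(0, 2, 2000),
            "Anom": rng.normal(size=2000),
            "D_q": np.repeat(rng.uniform(2, 40, 4), 500),
            "Q": np.repeat(list("abcd"), 500),
        }
    )
    fit = hm.fit_colonization_model(df)
    curves = hm.predict_response_curves(fit, df, "Anom", "D_q")
    assert np.allclose(curves["predicted"], 0.5, atol=0.1)


def test_prediction_curve_monotone_for_positive_slope_model(tile_df):
    fit = hm.fit_glm(tile_df, "Col ~ Anom + C(Q)", "Col ~ Anom + Q")
    curves = hm.predict_response_curves(fit, tile_df, "Anom", "D_q", anchor_quantiles=(0.5,))
    pred = curves["predicted"].to_numpy()
    assert (np.diff(pred) > 0).all()


def test_negative_interaction_spreads_low_density_curves(tile_df, col_fit):
    curves = hm.predict_response_curves(col_fit, tile_df, "Anom", "D_q")
    spread = curves.groupby("anchor")["predicted"].agg(np.ptp)
    assert spread["q10"] > spread["q90"]  # anomaly matters most in flower-poor quadrats


def test_predictions_invariant_to_quadrat_relabelling(tile_df):
    relab = tile_df.copy()
    mapping = {q: f"Z{i}" for i, q in enumerate(sorted(relab["Q"].unique(), reverse=True))}
    relab["Q"] = relab["Q"].map(mapping)
    f1 = hm.fit_colonization_model(tile_df)
    f2 = hm.fit_colonization_model(relab)
    c1 = hm.predict_response_curves(f1, tile_df, "Anom", "D_q")
    c2 = hm.predict_response_curves(f2, relab, "Anom", "D_q")
    assert np.allclose(c1["predicted"], c2["predicted"], atol=1e-8)
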