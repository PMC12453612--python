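"""Habitat-selection models: logistic colonization / reuse fits, the
growth-rate regression, forward-stepwise AIC ladders and prediction curves.

All models carry the quadrat identifier ``Q`` as a fixed categorical term,
including the null models, so the ladders compare habitat terms on top of
quadrat-level baselines.  Binary responses use a binomial logit GLM; the
growth-rate model is ordinary least squares of DPGR on log(Cover + 1) with
Cover the percentage mound cover of the preceding March.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelFit",
    "AICTable",
    "fit_glm",
    "fit_ols",
    "fit_colonization_model",
    "fit_reuse_model",
    "fit_dpgr_model",
    "explained_variance",
    "aic_ladder",
    "forward_stepwise_aic",
    "predict_response_curves",
    "COLONIZATION_LADDER",
    "REUSE_LADDER",
    "DPGR_LADDER",
]

# the explicit model ladders of the three broad-scale analyses (labels keep
# the field notation: Col/Reuse responses, Anom, D_t, D_q, quadrat factor Q)
COLONIZATION_LADDER = [
    ("Col ~ 1 + Q", "Col ~ 1 + C(Q)"),
    ("Col ~ Anom + Q", "Col ~ Anom + C(Q)"),
    ("Col ~ D_t + Q", "Col ~ D_t + C(Q)"),
    ("Col ~ D_q + Q", "Col ~ D_q + C(Q)"),
    ("Col ~ D_t + D_t:D_q + Q", "Col ~ D_t + D_t:D_q + C(Q)"),
    ("Col ~ Anom + D_t + Q", "Col ~ Anom + D_t + C(Q)"),
    ("Col ~ Anom + D_q + Q", "Col ~ Anom + D_q + C(Q)"),
    ("Col ~ Anom*D_t + Q", "Col ~ Anom*D_t + C(Q)"),
    ("Col ~ Anom*D_q + Q", "Col ~ Anom*D_q + C(Q)"),
]
REUSE_LADDER = [
    ("Reuse ~ 1 + Q", "Reuse ~ 1 + C(Q)"),
    ("Reuse ~ Anom + Q", "Reuse ~ Anom + C(Q)"),
    ("Reuse ~ D_t + Q", "Reuse ~ D_t + C(Q)"),
    ("Reuse ~ D_t + Anom + Q", "Reuse ~ D_t + Anom + C(Q)"),
    ("Reuse ~ D_t*Anom + Q", "Reuse ~ D_t*Anom + C(Q)"),
    ("Reuse ~ D_t + D_t:D_q + Q", "Reuse ~ D_t + D_t:D_q + C(Q)"),
]
DPGR_LADDER = [
    ("log(DGR) ~ 1 + Q", "DPGR ~ 1 + C(Q)"),
    ("log(DGR) ~ Cover + Q", "DPGR ~ Cover + C(Q)"),
    ("log(DGR) ~ log(Cover + 1) + Q", "DPGR ~ np.log(Cover + 1) + C(Q)"),
]


@dataclass
class ModelFit:
    """A fitted model plus the summaries the selection tables need."""

    label: str
    formula: str
    result: object  # statsmodels results instance
    family: str  # "binomial" | "gaussian"
    converged: bool = True

    @property
    def loglik(self) -> float:
        return float(self.result.llf)

    @property
    def n_params(self) -> int:
        return int(len(self.result.params))

    @property
    def aic(self) -> float:
        # defined from the likelihood, not delegated, so the identity
        # AIC = -2 loglik + 2 k holds exactly for every fit
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def bse(self) -> pd.Series:
        return self.result.bse

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.result.params,
                "se": self.result.bse,
                "p": self.result.pvalues,
            }
        )


@dataclass
class AICTable:
    """Ordered model-comparison table: label, df, AIC, dAIC, explained variance."""

    rows: pd.DataFrame
    fits: dict[str, ModelFit] = field(default_factory=dict)

    @property
    def best_label(self) -> str:
        return str(self.rows.loc[self.rows["dAIC"].idxmin(), "model"])

    def __repr__(self) -> str:
        return self.rows.to_string(index=False)


def _check_single_outcome_quadrats(df: pd.DataFrame, response: str) -> None:
    levels = df.groupby("Q", observed=True)[response].nunique()
    bad = levels[levels < 2]
    if len(bad):
        warnings.warn(
            f"{len(bad)} quadrat(s) have a single outcome level for {response}; "
            "their fixed effects are weakly identified",
            stacklevel=3,
        )


def fit_glm(df: pd.DataFrame, formula: str, label: str | None = None) -> ModelFit:
    """Binomial logit GLM via IRLS (tolerance 1e-8, 100 iterations)."""
    model = smf.glm(formula, data=df, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = model.fit(maxiter=100, tol=1e-8)
    fit = ModelFit(label or formula, formula, res, "binomial", converged=bool(res.converged))
    if np.abs(res.params).max() > 20:
        warnings.warn(
            f"very large coefficient in '{formula}': possible complete separation",
            stacklevel=2,
        )
    return fit


def fit_ols(df: pd.DataFrame, formula: str, label: str | None = None) -> ModelFit:
    res = smf.ols(formula, data=df).fit()
    rank = np.linalg.matrix_rank(res.model.exog)
    if rank < res.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design for '{formula}' (zero-variance regressor?)")
    return ModelFit(label or formula, formula, res, "gaussian")


def fit_colonization_model(tiles: pd.DataFrame) -> ModelFit:
    """Best colonization model: Col ~ Anom * D_q + Q on the March-free subset.

    ``tiles`` needs columns Col (0/1), Anom, D_q, Q; rows with undefined
    anomaly must be excluded beforehand.
    """
    if tiles["Anom"].isna().any():
        raise ValueError("colonization subset contains undefined anomalies")
    _check_single_outcome_quadrats(tiles, "Col")
    return fit_glm(tiles, "Col ~ Anom*D_q + C(Q)", "Col ~ Anom*D_q + Q")


def fit_reuse_model(tiles: pd.DataFrame) -> ModelFit:
    """Best reuse model: Reuse ~ D_t + D_t:D_q + Q (interaction without D_q main effect)."""
    _check_single_outcome_quadrats(tiles, "Reuse")
    if tiles.groupby("Q", observed=True)["D_q"].first().nunique() == 1:
        warnings.warn(
            "D_q is constant across quadrats; D_t:D_q is collinear with D_t",
            stacklevel=2,
        )
    return fit_glm(tiles, "Reuse ~ D_t + D_t:D_q + C(Q)", "Reuse ~ D_t + D_t:D_q + Q")


def fit_dpgr_model(tiles: pd.DataFrame) -> ModelFit:
    """Best growth-rate model: DPGR ~ log(Cover + 1) + Q, Cover in percent."""
    sub = tiles.dropna(subset=["DPGR"])
    return fit_ols(sub, "DPGR ~ np.log(Cover + 1) + C(Q)", "log(DGR) ~ log(Cover + 1) + Q")


def explained_variance(fit: ModelFit) -> float:
    """Deviance-based pseudo-R^2 for GLMs (null = plain intercept, no Q);
    ordinary R^2 for least squares."""
    res = fit.result
    if fit.family == "gaussian":
        return float(res.rsquared)
    null_dev = float(res.null_deviance)
    if null_dev == 0:
        raise ValueError("null deviance is zero; explained variance undefined")
    return 1.0 - float(res.deviance) / null_dev


def _fit_one(df: pd.DataFrame, formula: str, label: str, family: str) -> ModelFit | None:
    try:
        if family == "binomial":
            return fit_glm(df, formula, label)
        return fit_ols(df, formula, label)
    except Exception as err:  # noqa: BLE001 - non-convergence is data-dependent
        warnings.warn(f"model '{label}' failed to fit: {err}", stacklevel=3)
        return None


def aic_ladder(
    df: pd.DataFrame, models: list[tuple[str, str]], family: str = "binomial"
) -> AICTable:
    """Fit an explicit model list and tabulate df, AIC, dAIC, explained variance.

    Models that fail to converge keep their row with missing AIC rather than
    being dropped silently.
    """
    fits: dict[str, ModelFit] = {}
    recs = []
    for label, formula in models:
        fit = _fit_one(df, formula, label, family)
        if fit is None:
            recs.append({"model": label, "df": np.nan, "AIC": np.nan, "explained_variance": np.nan})
            continue
        fits[label] = fit
        recs.append(
            {
                "model": label,
                "df": fit.n_params,
                "AIC": fit.aic,
                "explained_variance": explained_variance(fit),
            }
        )
    rows = pd.DataFrame(recs)
    best = rows["AIC"].min()
    rows["dAIC"] = rows["AIC"] - best
    rows = rows[["model", "df", "AIC", "dAIC", "explained_variance"]]
    return AICTable(rows, fits)


def forward_stepwise_aic(
    df: pd.DataFrame,
    response: str,
    candidate_terms: list[str],
    base_terms: tuple[str, ...] = ("C(Q)",),
    family: str = "binomial",
    explicit_ladder: list[tuple[str, str]] | None = None,
) -> AICTable:
    """Greedy forward selection by AIC on top of the base terms.

    Starting from ``response ~ 1 + base``, repeatedly adds the candidate term
    (main effect, or interaction once both parents are in) that lowers AIC
    the most; stops when no addition improves AIC.  Ties break toward fewer
    parameters (i.e. the incumbent model).  If ``explicit_ladder`` is given,
    its models are evaluated as well and the returned table is their union
    with the visited models.
    """
    mains = [t for t in candidate_terms if ":" not in t]
    inters = [t for t in candidate_terms if ":" in t]

    def formula_for(terms: list[str]) -> tuple[str, str]:
        rhs = " + ".join(["1", *terms, *base_terms])
        label_rhs = " + ".join(["1", *terms, *[b.replace("C(Q)", "Q") for b in base_terms]])
        return f"{response} ~ {label_rhs}", f"{response} ~ {rhs}"

    visited: list[tuple[str, str]] = []
    current: list[str] = []
    label, formula = formula_for(current)
    visited.append((label, formula))
    current_fit = _fit_one(df, formula, label, family)
    current_aic = current_fit.aic if current_fit else np.inf

    while True:
        allowed = [t for t in mains if t not in current]
        for t in inters:
            a, b = t.split(":")
            if t not in current and a in current and b in current:
                allowed.append(t)
        best_term, best_aic = None, current_aic
        for t in allowed:
            label, formula = formula_for(current + [t])
            fit = _fit_one(df, formula, label, family)
            if (label, formula) not in visited:
                visited.append((label, formula))
            if fit is not None and fit.aic < best_aic:  # strict: ties keep fewer params
                best_term, best_aic = t, fit.aic
        if best_term is None:
            break
        current.append(best_term)
        current_aic = best_aic

    models = list(explicit_ladder) if explicit_ladder else []
    for pair in visited:
        if pair not in models:
            models.append(pair)
    table = aic_ladder(df, models, family)
    table.rows.attrs["selected"] = formula_for(current)[0]
    return table


def predict_response_curves(
    fit: ModelFit,
    data: pd.DataFrame,
    x_var: str,
    anchor_var: str,
    anchor_quantiles: tuple[float, ...] = (0.10, 0.50, 0.90),
    x_percentiles: tuple[float, float] = (1.0, 99.0),
    n_points: int = 100,
    anchor_values: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Prediction curves over the observed x range at fixed anchor covariates.

    For each anchor (quantile of ``anchor_var`` unless explicit values are
    given) the response is predicted on a grid spanning the 1st-99th
    percentile of ``x_var``, averaging the quadrat fixed effects on the
    linear-predictor scale before applying the inverse link.  Returns columns
    ``anchor, anchor_value, x, predicted``.
    """
    xs = np.linspace(*np.percentile(data[x_var].dropna(), x_percentiles), n_points)
    if anchor_values is None:
        anchors = {
            f"q{int(q * 100):02d}": float(np.quantile(data[anchor_var].dropna(), q))
            for q in anchor_quantiles
        }
    else:
        anchors = {f"a{i}": float(v) for i, v in enumerate(anchor_values)}
        lo, hi = data[anchor_var].min(), data[anchor_var].max()
        if any(v < lo or v > hi for v in anchors.values()):
            warnings.warn("anchor value outside the observed data range", stacklevel=2)
    q_levels = pd.unique(data["Q"])
    out = []
    for name, val in anchors.items():
        frame = pd.DataFrame(
            list(itertools.product(xs, q_levels)), columns=[x_var, "Q"]
        )
        frame[anchor_var] = val
        for col in data.columns:  # other covariates held at their mean
            if col not in frame.columns and pd.api.types.is_numeric_dtype(data[col]):
                frame[col] = float(data[col].mean())
        eta = fit.result.predict(frame, which="linear") if fit.family == "binomial" else fit.result.predict(frame)
        eta = np.asarray(eta).reshape(len(xs), len(q_levels)).mean(axis=1)
        pred = 1.0 / (1.0 + np.exp(-eta)) if fit.family == "binomial" else eta
        out.append(
            pd.DataFrame({"anchor": name, "anchor_value": val, "x": xs, "predicted": pred})
        )
    return pd.concat(out, ignore_index=True)
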