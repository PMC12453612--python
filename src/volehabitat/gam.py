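"""Gaussian additive models with penalized splines and ridge random intercepts.

Implements the model family used for the fine-scale depletion profile:

    y_i = alpha + f(x_i) + b_{g(i)} + eps_i,     eps ~ N(0, sigma^2)

where ``f`` is a cubic B-spline with a second-order difference penalty
(P-spline) under a sum-to-zero constraint, and ``b`` is a per-group
intercept shrunk by an identity (ridge) penalty — the penalized-regression
form of a Gaussian random intercept.  Smoothing parameters are chosen by
restricted maximum likelihood (REML) with the error variance profiled out;
the optimizer is Nelder-Mead on the log smoothing parameters.

Effective degrees of freedom are tr(A^{-1} X'X) with
A = X'X + sum_j lambda_j S_j, and the reported AIC is the conditional
-2 loglik + 2 (edf + 1), counting the variance as one parameter — the same
convention is applied to the unpenalized (plain least-squares) models so the
depletion model ladder is internally comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "AdditiveModelFit", "fit_additive_model"]

_EIG_TOL = 1e-10


@dataclass
class SplineBasis:
    """Cubic B-spline basis with sum-to-zero constraint and difference penalty."""

    knots: np.ndarray  # full knot vector (with boundary repeats)
    transform: np.ndarray  # (k, k-1) null-space map enforcing sum(B) beta = 0
    penalty: np.ndarray  # (k-1, k-1) transformed second-difference penalty
    degree: int = 3

    @classmethod
    def from_data(cls, x: np.ndarray, k: int = 10, degree: int = 3) -> "SplineBasis":
        """Basis of ``k`` functions with equidistant interior knots.

        Equally spaced knots are the standard P-spline construction (the
        difference penalty assumes them); resolution at short distances is
        obtained by modelling on the log scale, not by crowding knots.
        """
        x = np.asarray(x, dtype=float)
        if k < degree + 2:
            raise ValueError("need at least degree + 2 basis functions")
        n_interior = k - degree - 1
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise ValueError("x has no spread; cannot build a spline basis")
        if n_interior > 0:
            interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        else:
            interior = np.empty(0)
        knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
        raw = cls._raw_design(knots, degree, x)
        # sum-to-zero constraint: coefficients restricted to the null space of
        # the column-sum functional, removing confounding with the intercept
        c = raw.sum(axis=0, keepdims=True)
        transform = linalg.null_space(c)
        d2 = np.diff(np.eye(raw.shape[1]), n=2, axis=0)
        pen_full = d2.T @ d2
        penalty = transform.T @ pen_full @ transform
        return cls(knots=knots, transform=transform, penalty=penalty, degree=degree)

    @staticmethod
    def _raw_design(knots: np.ndarray, degree: int, x: np.ndarray) -> np.ndarray:
        k = len(knots) - degree - 1
        x = np.clip(x, knots[0], knots[-1])
        cols = [
            BSpline(knots, np.eye(k)[j], degree, extrapolate=False)(x) for j in range(k)
        ]
        out = np.column_stack(cols)
        return np.nan_to_num(out)

    def design(self, x: np.ndarray) -> np.ndarray:
        return self._raw_design(self.knots, self.degree, np.asarray(x, dtype=float)) @ self.transform


@dataclass
class AdditiveModelFit:
    """Fitted additive model with REML smoothing parameters."""

    beta: np.ndarray
    cov_beta: np.ndarray  # Bayesian posterior covariance sigma^2 * A^{-1}
    sigma2: float
    lambdas: np.ndarray
    edf_total: float
    edf_smooth: float
    loglik: float
    reml: float
    n_obs: int
    basis: SplineBasis | None
    group_levels: np.ndarray | None
    x_transform: str  # "identity" | "log"
    slices: dict[str, slice] = field(default_factory=dict)
    re_variance: float = 0.0
    converged: bool = True

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * (self.edf_total + 1.0)

    def _smooth_design(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        xt = np.log(x_new) if self.x_transform == "log" else x_new
        n = len(x_new)
        X = np.zeros((n, len(self.beta)))
        X[:, self.slices["intercept"]] = 1.0
        if self.basis is not None:
            X[:, self.slices["smooth"]] = self.basis.design(xt)
        return X

    def predict_curve(self, x_new: np.ndarray, ci: float = 0.95) -> pd.DataFrame:
        """Smooth + intercept on new x, random effects set to zero, with
        pointwise Bayesian intervals."""
        from scipy.stats import norm

        X = self._smooth_design(x_new)
        mu = X @ self.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov_beta, X))
        z = norm.ppf(0.5 + ci / 2)
        return pd.DataFrame(
            {"x": np.asarray(x_new, float), "fit": mu, "lower": mu - z * se, "upper": mu + z * se}
        )


def _build_design(
    x: np.ndarray | None,
    groups: np.ndarray | None,
    n: int,
    k: int,
    x_transform: str,
    penalize_groups: bool,
):
    blocks = [np.ones((n, 1))]
    slices = {"intercept": slice(0, 1)}
    penalties: list[tuple[np.ndarray, slice]] = []
    basis = None
    pos = 1
    if x is not None:
        xt = np.log(x) if x_transform == "log" else x
        basis = SplineBasis.from_data(xt, k=k)
        B = basis.design(xt)
        sl = slice(pos, pos + B.shape[1])
        blocks.append(B)
        slices["smooth"] = sl
        penalties.append((basis.penalty, sl))
        pos += B.shape[1]
    levels = None
    if groups is not None:
        levels, codes = np.unique(groups, return_inverse=True)
        if penalize_groups:
            G = np.zeros((n, len(levels)))
            G[np.arange(n), codes] = 1.0
            sl = slice(pos, pos + len(levels))
            penalties.append((np.eye(len(levels)), sl))
        else:
            # unpenalized factor: drop the first level for identifiability
            G = np.zeros((n, len(levels) - 1))
            mask = codes > 0
            G[np.arange(n)[mask], codes[mask] - 1] = 1.0
            sl = slice(pos, pos + len(levels) - 1)
        blocks.append(G)
        slices["groups"] = sl
        pos += G.shape[1]
    return np.hstack(blocks), slices, penalties, basis, levels


def _reml_score(
    log_lam: np.ndarray,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    penalties: list[tuple[np.ndarray, slice]],
    n: int,
    p: int,
) -> float:
    lam = np.exp(np.clip(log_lam, -30.0, 30.0))
    P = np.zeros_like(XtX)
    logdet_pen = 0.0
    rank_pen = 0
    for lj, (S, sl) in zip(lam, penalties):
        P[sl, sl] += lj * S
        ev = np.linalg.eigvalsh(S)
        pos = ev[ev > _EIG_TOL * ev.max()] if ev.max() > 0 else np.empty(0)
        logdet_pen += len(pos) * np.log(lj) + np.log(pos).sum()
        rank_pen += len(pos)
    A = XtX + P
    try:
        cho = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError:
        return np.inf
    beta = linalg.cho_solve(cho, Xty)
    rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 1e-300)
    pen = beta @ P @ beta
    mp = p - rank_pen  # dimension of the unpenalized (fixed) subspace
    dof = max(n - mp, 1)
    sigma2 = (rss + pen) / dof
    logdet_A = 2.0 * np.log(np.diag(cho[0])).sum()
    return dof * (np.log(2 * np.pi * sigma2) + 1) + logdet_A - logdet_pen


def fit_additive_model(
    y: np.ndarray,
    x: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    k: int = 10,
    x_transform: str = "identity",
    penalize_smooth: bool = True,
    penalize_groups: bool = True,
) -> AdditiveModelFit:
    """Fit y ~ intercept [+ s(x)] [+ group intercepts] by penalized least squares.

    ``x_transform="log"`` models the smooth on ln(x).  ``penalize_groups``
    switches the factor between a ridge random intercept (True) and a plain
    fixed factor (False); ``penalize_smooth=False`` is not supported (use a
    large ``k`` OLS instead) and is reserved.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if x is not None:
        x = np.asarray(x, dtype=float)
        if x_transform == "log" and (x <= 0).any():
            raise ValueError("log transform requires positive x")
    X, slices, penalties, basis, levels = _build_design(
        x, groups, n, k, x_transform, penalize_groups
    )
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    converged = True
    if penalties:
        # coarse grid start (REML surfaces can be multimodal), then Nelder-Mead
        grid = np.array([-4.0, 0.0, 4.0, 8.0])
        starts = np.array(np.meshgrid(*([grid] * len(penalties)))).reshape(len(penalties), -1).T
        scores = [_reml_score(s, XtX, Xty, yty, penalties, n, p) for s in starts]
        x0 = starts[int(np.argmin(scores))]
        res = optimize.minimize(
            _reml_score,
            x0,
            args=(XtX, Xty, yty, penalties, n, p),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 600},
        )
        log_lam = np.clip(res.x, -20, 25)
        converged = bool(res.success) or res.fun <= min(scores)
        reml = float(res.fun)
        lam = np.exp(log_lam)
    else:
        lam = np.empty(0)
        reml = np.nan

    P = np.zeros_like(XtX)
    rank_pen = 0
    for lj, (S, sl) in zip(lam, penalties):
        P[sl, sl] += lj * S
        ev = np.linalg.eigvalsh(S)
        rank_pen += int((ev > _EIG_TOL * max(ev.max(), 1e-300)).sum())
    A = XtX + P
    # ridge the unpenalized rank-deficient corner case rather than failing
    try:
        cho = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError:
        A = A + 1e-10 * np.eye(p) * np.trace(XtX) / p
        cho = linalg.cho_factor(A, lower=True)
    beta = linalg.cho_solve(cho, Xty)
    Ainv = linalg.cho_solve(cho, np.eye(p))
    H = Ainv @ XtX
    edf_total = float(np.trace(H))
    rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 0.0)
    pen = float(beta @ P @ beta)
    mp = p - rank_pen
    sigma2 = (rss + pen) / max(n - mp, 1) if penalties else rss / max(n - p, 1)

    edf_smooth = 0.0
    if "smooth" in slices:
        sl = slices["smooth"]
        edf_smooth = float(np.trace(H[sl, sl]))
    re_var = 0.0
    if groups is not None and penalize_groups and len(lam):
        re_var = sigma2 / lam[-1]  # ridge lambda = sigma^2 / tau^2

    sigma2_ml = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    return AdditiveModelFit(
        beta=beta,
        cov_beta=sigma2 * Ainv,
        sigma2=float(sigma2),
        lambdas=lam,
        edf_total=edf_total,
        edf_smooth=edf_smooth,
        loglik=float(loglik),
        reml=reml,
        n_obs=n,
        basis=basis,
        group_levels=levels,
        x_transform=x_transform,
        slices=slices,
        re_variance=float(re_var),
        converged=converged,
    )
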