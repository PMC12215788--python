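"""Shared estimation machinery: crossed random-intercepts REML and contrasts.

The linear mixed model used throughout is

    y = X beta + sum_g Z_g u_g + eps,   u_g ~ N(0, s2_g I),  eps ~ N(0, s2_e I),

where each Z_g is the one-hot indicator matrix of a (possibly crossed)
grouping factor. Estimation profiles beta and the residual variance out of
the (restricted) likelihood and optimizes over the variance ratios
theta_g = s2_g / s2_e >= 0. Because every Z_g is an indicator matrix, the
whole criterion reduces, via the Woodbury identity, to dense algebra on the
q x q Gram matrix of the stacked random-effect columns (q = total number of
group levels), which keeps each fit in the tens of milliseconds at the
panel sizes this package works with.

Fixed-effect covariance is the usual REML expression s2_e (X' H^-1 X)^-1
with H = I + sum_g theta_g Z_g Z_g'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, stats

from dyadisc.exceptions import (
    ConvergenceError,
    DegenerateDataError,
    RankDeficiencyError,
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """Fitted-model summary shared by the neural and behavioral models.

    Coefficients are on the fitted (possibly standardized) scale.
    ``n_unique`` counts undoubled observations; ``df_corrected`` is
    n_unique - k and is the df used for every t-based p-value downstream.
    """

    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    vcomp: dict
    sigma2_resid: float
    n_obs: int
    n_unique: int
    k: int
    df_corrected: int
    converged: bool
    standardize: bool
    outcome_sd: float
    column_stats: dict = field(default_factory=dict)
    factor_levels: dict = field(default_factory=dict)
    reference_level: str | None = None
    factor_name: str | None = None
    metadata: dict = field(default_factory=dict)

    def require_inference(self) -> None:
        if not self.converged:
            raise ConvergenceError(
                "model did not converge; inference suppressed"
            )
        if self.df_corrected <= 0:
            raise DegenerateDataError(
                f"corrected df = {self.df_corrected} <= 0; no valid inference"
            )


@dataclass
class ContrastResult:
    """A planned contrast between two factor levels (EMM difference)."""

    name: str
    level_a: str
    level_b: str
    estimate: float
    estimate_raw: float
    se: float
    t: float
    df: int
    p_raw: float
    ci_low: float
    ci_high: float
    p_adjusted: float | None = None

    def as_dict(self) -> dict:
        return {
            "contrast": self.name,
            "estimate": self.estimate,
            "estimate_raw": self.estimate_raw,
            "se": self.se,
            "t": self.t,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def corrected_df(n_unique: int, k: int) -> int:
    """Degrees of freedom N - k on the unique (undoubled) observation count."""
    n_unique = int(n_unique)
    k = int(k)
    if n_unique <= k:
        raise DegenerateDataError(
            f"need n_unique > k for inference; got n_unique={n_unique}, k={k}"
        )
    return n_unique - k


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------


def build_fixed_design(
    table: pd.DataFrame,
    outcome: str,
    categorical: str | None,
    levels: Sequence[str] | None,
    reference: str | None,
    numeric: Sequence[str],
    standardize: bool,
) -> tuple[np.ndarray, np.ndarray, list[str], dict, float]:
    """Assemble y and X (intercept, treatment-coded factor, numeric columns).

    With ``standardize`` the outcome and every non-intercept column
    (including 0/1 dummies) are z-scored with the sample sd. Returns
    (y, X, param_names, column_stats, outcome_sd); column_stats maps each
    column name to its (mean, sd) on the raw scale so contrasts can be
    mapped back.
    """
    y = table[outcome].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["intercept"]
    if categorical is not None:
        observed = set(table[categorical].unique())
        unknown = observed - set(levels)
        if unknown:
            raise DegenerateDataError(
                f"unknown {categorical} levels: {sorted(unknown)}"
            )
        for lev in levels:
            if lev == reference:
                continue
            cols.append((table[categorical] == lev).to_numpy(dtype=float))
            names.append(f"{categorical}[{lev}]")
    for col in numeric:
        cols.append(table[col].to_numpy(dtype=float))
        names.append(col)
    X = np.column_stack(cols)

    column_stats: dict[str, tuple[float, float]] = {}
    outcome_sd = 1.0
    if standardize:
        ysd = float(np.std(y, ddof=1))
        if ysd == 0:
            raise DegenerateDataError(f"outcome {outcome!r} is constant")
        outcome_sd = ysd
        y = (y - y.mean()) / ysd
        for j, name in enumerate(names):
            if name == "intercept":
                continue
            mu = float(X[:, j].mean())
            sd = float(np.std(X[:, j], ddof=1))
            if sd == 0:
                raise DegenerateDataError(
                    f"predictor column {name!r} is constant; cannot standardize"
                )
            X[:, j] = (X[:, j] - mu) / sd
            column_stats[name] = (mu, sd)
    return y, X, names, column_stats, outcome_sd


# ---------------------------------------------------------------------------
# profiled REML for crossed random intercepts
# ---------------------------------------------------------------------------


def fit_crossed_reml(
    y: np.ndarray,
    X: np.ndarray,
    factors: Mapping[str, np.ndarray],
    reml: bool = True,
    max_theta: float = 1e6,
    tie_groups: Sequence[Sequence[str]] = (),
) -> dict:
    """REML (or ML) fit of a linear model with crossed random intercepts.

    Parameters
    ----------
    y, X : outcome vector and fixed-effect design (with intercept column).
    factors : mapping factor name -> label array of length n; each factor
        contributes one random-intercept variance component.
    tie_groups : groups of factor names constrained to share one variance
        (used for role-symmetric dyadic factors, where the two member roles
        are interchangeable and hence have a common population variance).

    Returns a dict with beta, cov_beta, sigma2 (residual), vcomp (per
    factor), theta, converged, and bookkeeping sizes.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    if n <= p:
        raise DegenerateDataError(f"need n > p; got n={n}, p={p}")

    names = list(factors)
    # parameter index per factor; tied factors share one free variance ratio
    param_of: dict[str, int] = {}
    for group in tie_groups:
        unknown = [g for g in group if g not in factors]
        if unknown:
            raise ValueError(f"tie_groups names unknown factors: {unknown}")
    next_param = 0
    for name in names:
        group = next((g for g in tie_groups if name in g), None)
        anchor = next((m for m in group if m in param_of), None) if group else None
        if anchor is not None:
            param_of[name] = param_of[anchor]
        else:
            param_of[name] = next_param
            next_param += 1
    n_params = next_param

    codes_list, sizes = [], []
    for name in names:
        codes, uniques = pd.factorize(np.asarray(factors[name]), sort=True)
        if (codes < 0).any():
            raise ValueError(f"factor {name!r} has missing levels")
        codes_list.append(codes)
        sizes.append(len(uniques))
    G = len(names)
    q = int(np.sum(sizes)) if G else 0

    # precompute Gram blocks once; every REML evaluation is then O(q^3) dense
    if G:
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        rows = np.tile(np.arange(n), G)
        cols = np.concatenate(
            [off + codes for off, codes in zip(offsets, codes_list)]
        )
        Z = sparse.csr_matrix(
            (np.ones(n * G), (rows, cols)), shape=(n, q)
        )
        A = (Z.T @ Z).toarray()
        B = Z.T @ X
        c = Z.T @ y
        expand = np.repeat(np.arange(G), sizes)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    df_res = n - p if reml else n

    def profile(theta: np.ndarray):
        if G:
            s = np.sqrt(theta[expand])
            W = A * np.outer(s, s)
            W[np.diag_indices_from(W)] += 1.0
            L = linalg.cholesky(W, lower=True)
            U = linalg.solve_triangular(L, s[:, None] * B, lower=True)
            v = linalg.solve_triangular(L, s * c, lower=True)
            XHX = XtX - U.T @ U
            XHy = Xty - U.T @ v
            yHy = yty - float(v @ v)
            logdetW = 2.0 * float(np.sum(np.log(np.diag(L))))
        else:
            XHX, XHy, yHy, logdetW = XtX, Xty, yty, 0.0
        try:
            Lx = linalg.cholesky(XHX, lower=True)
        except linalg.LinAlgError as exc:
            raise RankDeficiencyError(
                "fixed-effect design is collinear (X'H^-1X not positive "
                "definite)"
            ) from exc
        beta = linalg.cho_solve((Lx, True), XHy)
        rss = max(yHy - float(XHy @ beta), 1e-300)
        sigma2 = rss / df_res
        crit = logdetW + df_res * np.log(sigma2)
        if reml:
            crit += 2.0 * float(np.sum(np.log(np.diag(Lx))))
        return crit, beta, XHX, sigma2

    converged = True
    if G:
        fac_param = np.array([param_of[name] for name in names])

        def objective(theta_params):
            return profile(np.maximum(theta_params, 0.0)[fac_param])[0]

        best = optimize.minimize(
            objective,
            np.full(n_params, min(0.5, max_theta)),
            method="L-BFGS-B",
            bounds=[(0.0, max_theta)] * n_params,
        )
        if not best.success:  # retry from a near-boundary start
            res = optimize.minimize(
                objective,
                np.full(n_params, min(0.02, max_theta)),
                method="L-BFGS-B",
                bounds=[(0.0, max_theta)] * n_params,
            )
            if res.fun < best.fun - 1e-10 or res.success:
                best = res
        theta = np.maximum(best.x, 0.0)[fac_param]
        converged = bool(best.success)
    else:
        theta = np.zeros(0)

    _, beta, XHX, sigma2 = profile(theta)
    cov_beta = sigma2 * linalg.inv(XHX)
    vcomp = {name: float(t * sigma2) for name, t in zip(names, theta)}
    return {
        "beta": beta,
        "cov_beta": cov_beta,
        "sigma2": float(sigma2),
        "vcomp": vcomp,
        "theta": dict(zip(names, theta)),
        "converged": converged,
        "n": n,
        "p": p,
        "q": q,
        "reml": reml,
    }


# ---------------------------------------------------------------------------
# contrasts of estimated marginal means
# ---------------------------------------------------------------------------


def emm_contrast(fit: ModelFit, level_a: str, level_b: str, name: str | None = None) -> ContrastResult:
    """Difference of estimated marginal means between two factor levels.

    Covariates are held at their (standardized) means, so only the factor
    dummy columns contribute to the contrast vector; on a standardized fit
    each dummy's indicator difference is divided by that column's raw-scale
    sd. The t test uses the corrected df stored on the fit.
    """
    fit.require_inference()
    if fit.factor_name is None:
        raise DegenerateDataError("fit has no categorical factor to contrast")
    levels = fit.factor_levels.get(fit.factor_name, [])
    for lev in (level_a, level_b):
        if lev not in levels:
            raise KeyError(
                f"unknown {fit.factor_name} level {lev!r}; known: {levels}"
            )
    cvec = pd.Series(0.0, index=fit.params.index)
    for lev in levels:
        if lev == fit.reference_level:
            continue
        col = f"{fit.factor_name}[{lev}]"
        diff = (1.0 if lev == level_a else 0.0) - (1.0 if lev == level_b else 0.0)
        if diff == 0.0:
            continue
        if fit.standardize:
            diff /= fit.column_stats[col][1]
        cvec[col] = diff

    estimate = float(cvec @ fit.params)
    var = float(cvec @ fit.cov_params.values @ cvec)
    se = float(np.sqrt(max(var, 0.0)))
    df = fit.df_corrected
    if se == 0.0:
        tval, p = 0.0, 1.0
        ci_low = ci_high = estimate
    else:
        tval = estimate / se
        p = 2.0 * float(stats.t.sf(abs(tval), df))
        half = float(stats.t.ppf(0.975, df)) * se
        ci_low, ci_high = estimate - half, estimate + half
    return ContrastResult(
        name=name or f"{level_a}_minus_{level_b}",
        level_a=level_a,
        level_b=level_b,
        estimate=estimate,
        estimate_raw=estimate * fit.outcome_sd,
        se=se,
        t=tval,
        df=df,
        p_raw=p,
        ci_low=ci_low,
        ci_high=ci_high,
    )
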