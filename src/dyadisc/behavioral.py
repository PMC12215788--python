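"""Behavioral models: correlational mixed model and experimental contrasts.

The correlational analysis regresses sharing likelihood on perceived
similarity with crossed random intercepts for participant and article
(optionally adjusting for interest and valence). The experimental analysis
is an ordinary linear model of sharing likelihood on a four-level
social-context condition (optionally controlling for baseline sharing and
interest), followed by pairwise planned contrasts with BH-FDR correction.

All variables are z-scored before fitting so coefficients are standardized
(raw-scale estimates are carried alongside). Inference uses residual-style
degrees of freedom, observations minus fixed-effect parameters; the df rule
is recorded in the fit metadata.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dyadisc.exceptions import DegenerateDataError, SchemaError
from dyadisc.inference import (
    ContrastResult,
    ModelFit,
    build_fixed_design,
    corrected_df,
    emm_contrast,
    fit_crossed_reml,
)
from dyadisc.multitest import bh_fdr
from dyadisc.synthetic import STUDY3_CONDITIONS

STUDY2_COLUMNS = ("participant", "article", "sharing", "similarity")
STUDY3_COLUMNS = ("participant", "condition", "sharing")


def _require_columns(table: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns: {missing}")


def _coef_inference(fit: ModelFit, name: str) -> ContrastResult:
    """Wald t inference for a single coefficient at the corrected df."""
    fit.require_inference()
    estimate = float(fit.params[name])
    se = float(fit.bse[name])
    df = fit.df_corrected
    tval = estimate / se
    p = 2.0 * float(stats.t.sf(abs(tval), df))
    half = float(stats.t.ppf(0.975, df)) * se
    # raw-scale slope: raw-outcome units per 1 sd of the predictor
    raw = estimate * fit.outcome_sd
    return ContrastResult(
        name=name,
        level_a=name,
        level_b="",
        estimate=estimate,
        estimate_raw=raw,
        se=se,
        t=tval,
        df=df,
        p_raw=p,
        ci_low=estimate - half,
        ci_high=estimate + half,
    )


def fit_study2(
    table: pd.DataFrame, adjusted: bool = False
) -> tuple[ModelFit, ContrastResult]:
    """Mixed model of sharing on perceived similarity.

    Random intercepts for participant and article; ``adjusted`` appends
    interest and valence as fixed control covariates. Returns the fit and
    the similarity-slope inference (standardized beta, SE, t, df, two-tailed
    p, 95% CI).
    """
    cols = STUDY2_COLUMNS + (("interest", "valence") if adjusted else ())
    _require_columns(table, cols, "study-2")
    if table["participant"].nunique() < 2 or table["article"].nunique() < 2:
        raise DegenerateDataError(
            "need >= 2 participants and >= 2 articles for crossed intercepts"
        )
    if np.ptp(table["similarity"].to_numpy(dtype=float)) == 0:
        raise DegenerateDataError("similarity column is constant")

    numeric = ["similarity"] + (["interest", "valence"] if adjusted else [])
    y, X, names, column_stats, outcome_sd = build_fixed_design(
        table,
        outcome="sharing",
        categorical=None,
        levels=None,
        reference=None,
        numeric=numeric,
        standardize=True,
    )
    res = fit_crossed_reml(
        y,
        X,
        factors={
            "participant": table["participant"].to_numpy(),
            "article": table["article"].to_numpy(),
        },
    )
    k = res["p"]
    fit = ModelFit(
        params=pd.Series(res["beta"], index=names),
        bse=pd.Series(np.sqrt(np.diag(res["cov_beta"])), index=names),
        cov_params=pd.DataFrame(res["cov_beta"], index=names, columns=names),
        vcomp=res["vcomp"],
        sigma2_resid=res["sigma2"],
        n_obs=res["n"],
        n_unique=res["n"],
        k=k,
        df_corrected=corrected_df(res["n"], k),
        converged=res["converged"],
        standardize=True,
        outcome_sd=outcome_sd,
        column_stats=column_stats,
        metadata={"df_rule": "n_obs - k (residual-style)", "adjusted": adjusted},
    )
    return fit, _coef_inference(fit, "similarity")


def fit_study3(table: pd.DataFrame, controlled: bool = False) -> ModelFit:
    """Ordinary linear model of sharing on the four-level condition factor.

    ``controlled`` adds baseline sharing and interest as covariates. The
    reference level is 'dissimilar'; contrasts are reference-free.
    """
    cols = STUDY3_COLUMNS + (("baseline_sharing", "interest") if controlled else ())
    _require_columns(table, cols, "study-3")
    observed = set(table["condition"].unique())
    unknown = observed - set(STUDY3_CONDITIONS)
    if unknown:
        raise SchemaError(f"unknown condition labels: {sorted(unknown)}")
    empty = [c for c in STUDY3_CONDITIONS if c not in observed]
    if empty:
        raise DegenerateDataError(f"conditions with no participants: {empty}")

    numeric = ["baseline_sharing", "interest"] if controlled else []
    y, X, names, column_stats, outcome_sd = build_fixed_design(
        table,
        outcome="sharing",
        categorical="condition",
        levels=list(STUDY3_CONDITIONS),
        reference="dissimilar",
        numeric=numeric,
        standardize=True,
    )
    res = fit_crossed_reml(y, X, factors={})  # ordinary least squares
    k = res["p"]
    return ModelFit(
        params=pd.Series(res["beta"], index=names),
        bse=pd.Series(np.sqrt(np.diag(res["cov_beta"])), index=names),
        cov_params=pd.DataFrame(res["cov_beta"], index=names, columns=names),
        vcomp={},
        sigma2_resid=res["sigma2"],
        n_obs=res["n"],
        n_unique=res["n"],
        k=k,
        df_corrected=corrected_df(res["n"], k),
        converged=True,
        standardize=True,
        outcome_sd=outcome_sd,
        column_stats=column_stats,
        factor_levels={"condition": list(STUDY3_CONDITIONS)},
        reference_level="dissimilar",
        factor_name="condition",
        metadata={"df_rule": "n_obs - k (residual-style)", "controlled": controlled},
    )


#: Pairwise condition contrasts in the conventional reporting order.
ALL_STUDY3_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("similar", "dissimilar"),
    ("similar", "mixed"),
    ("similar", "unclear"),
    ("mixed", "dissimilar"),
    ("unclear", "dissimilar"),
    ("mixed", "unclear"),
)


def study3_contrasts(
    fit: ModelFit,
    which: str | Sequence[tuple[str, str]] = "all",
) -> pd.DataFrame:
    """Pairwise condition contrasts with BH-FDR correction over the family.

    ``which`` is "all" (the six pairwise contrasts), "primary"
    (similar > dissimilar only), or an explicit list of level pairs.
    """
    if which == "all":
        pairs = ALL_STUDY3_CONTRASTS
    elif which == "primary":
        pairs = (("similar", "dissimilar"),)
    else:
        pairs = tuple(tuple(p) for p in which)
        for a, b in pairs:
            for lev in (a, b):
                if lev not in STUDY3_CONDITIONS:
                    raise KeyError(f"unknown contrast level {lev!r}")
    results = [emm_contrast(fit, a, b) for a, b in pairs]
    adjusted = bh_fdr([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return pd.DataFrame([r.as_dict() for r in results])
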