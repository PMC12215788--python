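"""Doubled-data crossed random-effects model for dyadic ISC data.

Each dyad x video observation is duplicated with member roles swapped so
that a symmetric dyadic outcome can carry member-specific random
intercepts (role-1 participant, role-2 participant, video, and both
role x video interactions). Because the doubling is redundant, all t-based
inference uses degrees of freedom N - k, where N is the number of unique
(undoubled) observations and k the number of fixed-effect parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from dyadisc.design import build_dyad_design, binarize_rating
from dyadisc.exceptions import DegenerateDataError, SchemaError
from dyadisc.inference import (
    ContrastResult,
    ModelFit,
    build_fixed_design,
    corrected_df,
    emm_contrast,
    fit_crossed_reml,
)
from dyadisc.multitest import bh_fdr, holm_bonferroni

SHARING_LEVELS = ("LL", "LH", "HH")

#: Random-intercept groupings of the crossed model.
RANDOM_FACTORS = ("role1", "role2", "video", "role1_video", "role2_video")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the region-wise dyadic mixed model.

    ``standardize`` z-scores the outcome and every predictor column
    (including the 0/1 category dummies), so coefficients and contrasts are
    reported in outcome-SD units; raw-scale estimates are carried alongside.
    ``count_intercept_in_k`` controls whether k (and hence the N - k df
    correction) includes the intercept column.

    ``redundancy_correction`` doubles the fixed-effect covariance (SE x
    sqrt(2)) because every unique observation enters the doubled table
    twice, so the likelihood sees twice the information actually present;
    without it the null rejection rate is badly inflated (about sqrt(2) on
    the t scale). It accompanies, not replaces, the N - k df rule.
    """

    outcome: str = "z_norm"
    category: str = "sharing_category"
    levels: tuple[str, ...] = SHARING_LEVELS
    reference_level: str = "LL"
    covariates: tuple[str, ...] = (
        "age_similarity",
        "gender_match",
        "country_match",
    )
    standardize: bool = True
    reml: bool = True
    count_intercept_in_k: bool = True
    redundancy_correction: bool = True
    #: upper bound on each variance ratio s2_g / s2_e; 0 pins every random
    #: effect at the boundary, making the fit ordinary least squares
    max_variance_ratio: float = 1e6

    def fixed_columns(self) -> list[str]:
        return [self.category, *self.covariates]


def _dyad_key(table: pd.DataFrame) -> pd.Series:
    a = table["subject_a"].astype(str)
    b = table["subject_b"].astype(str)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    return lo + "|" + hi + "|" + table["video"].astype(str)


def double_dyadic_data(table: pd.DataFrame) -> pd.DataFrame:
    """Duplicate each dyad x video row with member roles swapped.

    Input rows must be unique per unordered (dyad, video); feeding an
    already-doubled table is an error. The output has exactly 2N rows with
    identical outcome and dyad-level covariates within each pair, plus
    ``role1``/``role2`` columns and their role x video interaction labels.
    """
    for col in ("subject_a", "subject_b", "video"):
        if col not in table.columns:
            raise SchemaError(f"dyadic table missing column {col!r}")
    keys = _dyad_key(table)
    if keys.duplicated().any():
        raise SchemaError(
            "duplicate (dyad, video) rows: input appears to be doubled already"
        )
    fwd = table.copy()
    fwd["role1"] = table["subject_a"]
    fwd["role2"] = table["subject_b"]
    rev = table.copy()
    rev["role1"] = table["subject_b"]
    rev["role2"] = table["subject_a"]
    doubled = pd.concat([fwd, rev], ignore_index=True)
    # canonical row order: the fit is then exactly invariant to how the
    # caller oriented each dyad before doubling
    doubled = doubled.sort_values(
        ["video", "role1", "role2"], kind="mergesort"
    ).reset_index(drop=True)
    doubled["role1_video"] = (
        doubled["role1"].astype(str) + "|" + doubled["video"].astype(str)
    )
    doubled["role2_video"] = (
        doubled["role2"].astype(str) + "|" + doubled["video"].astype(str)
    )
    return doubled


def n_unique_observations(doubled: pd.DataFrame) -> int:
    """Count undoubled (dyad, video) observations in a doubled table."""
    return int(_dyad_key(doubled).nunique())


def fit_crossed_lmm(doubled: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML fit of the crossed random-intercepts model on a doubled table."""
    missing = [
        c
        for c in (spec.outcome, *spec.fixed_columns(), *RANDOM_FACTORS)
        if c not in doubled.columns
    ]
    if missing:
        raise SchemaError(f"doubled table missing columns: {missing}")
    outcome = doubled[spec.outcome].to_numpy(dtype=float)
    if np.ptp(outcome) == 0:
        raise DegenerateDataError(f"outcome {spec.outcome!r} is constant")

    present_levels = [
        lev for lev in spec.levels if (doubled[spec.category] == lev).any()
    ]
    if spec.reference_level in present_levels:
        reference = spec.reference_level
    else:  # fall back to the first observed level
        reference = present_levels[0]
    y, X, names, column_stats, outcome_sd = build_fixed_design(
        doubled,
        outcome=spec.outcome,
        categorical=spec.category,
        levels=present_levels,
        reference=reference,
        numeric=list(spec.covariates),
        standardize=spec.standardize,
    )
    factors = {f: doubled[f].to_numpy() for f in RANDOM_FACTORS}
    # the two member roles are exchangeable after doubling, so each role
    # pair shares one population variance
    res = fit_crossed_reml(
        y,
        X,
        factors,
        reml=spec.reml,
        max_theta=spec.max_variance_ratio,
        tie_groups=(("role1", "role2"), ("role1_video", "role2_video")),
    )

    n_unique = n_unique_observations(doubled)
    k = res["p"] if spec.count_intercept_in_k else res["p"] - 1
    df = corrected_df(n_unique, k)
    cov_beta = res["cov_beta"] * (2.0 if spec.redundancy_correction else 1.0)
    params = pd.Series(res["beta"], index=names)
    cov = pd.DataFrame(cov_beta, index=names, columns=names)
    return ModelFit(
        params=params,
        bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=names),
        cov_params=cov,
        vcomp=res["vcomp"],
        sigma2_resid=res["sigma2"],
        n_obs=res["n"],
        n_unique=n_unique,
        k=k,
        df_corrected=df,
        converged=res["converged"],
        standardize=spec.standardize,
        outcome_sd=outcome_sd,
        column_stats=column_stats,
        factor_levels={spec.category: present_levels},
        reference_level=reference,
        factor_name=spec.category,
        metadata={
            "reml": spec.reml,
            "count_intercept_in_k": spec.count_intercept_in_k,
            "random_factors": RANDOM_FACTORS,
        },
    )


def planned_contrast(
    fit: ModelFit, pair: tuple[str, str], name: str | None = None
) -> ContrastResult:
    """EMM difference between two sharing-category levels (two-tailed t)."""
    return emm_contrast(fit, pair[0], pair[1], name=name)


def merge_isc_design(
    isc_records: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Join ISC records with dyad design rows on (dyad, video)."""
    merged = isc_records.merge(
        design, on=["subject_a", "subject_b", "video"], how="inner"
    )
    if merged.empty:
        raise SchemaError("ISC records and design share no (dyad, video) rows")
    return merged


DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("HH", "LL"),
    ("HH", "LH"),
    ("LH", "LL"),
)


def region_wise_analysis(
    isc_records: pd.DataFrame,
    design: pd.DataFrame,
    spec: ModelSpec | None = None,
    contrasts: Sequence[tuple[str, str]] = (("HH", "LL"),),
    correction: str = "holm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit the crossed model per region and correct contrasts across regions.

    Returns a tidy table (region, contrast, beta, estimate_raw, se, t, df,
    p_raw, p_adjusted, significant, converged). Non-convergence is recorded
    per region and that region is excluded from the corrected family;
    structural errors abort with the region named.
    """
    spec = spec or ModelSpec()
    merged = merge_isc_design(isc_records, design)
    rows = []
    for region, block in merged.groupby("region", sort=True):
        doubled = double_dyadic_data(block.drop(columns=["region"]))
        try:
            fit = fit_crossed_lmm(doubled, spec)
        except (SchemaError, DegenerateDataError) as exc:
            raise type(exc)(f"region {region!r}: {exc}") from exc
        if not fit.converged:
            for pair in contrasts:
                rows.append(
                    {
                        "region": region,
                        "contrast": f"{pair[0]}_minus_{pair[1]}",
                        "beta": np.nan,
                        "estimate_raw": np.nan,
                        "se": np.nan,
                        "t": np.nan,
                        "df": fit.df_corrected,
                        "p_raw": np.nan,
                        "converged": False,
                    }
                )
            continue
        for pair in contrasts:
            cr = planned_contrast(fit, pair)
            rows.append(
                {
                    "region": region,
                    "contrast": cr.name,
                    "beta": cr.estimate,
                    "estimate_raw": cr.estimate_raw,
                    "se": cr.se,
                    "t": cr.t,
                    "df": cr.df,
                    "p_raw": cr.p_raw,
                    "converged": True,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    adjuster = {"holm": holm_bonferroni, "bh": bh_fdr, "none": None}[correction]
    for _, idx in table.groupby("contrast").groups.items():
        sub = table.loc[idx]
        ok = sub["converged"] & sub["p_raw"].notna()
        if ok.any():
            p = sub.loc[ok, "p_raw"].to_numpy()
            table.loc[sub.index[ok], "p_adjusted"] = (
                p if adjuster is None else adjuster(p)
            )
    table["significant"] = table["p_adjusted"] < alpha
    return table.reset_index(drop=True)


def permutation_null(
    isc_records: pd.DataFrame,
    ratings: pd.DataFrame,
    attrs: pd.DataFrame,
    spec: ModelSpec | None = None,
    contrast: tuple[str, str] = ("HH", "LL"),
    n_permutations: int = 1000,
    seed: int = 0,
    statistic: str = "lmm",
) -> dict[str, float]:
    """Permutation p-value for a sharing-category contrast, per region.

    Participant-level binarized sharing labels are permuted across
    participants *within each video* (participants, not dyadic rows, are the
    exchangeable units under the null of no label/ISC association), dyad
    categories are rebuilt, and the contrast t-statistic is recomputed.
    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_permutations).

    ``statistic`` chooses the refitted model per permutation: "lmm" (the
    doubled-data crossed model, matching the observed analysis) or "ols"
    (ordinary least squares on the undoubled rows, a fast approximation).
    """
    spec = spec or ModelSpec()
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} < 100 gives a coarse p-value",
            stacklevel=2,
        )
    if statistic not in ("lmm", "ols"):
        raise ValueError("statistic must be 'lmm' or 'ols'")

    levels = ratings.copy()
    levels["level"] = [
        binarize_rating(int(r)) for r in levels["rating"].to_numpy()
    ]
    if levels["level"].nunique() < 2:
        raise DegenerateDataError(
            "all binarized sharing labels identical; nothing to permute"
        )

    base_design = build_dyad_design(ratings, attrs)
    covariate_cols = ["age_similarity", "gender_match", "country_match"]
    dyad_cov = base_design.drop_duplicates(
        ["subject_a", "subject_b"]
    ).set_index(["subject_a", "subject_b"])[covariate_cols]

    def stat_for_labels(label_map: dict[tuple[str, str], str]) -> dict[str, float]:
        design = base_design[["subject_a", "subject_b", "video"]].copy()
        la = [
            label_map[(a, v)]
            for a, v in zip(design["subject_a"], design["video"])
        ]
        lb = [
            label_map[(b, v)]
            for b, v in zip(design["subject_b"], design["video"])
        ]
        cat = np.where(
            np.array(la) == np.array(lb),
            np.where(np.array(la) == "high", "HH", "LL"),
            "LH",
        )
        design["sharing_category"] = cat
        design = design.join(
            dyad_cov, on=["subject_a", "subject_b"], how="left"
        )
        merged = merge_isc_design(isc_records, design)
        out: dict[str, float] = {}
        for region, block in merged.groupby("region", sort=True):
            block = block.drop(columns=["region"])
            if statistic == "lmm":
                fit = fit_crossed_lmm(double_dyadic_data(block), spec)
            else:
                fit = _fit_ols_dyadic(block, spec)
            cr = emm_contrast(fit, contrast[0], contrast[1])
            out[region] = cr.t
        return out

    observed_labels = {
        (row.subject, row.video): row.level for row in levels.itertuples()
    }
    try:
        t_obs = stat_for_labels(observed_labels)
    except KeyError as exc:
        # permutations preserve per-video label counts, so a level missing
        # from the observed composition is missing from every permutation
        raise DegenerateDataError(
            f"contrast level absent from the observed dyad composition: {exc}"
        ) from exc

    rng = np.random.default_rng(seed)
    exceed = {region: 0 for region in t_obs}
    by_video = {
        video: block[["subject", "level"]].reset_index(drop=True)
        for video, block in levels.groupby("video")
    }
    for _ in range(n_permutations):
        perm_labels: dict[tuple[str, str], str] = {}
        for video, block in by_video.items():
            shuffled = rng.permutation(block["level"].to_numpy())
            for subj, lev in zip(block["subject"], shuffled):
                perm_labels[(subj, video)] = lev
        t_perm = stat_for_labels(perm_labels)
        for region in exceed:
            if abs(t_perm[region]) >= abs(t_obs[region]):
                exceed[region] += 1
    return {
        region: (1 + exceed[region]) / (1 + n_permutations)
        for region in exceed
    }


def _fit_ols_dyadic(block: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """OLS on undoubled dyadic rows, packaged as a ModelFit for contrasts."""
    present_levels = [
        lev for lev in spec.levels if (block[spec.category] == lev).any()
    ]
    reference = (
        spec.reference_level
        if spec.reference_level in present_levels
        else present_levels[0]
    )
    y, X, names, column_stats, outcome_sd = build_fixed_design(
        block,
        outcome=spec.outcome,
        categorical=spec.category,
        levels=present_levels,
        reference=reference,
        numeric=list(spec.covariates),
        standardize=spec.standardize,
    )
    res = fit_crossed_reml(y, X, factors={}, reml=True)
    k = res["p"] if spec.count_intercept_in_k else res["p"] - 1
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
        standardize=spec.standardize,
        outcome_sd=outcome_sd,
        column_stats=column_stats,
        factor_levels={spec.category: present_levels},
        reference_level=reference,
        factor_name=spec.category,
        metadata={"estimator": "ols"},
    )
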