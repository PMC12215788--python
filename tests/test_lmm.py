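"""Doubled-data crossed mixed model: doubling, REML fit, df, contrasts."""

import numpy as np
import pandas as pd
import pytest

from dyadisc.design import all_dyads, build_dyad_design
from dyadisc.exceptions import DegenerateDataError, RankDeficiencyError, SchemaError
from dyadisc.inference import fit_crossed_reml
from dyadisc.isc import compute_dyadic_isc, normalize_within_region
from dyadisc.lmm import (
    ModelSpec,
    _fit_ols_dyadic,
    corrected_df,
    double_dyadic_data,
    fit_crossed_lmm,
    permutation_null,
    planned_contrast,
    region_wise_analysis,
)
from dyadisc.synthetic import NeuralSimConfig, simulate_neural_panel


def _synthetic_dyadic_table(n_subjects=8, seed=0, effects=(0.4, -0.2)):
    """Dyadic rows with purely fixed-effect structure + iid noise."""
    rng = np.random.default_rng(seed)
    subjects = [f"s{i}" for i in range(n_subjects)]
    level = {s: rng.choice(["low", "high"]) for s in subjects}
    rows = []
    for a, b in all_dyads(subjects):
        la, lb = level[a], level[b]
        cat = "HH" if (la, lb) == ("high", "high") else (
            "LL" if (la, lb) == ("low", "low") else "LH"
        )
        age_sim = rng.uniform(0, 1)
        g = int(rng.integers(0, 2))
        c = int(rng.integers(0, 2))
        mu = effects[0] * (cat == "HH") + effects[1] * (cat == "LH") + 0.1 * age_sim
        rows.append(("v1", a, b, cat, age_sim, g, c, mu + rng.normal(0, 0.5)))
    return pd.DataFrame(
        rows,
        columns=[
            "video",
            "subject_a",
            "subject_b",
            "sharing_category",
            "age_similarity",
            "gender_match",
            "country_match",
            "z_norm",
        ],
    )


class TestDoubling:
    def test_minimal_case_swaps_roles(self):
        table = pd.DataFrame(
            {
                "subject_a": ["s1"],
                "subject_b": ["s2"],
                "video": ["v1"],
                "z_norm": [0.7],
            }
        )
        doubled = double_dyadic_data(table)
        assert len(doubled) == 2
        assert set(doubled["role1"]) == {"s1", "s2"}
        assert doubled["z_norm"].nunique() == 1
        assert sorted(doubled["role1_video"]) == ["s1|v1", "s2|v1"]

    def test_doubles_row_count(self):
        table = _synthetic_dyadic_table()
        assert len(double_dyadic_data(table)) == 2 * len(table)

    def test_rejects_predoubled_input(self):
        table = _synthetic_dyadic_table()
        doubled = double_dyadic_data(table)
        with pytest.raises(SchemaError, match="doubled"):
            double_dyadic_data(doubled)


class TestCorrectedDf:
    def test_arithmetic(self):
        assert corrected_df(100, 6) == 94
        assert corrected_df(29770, 6) == 29764

    def test_k_equals_design_matrix_columns(self):
        table = _synthetic_dyadic_table(seed=5)
        fit = fit_crossed_lmm(double_dyadic_data(table), ModelSpec())
        # intercept + 2 category dummies + 3 covariates
        assert fit.k == 6
        assert fit.df_corrected == len(table) - 6

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            corrected_df(6, 6)


class TestReml:
    def test_matches_statsmodels_mixedlm_on_crossed_data(self):
        """Independent oracle: same crossed model via statsmodels MixedLM."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(2)
        ua = rng.normal(0, 0.7, 12)
        ub = rng.normal(0, 0.4, 6)
        rows = []
        for i in range(12):
            for j in range(6):
                for _ in range(3):
                    x = rng.normal()
                    rows.append(
                        (f"a{i}", f"b{j}", x, 1.0 + 0.5 * x + ua[i] + ub[j] + rng.normal())
                    )
        df = pd.DataFrame(rows, columns=["fa", "fb", "x", "y"])
        X = np.column_stack([np.ones(len(df)), df.x])
        ours = fit_crossed_reml(
            df.y.to_numpy(), X, {"fa": df.fa.to_numpy(), "fb": df.fb.to_numpy()}
        )
        ref = smf.mixedlm(
            "y ~ x",
            df,
            groups=np.ones(len(df)),
            vc_formula={"fa": "0 + C(fa)", "fb": "0 + C(fb)"},
        ).fit(reml=True)
        assert ours["beta"] == pytest.approx(ref.fe_params.values, abs=1e-4)
        assert np.sqrt(np.diag(ours["cov_beta"])) == pytest.approx(
            ref.bse_fe.values, rel=2e-3
        )
        assert ours["sigma2"] == pytest.approx(ref.scale, rel=1e-3)
        assert list(ours["vcomp"].values()) == pytest.approx(
            ref.vcomp, abs=2e-3
        )

    def test_collinear_design_refused(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        X = np.column_stack([np.ones(40), x, 2 * x])
        with pytest.raises(RankDeficiencyError):
            fit_crossed_reml(rng.normal(size=40), X, {})


class TestCrossedLmm:
    def test_role_swap_invariance(self):
        """Re-orienting dyads before doubling leaves estimates unchanged."""
        config = NeuralSimConfig(
            n_subjects=6,
            n_videos=2,
            n_regions=2,
            timepoints_per_video=(80, 80),
            signal_regions=("r001",),
            seed=3,
        )
        panel, ratings, attrs = simulate_neural_panel(config)
        isc = normalize_within_region(compute_dyadic_isc(panel))
        design = build_dyad_design(ratings, attrs)
        merged = isc.merge(design, on=["subject_a", "subject_b", "video"])
        block = merged[merged.region == "r001"].drop(columns="region")

        spec = ModelSpec(covariates=("age_similarity",))
        fit_fwd = fit_crossed_lmm(double_dyadic_data(block), spec)

        flipped = block.copy()
        rng = np.random.default_rng(9)
        flip = rng.random(len(flipped)) < 0.5
        a = flipped["subject_a"].to_numpy().copy()
        b = flipped["subject_b"].to_numpy().copy()
        flipped["subject_a"] = np.where(flip, b, a)
        flipped["subject_b"] = np.where(flip, a, b)
        fit_rev = fit_crossed_lmm(double_dyadic_data(flipped), spec)

        np.testing.assert_allclose(
            fit_fwd.params.values, fit_rev.params.values, rtol=1e-8, atol=1e-10
        )

    def test_matches_ols_when_no_random_structure(self):
        """With iid noise only, mixed fixed effects collapse onto OLS."""
        table = _synthetic_dyadic_table(n_subjects=10, seed=4)
        mixed = fit_crossed_lmm(double_dyadic_data(table), ModelSpec())
        ols = _fit_ols_dyadic(table, ModelSpec())
        np.testing.assert_allclose(
            mixed.params.values, ols.params.values, atol=1e-3
        )
        # at the variance boundary the collapse is exact
        pinned = fit_crossed_lmm(
            double_dyadic_data(table), ModelSpec(max_variance_ratio=0.0)
        )
        np.testing.assert_allclose(
            pinned.params.values, ols.params.values, atol=1e-10
        )
        assert all(v == 0.0 for v in pinned.vcomp.values())

    def test_constant_outcome_flagged(self):
        table = _synthetic_dyadic_table(seed=6)
        table["z_norm"] = 1.0
        with pytest.raises(DegenerateDataError, match="constant"):
            fit_crossed_lmm(double_dyadic_data(table), ModelSpec())


@pytest.fixture(scope="module")
def fitted():
    table = _synthetic_dyadic_table(n_subjects=10, seed=8)
    return fit_crossed_lmm(double_dyadic_data(table), ModelSpec())


class TestContrasts:
    def test_identity_contrast_is_null(self, fitted):
        cr = planned_contrast(fitted, ("HH", "HH"))
        assert cr.estimate == 0.0
        assert cr.p_raw == 1.0

    def test_linearity_of_contrasts(self, fitted):
        hh_ll = planned_contrast(fitted, ("HH", "LL")).estimate
        hh_lh = planned_contrast(fitted, ("HH", "LH")).estimate
        lh_ll = planned_contrast(fitted, ("LH", "LL")).estimate
        assert hh_ll == pytest.approx(hh_lh + lh_ll, abs=1e-12)

    def test_antisymmetry(self, fitted):
        fwd = planned_contrast(fitted, ("HH", "LL"))
        rev = planned_contrast(fitted, ("LL", "HH"))
        assert fwd.estimate == pytest.approx(-rev.estimate)
        assert fwd.p_raw == pytest.approx(rev.p_raw)

    def test_ci_brackets_estimate_and_padj_flag(self, fitted):
        cr = planned_contrast(fitted, ("HH", "LL"))
        assert cr.ci_low < cr.estimate < cr.ci_high


class TestRegionWise:
    def test_signal_regions_detected_null_regions_quiet(self, signal_panel_bundle):
        config, panel, ratings, attrs = signal_panel_bundle
        isc = normalize_within_region(compute_dyadic_isc(panel))
        design = build_dyad_design(ratings, attrs)
        results = region_wise_analysis(isc, design, contrasts=(("HH", "LL"),))
        sig = set(results.loc[results.significant, "region"])
        assert sig == set(config.signal_regions)
        null_beta = results.loc[
            ~results.region.isin(config.signal_regions), "beta"
        ].abs()
        sig_beta = results.loc[
            results.region.isin(config.signal_regions), "beta"
        ]
        assert sig_beta.min() > null_beta.max()

    def test_single_region_adjusted_equals_raw(self):
        table = _synthetic_dyadic_table(n_subjects=10, seed=13)
        table["region"] = "only"
        design = table.drop(columns=["z_norm", "region"])
        isc = table[["subject_a", "subject_b", "video", "region", "z_norm"]]
        results = region_wise_analysis(isc, design, contrasts=(("HH", "LL"),))
        assert results.loc[0, "p_adjusted"] == pytest.approx(
            results.loc[0, "p_raw"]
        )

    def test_region_relabeling_permutes_rows(self, signal_panel_bundle):
        _, panel, ratings, attrs = signal_panel_bundle
        isc = normalize_within_region(compute_dyadic_isc(panel))
        design = build_dyad_design(ratings, attrs)
        base = region_wise_analysis(isc, design).set_index("region")
        mapping = {"r001": "r004", "r004": "r001"}
        renamed = isc.assign(region=isc.region.replace(mapping))
        swapped = region_wise_analysis(renamed, design).set_index("region")
        for old, new in mapping.items():
            assert swapped.loc[new, "beta"] == pytest.approx(base.loc[old, "beta"])
            assert swapped.loc[new, "p_adjusted"] == pytest.approx(
                base.loc[old, "p_adjusted"]
            )


@pytest.fixture(scope="module")
def one_region_bundle():
    config = NeuralSimConfig(
            n_subjects=10,
        n_videos=2,
        n_regions=1,
        timepoints_per_video=(80, 80),
        signal_regions=(),
        coupling_high=0.5,
        coupling_low=0.5,
        seed=17,
    )
    panel, ratings, attrs = simulate_neural_panel(config)
    isc = normalize_within_region(compute_dyadic_isc(panel))
    return isc, ratings, attrs


class TestPermutation:
    def test_deterministic_given_seed(self, one_region_bundle):
        isc, ratings, attrs = one_region_bundle
        kwargs = dict(n_permutations=30, seed=5, statistic="ols")
        with pytest.warns(UserWarning, match="coarse"):
            p1 = permutation_null(isc, ratings, attrs, **kwargs)
        with pytest.warns(UserWarning, match="coarse"):
            p2 = permutation_null(isc, ratings, attrs, **kwargs)
        assert p1 == p2
        assert all(0 < p <= 1 for p in p1.values())

    def test_lmm_and_ols_statistics_agree_on_sign_of_evidence(self, one_region_bundle):
        isc, ratings, attrs = one_region_bundle
        with pytest.warns(UserWarning, match="coarse"):
            p_lmm = permutation_null(
                isc, ratings, attrs, n_permutations=20, seed=1, statistic="lmm"
            )
        assert 0 < list(p_lmm.values())[0] <= 1

    def test_zero_permutations_rejected(self, one_region_bundle):
        isc, ratings, attrs = one_region_bundle
        with pytest.raises(ValueError):
            permutation_null(isc, ratings, attrs, n_permutations=0)

    def test_degenerate_labels_rejected(self, one_region_bundle):
        isc, _, attrs = one_region_bundle
        subjects = sorted(set(isc.subject_a) | set(isc.subject_b))
        flat = pd.DataFrame(
            [(s, v, 1) for s in subjects for v in ("v01", "v02")],
            columns=["subject", "video", "rating"],
        )
        with pytest.raises(DegenerateDataError, match="permute"):
            permutation_null(isc, flat, attrs, n_permutations=100)
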