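"""Synthetic generators: reproducibility, planted structure, closed forms."""

import numpy as np
import pandas as pd
import pytest

from dyadisc.exceptions import ConfigurationError
from dyadisc.isc import compute_dyadic_isc, normalize_within_region
from dyadisc.synthetic import (
    BehavioralSimConfig,
    NeuralSimConfig,
    population_isc,
    rating_from_engagement,
    simulate_neural_panel,
    simulate_study2_table,
    simulate_study3_table,
)


class TestNeuralConfig:
    @pytest.mark.parametrize(
        "overrides,field",
        [
            (dict(n_subjects=1), "n_subjects"),
            (dict(noise_sd=0.0), "noise_sd"),
            (dict(coupling_high=0.1, coupling_low=0.5), "coupling"),
            (dict(timepoints_per_video=(150,)), "timepoints_per_video"),
            (dict(signal_regions=("nope",)), "signal_regions"),
            (dict(rating_cuts=(0.5, 0.4, 0.8, 0.9)), "rating_cuts"),
        ],
    )
    def test_invalid_config_names_offending_field(self, overrides, field):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            NeuralSimConfig(**overrides).validate()

    def test_full_scale_preset_geometry(self):
        config = NeuralSimConfig.full_scale()
        assert config.n_subjects == 66
        assert config.n_videos == 14
        assert config.n_regions == 214
        assert len(config.regions()) == 214
        # durations span 91-734 s at TR = 0.8 s
        assert min(config.timepoints_per_video) == round(91 / 0.8)
        assert max(config.timepoints_per_video) == round(734 / 0.8)


class TestNeuralPanel:
    def test_bit_reproducible_given_seed(self):
        config = NeuralSimConfig(
            n_subjects=4, n_videos=2, n_regions=2, timepoints_per_video=(50, 40),
            signal_regions=("r001",), seed=123,
        )
        p1, r1, a1 = simulate_neural_panel(config)
        p2, r2, a2 = simulate_neural_panel(config)
        pd.testing.assert_frame_equal(p1.to_long_frame(), p2.to_long_frame())
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(a1, a2)

    def test_series_stable_when_regions_added(self):
        base = NeuralSimConfig(
            n_subjects=3, n_videos=1, n_regions=2, timepoints_per_video=(40,),
            signal_regions=(), seed=5,
        )
        more = NeuralSimConfig(
            n_subjects=3, n_videos=1, n_regions=4, timepoints_per_video=(40,),
            signal_regions=(), seed=5,
        )
        p_base, _, _ = simulate_neural_panel(base)
        p_more, _, _ = simulate_neural_panel(more)
        for region in ("r001", "r002"):
            np.testing.assert_array_equal(
                p_base.cell("s001", "v01")[region],
                p_more.cell("s001", "v01")[region],
            )

    def test_ratings_ages_and_sizes(self, signal_panel_bundle):
        config, panel, ratings, attrs = signal_panel_bundle
        assert ratings["rating"].isin([1, 2, 3, 4, 5]).all()
        assert (attrs["age"] > 0).all()
        assert len(attrs) == config.n_subjects
        assert len(ratings) == config.n_subjects * config.n_videos
        assert len(panel.subjects) == config.n_subjects
        assert len(panel.regions()) == config.n_regions

    def test_dropped_cells_absent(self):
        config = NeuralSimConfig(
            n_subjects=4, n_videos=2, n_regions=2, timepoints_per_video=(40, 40),
            signal_regions=(), dropped_cells=(("s002", "v01"),), seed=8,
        )
        panel, ratings, _ = simulate_neural_panel(config)
        assert not panel.has_cell("s002", "v01")
        assert panel.has_cell("s002", "v02")
        assert ((ratings.subject == "s002") & (ratings.video == "v01")).sum() == 0

    def test_rating_rule_monotone_quantile_map(self):
        cuts = (0.40, 0.70, 0.85, 0.95)
        assert [
            rating_from_engagement(e, cuts) for e in (0.2, 0.5, 0.75, 0.9, 0.99)
        ] == [1, 2, 3, 4, 5]


class TestPlantedISC:
    def test_vanishing_noise_equal_coupling_gives_unit_isc(self):
        config = NeuralSimConfig(
            n_subjects=4, n_videos=1, n_regions=2, timepoints_per_video=(60,),
            signal_regions=(), coupling_high=0.7, coupling_low=0.7,
            noise_sd=1e-7, seed=2,
        )
        panel, _, _ = simulate_neural_panel(config)
        records = compute_dyadic_isc(panel, clamp=True)
        assert (records["r"] > 0.999).all()

    def test_zero_coupling_isc_shrinks_with_length(self):
        def mean_abs_isc(n_t, seed):
            config = NeuralSimConfig(
                n_subjects=6, n_videos=1, n_regions=3,
                timepoints_per_video=(n_t,), signal_regions=(),
                coupling_high=0.0, coupling_low=0.0, seed=seed,
            )
            panel, _, _ = simulate_neural_panel(config)
            return compute_dyadic_isc(panel)["r"].abs().mean()

        short = mean_abs_isc(100, 31)
        long = mean_abs_isc(2500, 31)
        assert short < 0.2
        assert long < short / 2  # ~1/sqrt(T) scaling

    def test_closed_form_limit_at_long_series(self):
        # empirical ISC -> l1 l2 / sqrt((l1^2+s^2)(l2^2+s^2)) within 0.02
        config = NeuralSimConfig(
            n_subjects=6, n_videos=1, n_regions=2,
            timepoints_per_video=(10_000,), signal_regions=(),
            coupling_high=0.8, coupling_low=0.8, noise_sd=1.0, seed=21,
        )
        panel, _, _ = simulate_neural_panel(config)
        records = compute_dyadic_isc(panel)
        expected = population_isc(0.8, 0.8, 1.0)
        assert records["r"].mean() == pytest.approx(expected, abs=0.02)

    def test_closed_form_against_monte_carlo_oracle(self):
        """Independent simulation of the generative model (no package code)."""
        rng = np.random.default_rng(77)
        l1, l2, sd, n_t, reps = 1.0, 0.5, 1.0, 200, 1200
        rs = np.empty(reps)
        for i in range(reps):
            s = rng.standard_normal(n_t)
            x = l1 * s + rng.normal(0, sd, n_t)
            y = l2 * s + rng.normal(0, sd, n_t)
            rs[i] = np.corrcoef(x, y)[0, 1]
        assert rs.mean() == pytest.approx(population_isc(l1, l2, sd), abs=0.01)

    def test_hh_dyads_more_similar_than_ll_in_signal_regions(self, signal_panel_bundle):
        config, panel, ratings, attrs = signal_panel_bundle
        from dyadisc.design import build_dyad_design

        isc = normalize_within_region(compute_dyadic_isc(panel))
        design = build_dyad_design(ratings, attrs)
        merged = isc.merge(design, on=["subject_a", "subject_b", "video"])
        in_signal = merged.region.isin(config.signal_regions)
        gap_signal = (
            merged[in_signal & (merged.sharing_category == "HH")]["r"].mean()
            - merged[in_signal & (merged.sharing_category == "LL")]["r"].mean()
        )
        gap_null = (
            merged[~in_signal & (merged.sharing_category == "HH")]["r"].mean()
            - merged[~in_signal & (merged.sharing_category == "LL")]["r"].mean()
        )
        expected_gap = population_isc(1.0, 1.0, 1.0) - population_isc(0.5, 0.5, 1.0)
        assert gap_signal == pytest.approx(expected_gap, abs=0.05)
        assert abs(gap_null) < 0.03


class TestStudy2Generator:
    def test_deterministic_and_schema(self):
        cfg = BehavioralSimConfig(seed=4)
        t1 = simulate_study2_table(cfg)
        t2 = simulate_study2_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == cfg.n_participants * cfg.n_items
        assert t1["similarity"].between(0, 100).all()

    def test_discretized_outcome_on_scale(self):
        table = simulate_study2_table(BehavioralSimConfig(discretize=True, seed=1))
        assert table["sharing"].isin([1, 2, 3, 4, 5]).all()

    def test_null_slope_recovered_near_zero(self):
        from dyadisc.behavioral import fit_study2

        cfg = BehavioralSimConfig(
            n_participants=150, n_items=10, slope_similarity=0.0, seed=14
        )
        _, slope = fit_study2(simulate_study2_table(cfg))
        assert abs(slope.estimate_raw) < 0.08

    def test_zero_item_variance_boundary(self):
        from dyadisc.behavioral import fit_study2

        cfg = BehavioralSimConfig(
            n_participants=120, n_items=8, sd_item_intercept=0.0, seed=15
        )
        fit, _ = fit_study2(simulate_study2_table(cfg))
        assert fit.vcomp["article"] == pytest.approx(0.0, abs=0.01)
        assert fit.vcomp["participant"] > 0.05

    def test_too_few_units_rejected(self):
        with pytest.raises(ConfigurationError, match="n_items"):
            simulate_study2_table(BehavioralSimConfig(n_items=1))


class TestStudy3Generator:
    def test_balanced_allocation_and_determinism(self):
        cfg = BehavioralSimConfig(n_per_condition=30, seed=9)
        t1 = simulate_study3_table(cfg)
        t2 = simulate_study3_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        counts = t1["condition"].value_counts()
        assert set(counts.index) == {"similar", "dissimilar", "unclear", "mixed"}
        assert (counts == 30).all()
        assert t1["participant"].is_unique

    def test_missing_condition_mean_rejected(self):
        cfg = BehavioralSimConfig(
            condition_means={"similar": 3.0, "dissimilar": 2.4}
        )
        with pytest.raises(ConfigurationError, match="missing"):
            simulate_study3_table(cfg)

    def test_group_gap_matches_population_difference(self):
        gaps = []
        for seed in range(10):
            table = simulate_study3_table(BehavioralSimConfig(seed=200 + seed))
            means = table.groupby("condition")["sharing"].mean()
            gaps.append(means["similar"] - means["dissimilar"])
        assert np.mean(gaps) == pytest.approx(0.6, abs=0.15)
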