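"""Seeded generators for neural panels and behavioral tables.

The neural generator emulates the structure of a naturalistic-viewing
study: subjects watch a set of videos while a regional mean time series is
recorded per brain region, then rate how likely they would be to share
each video (1-5). Ground truth is planted through a shared latent stimulus
signal: subject i's series in region r for video v is

    lambda_{i,v,r} * s_{v,r} + noise,     noise ~ N(0, noise_sd^2) i.i.d.,

where s_{v,r} has unit population variance and the coupling lambda is
``coupling_high`` when the subject's latent engagement with the video puts
their rating at 3 or above *and* the region is a signal region, else
``coupling_low``. Two subjects with couplings l1, l2 then have population
ISC l1*l2 / sqrt((l1^2 + sd^2)(l2^2 + sd^2)), so high-sharing dyads are
more neurally similar than low-sharing dyads in signal regions by
construction and indistinguishable elsewhere.

All randomness flows from a single integer seed through named per-cell
substreams, so panels are bit-reproducible and existing series do not
change when regions are added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dyadisc.exceptions import ConfigurationError
from dyadisc.isc import TimeSeriesPanel
from dyadisc.parcellation import build_region_registry, generic_region_labels

#: Latent-engagement quantile cut-points -> rating 1..5 with probabilities
#: (.40, .30, .15, .10, .05): mean 2.10, median 2, ~30% "high" (rating >= 3),
#: mirroring the skewed sharing-likelihood distribution typical of this design.
DEFAULT_RATING_CUTS = (0.40, 0.70, 0.85, 0.95)

_COUNTRIES = ("USA", "China", "India", "Korea", "Mexico", "Canada")
_COUNTRY_P = (0.70, 0.10, 0.05, 0.05, 0.05, 0.05)


@dataclass(frozen=True)
class NeuralSimConfig:
    """Generative parameters for the synthetic neural panel.

    The default geometry is a downsized study (20 subjects, 4 videos, 10
    regions, 150 timepoints per video) for test speed; ``full_scale()``
    returns the full 66 subjects x 14 videos x 214 regions design with
    video durations spanning 91-734 s at TR = 0.8 s.
    """

    n_subjects: int = 20
    n_videos: int = 4
    n_regions: int = 10
    timepoints_per_video: tuple[int, ...] = (150, 150, 150, 150)
    signal_regions: tuple[str, ...] = ("r001", "r002", "r003")
    coupling_high: float = 1.0
    coupling_low: float = 0.5
    noise_sd: float = 1.0
    rating_cuts: tuple[float, float, float, float] = DEFAULT_RATING_CUTS
    smoothing_window: int = 5
    region_labels: tuple[str, ...] | None = None
    dropped_cells: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def regions(self) -> list[str]:
        if self.region_labels is not None:
            return list(self.region_labels)
        return generic_region_labels(self.n_regions)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.n_videos < 1:
            raise ConfigurationError("n_videos must be >= 1")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if len(self.timepoints_per_video) != self.n_videos:
            raise ConfigurationError(
                "timepoints_per_video must list one count per video"
            )
        if any(t < 3 for t in self.timepoints_per_video):
            raise ConfigurationError(
                "timepoints_per_video entries must be >= 3"
            )
        if not (self.coupling_high >= self.coupling_low >= 0):
            raise ConfigurationError(
                "require coupling_high >= coupling_low >= 0"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.smoothing_window < 1:
            raise ConfigurationError("smoothing_window must be >= 1")
        regions = self.regions()
        if self.region_labels is not None and len(regions) != self.n_regions:
            raise ConfigurationError(
                "region_labels length must equal n_regions"
            )
        unknown = set(self.signal_regions) - set(regions)
        if unknown:
            raise ConfigurationError(
                f"signal_regions not in region labels: {sorted(unknown)}"
            )
        cuts = self.rating_cuts
        if len(cuts) != 4 or any(
            not (0.0 < a < 1.0) for a in cuts
        ) or any(cuts[i] >= cuts[i + 1] for i in range(3)):
            raise ConfigurationError(
                "rating_cuts must be 4 strictly increasing values in (0, 1)"
            )

    @classmethod
    def full_scale(cls, seed: int = 0, **overrides) -> "NeuralSimConfig":
        """Full-scale preset: 66 subjects, 14 videos (91-734 s at TR 0.8 s),
        214-region registry."""
        registry = tuple(build_region_registry())
        durations = np.linspace(91.0, 734.0, 14)
        timepoints = tuple(int(round(d / 0.8)) for d in durations)
        defaults = dict(
            n_subjects=66,
            n_videos=14,
            n_regions=214,
            timepoints_per_video=timepoints,
            region_labels=registry,
            signal_regions=registry[:6],
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _stimulus(rng: np.random.Generator, n_timepoints: int, window: int) -> np.ndarray:
    """Moving-average-smoothed Gaussian signal with unit population variance."""
    white = rng.standard_normal(n_timepoints + window - 1)
    kernel = np.ones(window) / window
    smoothed = np.convolve(white, kernel, mode="valid")
    return smoothed * np.sqrt(window)  # MA(w) of N(0,1) has variance 1/w


def rating_from_engagement(engagement: float, cuts: Sequence[float]) -> int:
    """Monotone map from latent engagement in [0,1] to a 1-5 rating."""
    return 1 + int(np.searchsorted(np.asarray(cuts), engagement, side="left"))


def simulate_neural_panel(
    config: NeuralSimConfig,
) -> tuple[TimeSeriesPanel, pd.DataFrame, pd.DataFrame]:
    """Generate (panel, ratings, attributes) with known ground truth.

    Returns the time-series panel, a ratings table (subject, video, rating)
    and an attributes table (subject, age, gender, country). Deterministic
    given ``config.seed``.
    """
    config.validate()
    subjects = [f"s{i:03d}" for i in range(1, config.n_subjects + 1)]
    videos = [f"v{i:02d}" for i in range(1, config.n_videos + 1)]
    regions = config.regions()
    signal = set(config.signal_regions)
    dropped = {(s, v) for s, v in config.dropped_cells}

    # latent engagement and ratings: one substream per subject
    engagement = {}
    ratings_rows = []
    for si, subject in enumerate(subjects):
        rng = np.random.default_rng([config.seed, 1, si])
        e = rng.uniform(0.0, 1.0, size=config.n_videos)
        for vi, video in enumerate(videos):
            engagement[(subject, video)] = e[vi]
            if (subject, video) not in dropped:
                ratings_rows.append(
                    (subject, video, rating_from_engagement(e[vi], config.rating_cuts))
                )
    ratings = pd.DataFrame(ratings_rows, columns=["subject", "video", "rating"])

    # shared stimulus per (video, region); noise per (subject, video, region)
    panel = TimeSeriesPanel()
    high_threshold_engagement = config.rating_cuts[1]  # rating >= 3
    for vi, video in enumerate(videos):
        n_t = config.timepoints_per_video[vi]
        stim = {
            region: _stimulus(
                np.random.default_rng([config.seed, 2, vi, ri]),
                n_t,
                config.smoothing_window,
            )
            for ri, region in enumerate(regions)
        }
        for si, subject in enumerate(subjects):
            if (subject, video) in dropped:
                continue
            engaged = engagement[(subject, video)] >= high_threshold_engagement
            cell = {}
            for ri, region in enumerate(regions):
                lam = (
                    config.coupling_high
                    if engaged and region in signal
                    else config.coupling_low
                )
                noise_rng = np.random.default_rng([config.seed, 3, si, vi, ri])
                cell[region] = lam * stim[region] + noise_rng.normal(
                    0.0, config.noise_sd, size=n_t
                )
            panel.add_cell(subject, video, cell)

    attr_rng = np.random.default_rng([config.seed, 4])
    attrs = pd.DataFrame(
        {
            "subject": subjects,
            "age": attr_rng.integers(18, 24, size=config.n_subjects),
            "gender": attr_rng.choice(["F", "M"], size=config.n_subjects),
            "country": attr_rng.choice(
                _COUNTRIES, size=config.n_subjects, p=_COUNTRY_P
            ),
        }
    )
    return panel, ratings, attrs


def population_isc(lambda_1: float, lambda_2: float, noise_sd: float) -> float:
    """Closed-form population ISC for two subjects coupled to the same signal."""
    denom = np.sqrt(
        (lambda_1**2 + noise_sd**2) * (lambda_2**2 + noise_sd**2)
    )
    return float(lambda_1 * lambda_2 / denom)


# ---------------------------------------------------------------------------
# behavioral generators
# ---------------------------------------------------------------------------

STUDY3_CONDITIONS = ("similar", "dissimilar", "unclear", "mixed")


@dataclass(frozen=True)
class BehavioralSimConfig:
    """Generative parameters for the behavioral tables.

    Correlational mode (``simulate_study2_table``): each of
    ``n_participants`` rates ``n_items`` news articles; sharing =
    grand mean + participant intercept + item intercept +
    slope_similarity * z(similarity) + residual, with similarity drawn on
    0-100. Experimental mode (``simulate_study3_table``): balanced
    assignment of ``n_per_condition`` participants to each of the four
    social-context conditions; sharing = condition mean + residual, with
    interest and baseline-sharing covariates coupled to the sharing
    residual by ``covariate_coupling``.
    """

    n_participants: int = 100
    n_items: int = 5
    slope_similarity: float = 0.4
    grand_mean: float = 2.5
    sd_participant_intercept: float = 0.5
    sd_item_intercept: float = 0.3
    sd_residual: float = 1.0
    discretize: bool = False
    condition_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "similar": 3.0,
            "mixed": 2.8,
            "unclear": 2.6,
            "dissimilar": 2.4,
        }
    )
    n_per_condition: int = 75
    covariate_coupling: float = 0.3
    seed: int = 0

    def validate_study2(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError(
                "n_participants must be >= 2 (random intercepts unidentifiable)"
            )
        if self.n_items < 2:
            raise ConfigurationError(
                "n_items must be >= 2 (random intercepts unidentifiable)"
            )
        for name in ("sd_participant_intercept", "sd_item_intercept"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sd_residual <= 0:
            raise ConfigurationError("sd_residual must be > 0")

    def validate_study3(self) -> None:
        if self.n_per_condition < 1:
            raise ConfigurationError("n_per_condition must be >= 1")
        if self.sd_residual <= 0:
            raise ConfigurationError("sd_residual must be > 0")
        extra = set(self.condition_means) - set(STUDY3_CONDITIONS)
        if extra:
            raise ConfigurationError(
                f"condition_means has unknown conditions: {sorted(extra)}"
            )
        missing = set(STUDY3_CONDITIONS) - set(self.condition_means)
        if missing:
            raise ConfigurationError(
                f"condition_means missing conditions: {sorted(missing)}"
            )


def _discretize(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), 1, 5).astype(int)


def simulate_study2_table(config: BehavioralSimConfig) -> pd.DataFrame:
    """Correlational table: participant, article, sharing, similarity,
    interest, valence. Deterministic given ``config.seed``."""
    config.validate_study2()
    rng = np.random.default_rng([config.seed, 10])
    n, m = config.n_participants, config.n_items
    participants = [f"p{i:03d}" for i in range(1, n + 1)]
    articles = [f"a{j:02d}" for j in range(1, m + 1)]
    b_p = rng.normal(0.0, config.sd_participant_intercept, size=n)
    b_i = rng.normal(0.0, config.sd_item_intercept, size=m)

    similarity = rng.uniform(0.0, 100.0, size=(n, m))
    z_sim = (similarity - similarity.mean()) / similarity.std(ddof=1)
    interest = np.clip(
        0.5 * similarity + 25.0 + rng.normal(0.0, 15.0, size=(n, m)), 0, 100
    )
    valence = np.clip(rng.normal(50.0, 15.0, size=(n, m)), 0, 100)
    sharing = (
        config.grand_mean
        + b_p[:, None]
        + b_i[None, :]
        + config.slope_similarity * z_sim
        + rng.normal(0.0, config.sd_residual, size=(n, m))
    )
    if config.discretize:
        sharing = _discretize(sharing)
    pi, ai = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    return pd.DataFrame(
        {
            "participant": np.array(participants)[pi.ravel()],
            "article": np.array(articles)[ai.ravel()],
            "sharing": sharing.ravel(),
            "similarity": similarity.ravel(),
            "interest": interest.ravel(),
            "valence": valence.ravel(),
        }
    )


def simulate_study3_table(config: BehavioralSimConfig) -> pd.DataFrame:
    """Experimental table: participant, condition, sharing, interest,
    baseline_sharing, with balanced random assignment. Deterministic given
    ``config.seed``."""
    config.validate_study3()
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_per_condition * len(STUDY3_CONDITIONS)
    participants = [f"q{i:03d}" for i in range(1, n + 1)]
    conditions = rng.permutation(
        np.repeat(STUDY3_CONDITIONS, config.n_per_condition)
    )
    means = np.array([config.condition_means[c] for c in conditions])
    resid = rng.normal(0.0, config.sd_residual, size=n)
    sharing = means + resid
    interest = (
        3.0 + config.covariate_coupling * resid + rng.normal(0.0, 0.8, size=n)
    )
    baseline = (
        3.0 + config.covariate_coupling * resid + rng.normal(0.0, 0.8, size=n)
    )
    if config.discretize:
        sharing = _discretize(sharing)
        interest = _discretize(interest)
        baseline = _discretize(baseline)
    return pd.DataFrame(
        {
            "participant": participants,
            "condition": conditions,
            "sharing": sharing,
            "interest": interest,
            "baseline_sharing": baseline,
        }
    )
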