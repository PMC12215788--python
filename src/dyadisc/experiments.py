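"""Replicated simulation experiments: calibration, power, parameter recovery.

These are the package's headline self-checks, shared by the test suite and
the acceptance script. Every experiment regenerates its data from a seed,
runs the full analysis path (generator -> ISC -> design -> doubled-data
crossed model -> corrected inference), and reports rates or recovered
effects. Problem sizes are the downsized test geometry (20 subjects, 4
videos, 10 regions, 150 timepoints) so a full battery completes in a few
minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from dyadisc.behavioral import fit_study2, fit_study3, study3_contrasts
from dyadisc.design import build_dyad_design
from dyadisc.isc import compute_dyadic_isc, normalize_within_region
from dyadisc.lmm import ModelSpec, permutation_null, region_wise_analysis
from dyadisc.synthetic import (
    BehavioralSimConfig,
    NeuralSimConfig,
    population_isc,
    simulate_neural_panel,
)


def _panel_analysis(config: NeuralSimConfig, contrasts=(("HH", "LL"),)):
    panel, ratings, attrs = simulate_neural_panel(config)
    isc = normalize_within_region(compute_dyadic_isc(panel))
    design = build_dyad_design(ratings, attrs)
    return region_wise_analysis(isc, design, ModelSpec(), contrasts=contrasts)


def _derived_seeds(seed: int, tag: int, n: int) -> np.ndarray:
    return np.random.default_rng([seed, tag]).integers(0, 2**31 - 1, size=n)


def null_calibration(n_panels: int = 200, seed: int = 1) -> dict:
    """Family-wise false-positive rate of the HH-LL contrast on null panels.

    Half the panels carry a shared stimulus signal in every region but no
    sharing-category effect (equal couplings 0.5); the other half are pure
    noise (couplings 0). Reports the pooled and per-regime fraction of
    panels with any Holm-significant region at alpha = 0.05, and the raw
    per-region rejection rate.
    """
    n_each = n_panels // 2
    results = {"coupled": [], "noise": []}
    raw_p = []
    for regime, coupling in (("coupled", 0.5), ("noise", 0.0)):
        for s in _derived_seeds(seed, 61 if regime == "coupled" else 62, n_each):
            config = NeuralSimConfig(
                coupling_high=coupling, coupling_low=coupling, seed=int(s)
            )
            table = _panel_analysis(config)
            results[regime].append(bool(table["significant"].any()))
            raw_p.extend(table["p_raw"].tolist())
    raw_p = np.asarray(raw_p)
    fam = {k: float(np.mean(v)) for k, v in results.items()}
    return {
        "n_panels": 2 * n_each,
        "familywise_rate": float(
            np.mean(results["coupled"] + results["noise"])
        ),
        "familywise_rate_coupled_null": fam["coupled"],
        "familywise_rate_noise_null": fam["noise"],
        "raw_rejection_rate": float(np.mean(raw_p < 0.05)),
    }


def permutation_uniformity(
    n_replicates: int = 300, n_permutations: int = 49, seed: int = 1
) -> dict:
    """Distribution of permutation p-values across replicate null panels.

    One-region null panels with a shared signal but no category effect; the
    contrast statistic is the OLS t (the fast statistic option) so the
    check covers many replicates. Under the null the p-values should be
    approximately uniform on (0, 1].
    """
    pvals = []
    import warnings

    for s in _derived_seeds(seed, 63, n_replicates):
        config = NeuralSimConfig(
            n_subjects=12,
            n_videos=2,
            n_regions=1,
            timepoints_per_video=(120, 120),
            signal_regions=(),
            coupling_high=0.5,
            coupling_low=0.5,
            seed=int(s),
        )
        panel, ratings, attrs = simulate_neural_panel(config)
        isc = normalize_within_region(compute_dyadic_isc(panel))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from dyadisc.exceptions import DegenerateDataError

            try:
                p = permutation_null(
                    isc,
                    ratings,
                    attrs,
                    # gender/country matches can be constant in a 12-subject
                    # sample; age similarity always varies
                    spec=ModelSpec(covariates=("age_similarity",)),
                    n_permutations=n_permutations,
                    seed=int(s) % 100000,
                    statistic="ols",
                )
            except DegenerateDataError:
                # composition without both contrast levels: untestable panel
                continue
        pvals.append(next(iter(p.values())))
    pvals = np.asarray(pvals)
    return {
        "n_replicates": n_replicates,
        "mean_p": float(pvals.mean()),
        "rejection_rate_at_05": float(np.mean(pvals <= 0.05)),
        "p_values": pvals.tolist(),
    }


def signal_detection(
    n_replicates: int = 100, seed: int = 1, n_subjects: int = 30
) -> dict:
    """Rate at which the analysis flags exactly the planted signal regions.

    Default couplings (1.0 in 3 of 10 signal regions for engaged subjects,
    0.5 elsewhere, noise sd 1) give a population ISC gap of 0.3 between HH
    and LL dyads in signal regions. Panels use 30 subjects: a sample large
    enough for the corrected inference to hold its nominal error rate while
    keeping a 100-replicate battery to a couple of minutes (the full-study
    roster of 66 subjects behaves the same but costs ~10x). A replicate
    counts as a success only if the Holm-corrected significant set equals
    the planted set exactly.
    """
    config0 = NeuralSimConfig()
    gap = population_isc(
        config0.coupling_high, config0.coupling_high, config0.noise_sd
    ) - population_isc(config0.coupling_low, config0.coupling_low, config0.noise_sd)
    exact, misses, false_flags = 0, 0, 0
    for s in _derived_seeds(seed, 64, n_replicates):
        config = NeuralSimConfig(n_subjects=n_subjects, seed=int(s))
        table = _panel_analysis(config)
        flagged = set(table.loc[table["significant"], "region"])
        planted = set(config.signal_regions)
        exact += flagged == planted
        misses += len(planted - flagged) > 0
        false_flags += len(flagged - planted) > 0
    return {
        "n_replicates": n_replicates,
        "population_isc_gap": float(gap),
        "exact_detection_rate": exact / n_replicates,
        "miss_rate": misses / n_replicates,
        "false_flag_rate": false_flags / n_replicates,
    }


def study2_recovery(n_replicates: int = 200, seed: int = 1) -> dict:
    """Mean recovered similarity slope at generator slope 0.4 (200 x 20)."""
    estimates = []
    for s in _derived_seeds(seed, 65, n_replicates):
        config = BehavioralSimConfig(
            n_participants=200, n_items=20, slope_similarity=0.4, seed=int(s)
        )
        from dyadisc.synthetic import simulate_study2_table

        _, slope = fit_study2(simulate_study2_table(config))
        estimates.append(slope.estimate_raw)
    return {
        "n_replicates": n_replicates,
        "true_slope": 0.4,
        "mean_recovered_slope": float(np.mean(estimates)),
        "sd_recovered_slope": float(np.std(estimates, ddof=1)),
    }


def study3_recovery(n_replicates: int = 200, seed: int = 1) -> dict:
    """Mean recovered similar-dissimilar contrast at a true gap of 0.6."""
    estimates = []
    for s in _derived_seeds(seed, 66, n_replicates):
        from dyadisc.synthetic import simulate_study3_table

        table = simulate_study3_table(BehavioralSimConfig(seed=int(s)))
        fit = fit_study3(table)
        res = study3_contrasts(fit, which="primary")
        estimates.append(float(res.loc[0, "estimate_raw"]))
    return {
        "n_replicates": n_replicates,
        "true_gap": 0.6,
        "mean_recovered_gap": float(np.mean(estimates)),
        "sd_recovered_gap": float(np.std(estimates, ddof=1)),
    }
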