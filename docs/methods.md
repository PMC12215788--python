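# Methods

This note documents the models, the generative assumptions behind the
synthetic data, the numerical choices, and the design decisions that were
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Dyadic ISC

For every unordered pair of subjects that both watched a video, the sample
Pearson correlation of their regional mean time series is computed per
region, Fisher-transformed (z = atanh r), and z-scored within region across
all dyad × video records of that region (sample sd, ddof = 1; the
convention is documented because the alternative is a one-flag change).
Records exist only where both members hold the video, so partial data
simply shrinks the dyad count: with n_v subjects holding video v the table
has Σ_v C(n_v, 2) × n_regions rows.

Numerical choices:

- Correlations are computed on each video's full retained series — no
  detrending, filtering or trimming; inputs are assumed already
  preprocessed and buffer-trimmed.
- |r| = 1 (possible on noise-free synthetic input) is an error by default;
  `clamp_correlations` (|r| ≤ 1 − 1e-7) must be invoked explicitly so
  infinities never propagate silently into the normalization.
- Zero-variance series raise a named error rather than returning 0.
- Dyads are stored lexicographically ordered (subject_a < subject_b), so
  symmetry is structural: a pair can never appear in both orders.

## 2. Dyad-level design

Ratings 1–2 map to "low", ≥3 to "high" (the threshold is a config constant;
the generator's rating distribution has mean ≈ 2.1 and median 2, so ≈30% of
ratings are high). Categories: LL, LH (unordered), HH. Age similarity is
1 − |Δage| / max|Δage| with the maximum taken over the *retained* analysis
dyads — values are cohort-relative by definition, and the all-equal-ages
corner returns 1.0 with a warning instead of dividing by zero. Gender and
country matches are exact string equality; a case-insensitive near-match
warns, because silent fuzzy matching has burned everyone at least once.

## 3. The doubled-data crossed model

Each dyad × video row is duplicated with member roles swapped so a
symmetric outcome can carry member-specific crossed random intercepts:
role-1 participant, role-2 participant, video, and both role × video
interactions. After doubling, rows are sorted into a canonical order, which
makes the fit bit-for-bit invariant to how callers oriented each dyad.

Estimation is REML via a profiled criterion: with variance ratios
θ_g = σ²_g/σ²_e, H = I + Σ θ_g Z_g Z_gᵀ, both β and σ²_e have closed-form
profiles, and the Woodbury identity reduces every evaluation to dense
algebra on the q × q Gram matrix of the stacked indicator columns
(q = total group levels; ≈200 at the default geometry). L-BFGS-B optimizes
over θ ≥ 0 (start 0.5, fallback restart at 0.02; bound 1e6). The two role
factors are tied to one variance, as are the two role × video factors:
after doubling the roles are exchangeable, so these are single population
parameters — and the smaller parameter space is faster and slightly more
stable. The implementation is cross-checked in the test suite against
statsmodels MixedLM with variance components on small crossed data.

### Inference under redundancy

Two corrections address the doubling:

1. **Degrees of freedom**: every t-based p-value and CI uses
   df = N − k, where N is the count of unique (undoubled) observations and
   k the number of fixed-effect columns *including* the intercept
   (k is the conservative design-matrix column count; the intercept-free
   convention is a config switch, `count_intercept_in_k`).
2. **Information halving**: the doubled likelihood counts each observation
   twice, so the naive fixed-effect covariance is ~2× too small. The
   covariance is doubled (SE × √2); without this the null rejection rate
   at α = 0.05 is roughly 0.19 instead of ≈0.05 (the calibration battery
   measures this). The correction is exposed as
   `ModelSpec.redundancy_correction` and can be disabled for the literal
   df-only variant.

Even with both corrections a mild anti-conservatism remains at small
rosters (the calibration experiment quantifies it): with 20 subjects the
variance components are noisy and the t reference with df = N − k does not
absorb that uncertainty. Satterthwaite/Kenward–Roger-style df are out of
scope by design; the permutation test is the assumption-free alternative.

### Standardization and contrasts

With `standardize` (default), the outcome and every predictor column —
including the 0/1 category dummies — are z-scored before fitting, the most
literal reading of "all variables converted to z-scores"; contrasts are
then in outcome-SD units, and raw-scale estimates are carried alongside.
Planned contrasts are differences of estimated marginal means with
covariates at their means, so only the category dummies contribute to the
contrast vector; SEs come from the (corrected) fixed-effect covariance and
two-tailed p-values from t with df = N − k. The reference level is LL
(making the headline HH coefficient directly interpretable), but contrasts
are reference-free. Region-wise families are Holm–Bonferroni-corrected
across regions per contrast; non-converged regions are recorded and
excluded from the corrected family, never imputed.

### Permutation test

The exchangeable units are participants, not dyadic rows: within each
video, the binarized sharing labels are permuted across participants, dyad
categories are rebuilt (covariates unchanged), and the contrast statistic
is recomputed; p = (1 + #{|t_perm| ≥ |t_obs|}) / (1 + n_perm). Because
permutations preserve per-video label counts, a contrast level absent from
the observed composition is absent from every permutation — that case
raises an error rather than returning a vacuous p. The refitted statistic
is the crossed-model contrast t by default, or an OLS t (`statistic="ols"`)
when many permutations are needed; permutation validity does not depend on
the statistic choice.

## 4. Behavioral models

**Correlational study**: sharing ~ z(similarity) with crossed random
intercepts for participant and article (same REML machinery), optionally
plus z(interest) and z(valence). Reported df follow the residual-style rule
n_obs − k, recorded in the fit metadata; no claim is made that this matches
any particular published df convention, which is typically unstated.
Collinear designs (e.g., similarity duplicated as interest) are refused
with a rank-deficiency error, never fitted silently.

**Experimental study**: OLS of sharing on the four-level condition factor
(reference "dissimilar"), optionally controlling for baseline sharing and
interest; all pairwise contrasts BH-FDR-corrected within the requested
family. Without covariates the raw-scale contrasts equal group-mean
differences exactly (tested to 1e-10). With 300 participants and no
covariates the residual df is 296; with both covariates, 294.

**Degenerate limit**: pinning every variance ratio at zero
(`max_variance_ratio=0`) reduces the mixed model exactly to OLS; this is
the boundary at which the OLS-equivalence check is exact. With freely
estimated components, boundary noise keeps REML estimates a small positive
amount in about half of null datasets, which shifts GLS fixed effects at
the 1e-3 level on subject-structured designs — an estimator property, not
a bug, and the reason the exact comparison is made at the boundary.

## 5. Synthetic data: what it emulates, what it does not

Geometry defaults are a downsized study for test speed — 20 subjects, 4
videos, 10 regions, 150 timepoints per video — with a `full_scale()`
preset at the full 66 subjects × 14 videos × 214 regions and video
durations spanning 91–734 s at TR = 0.8 s. The region registry composes
200 cortical parcel labels with 14 bilateral subcortical labels; regions
are opaque strings with no geometry.

The stimulus signal per (video, region) is Gaussian white noise smoothed
with a 5-point moving average (configurable) and rescaled to unit
population variance — enough temporal autocorrelation to look BOLD-like
without changing population correlations. Subject series are
λ·s + N(0, σ²) with λ = `coupling_high` when the subject's latent
engagement for the video exceeds the high-rating threshold *and* the
region is a signal region, else `coupling_low`. Engagement is uniform on
[0,1] per subject × video and thresholded at fixed quantile cut-points
(0.40/0.70/0.85/0.95) to produce 1–5 ratings with mean ≈ 2.1 and median 2;
a monotone engagement → (coupling, rating) link is the minimal structure
that makes HH > LL true by construction. The closed-form population ISC
λ₁λ₂/√((λ₁²+σ²)(λ₂²+σ²)) is verified both against an in-test Monte-Carlo
oracle and against the generator's empirical ISC at 10⁴ timepoints.

All randomness flows from one integer seed through named substreams per
(subject), (video, region) and (subject, video, region), so panels are
bit-reproducible and existing series are stable when regions are added.
Whole subject × video cells can be dropped to emulate partial data; no
default drop pattern is shipped because there is no canonical one.

Deliberately not modeled: voxel images, hemodynamic convolution, head
motion, scanner noise spectra, spatial correlation between regions, and
rating measurement error independent of engagement. Passing tests
demonstrate the statistical machinery is correct under the stated
generative model — they do not validate preprocessing choices or the
additivity of real BOLD dependence structure.

Behavioral generators: the correlational table draws similarity uniform on
0–100 and builds sharing = grand mean + participant intercept + item
intercept + slope · z(similarity) + residual (defaults 2.5, sd 0.5, sd 0.3,
slope 0.4, sd 1.0), with optional rounding/clipping to the 1–5 scale; the
experimental table assigns exactly n-per-condition participants (default
75) to the four social contexts with means 3.0 / 2.8 / 2.6 / 2.4 and unit
residual sd — a similar-vs-dissimilar gap of 0.6 raw points, in the range a
moderate manipulation produces on a 5-point scale — plus interest and
baseline-sharing covariates correlated with the sharing residual
(coupling 0.3).

## 6. Replicated self-checks and problem sizes

The experiment battery (`dyadisc.experiments`, run by the acceptance
script and the acceptance tests) uses these sizes, chosen to give each
check resolving power at a few minutes' total runtime on one CPU:

- **Null calibration**: 200 panels at the 20-subject test geometry, split
  100/100 between two null regimes — shared signal with no category effect
  (couplings 0.5/0.5), and pure noise (0/0). The first keeps the realistic
  dyadic dependence structure; the second is the independence baseline.
  Family-wise significance after Holm at α = 0.05 is compared to
  0.05 + 2·binomial SE.
- **Permutation calibration**: 300 one-region null panels (12 subjects, 2
  videos), 49 permutations each with the OLS statistic; rejection at 0.05
  and the mean p are checked against binomial/uniform bounds.
- **Signal detection**: 100 panels at 30 subjects — the smallest roster at
  which the corrected inference holds its nominal error rate, so that the
  exact-set criterion (flag all three signal regions and nothing else)
  reflects power rather than small-sample miscalibration.
- **Parameter recovery**: 200 replicates each for the similarity slope
  (200 participants × 20 items, true 0.4) and the condition gap (true 0.6).

## 7. Known limitations

- The N − k df rule with the √2 information correction is well calibrated
  but not exact at small rosters; family-wise error at 20 subjects runs
  slightly above nominal in the shared-signal null regime. Use the
  permutation test when exactness matters.
- The fitter handles random intercepts only (no random slopes), REML or
  ML, single residual variance — exactly the model family the pipeline
  needs, nothing more.
- Non-binarized (ordinal) sharing models, matched-count subsampling, and
  leave-one-out/group-average ISC variants are out of scope; the
  binarization threshold and k-convention switches exist so the nearby
  variants are one flag away.
- The full-scale preset is provided for geometry fidelity; simulating and
  fitting it whole is memory- and CPU-heavy and is not exercised by the
  test suite beyond registry propagation.
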