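# dyadisc

Dyadic inter-subject correlation (ISC) analysis: does neural similarity
between two people watching the same videos track how likely each of them is
to share those videos?

`dyadisc` implements the full statistical pipeline for that question, plus
the two companion behavioral analyses, over a seeded synthetic-data generator
with known ground truth, so every stage is verifiable end to end without any
neuroimaging download.

## Who this is for

Researchers analyzing naturalistic-viewing fMRI with dyadic similarity
outcomes (ISC matrices) and self-report sharing data, and methodologists who
want a tested reference implementation of the doubled-data crossed
random-effects approach for symmetric dyadic outcomes.

## The model

For subjects *i*, *j*, video *v* and brain region *r* (regions are opaque
labels: a 200-parcel cortical scheme plus 14 subcortical regions, 214 in
all), the pipeline computes the Pearson correlation
r<sub>ij,v,r</sub> between the two regional mean time series, applies the
Fisher transform z = atanh(r), and z-scores the result within region. Each
participant's 1–5 sharing-likelihood rating is binarized (1–2 low, ≥3 high)
and each dyad × video is categorized LL / LH / HH; age similarity
(1 − |Δage|/max|Δage|), gender match and country match enter as covariates.

Because ISC is symmetric in the dyad, each observation is **doubled** with
member roles swapped, and the region-wise linear mixed model

    z_norm ~ sharing_category + age_sim + gender_match + country_match
             + (1|role1) + (1|role2) + (1|video) + (1|role1:video) + (1|role2:video)

is fitted by REML (crossed random intercepts; the two role factors share one
variance by exchangeability). Inference corrects for the doubling twice
over: degrees of freedom are set to N − k on the *unique* observation count,
and the fixed-effect covariance is doubled (SE × √2) because the doubled
likelihood counts each observation twice. Planned contrasts of estimated
marginal means (headline: HH − LL) are Holm–Bonferroni-corrected across
regions; a within-video label-permutation test is available as a
nonparametric check.

The behavioral arms: a crossed mixed model of sharing likelihood on
perceived similarity (random intercepts for participant and article,
optionally adjusting for interest and valence), and an OLS model of sharing
likelihood on a four-level social-context condition with all pairwise
contrasts under BH-FDR. All models report standardized coefficients
(everything z-scored), with raw-scale estimates alongside.

The synthetic generator plants ground truth through a shared stimulus
signal: subject *i*'s series is λ·s + noise, with λ high only for engaged
(high-rating) subjects in designated signal regions, so the population ISC
is λ₁λ₂/√((λ₁²+σ²)(λ₂²+σ²)) and the HH > LL contrast is true by
construction exactly where planted.

## Worked example

```bash
python analysis/01_simulate.py           # 20 subjects, 4 videos, 10 regions
python analysis/02_neural_similarity.py  # ISC -> design -> crossed LMM
python analysis/03_behavioral.py         # similarity slope + condition contrasts
```

The neural arm prints the region-wise HH−LL contrast:

```
region    beta       t  df  p_raw  p_adjusted  significant
  r001  2.4139 19.6612 754 0.0000         0.0         True
  r002  2.6116 21.5363 754 0.0000         0.0         True
  r003  2.2754 18.0180 754 0.0000         0.0         True
  r004  0.0247  0.1370 754 0.8910         1.0        False
  ...
significant regions: ['r001', 'r002', 'r003'] (signal regions are r001-r003)
```

Exactly the three regions where the generator planted a coupling difference
survive Holm correction; `beta` is the HH−LL difference in outcome-SD units
and `df` = 760 unique dyad×video observations − 6 fixed effects. The
behavioral arm recovers a positive standardized similarity slope
(0.318, t(498) = 7.76) that survives adjustment for interest and valence
(0.268), and condition contrasts in which sharing with a similar group
exceeds sharing with a dissimilar one (raw gap 0.68, adjusted p = 0.0002).

The same stages are scriptable via the CLI:

```bash
dyadisc run --outdir runs/demo --seed 7
dyadisc fit-neural --outdir runs/demo --contrast all --correction holm
dyadisc permute --outdir runs/demo --n-perm 999
dyadisc validate --ratings runs/demo/ratings.tsv
```

## Layout

```
src/dyadisc/       library: synthetic, parcellation, isc, design, lmm,
                   behavioral, multitest, inference, experiments, pipeline, cli
analysis/          numbered narrative drivers writing to results/
tests/             pytest suite (unit, property, acceptance batteries)
scripts/           acceptance.py
docs/methods.md    modeling and design notes
```
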