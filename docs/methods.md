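# Methods

`pedbc` implements a complete analysis chain for profiling body composition
in school-age children: reference-value models for body-composition indices,
z-score standardization, wearable-data screening, missing-data handling,
cluster discovery, and between-cluster comparisons. Because individual-level
cohort data of this kind cannot be redistributed, the package ships a
synthetic-cohort generator whose statistical structure matches what the
downstream stages assume; every stage is exercised end to end on generated
data.

## Body-composition indices and reference models

A body-composition index (BCI) is a bioimpedance component mass divided by
height squared: FMI (fat), LMI (lean), MMI (muscle), BNI (bone), TWI (total
body water), all in kg/m²; BMI is handled by the same machinery. Reference
models are built per sex and index in three steps:

1. **Binning.** Observations are grouped by sex and *floored* integer age
   (7.0–7.9 → 7). Each bin contributes its mean and sample SD (n−1
   denominator). Bins with fewer than two observations are dropped with a
   warning. Flooring (rather than rounding) was chosen because a child aged
   7.9 is conventionally "7 years old"; the SD uses n−1 because bins are
   samples, not populations.
2. **Curve fitting.** Three score series — mean, mean+1SD, mean−1SD — are
   each fitted with a least-squares cubic in integer age. Cubics capture
   the mild growth-curve curvature over ages 7–14 without the tail
   oscillation of higher degrees.
3. **Evaluation.** Query ages are rounded to 0.1 years. The reference mean
   is the fitted mean curve; the reference SD is `(upper − lower) / 2`,
   which averages the two one-sided estimates and is symmetric by
   construction. The asymmetry `(upper − mean) − (mean − lower)` is exposed
   as a diagnostic (`sd_asymmetry`). The SD is floored at 1e-6 kg/m² so
   degenerate fixtures cannot divide by zero. A z-score is then
   `(value − mean) / sd`.

The fitted age domain is `[min integer age, max integer age + 0.9]`, i.e.
every child whose floored age has a bin is in-domain. Extrapolation beyond
the domain raises by default (cubic tails are untrustworthy); a `clamp_age`
flag evaluates at the nearest domain edge instead.

Height, weight and BMI z-scores — obtained from an external national
reference tool in the original workflow — go through the identical
three-curve machinery here; any numeric column can be modelled.

Open choices resolved: repeated measures of the same child across waves are
pooled when fitting (all subject-wave observations enter their age bin); a
first-observation-per-child restriction can be applied upstream by
filtering the cohort table.

## Synthetic cohort generator

The generator emulates a three-wave annual school cohort: 353 enrolled
children, per-wave participation probabilities chosen so expected wave
sizes are 336/318/263 (≈917 subject-wave observations), ages 7.0–13.9 with
exactly +1.0 year per wave (real measurement dates drift by months; this is
a documented simplification).

**Masses.** Each subject-wave draws a z-vector over (FMI, MMI, BNI), either
from planted cluster centroids plus within-cluster Gaussian noise
(SD 0.3 by default) or from a latent-factor model (fat–lean loading 0.55,
bone–muscle loading 0.95, which yields r(LMI, MMI) > 0.999). Component
masses are reconstructed through per-sex cubic generating curves, and the
remaining quantities follow the generator's declared conventions (the BIA
device's internal identities are proprietary, so the package fixes its
own): `fat + lean = weight` and `muscle + bone = lean` exactly;
`water = 0.73·lean·(1 + δ)` with δ ~ N(0, 0.005), clipped below lean;
`bfp = 100·fat/weight`. Under these conventions lean, muscle and water
indices are near-collinear (r > 0.99), matching what BIA outputs show.

**Planted clusters.** The five default centroids in (FMI, MMI, BNI, TWI)
z-space follow the observed subpopulation semantics — all-low,
slightly-low, slightly-high, all-high, and high-fat/average-muscle — with
minimum pairwise separation 2.0 so recovery is decidable at within-SD 0.3.
A child keeps one cluster across waves; per-wave jitter (SD 0.15) models
year-to-year drift.

**Correlates.** Abdominal circumference, total cholesterol, triglycerides
(log-normal) and HDL-C are drawn with a mild dependence on the fat z-score,
so the high-fat cluster shows larger AC, higher TC/HDLC and TG/HDLC, and
shorter sleep — the gradient the comparison suite is meant to detect.
Wrist-device traces are 11 days with per-day category minutes, steps and
sleep; a configurable fraction of days (default 20%) is forced under the
0.8 monitored-time criterion and 5% under the 0.1 activity criterion.
Subject-level mean MVPA is ~N(80, 20) min/day, putting roughly 83% of
subject-waves above the WHO 60-minute guideline.

**Missingness.** Nullable fields are masked independently at the printed
per-indicator rates (AC 0.33%, lipid panel 12.00% — nulled jointly as one
blood draw — steps 9.38%, activity 14.61%, sleep 19.96%). The default
mechanism is MCAR; these rates are generator defaults, not estimates. All
randomness flows from one seed through spawned per-operation streams, so
adding a generator call does not perturb existing draws.

What the generator does **not** emulate: secular height/weight trends,
seasonal activity patterns, device-specific error structure, the empirical
BMI–MMI correlation of a real cohort (planted clusters make it higher than
observed in practice), and informative missingness. Tests passing on
synthetic data therefore validate the machinery, not population claims.

## Wearable screening

Daily screening is sequential: (1) raw epochs aggregate to calendar days at
the midnight delimiter; a sleep episode starting between 18:00 and noon of
the next day is credited in full to the wake day (episodes starting between
noon and 18:00 fall outside the recording window and are dropped); (2) each
subject's first and last three wear dates are removed; (3) a day survives
only if monitored/1440 > 0.8 **and** (light+moderate+vigorous)/1440 > 0.1 —
both strict, checked in that order; (4) day-level steps and sleep values
outside mean ± 2 sample SDs are removed — inclusive bounds, single pass
(no re-computation after removal), with the mean/SD taken cohort-wide
within measurement year over the days that survived the wear filters
(a per-subject scope is available by flag); (5) survivors are averaged per
participant-year; subject-waves losing all days become missing values for
the imputation stage. Every input day lands in exactly one of
retained/excluded, and the exclusion reason is the first failed criterion.

## Missing data

*kNN (main route).* The distance between two rows is Euclidean over their
mutually observed features, each scaled by the column's observed-sample SD,
and reweighted by `p/m` (p features, m mutually observed) so sparse overlap
does not shrink distances. Each missing cell is the unweighted mean of the
k = 5 nearest rows observing that column; fewer than k donors means all are
used; distance ties break by row order. This contract is deliberately
explicit so an exhaustive brute-force oracle can reproduce it bit-for-bit
(and does, in the test suite).

*Chained-equation PMM (sensitivity route).* Defaults: m = 20 completed
datasets, 50 cycles each, 5 donors, seed 1234. Missing cells initialize as
random draws from the observed column values; columns are visited in
ascending missing count. Each cycle regresses the target on all other
columns (ridge-stabilized least squares), draws σ² and β from their
posterior, predicts missing rows from the draw and observed rows from the
least-squares fit (type-1 matching), and copies the observed value of a
donor drawn uniformly from the 5 closest predicted means — so every imputed
value is an observed value of its column. Estimates across the m datasets
pool by Rubin's rules with Barnard–Rubin degrees of freedom.

*Complete cases.* Listwise deletion over the analysis columns, with the
dropped count reported.

## Clustering

Features are the z-scores of BMI, FMI, MMI and BNI: the collinear
lean/muscle/water trio (pairwise |r| > 0.99, grouped by transitive closure)
collapses to its muscle representative before clustering, and the features
are already z-scaled so no further standardization is applied. Ward
minimum-variance agglomeration (scipy linkage; heights follow scipy's Ward
convention) is cut below the last k−1 merges at k = 5; k-means
(k-means++ seeding, 10 restarts, fixed seed) serves as the sensitivity
check, with the adjusted Rand index quantifying agreement. k = 5 is fixed
to mirror the established subpopulation scheme — no automatic model
selection is performed.

Canonical labelling makes results comparable across runs: the three
lowest-BMI centroids become clusters 1–3 in ascending BMI; of the top two,
the higher-MMI centroid is 4 (balanced high build) and the other is 5
(high fat, average muscle — the risk-profile cluster). BMI ties break by
ascending FMI.

Cluster-recovery checks run on the planted cohort's ground-truth z-matrix
(standardized against the generating curves), where the within-cluster SD
is exactly the nominal 0.3; re-estimating the reference from the same
n = 500 cohort adds curve-estimation noise and lowers ARI to roughly
0.85–0.9 — a property of reference estimation at that sample size, not of
the clustering.

## Group comparisons

Unadjusted: one-way ANOVA per indicator across clusters, chi-square
(no continuity correction) for sex/year/age composition, Pearson r for
index correlations. Adjusted: each indicator regresses on cluster
(indicator-coded, cluster 1 reference), measurement year (categorical),
sex (boys 0, girls 1) and age (continuous years), with a Gaussian random
intercept per child fitted by REML when repeated measures exist; a
boundary (non-positive) variance estimate degenerates to OLS with a
warning. Confidence intervals for fixed effects are Wald-based.
Coefficients and CI endpoints are additionally reported exponentiated,
matching the forest-plot convention for these outcomes; outcomes are not
log-transformed first (raw-scale outcomes such as step counts can
therefore overflow to `inf` on the exponentiated scale — the raw columns
remain authoritative). On the multiple-imputation path the model is refit
by OLS per completed dataset (no random intercept) and pooled by Rubin's
rules before exponentiation. No multiplicity correction is applied across
the eight indicators (α = 0.05 per test).

## Problem sizes and numerical choices

Default test and acceptance runs use: a ~917-observation three-wave cohort
(353 children); n = 500 single-wave cohorts for cluster recovery; n = 200
per age-sex bin for reference-curve recovery; 100 random 50×6 matrices for
the kNN oracle; 100 replicates for ANOVA calibration; 200 subjects × 3
waves for mixed-model recovery. These sizes give stable statistics while
keeping the whole suite fast on one CPU. Tolerances: exact arithmetic
checks at 1e-8–1e-12; simulation recovery at 3 standard errors; calibration
inside 99% binomial bands. Ridge stabilization (1e-8) guards the chained
regressions against collinear predictors; constant columns get unit scale
in the kNN distance.

## Known limitations

- Reference curves are mean±SD cubics, not LMS (Box–Cox) references; no
  percentile curves, no skewness modelling.
- The SD filter is single-pass; an iterated filter would remove slightly
  more points.
- The mixed model supports a single random intercept only (no slopes).
- Canonical labelling is specific to the five-cluster scheme.
- Synthetic realism is limited to the documented structure; defaults are
  plausible for Japanese elementary-school children but are not population
  norms.
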