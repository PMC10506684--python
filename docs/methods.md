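# Methods

## Model

Every diagnostic parameter (global value, 45° sector, or macular
hemisphere) is modeled per eye as

    y_ij = β0 + β_age (age_i − 50) + β_male I(male_i) + β_ssi (SSI_ij − 50)
         + β_myo h_myo,ij + β_hyp h_hyp,ij + u_i + ε_ij

for eye *j* of participant *i*, where the hinge terms

    h_myo = (a − a_ref) · I(SE < 0)      h_hyp = (a − a_ref) · I(SE ≥ 0)

split one ametropia variable *a* — axial length (AL, reference
23.7 mm), spherical-equivalent refraction (SE, reference 0 D) or
apparent disk diameter (DD, reference 0) — at the emmetropic breakpoint
SE = 0 D. Eyes with SE exactly 0 fall on the hyperopic hinge, which is
immaterial because the hinge value is 0 there. `u_i ~ N(0, σ_u²)` is a
participant random intercept absorbing the correlation between fellow
eyes; `ε_ij ~ N(0, σ_e²)` is the residual. Exactly one ametropia
variable enters per model; age, sex and the scan's signal strength
index are always included.

Estimation is restricted maximum likelihood via `statsmodels.MixedLM`
with a single random intercept (no random slopes: nothing in the design
identifies participant-specific ametropia slopes with at most two eyes
per participant). Coefficient p-values use the large-sample normal
approximation; with ~1300 eyes a small-sample df correction would be
immaterial. The myopic-vs-hyperopic segment contrast is a 1-df Wald
test on β_myo − β_hyp, algebraically identical to testing the
interaction coefficient in the equivalent parameterization
`a_centered + a_centered·I(myopic)` (a property the test suite checks).

Standardized slopes are `β · SD(a) / SD(y)` over the whole analysis
cohort — the change in outcome SDs per covariate SD — used to compare
effect sizes across covariates.

### Sector-vs-global slope comparison

Whether a sector's ametropia slope differs from the global one is
tested in a joint long-format mixed model: regions stacked per eye,
fixed effects = region factor + shared covariates + hinge terms +
region×hinge interactions, random intercept per participant. Each
sector's myopic interaction contrast gets a 1-df Wald F-test,
Bonferroni-corrected across the eight sectors (α = 0.05/8 = 0.00625).
This is the standard construction for an "ANOVA F-test with mixed
effects" on slope heterogeneity; with 1-df contrasts F = z².

## Adjustment

    adjusted = raw − (age−50)·β_age − I(male)·β_male − (SSI−50)·β_SSI
                   − (a − a_ref)·β_a

Reference values: age 50 y (emmetropic mean age), SSI 50 (the
low-quality cutoff), AL 23.7 mm (emmetropic mean); SE and DD are
subtracted uncentered (reference 0), exactly as the formula is applied
in practice. The uncentered SE/DD forms shift all values by a constant,
which is harmless because normative thresholds are re-derived from the
emmetropes *after* adjustment. Global parameters are adjusted with the
global slopes, sectors with their own sectoral slopes. By default the
adjustment is piecewise: myopic-side eyes get β_myo, hyperopic-side
eyes get β_hyp (0 when not supplied — hyperopic slopes are typically
non-significant); `CoefficientTable(piecewise=False)` applies a single
slope to all eyes.

## Normative thresholds and false-positive analysis

The abnormality threshold per region and adjustment state is the
empirical 5th percentile of the emmetropic eyes, implemented as the
k-th order statistic with k = ceil(0.05·n). This convention guarantees
at most 5% of the reference sample itself falls strictly below the
threshold and is exactly reproducible across platforms; the
interpolated quantile is available via `interpolated=True`. Flagging is
strict (`value < threshold`); values equal to the threshold are normal;
missing values yield missing flags excluded from rates.

Per-stratum rates are contrasted against emmetropia with Pearson's χ²
on the 2×2 flagged/unflagged table, 1 df, no continuity correction
(cell counts are large at the default cohort scale; a Yates-corrected
variant is one flag away in `scipy`). The paired pre/post-adjustment
change within a stratum uses McNemar's test on the discordant counts
with continuity correction, (|b−c|−1)²/(b+c); b+c = 0 gives p = 1. No
multiplicity correction is applied to these rate tests — the Bonferroni
factor 8 belongs to the sector-vs-global slope family only. A seeded
single-eye-per-participant replicate of the whole sweep serves as a
sensitivity check on two-eye clustering.

## Synthetic cohort generator

The generator emulates the *post-exclusion* analysis cohort of a
population-based normative study: 789 participants in four refraction
strata (high myopia SE < −6 D, low myopia [−6, −1), emmetropia [−1, 1],
hyperopia > 1 D) with per-stratum participant shares 66/336/284/103 and
per-stratum two-eye probabilities chosen so expected eye counts are
117/590/480/152 (~1339 eyes, overall two-eye fraction ≈ 0.70).

Covariates are truncated normals per stratum (age to [18, 78] y, SE to
the stratum interval, SSI to [50, 100], IOP to ≤ 21 mmHg, cup-to-disk
ratio to ≤ 0.7). Because truncation biases a rejection-sampled mean
toward the interval interior — a nominal N(−7.9, 1.6²) high-myopia SE
truncated at −6 D would realize −8.3 D — the generator moment-matches
the location: it solves for the underlying μ such that the *truncated*
mean equals the configured stratum mean (scale is kept, so realized SDs
shrink slightly under two-sided truncation; means, which the
calibration targets, are exact in expectation). Biometry follows SE
linearly: AL = 23.8 − 0.34·SE + N(0, 0.8²) mm and
DD = 1.64 + 0.018·SE + N(0, 0.15²) mm, interpolating the stratum means
(emmetropic AL ≈ 23.7 mm at the stratum's mean SE of +0.1 D); disk area
is back-derived as π(DD/2)².

Outcomes follow the broken-stick equation above with default
coefficients equal to the AL-model regression rows of the calibration
tables for all 21 regions (9 NFLT, 3 GCCT, 9 NFLP-CD). Design choices
a user should know:

- **Globals are generated independently of their sectors**, from their
  own coefficient rows, so global-row recovery is exact by
  construction; the device-software question of whether the global
  equals the sector mean is deliberately not modeled, and internal
  global-vs-sector-mean consistency is sacrificed.
- **Sector intercepts are free parameters** (not published anywhere);
  defaults follow the TSNIT double-hump profile (temporal thin,
  superior/inferior thick). They affect no slope or rate analysis.
- **Variance components** (random-intercept and residual SDs) are free
  parameters tuned once so marginal SDs land near the cohort values
  (global NFLT 9.0 µm, GCCT 6.8 µm, NFLP-CD 2.8%) with a two-eye ICC
  in the 0.5–0.7 range typical of ocular measurements.
- **QC-failure injection** (low SSI, high IOP, high CDR, missing
  values) defaults to rate 0 — the default cohort is already
  post-exclusion; nonzero rates exist to exercise the QC stage.

What the generator does *not* emulate: anatomic nerve-fiber trajectory
variation (sector outcomes are conditionally independent given the
shared random intercept, whereas real sectors are strongly
cross-correlated within an eye), non-Gaussian tails, measurement
floor/ceiling effects, axial-length measurement error, and any
between-eye asymmetry structure beyond the shared intercept. Passing
tests therefore demonstrate that the estimation and screening machinery
is correct and calibrated under the stated generating model — not that
the specific published coefficient values are externally valid.

## Strata and QC conventions

Interval endpoints are not universally standardized; here high myopia
is SE < −6, low myopia [−6, −1), emmetropia [−1, 1] (closed on both
sides — it is the reference group), hyperopia > 1. Exclusions: any
scan SSI < 50 drops the eye from all analyses (complete-case eyes; a
per-scan retention switch exists), IOP > 21 mmHg, CDR > 0.7, any
missing measurement. All rules are strict inequalities at the printed
limits, so SSI exactly 50 and IOP exactly 21 are kept.

## Problem sizes and numerics

The default simulated cohort is ~789 participants / ~1339 eyes, the
scale the calibration targets. The test suite runs reduced cohorts
(120–600 participants) for speed and one full-scale cohort for the
headline checks; the acceptance script averages 24 full-scale
replicates so Monte-Carlo SEs on recovered slopes are a few
hundredths. REML variance estimates at the σ_u = 0 boundary are
reported as the boundary value with a note in `FitResult.diagnostics`
on non-convergence; rank-deficient designs (e.g. no hyperopic eyes for
the hyperopic hinge) raise immediately with the reason. Left-eye sector
mirroring is assumed handled at ingest: stored sector columns are
always in right-eye orientation.
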