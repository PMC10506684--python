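# sectornorm

Sector-based normative adjustment of OCT/OCTA glaucoma diagnostic
parameters for refractive-error bias.

## The problem

Glaucoma screening compares a patient's peripapillary nerve fiber layer
thickness (NFLT), macular ganglion cell complex thickness (GCCT) and
peripapillary capillary density (NFLP-CD) against a normative database:
values below the 5th percentile of healthy reference eyes are flagged
abnormal. In myopic eyes the longer axial length (AL) reduces the
optical magnification of the scan, widening the effective sampling
circle, so healthy myopes read "thin" and are flagged at far more than
the nominal 5% rate — and the bias differs sharply *by sector*: the
superior, nasal and inferior sectors thin with axial elongation while
the temporal sectors thicken. A single global correction therefore
under- or over-corrects individual sectors.

`sectornorm` is a library for studying and correcting this bias. It is
aimed at researchers in ophthalmic imaging and biostatistics who need a
tested, seeded implementation of the full analysis chain:

1. **Synthetic cohorts** with realistic stratified covariate structure
   (age, sex, spherical equivalent SE, AL, disk diameter DD, intraocular
   pressure, per-scan signal strength SSI) and two-eye clustering within
   participants.
2. **Broken-stick linear mixed models**: for each parameter and region,

   `y = β₀ + β_age·(age−50) + β_male·I(male) + β_SSI·(SSI−50)
        + β_myo·h_myo + β_hyp·h_hyp + u_participant + ε`

   with hinge terms `h_myo = (a − a_ref)·I(SE<0)`,
   `h_hyp = (a − a_ref)·I(SE≥0)` splitting the ametropia variable
   `a ∈ {AL, SE, DD}` at the emmetropic breakpoint (SE = 0 D), a
   participant random intercept `u`, REML variance components, and a
   Wald test of the myopic-vs-hyperopic segment difference.
3. **Covariate adjustment** per region:
   `adjusted = raw − (age−50)β_age − I(male)β_male − (SSI−50)β_SSI −
   (a − a_ref)β_a` (AL reference 23.7 mm; SE and DD uncentered).
4. **False-positive analysis**: 5th-percentile emmetrope thresholds,
   per-stratum rates, χ² contrasts vs emmetropia, McNemar tests of the
   paired pre/post-adjustment reduction, and a single-eye sensitivity
   replicate.

## Worked example

```python
from sectornorm import ModelSpec, fit_model, generate_cohort

records = generate_cohort(seed=1)          # ~789 participants, ~1339 eyes
fit = fit_model(records, ModelSpec("nflt_global", "AL"))
print(fit.params["myopic"], fit.bse["myopic"], fit.interaction_p)
```

prints (seed 1) a myopic-segment slope of `-2.00 ± 0.20` µm/mm with
segment-difference p `1.5e-07`: each extra millimetre of axial length
costs a myopic eye about 2 µm of measured global NFLT, while the
hyperopic segment is flat. Running the screening comparison
(`examples/04_adjust_and_screen.py`) shows the consequence and the fix:

```
adjustment     stratum  n_eyes  fp_rate  chi2_p  mcnemar_p
       raw high_myopia     104   0.1827  0.0000        NaN
        AL high_myopia     104   0.0673  0.4312     0.0015
```

18% of healthy high-myopic eyes are flagged abnormal before adjustment
(χ² vs emmetropia p < 1e-4); AL adjustment with the fitted sector
slopes returns the rate to the ~5% expected of healthy eyes, and the
McNemar test confirms the paired reduction. The scripts in `examples/`
walk through each capability (simulation, model fitting, sector-vs-
global comparison, screening, the full pipeline); a thin CLI
(`sectornorm simulate|qc|fit|adjust|fpr|all`) wraps the same functions.

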