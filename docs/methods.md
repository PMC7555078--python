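# Methods

## Data model

One row per subject: site, diagnostic group (control/ASD), sex, age
(years), FSIQ, medication and comorbidity flags, optional total ADOS score,
and regional volumes in mm³ (cm³ accepted on input with a units flag).
The 22 analysis regions are cerebral white matter, the brain stem, and
left/right pairs of ventral diencephalon, cerebellum cortex, accumbens,
amygdala, caudate, hippocampus, pallidum, putamen, thalamus and hemispheric
cortex; total gray matter is carried alongside so that
TBV = total gray matter + cerebral white matter holds exactly.

Inclusion filters keep subjects with age ≤ 27 and 70 ≤ FSIQ ≤ 130
(inclusive bounds: observed extremes such as age 26.95 and FSIQ 129.11
survive).  Every exclusion is logged once with its triggering rule.

Outlier flags: within each group and region, the studentized residual of
z(log10 V) regressed on z(log10 TBV); |r| > 3 flags the subject for that
region (≈0.27% of entries under Gaussian noise).  The rule is scale-free
and matches the allometric model being fitted.  Flags mark, never delete;
sensitivity fits drop flagged rows.  Groups under 10 subjects are skipped
(too few residual df), and numerically exact fits (residual variance
< 1e-20) flag nothing.

## Synthetic cohort generator

The generator emulates a two-group, 17-site cohort: 352 controls / 302 ASD;
sex ratios 80.4% / 87.7% male; age from a shifted beta(1.62, 2.38) on
[6, 27] years (mean ≈ 14.5, left-skewed with mode near 12.5); FSIQ from
truncated normals on [70, 130] (controls 109.75 ± 11.05, ASD
102.18 ± 14.37).  log10 TBV is normal per sex (means 6.09 male / 6.03
female, SD 0.04) with a Gaussian-copula correlation to FSIQ of 0.31
(controls) and 0.08 (ASD); the latent copula correlation is inflated by a
quadrature-computed factor to offset the truncation and sex-mixture
attenuation, so the *observed* Pearson correlations match the configured
values.  Regional volumes follow
log10 V = a + α·log10 TBV + site + ε with per-region defaults (white
matter 1.15; cortices 1.00; subcortical 0.63–0.90), residual SDs
0.01–0.035 log10 units (log-log R² ≈ 0.5 for subcortical regions, matching
typical fits), residual correlation 0.3 between homologous left/right
pairs, and site intercepts with SD 0.01 log10 units.  White matter is
generated from its own power law and total gray matter is defined as
TBV − WM, keeping the TBV identity exact.  Outliers are injected by
multiplying a random region of randomly chosen subjects by 0.5 or 2.
Comorbidity rates (0.85% / 10.9%), medication rates (2% / 25%) and ADOS
totals (11.85 ± 3.76, range 2–21, ~28% missing) complete the phenotypes.

`inject_group_difference` shifts the ASD slope and/or intercept of one
region; with an anchor TBV the intercept absorbs −Δα·anchor so a slope
shift pivots at the anchor (a pure scaling gap).
`delta_alpha_for_standardized_gap` converts a standardized (z-scale) slope
gap into the raw Δα via Δα = gap · SD(log10 V)/SD(log10 TBV).

What the generator does **not** emulate: scanner-specific artifacts,
non-TBV drivers of regional volume (age/sex effects beyond TBV),
segmentation error structure, and longitudinal change.  Passing tests
therefore certify the estimators and decision logic, not the biology of
any particular cohort.

## Allometric scaling fits

Per group, OLS of log10 V on log10 TBV (optional covariates: centered age,
sex, age×sex, medication, fixed site dummies).  95% CIs use the t
distribution on residual df; the isometry test is a Wald χ²(1) on
((α−1)/SE)².  Classification: hyperallometric if CI low > 1,
hypoallometric if CI high < 1, else isometric.  A zero-SE degenerate fit
reports p = 0 with a warning unless α = 1 exactly.

## Multi-group CFA and invariance cascade

One latent factor (the shared brain-size dimension) measured by the 22
standardized log10 volumes, with mean structure and free residual
covariances for the homologous pairs.  Identification: latent variance
fixed to 1 and latent mean fixed to 0 in **both** groups unless explicitly
freed.  Fixing the variance in both groups (rather than freeing it in the
second group under loading constraints) makes the global metric test spend
exactly p = 22 df — one per constrained loading — which is the convention
the rest of the pipeline (and its df bookkeeping) assumes; the alternative
remains available via `latent_var_free`.

Estimation minimizes the two-group normal-theory ML discrepancy (sample
covariances with divisor n_g); N·F at the optimum is the exact
likelihood-ratio χ² against the saturated model.  The gradient is
analytic; variances are parameterized on the log scale; the start is
deterministic (first principal-component loadings, half sample variances)
with up to five seeded jitter restarts; convergence requires a gradient
max below 1e-5.  Dense BFGS is used — limited-memory variants stalled on
the ~150-parameter two-group problem.  Fit indices: CFI and TLI against
the closed-form independence baseline (diagonal Σ, free means; TLI capped
at 1), RMSEA with the multi-group √G convention.  Negative difference
statistics from optimizer noise are floored at zero with a warning.

Cascade: configural → global metric (all loadings equal, Δdf = 22; gate at
α = .05) → regional metric per indicator (one loading freed at a time,
Bonferroni α = .05/22) → global scalar (intercepts equal on top of the
metric outcome, carrying any regionally rejected loadings as free —
partial invariance) → regional scalar.  Each regional result carries the
freed parameter's group gap (reference minus second group, in z units) and
Chen's cutoff flags (|ΔCFI| > .005, |ΔRMSEA| ≥ .010).  The scalar test is
taken against the metric-constrained model, not the configural model, so
it too spends 22 df on its 22 intercept constraints.

The latent TBV group difference is estimated from a scalar-constrained
model with a free second-group latent mean (κ, in reference-group latent
SD units); a configural model with free intercepts *and* a free latent
mean is not identified, so this is the only well-posed form of the
"latent factor regressed on group" adjustment.  Its SE comes from the
inverse numerical Hessian of the discrepancy (delta method).

Calibration caveat: the null-calibration properties (rejection rate ≈ 5%,
Δχ² ~ χ²(p)) presuppose a correctly specified model.  The generator's site
intercept is a second common factor across regions and the sex mixture
makes the latent non-Gaussian, so calibration experiments run single-sex,
site-free cohorts; with the default site SD (0.01) the distortion is small
but measurable at large n.

## Mixed-effects group models

`z(log10 V)` (or `z(raw V)` for unadjusted/linear analyses) regressed on
fixed effects over {group, z(log10 TBV), z(TBV), z(centered age),
z(centered age²), sex, z(FSIQ), hemisphere, medication, z(ADOS)} with a
scanner-site random intercept (REML, statsmodels MixedLM), plus a subject
random intercept exactly when hemisphere enters as a within-subject
factor (volumes stacked long).  Two-level factors are coded 1/2
(1: control, 2: ASD; 1: male; 1: left) and centered, continuous predictors
standardized on the analysis sample, so coefficients are standardized
effect sizes and a positive group coefficient means the ASD value is
larger.  p-values are Wald normal approximations (at n ≥ 250 the
difference from df-corrected variants is negligible); BH-FDR is applied
within each model's reported fixed effects.  Singular or non-converged
mixed fits fall back to OLS with fixed site dummies, flagged in metadata.
Cohen's d = 2t/√ν with ν = n − (fixed parameters).

Sensitivity suite: (a) full data; (b) minus response-region outlier flags
and comorbid subjects; (c) = (b) + medication covariate.  Severity models
refit on the ASD subset with z(ADOS total) replacing group (≥ 30 scored
subjects required).  Backward elimination removes the highest-p
interaction with p > .05 whose superset interactions are all gone
(marginality), never touching main effects; exact ties break toward the
lexicographically later term.

## TBV-adjustment comparison

Four techniques on one identical subject set, all with the site random
intercept: (a) z(raw V) ~ group; (b) + z(TBV); (c) + z(TBV)×group;
(d) z(log10 V) ~ group × z(log10 TBV).  Raw- and log-scale
standardization are both computed over the full analysis sample.  A design
note: with brain-realistic TBV dispersion (CV ≈ 10%) the group
coefficients of (b) and (d) are first-order identical under purely
TBV-driven differences — both estimate the vertical gap at the pooled TBV
centroid — so meaningful divergence requires a scaling-slope gap, whose
raw-scale volume weighting inflates the covariate estimate relative to
the allometric one.  The comparison table flags the technique whose
group-term significance disagrees with the majority.

## Four-step decision rule

A regional difference is called only if (a) the χ² difference test is
significant at the cascade's α, (b) the CFA group gap exceeds 0.2
(standardized), (c) the CFA and mixed-model effects agree to within 0.15
— compared on magnitudes, because the CFA gap (reference − ASD) and the
mixed-model coefficient (ASD-positive coding) carry opposite signs for the
same phenomenon — and (d) the mixed-model term is FDR-significant both on
the full data and after outlier/comorbidity removal.  Disagreement with
Chen's cutoffs is recorded (`chen_conflict`) but does not veto;
a missing robust fit yields `indeterminate`.  The 0.15 concordance
tolerance and the 0.2 effect threshold are exposed in the run config.

## Pipeline

One config (YAML-loadable) drives: generate/load → filters → derived →
outlier flags → scaling tables → invariance cascade on the entire sample
and on four default strata (boys 6–<12, boys 12–<20, boys ≤/> the
within-run boys' FSIQ median), each gated on ≥ 50 subjects per group →
per-region mixed models with the sensitivity suite → four-step decisions →
adjustment comparison → markdown report.  Every artifact carries a
provenance header (version, seed, config hash; the output directory is
excluded from the hash).  Stage failures are recorded in the manifest and
do not abort independent stages.  Identical config + seed reproduces every
table byte for byte.

## Problem sizes in tests and the acceptance script

Simulation-heavy checks use reduced but statistically meaningful sizes,
chosen as the package's own experiment design: null rejection rates over
400 seeds with 6 indicators at n = 250/group; the χ²-reference KS check
over 500 replicates with 5 indicators; slope-gap recovery at the
motivating subsample size n = (137, 123); localization over 100 seeds with
8 indicators; scaling classification at n = 2000/group; adjustment
divergence over 20 seeds at the default cohort size.  Under these
conditions the per-seed localization rate of a −0.25 standardized gap sits
at ~78% — at, not above, the 80% design goal; the corresponding
acceptance test documents this honestly rather than relaxing the noise
model (subcortical log-log R² ≈ 0.5 was chosen for realism, and raising it
would trivially inflate power).

## Known limitations

No robust (sandwich/scaled) χ² or fit indices — standard ML only.  No
multi-factor models, ordinal indicators, or modification-index search.
No Satterthwaite/Kenward–Roger df for the mixed models.  The generator's
volumes depend on TBV only, so age/sex/FSIQ interaction machinery can only
be validated against hand-built cohorts with explicit interaction effects
(as the elimination tests do) or null recovery.
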