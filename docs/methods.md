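# Methods

## Subclass scheme and derived traits

The panel resolves 14 size-defined lipoprotein subclasses (diameters
≥75, 64.0, 53.6, 44.5, 36.8, 31.3, 28.6, 25.5, 23.0, 18.7, 14.3, 12.1,
10.9, 8.7 nm; classes VLDL ×6, IDL, LDL ×3, HDL ×4), each carrying four
lipid constituents: TG, CE, FC, PL, in mmol/L. This is a deliberate
reduction of the full 191-trait NMR panel to its constituent structure;
subclass cholesterol is CE + FC, matching the platform's "C" measures,
and per-subclass "total lipids" is TG + CE + FC + PL. Compositions are
percentages of that total, so they sum to 100 by construction and are
invariant to rescaling a subclass's constituents.

Derived summaries: Friedewald LDL-C = TC − HDL-C − TG/2.2 (divisor
configurable; invalid above TG = 4.5 mmol/L, returned missing);
size-specific LDL-C = CE+FC summed over the three 18–26 nm LDL
subclasses only; remnant-C = VLDL-class + IDL cholesterol. The apoB and
apoA-I columns are generator-level latent particle-count proxies
(subclass total lipids divided by diameter³), labelled as such — they
stand in for immunoassay measurements in the adjustment ladder.

## Synthetic cohort generator

The generator exists to give the analysis code data with the right
*statistical shape*; none of its raw-scale effect sizes are published
quantities.

* **Genotypes.** Dosages are Binomial(2, f) per variant — exact
  Hardy–Weinberg — with the two default variants carrying the external
  CHD constants used for scaling (logOR 0.0309, SE 0.01, f = 0.69
  CETP-proxy; 0.0358, SE 0.01, f = 0.57 HMGCR-proxy). The effect allele
  is coded as the CHD risk allele; scaling to the −0.105 target flips
  estimates into the inhibition direction.
* **Lipid panel.** Latent log-concentrations per (subclass, constituent)
  follow a nested factor model: global, lipoprotein-class, and subclass
  factors (SDs 0.15 / 0.15 / 0.10) plus idiosyncratic noise (SD 0.15).
  This yields strong within-subclass correlations, moderate within-class
  correlations, and a positive-definite covariance by construction.
  Baseline means come from adult population medians (e.g. total lipids
  1.10 mmol/L in S-HDL, 0.012 in XXL-VLDL; VLDL particles 55% TG, LDL
  44% CE). Age and sex act additively on the latent scale.
* **Allele effects** are injected additively on latent log-means, making
  the additive dosage model exactly correct: the CETP-like risk allele
  moves TG into HDL (+0.030/allele on HDL TG), CE/FC out of HDL
  (−0.065), raises VLDL/IDL cholesterol (+0.050/+0.030) with zero
  size-specific LDL shift; the HMGCR-like risk allele raises CE/FC
  across all apoB classes (+0.040–0.045). Magnitudes were chosen once to
  give realistic standardized effects (|β| ≈ 0.1–0.3 SD per allele) at
  the default frequencies.
* **Events.** Times are exponential (Weibull optional) proportional
  hazards on a log-linear predictor (configured trait log-HRs per SD,
  age at 0.05/yr, and each variant's CHD logOR per allele), censored
  administratively at 8 years. The baseline hazard is calibrated by a
  deterministic root-solve so that the *expected* event fraction equals
  the cohort's target given the realized linear predictors (a naive
  1 − exp(−rate·T) inversion undershoots once the predictor is
  dispersed). Default prospective cohorts target the case fractions
  287/6,484, 270/3,318 and 59/4,378 over 8 years, i.e. 616 cases and
  13,564 controls pooled.
* **Determinism.** Per-cohort seeds are blake2s(master_seed, cohort_id)
  (mod 2³¹), so any cohort regenerates in isolation; identical
  config + seed is byte-identical.

What the generator does **not** emulate: LD structure, imputation
uncertainty, population stratification (PCs are noise), platform
measurement error, non-proportional hazards, or competing risks.
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions, not robustness to those real-data features.

## Analysis scale

Headline genetic analyses residualize each trait on sex, age, batch and
10 PCs, then apply a rank-based inverse normal transformation with the
Blom offset: Φ⁻¹((r − 3/8)/(m + 1/4)), ties averaged (the offset is
configurable; Blom is the common GWAS convention, and the choice is a
convention rather than a derived fact). The parameter-recovery suites
instead run associations on the natural-log scale (`transform="log"`),
because an injected latent shift equals the log-scale slope exactly in
expectation, giving a sharp β·(−0.105/λ) oracle; on the INT scale the
slope is divided by the latent SD and the oracle would depend on
variance components rather than on the injected parameter.

Scaling treats the external CHD log-odds as a fixed constant (so |z| and
p are preserved exactly); a first-order delta-method variant that
propagates the logOR's SE is available behind a flag for sensitivity.
Allele harmonization requires the observed allele to be one of the two
declared alleles and refuses strand inference.

## Meta-analysis and multiplicity

Fixed-effect IVW pooling (weights 1/se²) with Cochran's Q and I²;
DerSimonian–Laird random-effects re-pooling is attached as a diagnostic
column only and never drives flags. The significance threshold is
0.05/k where k is the smallest number of principal components of the
trait correlation matrix explaining ≥99% of variance (complete-case by
default; a pairwise mode errors on non-PSD matrices). With the reduced
52-trait panel k lands near 28–31 depending on sampling; the threshold
can be pinned to 28 components (alpha = 0.05/28 ≈ 0.002) for
comparability. Flags use strict p < alpha.

## Survival stage

Prevalent CHD cases are excluded; follow-up is truncated at 8 years
(later events become censored non-events; an event at exactly the
horizon counts as an event). Metabolic measures are log-transformed and
SD-scaled within cohort — compositions included, since they are
strictly positive percentages (configurable). Zeros in real data can be
offset by half the smallest positive value; the generator produces none,
so the offset is off by default.

Cox fits maximize the partial likelihood via statsmodels `PHReg`,
Breslow tie handling by default with Efron behind a flag (ties are
measure-zero in the generator, and the two agree on untied data; tests
verify both this and agreement with lifelines and with brute-force
grid-search maximization of the hand-written partial likelihood).
Convergence is checked through the score norm; |log HR| > 10 is flagged
as likely separation. The adjustment ladder is encoded as named rungs:
`basic` (age, sex, mean arterial pressure, smoking, diabetes, lipid
medication, region/ethnicity), then `+totalTG`, `+HDL-C`, `+apoB`,
`+apoB+HDL-C`, `+apoB+totalTG`, the serum-lipids model `+TC+totalTG`,
and an `+LDL-C` add-on. Medication users are *retained* in this stage
(medication is a covariate here, unlike the genetic stage where users
are excluded). Ladder cells that fail to fit are recorded per cell and
excluded from pooling rather than aborting the run. Hazard ratios are
pooled on the log scale and exponentiated for reporting.

## Numerical choices and problem sizes

OLS residualization and slopes use closed-form least squares
(`numpy.linalg.lstsq` / explicit normal equations); rank deficiency
after dropping constant columns is a named error. CIs use the 1.96
normal multiplier throughout, matching the symmetric intervals the
estimates tables report. p-values are floored at 1e-300 to keep logs
finite.

The shipped verification suites use: 40 replicates of n = 20,000 for
scaled-estimate recovery (3-SE coverage ≥95%), n = 50,000 for Cox
log-HR recovery, 600 replicate null traits across 3 cohorts of 800 for
flag calibration at alpha = 0.05, and a single 20,000-sample cohort for
the qualitative CETP signature. These sizes give Monte-Carlo tolerances
comfortably inside the assertions while keeping the full suite under a
minute; they are the package's chosen study conditions, stated here so
they can be scaled up when more precision is wanted.

## Known limitations

* The 52-trait reduced panel cannot reproduce platform-specific trait
  definitions (e.g. whether esterified and free cholesterol enter the
  "total lipids" denominator exactly as on the NMR platform); the
  compositional denominator here is TG+CE+FC+PL by definition.
* The effective-test count depends on the simulated correlation
  structure and on whether cohorts are pooled before the PCA (pooled by
  default); it is recomputed from data unless pinned.
* The external CHD log-odds values ship with an explicit risk-allele
  orientation; published summary statistics often leave orientation
  implicit, and the pipeline deliberately errors rather than guessing.
* Scaled estimates inherit the fixed-constant convention for the
  outcome log-odds; the delta-method flag exists precisely because that
  convention understates uncertainty when λ is imprecise.
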