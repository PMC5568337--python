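# Methods

## Generative model

The synthetic cohort emulates a clinic-based case-control collection with
three diagnostic groups — controls, normal tension glaucoma (NTG) and high
tension glaucoma (HTG) — defined by maximum IOP and optic-disc criteria:
HTG requires at least one IOP reading ≥ 22 mmHg, NTG and controls require
IOP ≤ 21 mmHg throughout, and controls additionally require mean VCDR ≤ 0.4
and no glaucoma.

Two latent quantities drive group membership:

1. **Latent maximum IOP.** For participant *i*,

       IOP_i = b0 + Σ_v d_iv·β_v + β_age·(age_i − 65) + β_male·male_i
               + δ·vuln_i + ε_i,      ε_i ~ N(0, σ_IOP²)

   with dosages `d_iv ~ Binomial(2, f_v)` under Hardy-Weinberg. When the
   latent value crosses 22 mmHg, an independent log-normal draw
   `exp(N(μ_t, σ_t²))` is added. Rationale: the observed quantity is the
   *maximum* over many tonometry readings in eyes that are actually
   hypertensive, a floored and strongly right-skewed statistic (group mean
   28.6, SD 8.3 above a hard floor of 22 cannot be Gaussian).

2. **Glaucoma vulnerability** `vuln_i ~ Bernoulli(p_v)`, a single latent
   standing in for the aggregate burden of non-IOP-related susceptibility
   variants. Vulnerable subjects develop glaucoma; their phenotype (NTG vs
   HTG) is then decided purely by maximum IOP. No non-IOP variant genotypes
   are simulated — no in-scope analysis needs them.

   The vulnerability shift δ is an extension beyond the minimal additive
   model: conditional on IOP ≤ 21, vulnerability alone cannot separate the
   NTG maximum-IOP distribution (18.4 ± 1.9) from the control distribution
   (15.0 ± 2.6), because the two would share one truncated distribution.
   A latent shift for vulnerable subjects — clinically, glaucoma patients
   present with higher pressure exposure than screening-negative controls
   even below the normal ceiling — makes both group means attainable
   simultaneously and is recoverable by regression.

Mean VCDR is linear in the observed maximum IOP with a glaucoma offset:

    VCDR_i = c0 + c1·maxIOP_i + c2·vuln_i + η_i,   η_i ~ N(0, σ_V²),

clamped to [0, 1]. Maximum IOP is rounded to 1 decimal (tonometry
granularity) and VCDR to 2 decimals *before* group assignment, so the CSV
representation is lossless and rounding cannot reclassify rows downstream.
A latent IOP in (21.05, 21.95) rounds strictly between the two thresholds;
such draws (and vulnerable draws failing both criteria, or non-vulnerable
draws with VCDR > 0.4) are "ineligible" and rejected during quota sampling.

Quota sampling draws candidates per group using group-specific age/sex
profiles (controls 67.7 ± 11.2 y, 36.6% male; NTG 63.8 ± 13.3 y, 39.1%;
HTG 63.7 ± 14.2 y, 61.2% male as baseline) and keeps those the model
assigns to that group, until the quotas (246/261/255 by default) are met
exactly; a cap of 1000 × total quota draws guards against infeasible
configurations. Because selection acts after the draw, realised covariate
moments differ slightly from the profile baselines (e.g. males are
over-retained in HTG via the male IOP effect); the profiles are sampling
distributions, not post-selection targets. The control "over 40 years"
recruitment criterion is not enforced — age is a covariate only and no age
moment is a validation target.

## Calibration

Allele frequencies, per-allele effects and the remaining free parameters
are not published. The shipped `paper_calibrated` profile is the frozen
output of `iopgrs.calibrate`, which matches large-sample simulated moments
to the published group summaries:

| target (group, statistic) | value | knob |
|---|---|---|
| control mean max IOP | 15.0 mmHg | baseline `b0` |
| NTG mean max IOP | 18.4 mmHg | vulnerability shift `δ` |
| HTG mean max IOP | 28.6 mmHg | tail location `μ_t` |
| control SD max IOP | 2.6 mmHg | noise `σ_IOP` |
| HTG SD max IOP | 8.3 mmHg | tail scale `σ_t` |
| control mean GRS | 8.7 | shared frequency `f` |
| HTG mean GRS | 9.1 | shared per-allele effect `β` |
| group mean VCDR | 0.34 / 0.83 / 0.85 | `c0`, `c2`, `c1` |
| pooled standardized VCDR-on-IOP β | 0.48 | VCDR noise `σ_V` |

Equal frequencies and effects across the nine variants reflect the
unweighted score's exchangeability assumption; each value remains
individually configurable. The calibrated profile has f ≈ 0.483 (implied
population mean GRS ≈ 8.7) and β ≈ 0.17 mmHg per allele; the HTG–control
GRS separation of 0.4 alleles then arises purely from selection on the
IOP threshold, and the implied per-allele HTG-vs-control odds ratio
(≈ exp(0.4 / var(G)) ≈ 1.09) lands near the published adjusted estimate of
1.12 without being targeted directly — a useful consistency check.

Two search strategies are provided. Per-knob damped secant iteration works
when targets decouple (each statistic monotone in its own knob, weak
cross-talk). The default profile was fitted with the joint Nelder–Mead
mode, which minimises the tolerance-scaled squared error over all knobs:
the VCDR block is strongly coupled (the control mean is a truncated-normal
mean that saturates as the noise SD grows, and the pooled correlation
depends on every VCDR parameter), and coordinate-wise updates oscillate
there. Both modes evaluate statistics under **common random numbers** with
fixed-size candidate blocks: the same evaluation seed and block sizes every
iteration make each statistic a smooth, deterministic function of the
parameters, so the optimiser sees the response surface rather than Monte
Carlo noise. Fitted parameters were then re-verified on three independent
seeds at 20,000 eligible draws per group; the profile records the targets
with the achieved values.

## Scoring and missing data

Unweighted scores are plain dosage sums; weighted scores use natural-log
odds ratios as weights, `Σ_v d_iv·ln(OR_v)`, read as "each risk-allele copy
contributes its variant's log-OR" — the only interpretation consistent with
per-allele ORs and additive coding. Per-variant ORs are estimated by
unadjusted single-predictor logistic regression of case status (default
HTG vs control, i.e. IOP elevation) on dosage; variants showing quasi- or
complete separation are flagged and excluded from weighted scoring with a
warning rather than penalised, keeping the estimator as described. Missing
dosages follow an explicit policy: `exclude` (default) drops the
participant and reports the count; `mean_impute` substitutes the variant's
observed mean dosage and flags the score vector as imputed.

## Association stages

- **Linear.** OLS with intercept; standardized coefficients
  `β_raw·sd(x)/sd(y)` are reported *alongside* raw coefficients and
  raw-scale standard errors, rather than reproducing the ambiguous
  convention of pairing a standardized β with a raw-scale SE in one
  column. Constant or linearly dependent columns raise a collinearity
  error naming the offending columns. The variant stage fits all nine
  dosages simultaneously (plus age and sex), matching a single
  model-level F; per-variant marginal fits can be composed from the same
  primitive.
- **ANOVA.** One-way fixed-effects F across the three groups; post hoc
  pairwise two-sample t-tests with pooled variance (Welch by flag), with
  significance declared at the fixed threshold 0.05/3 on unadjusted
  p-values and 3×p adjusted values also reported. Which post hoc flavour
  the original SAS analysis used is unstated; pooled is the classical
  Bonferroni post hoc and is the documented default.
- **Logistic.** Case (NTG or HTG) versus control on age, male sex (male=1)
  and the unweighted GRS; per-unit Wald ORs and 95% CIs. Separation is
  detected (solver failure, non-convergence, or runaway |coefficient| > 15
  on the logit scale) and returned as a flagged result with no numeric ORs.

All stages drop rows with missing required fields, report `n_used`, and are
invariant to input row order.

## Cutoff enrichment

`relative_ratio(a, b, A, B) = (a/b)/(A/B)` compares the HTG:control
composition above a GRS threshold with the full sample (29/11 vs 255/246
at threshold 12 gives 2.54). A subgroup-versus-total comparison is nested,
so the accompanying chi-square test uses the standard well-posed partition
2×2 — (GRS ≥ t vs < t) × (HTG vs control) — reported both uncorrected and
with Yates continuity correction. On the published counts these give
p ≈ 0.004 and p ≈ 0.007 respectively, neither of which equals the printed
p = 0.0085; the original test construction is not recoverable from the
text, so the package asserts its own formula-oracle-validated statistics
and documents the discrepancy rather than tuning to match. Infinite
(b = 0 < a) and undefined (a = b = 0) ratios are carried as flagged
sentinels, never silent NaN, and serialise as null + flag in JSON.

## Numerical and design choices

- Natural logarithm throughout for OR weights (standard logistic scale).
- Two-sided tests; α = 0.05 everywhere except the 0.05/3 post hoc rule.
- Sex coding male = 1, female = 0; age centred at 65 years in the
  generator.
- Display rounding (ORs to 2 dp, ratios to 2 dp) happens only at the CLI;
  reports serialise at full precision, and byte-identical reports are
  guaranteed for identical config + seed.
- Generator noise scales may be exactly zero to support deterministic
  degenerate checks (additivity at machine precision).
- VCF ingestion matches records by rsID only and requires the risk allele
  to equal REF or ALT; anything else is a hard error (no silent strand
  flips on a nine-variant panel).

## What the simulation does and does not show

The generator reproduces the *moment structure* the analyses consume:
Hardy-Weinberg genotypes, additive dosage effects on a truncated/inflated
IOP scale, group-conditional IOP and VCDR summaries, and quota-sampled
case-control composition. It does not model linkage disequilibrium between
variants, longitudinal IOP series or 24-hour variation, medication or
corneal-thickness adjustments (not performed in the emulated design),
family-history structure, or unequal per-variant effects. Passing tests
therefore demonstrate that the pipeline's statistics behave correctly on
data with the assumed structure — not that the calibrated parameters are
the study population's true values, which are not identifiable from the
published summaries (the calibration is self-consistent, not unique).
Problem sizes in the validation suite (20,000 eligible draws per group for
moment checks; 200 replicates at 255+246 for odds-ratio recovery; 50 quota
cohorts for the pooled VCDR-IOP coefficient) were chosen so Monte Carlo
error is several times smaller than the tolerance being checked.
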