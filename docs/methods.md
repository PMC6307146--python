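# Methods

## The repeated-measures design

The unit of analysis is the within-person change in methylation between
two blood draws. Working with differences of *technical residuals* rather
than raw beta values serves two purposes: per-visit residualization on
technical covariates and estimated cell proportions removes batch
structure that differs between the two assays, and differencing removes
every stable person-level confounder (genotype, stable cell composition,
constant exposures). Residualization is run separately per visit and per
cohort because chips, plates, and control-probe structure are
visit-specific; pairing is by an individual identifier, never by column
position. The completeness filter precedes residualization: the analysis
set is defined by CpGs observed in every sample at both visits, because
the penalized-regression stages cannot tolerate missing predictors and
imputation is deliberately out of scope.

In the regression the outcome is coded 0 on every baseline row and the
observed difference on the follow-up row, with the event indicator 0 at
baseline and equal to case status at follow-up. The event contrast
therefore lives entirely on follow-up rows; a visit main effect is not
included since it would be confounded with the baseline-zero outcome
coding. Clinical covariates (age, sex, BMI, type-2 diabetes, hypertension,
physical activity, pack-years, alcohol g/day) enter with their
visit-specific values, so secular changes in them are adjusted at both
time points.

## GEE estimation

Each CpG is fit with a Gaussian identity-link GEE clustered on the
individual. The default working correlation is independence: point
estimates then coincide exactly with OLS on the stacked rows, and the
cluster-robust sandwich supplies valid variances under arbitrary
within-person correlation. This equivalence is exploited to evaluate the
genome-wide scan in closed form, vectorized across CpGs — the same
estimator a per-CpG GEE fit returns (a unit test asserts exact agreement
with `statsmodels` GEE), at a small fraction of the cost. An exchangeable
working correlation is available by configuration and falls back to
independence (flagged) if its iteration fails. Wald z statistics are
referred to the standard normal, two-sided.

CpGs with zero outcome variance are flagged `degenerate` and excluded from
the Benjamini–Hochberg correction's test count, so undefined tests do not
dilute the FDR. The screening threshold (q < 0.15) is deliberately
liberal and configurable: the screen's purpose is inclusion, with false
positives removed downstream by penalized selection in independent
samples.

Calibration: with few events (~50 cases of 1,000) the sandwich variance
for the event contrast rests effectively on the case clusters, so the
type-I error at α = 0.05 runs very slightly hot (≈0.05–0.06 in the
package's own null experiments). No small-sample correction is applied —
the multi-stage design absorbs screening false positives by construction.
Note also that genome-wide p-values are *exchangeably dependent*: the
generator (like real blood methylation) includes a shared per-individual
drift, so across replicates the empirical rejection rate and KS uniformity
statistic fluctuate more than binomial/independent theory suggests.

## Elastic-net cascade

Selection is a two-cohort cascade: a penalized logistic model on the
discovery cohort restricted to EWAS survivors, then a second, independently
tuned model on the refinement cohort restricted to the stage-1 non-zero
set. Predictors are standardized internally; reported coefficients are on
the original ΔCpG scale. The mixing parameter defaults to α = 0.5 (lasso
α = 1 available). The penalty path is geometric from the data-derived
λ_max down to λ_max/100; with tens of events the deeper end of the path is
near-separable, slow, and never optimal under cross-validation, which is
why the path stops there.

The path is fit by iteratively reweighted least squares with cyclic
coordinate descent over an active set, warm-started along the path —
written in-package because general-purpose solvers take minutes per path
on near-separable rare-event problems of this shape; the solver is
verified against an independent implementation (saga) to ~1e-6 and
against unpenalized maximum likelihood at vanishing penalty.

λ is chosen by stratified K-fold (K = 10) cross-validated binomial
deviance. The default rule is **one standard error** rather than the
deviance minimum: with a strong planted signal and rare events the CV
deviance curve is nearly flat past the true support, so the minimizer
drifts deep into the path and retains dozens of noise CpGs, while the 1-SE
rule reliably returns the sparse panel the cascade is designed to produce.
Stratification is forced by the extreme class imbalance; when there are
fewer events than folds, the fold count is reduced (with a logged warning)
rather than producing event-free folds. Ridge (α = 0) is rejected
outright: selection by "non-zero coefficients" is undefined without an L1
component.

## Medication-confounding filter

Each of seven medication classes defines a three-level change factor
between visits (no-change reference, started, stopped). Per candidate CpG
and class, ΔCpG is regressed on the factor and the start/stop contrasts
are tested jointly — one Wald test per CpG × class, so 11 candidates and 7
varying classes give 77 tests. The Bonferroni family is all performed
tests; a class nobody started or stopped contributes none, and a missing
single level (e.g., nobody stopped statins) simply drops that contrast
from the joint test. Clinical confounders are not re-adjusted here: the
candidates already survived a covariate-adjusted EWAS. Bonferroni (not
FDR) is used to make removal conservative — the cost of wrongly discarding
a genuine locus exceeds the cost of keeping a marginal one.

The filter is marginal per CpG, so removing one flagged CpG never changes
another's flag. Its specificity depends on medication change not being
fully determined by the event: event-driven initiation elevated but a
per-class minority of changers leaves true event-responsive CpGs below the
Bonferroni threshold while medication-responsive CpGs (which shift in
*all* changers) are removed.

## Fingerprint and ROC evaluation

The final panel is re-weighted by unpenalized logistic regression on the
development cohorts. With few events and strong CpGs the MLE often
diverges (perfect separation); the fit then falls back to a
ridge-stabilized logistic fit, flagged in the model object — the ranking
of individuals, hence the AUC, remains well-defined. AUC is the
Mann–Whitney pair statistic (ties counted ½), with a one-sided p-value
against AUC = 0.5 from the tie-corrected normal approximation; AUC is
invariant to any strictly monotone transform of the scores. Development
cohorts are scored in-sample (each with its own refit); the validation
cohort is scored out-of-sample with the discovery-cohort weights.

## Multi-omic integration

The eQTM models use the follow-up-visit beta value as the predictor and
expression as the outcome, adjusted for age, sex, estimated cell
proportions, and technical factors. "1 Mb window" is read as a total span
centered on the CpG (±500 kb) by default, with a flag for ±1 Mb; the
per-CpG Bonferroni family is the number of distinct *genes* (not probes)
in the window, and gene positions are the representative (TSS-like)
coordinates supplied in the annotation. Transcriptome–metabolome edges
arrive as reported Spearman correlations with their sample sizes; p-values
come from the t transform on n−2 degrees of freedom, the BH-FDR is
computed over the whole supplied table (after upstream removal of
unknown-structure metabolites), edges are retained at suggestive
p < 0.001, and q < 0.05 marks the FDR tier. Methylation–expression edges
enter at nominal p < 0.05. Edge signs follow the statistic's sign; genes
named only in the correlation table are kept but flagged unanchored.
Export is SIF (layer+sign encoded in the interaction type; isolated nodes
in single-column form) and GraphML (lossless for all attributes).

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not array chemistry. Methylation is simulated on the logit scale — CpG
means drawn to sit away from the boundaries, persistent between-individual
offsets (SD 0.5), per-visit technical components with CpG loadings
(SD 0.15), Dirichlet cell proportions jittered between visits with
CpG-specific loadings, a per-individual follow-up drift (SD 0.1), and
visit-to-visit noise (SD 0.3) — then mapped through the logistic function,
which keeps beta values in [0, 1] while letting all effects act
additively. Incident events are Bernoulli at the configured rate; planted
CpGs receive a follow-up-only case shift expressed in units of the noise
SD. Medication usage runs per class with baseline prevalence 0.15,
control start rate 0.06 between visits, case start rate 0.18, and stop
rate 0.05; medication-confounded CpGs shift in every changer of their
assigned class regardless of case status. Missingness is completely at
random (the completeness filter only needs presence/absence structure).

Default sizes (1,000 individuals, 2,000 CpGs, 10 planted CpGs at 1.5
noise-SD, 5% event rate) are a desk-scale rendering of a population cohort
with rare incident events; the planted effect sizes are calibrated so that
recovery experiments are informative, not to match any particular cohort's
(unpublished) per-CpG effects. Sister cohorts of one study should share a
`truth_seed` so planted identities and directions agree across cohorts
while the data differ. What the generator does *not* emulate — probe-type
chemistry, SNP-under-probe artifacts, batch-by-position interactions,
confounding of clinical covariates with methylation — bounds what passing
tests show about real data: they validate the statistical machinery, not
robustness to array artifacts.

## Numerical choices and degenerate inputs

- Collinear technical covariates are dropped by pivoted-QR rank detection
  with original column order as the deterministic tie-break (logged).
- The coordinate-descent solver floors IRLS weights at 1e-5 and declares
  convergence at 1e-7 on standardized coefficients; KKT violations re-enter
  the active set before convergence is accepted.
- BH-FDR follows the step-up definition exactly (monotone in p-rank,
  clipped to 1); ties in EWAS sort order are broken by CpG id.
- Zero-variance outcomes, empty candidate panels, single-class evaluation
  cohorts, unknown export formats, and out-of-range beta values are
  rejected with specific errors; per-CpG scan failures are flagged
  records, never aborts.
- All randomness flows from explicit seeds; reruns with the same
  configuration are byte-identical outside report timestamps.

## Post-hoc power

The power helper uses the two-sample normal approximation for the
difference in mean ΔCpG between cases and controls,
power = Φ(|δ|/(σ·√(1/n₁+1/n₀)) − z₁₋α/₂) plus the opposite tail for
two-sided tests — the relevant regime being extreme imbalance (tens of
cases against ~1,000 controls), where power for small effects is low; this
is the quantitative motivation for the liberal screen plus
independent-cohort refinement design.

## Known limitations

- The GEE scan's slight anti-conservatism under rare events is documented
  rather than corrected; screening inclusiveness is a design feature.
- In-sample development AUCs with few events are near 1 by construction
  and should never be quoted as performance; only the validation AUC is.
- The eQTM window convention and gene coordinates make window gene counts
  annotation-dependent; both are recorded in output metadata.
- The generator's medication dynamics are a single-parameter compromise
  across seven real drug classes whose post-event initiation rates differ
  widely in reality.
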