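# Methods

## Study design being modelled

The pipeline reproduces the analysis graph of a longitudinal
case-control methylation study: patients with anxiety disorders measured
on an EPIC-like array at baseline (T0), after cognitive-behavioural
therapy (T1) and at 6-month follow-up (T2), against healthy controls
measured at baseline only. Treatment response is a ≥ 50% decrease in the
HAM-A anxiety score from baseline (boundary included); a zero baseline
makes the fractional change undefined and the patient is labelled
missing. Three association questions are asked of the same adjusted
data: does baseline methylation differ between patients and controls,
does baseline methylation predict response, and does methylation change
within patients along with response.

## Synthetic cohorts

All analyses run on simulated data with known ground truth. Per probe
and sample, the methylation beta value is a logistic-normal draw

    beta = expit( logit(mu) + bio + batch·loading + tech·loading_t + eps )

* `mu` — probe-level mean; bimodal across probes (Beta(2,18),
  Beta(18,2), Beta(5,5) mixture), as in real methylomes. At the 100
  cell-reference probes `mu` is instead the Dirichlet-weighted mixture
  of six leukocyte reference signatures (default mixture concentration
  follows typical blood: granulocytes ≈ 60%, CD4T ≈ 15%, …).
* `bio` — person-level biological variation shared across a person's
  timepoints. Methylomes are variance-heterogeneous, so the per-probe
  SD is drawn from a three-class mixture (60% tight / 30% intermediate /
  10% variable at 0.25×/0.6×/1× of `bio_sd`, default 0.6 on the natural
  logit scale; ≈ 0.04–0.15 beta SD at intermediate probes). Reference
  probes are damped to 0.1 — their defining property is that cell
  composition dominates their variance. Spiked probes are placed in the
  variance class where their planted effect is identifiable: a 0.10
  group difference at a hyper-variable probe would be unidentifiable at
  n = 100 in any study, while a response-predictive probe must vary
  between people to carry information.
* `batch` — a per-sample batch shift (default SD 0.3) with
  sign-symmetric loadings on all control probes and a random 20% of
  genomic probes, so control-probe PCA can genuinely recover and remove
  it. Sign-symmetric loadings keep per-class control means unimodal,
  which matters for the robust outlier rule below.
* `tech` — a per-array technical factor (default SD 0.2) loading on the
  control probes and 30% of genomic probes; this is the array-level
  variation (scan/chip effects) that control-probe adjustment exists to
  remove, and it is what makes the longitudinal adjustment identified
  rather than noise-fitting.
* `eps` — i.i.d. measurement noise (default SD 0.1).

Sex structure: chrY probes are detected only in males; ~25% of chrX
probes are intermediate (β ≈ 0.5) in females, per the typical share of
X-inactivation-driven CpGs, with males near 0 or 1. Controls' sexes are
frequency-matched to the patients' realized split, as in a matched
case-control design; unmatched draws make every chrX statistic co-vary
with the per-seed sex imbalance.

HAM-A trajectories: baseline ~ Normal(24.5, 5.3) truncated at the
inclusion floor of 19; the follow-up score is baseline × (1 −
improvement), where improvement comes from a responder/non-responder
mixture (means 0.68 / 0.25) with a margin around the 50% boundary so
integer rounding of scores cannot flip the planted status. Baseline
methylation at response-spiked probes shifts the responder log-odds
(slope in log-odds per unit M value). Dropout thins the follow-up
panels the way the motivating study's did: ~11%/19% of patients lack the
T1/T2 score and a further ~21%/26% lack the methylation sample, so the
case-control, prediction and longitudinal designs use progressively
smaller Ns.

Planted QC violators are generated to *exactly* the rule boundaries:
call rate 0.94 (fail), 0.95 (boundary, must be retained), 6% missing
signal, a reported-sex flip, and a +4-logit shift of one
bisulfite-conversion control class. A sample with no signal at 6% of
probes necessarily also fails the call-rate rule; the recorded truth
carries both reasons.

What the generator does **not** emulate: raw two-channel intensities and
detection p-values (the detection mask stands in), probe-type chemistry
bias, age/sex/smoking effects on methylation outside the spiked probes,
within-person cell-composition drift between draws, and genomic
autocorrelation between neighbouring CpGs. Passing tests therefore
demonstrate the statistical machinery under the stated structure, not
preprocessing of raw array data.

## Quality control

Per sample: call rate = fraction of genomic probes detected with a
non-missing beta (< 0.95 excludes); missing-signal fraction = fraction
of probes with no signal (≥ 5% excludes); sex predicted from chrY
detection fraction (≥ 0.5 → male), falling back on the share of
intermediate chrX betas, with an explicit "uncallable" status when no
sex-chromosome probes exist; per-class control-probe means flagged
beyond 4 robust SDs (median ± k·MAD·1.4826) of the cohort. A sample
excluded at baseline is excluded from all analyses. Probe filters: SNP
within 5 bp at MAF ≥ 0.01, cross-reactivity, control status; a probe
failing both content filters is tallied under the SNP rule (fixed
precedence). The number of surviving probes defines the Bonferroni
threshold α/n; the suggestive threshold is 1E−5 with a strict upper
bound (the significant boundary is inclusive, matching the usual
reporting convention "p ≤ threshold" vs "p < 1E−5").

## Adjustment for technical variance and cell composition

M values use the log2 logit with clipping offset 0.001 (round trip exact
to 1e−12 inside the clip range). Control-probe PCA is column-centered
but not variance-scaled, with a deterministic sign convention
(largest-magnitude loading positive). Cell composition is estimated per
sample by constrained projection onto the six reference signatures:
minimise ‖y − Rω‖² subject to ω ≥ 0 and Σω ≤ 1, solved exactly via
non-negative least squares on a penalty-augmented system (the slack
equation Σω + u = 1, u ≥ 0 is enforced with weight 1e6; constraint
violation ~1e−11). The sum is allowed to fall short of one because the
reference panel never explains a sample completely.

Cross-sectional designs residualize M values on an intercept, the first
ten control-probe PCs and five of the six cell fractions (granulocytes,
the largest compartment, is the reference category — the fractions sum
to ≈ 1, so including all six would be collinear with the intercept).
The technical fit is performed jointly over all arrays (timepoints
stacked), which is also how control-probe-PC pipelines process multi-
timepoint studies: the per-probe intercept then cancels exactly in
within-patient differences.

For the longitudinal design the covariate coefficients are re-fit on
**within-person** variation (person fixed effects, estimated in-sample):
within-patient differences are exquisitely precise because person-level
biology cancels, and coefficients estimated from between-person
variation would leak estimation error scaled by the much larger
cross-sectional variance into the paired test. Person effects themselves
cancel in the differences, so residuals keep each person's mean level.
A cross-fitted variant (two person folds) is available but not the
default: measured on null cohorts, in-sample fitting is centered while
cross-fitting doubles coefficient noise and inflates the paired test.

## Association designs

* **Case-control**: per-probe Welch two-sample t on adjusted M values
  (unequal group sizes and variances; Welch–Satterthwaite df), two-sided
  p. Complete-case per probe: residual entries whose underlying beta was
  undetected do not enter (chrY probes are thus compared among males).
  The effect column is the raw-beta group difference Δβ (patients minus
  controls) with effect_pct = 100·Δβ / control mean — the test runs on
  the adjusted scale while the effect is reported on the interpretable
  beta scale, as EWAS tables conventionally pair them. Significant hits
  are re-tested post hoc in a linear model with comorbid depression as a
  second binary predictor and classified as remaining significant /
  suggestive / dropped; a constant depression vector degrades gracefully
  to the pooled-variance t-test.
* **Response prediction (binary)**: per-probe maximum-likelihood
  logistic regression (IRLS) of responder status on baseline
  methylation; a positive coefficient means higher methylation predicts
  higher response odds. The pipeline passes the technically-residualized
  M value as the predictor together with the clinical covariates (age,
  sex, smoking, depression, baseline HAM-A). This two-step form is
  statistically equivalent to entering the ten control PCs and cell
  fractions directly into the logistic model but keeps the model at ~7
  parameters: with the full covariate stack the binomial model has ~22
  parameters for < 100 labelled patients and no standard test (Wald,
  LRT, score, Firth) holds its level — measured null rejections 0.078 /
  0.095 / 0.087 / 0.031 at α = 0.05 against a target of 0.05. Wald z is
  referenced to a t distribution on the residual df (the normal
  reference is anticonservative when covariates are many relative to n).
  Perfect separation and non-convergence are flagged, never imputed.
* **Response (continuous)**: OLS of the percentage HAM-A change on
  methylation plus the full covariate stack minus baseline HAM-A,
  vectorized across probes through the covariate-complement projection
  (identical to the joint fit by Frisch–Waugh; verified against
  statsmodels to 1e−10).
* **Longitudinal**: within-patient differences of (within-person-)
  adjusted M values tested against zero by a one-sample t, separately in
  responders and non-responders; strata under 3 patients are skipped
  with a warning; the effect column is the mean raw-beta change.
* **Smoking EWAS**: per-probe Huber M-estimation (tuning constant 1.345,
  95% Gaussian efficiency) of beta values on smoking status within the
  patient group, adjusted for sex, age, cell fractions and control PCs.
  Scale is estimated jointly with location by Huber's proposal 2: on
  skewed, bounded beta outcomes at n ≈ 100 with 17 covariates the
  simpler MAD scale understates SEs (measured null rejection
  0.061–0.063 vs 0.050; proposal 2 gives 0.056–0.058, and at n = 378
  the design is calibrated either way). p-values use a t reference on
  the residual df.
* **Overlap**: |A ∩ B| with an upper-tail hypergeometric p, evaluated
  stably in log space for genome-scale universes.

## Diagnostics

λ = median(observed χ²₁) / median(theoretical χ²₁), with the theoretical
median evaluated from the inverse CDF at runtime; computed only from
non-flagged rows and invariant to permutation. QQ tables use the
(rank − 0.5)/n expected grid. Result tables are sorted by (p, probe_id)
— deterministic tie-break — and serialized at 15 significant digits;
Manhattan files are BED-like with 0-based half-open intervals
(pos−1, pos).

## Numerical and degenerate-input policy

Zero-variance probes, perfect separation, non-convergence and
zero-variance outcomes produce flagged rows with no p-value; flagged
rows are excluded from tier classification and λ. Missing betas are
mean-imputed per probe before PCA/residualization (missingness is capped
by QC at 5%), while the Welch and logistic tests are complete-case per
probe. When the evaluated probe count is small enough that the
Bonferroni threshold exceeds 1E−5 the suggestive band is simply empty.
One global seed expands into per-stage seeds via
`SeedSequence([seed, stage])`; reruns are bit-identical including file
hashes.

## Problem sizes

Default test and demonstration cohorts use 600–5,000 probes and 70–300
samples; calibration checks run at 5,000 probes with 100 patients + 100
controls, and the inflation diagnostic was additionally verified at
20,000 probes. The generator supports full-array scale (780,145 kept
probes) but the statistical properties asserted here do not require it.

## Known limitations

The binary response design at < 100 labelled patients is at the edge of
logistic asymptotics even in two-step form; per-stratum longitudinal
rejection rates at ~30 pairs wobble ±0.015 across seeds because residual
technical structure correlates probes (true of real data as well — the
calibration guarantees hold at the design level, pooled over strata and
timepoints). Probe-level independence of p-values is assumed by the KS
and binomial checks; the generator's batch/tech factors violate it
mildly. Nearest-gene annotation is a manifest lookup, not a genomic
computation. No probe-type bias correction, no raw-intensity
normalisation, no enrichment analysis.
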