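# Methods

## Assay model

The package models a single-CpG MSRE-qPCR assay. A methylation-sensitive
enzyme (HaeIII, recognition site GG^CC) cleaves its site only when the
internal CpG is unmethylated; the methylated fraction *m* of a sample
therefore survives digestion. Amplifying digested and undigested
aliquots with the same primers gives

ΔCt = Ct(digested) − Ct(undigested),  % methylation = 100·e^(−0.7·ΔCt).

Assumptions inherited from the assay: ~100% amplification efficiency,
complete digestion of unmethylated template (checked by the 0%
standard), and a fixed −0.7 coefficient. The coefficient is treated as
an assay constant, not a fitted parameter; since 0.7 ≈ ln 2 the formula
is within 1 percent point of the 2^−ΔCt rule over ΔCt ∈ [0, 10], and the
e-form is canonical throughout.

Replicates (duplicates by default) are reduced by the arithmetic mean of
Ct before ΔCt — Ct is the linear scale of the measurement, and for n = 2
mean and median coincide. A negative ΔCt can only arise from noise at
m ≈ 1 and clamps to 100% with a warning. A digested reaction that never
amplifies is reported at the cycle cap and flagged `below_detection`;
its computed percentage is an upper bound (the forward model maps m = 0
to the cap exactly).

Hypomethylation % is defined as 100 − methylation %. This is the only
definition consistent with the paired group summaries the defaults are
calibrated to (92% hypomethylation alongside "lower methylation" in the
case group).

## Synthetic-data generator

The generator is the package's study design; its defaults are the study
conditions, not tuning dials.

**Group mode** (diagnostic surface). True methylation (% scale) per
group is a two-component mixture: a core truncated normal on the
correct side of the 55% cutoff — PCa on [0, 50], BPH on [60, 100] — plus
a narrow contamination component just across the cutoff on the wrong
side (PCa contaminants centered at 60%, BPH at 48%, sd 5%, truncated to
the wrong side), at an exactly-rounded fraction of 3/180 per group.
This shape is forced by the published operating characteristics: a
single normal per group cannot produce 177/180 sensitivity and
specificity *and* an AUC of 0.9992 simultaneously, whereas a
near-cutoff contaminant pair discordant with ~3 samples per group does
(3×3 contaminant–contaminant pairs plus a few noise-driven inversions
out of 180×180 leaves the AUC near 0.999).

Core component means are calibrated (see below) so the *measured* group
hypomethylation means land on 92% (PCa) and 15.5% (BPH): core
methylation means 7.094% and 85.692%, with the printed group sds
(11.76, 15.12) used as the underlying truncated-normal scales. The BPH
core mean sits ~0.6% above the naive mixture solution because clamping
measured methylation at 100% biases the measured mean down slightly;
calibration targets the measured quantity, which is what the assay
reports.

**Stratified mode** (association surface). PCa subjects are assigned to
tumor-stage strata {I: 7, II: 15, III: 33, IV: 70, V: 55} and ISUP-grade
strata {1: 15, 2: 20, 3: 46, 4: 20, 5: 79}, with per-stratum mean
hypomethylation {10, 35, 64.5, 96, 100}% and {5.66, 30, 55.2, 74, 100}%.
Stage and grade are coupled comonotonically (both label sequences filled
in severity order), the maximal-agreement coupling consistent with both
marginal count tables — the source gives no per-sample stage×grade
cross-table. A subject's expected hypomethylation blends its two
stratum means with weight 0.65 on stage, plus N(0, 2%) residual spread,
clipped to [0, 100] so advanced strata saturate at complete
hypomethylation. Weight and spread were calibrated against the
published per-sample regression coefficients (r = 0.9574 stage, 0.9348
grade); with duplicate-Ct measurement noise the achievable stage r
plateaus near 0.95, ~0.01 under the published value, which is the
closest the stated Ct noise allows.

The two modes exist because the two published summaries are mutually
inconsistent: the group-level mean hypomethylation (92%) is well above
the stage-weighted mean of the stratum table (~83%). Rather than
silently averaging, each analysis uses the mode that reproduces its own
printed surface. A related labeling discrepancy — the stratum table
lists five stage levels I–V while the figures speak of TS1–TS4 — is
resolved in favor of the five-level table.

**Covariates.** PSA is lognormal per group, parameterized by the
printed median and sd (PCa: median 12, sd 21.33 ng/mL; BPH: 4.4, 5.4);
median ≪ mean in the source indicates right skew, which the lognormal
captures while matching the median exactly. PSA is coupled to the
methylation *rank* within group through a Gaussian copula (normal
scores of ranks mixed with fresh noise), leaving the marginal exact.
The within-group copula correlation defaults to +0.2 — calibrated so
the *pooled* two-group Spearman between PSA and methylation lands on
−0.364: pooling alone (high-PSA/low-methylation cases vs.
low-PSA/high-methylation controls) over-shoots to ≈ −0.45, so a small
positive within-group correlation relaxes it to the target. Age and
prostate weight are truncated normals on [40, 100] years and [1, 200] g
matching the printed moments, uncoupled from methylation (the source
reports no association).

**qPCR forward model.** Undigested Ct ~ baseline + N(0, σ); digested
Ct ~ baseline − ln(m)/0.7 + N(0, σ), capped. Defaults: baseline 25
cycles, cap 40 cycles, σ = 0.15 cycles — typical bench values; the
source is silent on all three. With duplicates the ΔCt noise sd is
0.15 cycles, i.e. a ~10.5% coefficient of variation on measured
methylation, which is what limits the stratified-mode regression r and
produces the occasional near-cutoff misclassification beyond the
designed contaminants.

**Gel densitometry.** Expected D/C ratio = 0.14 + 0.82·m, clipped to
[0, 1.2], plus N(0, 0.105) noise; the affine coefficients follow the
two printed group means (D/C 0.21 at m ≈ 0.08, 0.83 at m ≈ 0.845) and
the noise sd is calibrated to the published qPCR–gel concordance
R² = 0.91. The undigested reference intensity is a lognormal around
1000 arbitrary units — only the ratio carries signal. Raw fluorescence
curves, melt curves and gel images are out of scope; Ct values and band
intensities are the measurement surface.

**Randomness.** A single config seed is expanded into fixed per-stage
substreams (cohort / qPCR / gel / standards), so adding a stage never
perturbs earlier stages' draws and every artifact is byte-identical
across reruns.

## Calibration

`calibrate_generator` moment-matches the generator to named pipeline
outputs (group hypomethylation means, D/C means, concordance R², pooled
PSA Spearman, stage/grade regression r). Each target is governed by one
monotone knob, so bounded bisection on a fixed-seed Monte-Carlo
evaluation (n = 10,000 subjects, or 30 × cohort-size replications for
cohort-level statistics) converges deterministically; the gel affine
pair is solved in closed form from the two group means. Targets already
within tolerance leave the config untouched; a target outside the
knob's achievable range raises a calibration failure naming it. The
shipped defaults are the output of this routine.

## Diagnostics

Classification is strict: positive (PCa-like) iff methylation % < 55;
boundary samples are negative. The ROC sweeps thresholds between every
pair of adjacent distinct scores (±∞ sentinels); rates are counted
positionally in the gaps, so they are exact even where a floating-point
midpoint would collide with a neighboring score. The trapezoidal AUC
then equals the concordance probability P(score_pos < score_neg) +
½·P(tie) exactly, which the test suite verifies against an exhaustive
pair-counting oracle and an independent library implementation. AUC
uncertainty uses the Hanley–McNeil closed form by default (the form
classic ROC software prints) with a stratified percentile bootstrap as
an alternative; at a degenerate AUC of 0 or 1 the closed form returns
SE 0 with a warning. A Youden-J utility is provided but the headline
operating point is always the fixed cutoff.

## Statistics

Mann-Whitney U (exact for small untied samples, tie-corrected normal
approximation otherwise), Kruskal-Wallis with tie correction, Spearman
and OLS with t-based slope CIs delegate to scipy. Dunn's post-hoc z
tests are implemented directly (pooled mean-rank differences with
tie-corrected variance; Bonferroni over all pairs by default, raw
p-values by flag) since no installed library provides them. All tests
are two-sided at α = 0.05. For the stage/grade association the pipeline
reports both the per-sample OLS correlation r and the Spearman ρ — the
source labels the same quantity both ways in different places — with the
regression r used for replication comparisons. The PSA correlation
pools both groups, matching the source's full 0–120 ng/mL range. The
fraction of samples at complete hypomethylation (below-detection calls)
is reported as a diagnostic but deliberately not calibrated: whether
the published misclassified samples overlap its complete-hypomethylation
count is not stated anywhere.

## Problem sizes and what the tests show

Replication experiments average the full pipeline over 100 fresh
360-sample cohorts (1,000 runs for the 4-point standard curve) — a few
seconds of compute; the in-suite versions use 25 seeds with
correspondingly wider bands. The null-calibration property checks
(type-I error of the rank tests in [0.03, 0.07]) use 10,000 simulations.

Passing tests show that the quantification, classification and
statistical machinery is correct *given the forward models*, and that
the generator reproduces the published summary surface. They do not
validate the biology: real blood-leukocyte methylation has
batch/extraction effects, digestion-efficiency variation, primer
competition and population structure that the generator deliberately
omits. The standard-curve bound illustrates the limits: at the default
0.15-cycle noise the *median* 4-point R² is ≈ 0.985 (meeting the
published > 0.98), but the seed-to-seed spread is wide (5th percentile
≈ 0.94) — a reminder that a 4-point calibration line is a coarse
instrument.

## Known limitations

* The −0.7 coefficient's empirical origin is unrecoverable; it is a
  constant, so any true deviation from 100% efficiency would bias all
  percentages multiplicatively.
* The 0% standard cannot enter the log-scale calibration fit; it serves
  only as the complete-digestion control.
* Stage and grade are modeled comonotonically; real stage×grade joint
  distributions are noisier, so the grade regression here inherits more
  structure from stage than a real cohort would.
* Contamination subjects are placed symmetric and narrow across the
  cutoff; the published error geometry (where the 3 + 3 misclassified
  samples actually lie) is unknown.
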