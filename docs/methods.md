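# Methods

## Overview

The pipeline derives a radiosensitivity miRNA signature in three stages:
an in vitro microarray screen (normalization → fold change → threshold
analysis → hit calling), a patient-cohort concordance screen, and a
correlation-based sample-size calculation. Because the original raw
fluorescence sheets and the clinical cohort are not shippable, both inputs
are emulated by synthetic generators with first-class ground truth; the
published 28-row screen table is packaged verbatim as the in vitro
reference.

## Array model and normalization

Each array condition (cell line × treatment) carries triplicate spots per
gene plus housekeeping positive controls and bacterial negative controls.
Replicates are summarized by the arithmetic mean and the sample SD (n−1
denominator; SD = 0 when only one spot survives) — triplicates are treated
as a sample of spot-level variation. Normalized expression is
`mean(gene) / mean over positive-control gene means`, computed per array
(no cross-array normalization), which makes all normalized values invariant
to any global intensity rescaling of that array.

**Detection.** A gene is *detected* when its mean exceeds
`max(detection_floor, negative-control background)`; background is the mean
of negative-control means. The floor defaults to 0 a.u.: the convention in
the screen tables is that non-detection appears only as `0 / 0` fold-change
rows, and this rule generates those zeros mechanically.

**Fold change.** `fc = value_IR / value_mock` for genes detected on both
sides, else 0 with SD 0. The per-row SD is first-order error propagation,
`sd_fc ≈ fc · sqrt(cv_IR² + cv_mock²)` with `cv` the replicate CV of the raw
intensities. Whether published per-row SDs are propagated or replicate-level
fold-change SDs is not derivable from the table itself; propagation is the
default and the only implemented variant.

Both channels (F635/F532) are stored; analysis uses one channel, default
F635.

## Threshold analysis

The fold-change test partitions genes into successes (fc > 0) and failures
(fc = 0). The threshold θ on fluorescence X is bracketed by
`lower = max{X | F}` and `upper = min{X | S}`; `separated = lower < upper`.
Only the interval is identified by the data, so the interval is always
reported in full; for classification the midpoint is used as the operative
θ (symmetric, deterministic), with the boundary convention `X ≤ θ → F`.
Single-class data leave θ undefined and raise an error (the pipeline logs
and skips such conditions). No logistic model is fitted: with perfect
separation the MLE does not exist, which is precisely why the interval
estimate is used.

## Hit calling

"±2 SD" is formalized on the linear fold-change scale: up when
`fc − 1 ≥ k·sd` and fc > 1; down when `1 − fc ≥ k·sd` and fc < 1; k = 2 by
default. Ties count as significant. `fc = 0 ∧ sd = 0` is *undetected* and
excluded from up/down counts — zeros denote absent signal, not measured
repression. Two documented edge cases: `fc = 0` with `sd > 0` is treated as
measured repression (down), and `sd = 0` with `fc ∉ {0, 1}` is significant
(any nonzero effect exceeds a zero-width noise band).

Applied to the packaged screen table this rule yields, for the
ATM-deficient line, 9 up / 5 down / 7 undetected / 7 unchanged — these
deterministic counts, not any externally quoted tally, are the package's
reference (frozen byte-for-byte in `tests/data/hits_atm_null_regression.tsv`).
An alternative reading — a population SD across all fold changes — was
rejected: it calls far fewer hits on the same table.

## Cohort concordance screen

Per miRNA: arm means; ratios `(mean_arm + pseudo)/(mean_untreated + pseudo)`
with pseudocount 1.0 (continuity: as pseudo → 0 on positive data the ratios
converge to the plain means ratio); and a two-sided Welch t-test of
responders vs progressors on log2(x + pseudo). Welch rather than pooled
Student is the default for robustness on skewed expression; a pooled option
exists. The responder-vs-progressor contrast is the tested hypothesis; both
ratios vs untreated are reported.

Direction is the sign of the log2 ratio outside a dead band ε = 0.25
(≈1.19-fold), which suppresses flat-direction noise. Concordance requires
(i) opposite non-flat directions in the two irradiated arms, (ii) responder
direction equal to the in vitro reference direction, (iii) p ≤ α = 0.05,
raw p-values (no multiple-testing correction by default; BH/Bonferroni can
be applied downstream on the reported p column). The in vitro reference is
an explicit parameter — either a genotype (directions derived from the
screen table by the hit rule) or an explicit direction table; the packaged
table encodes up: miR-016, miR-029b, miR-150, miR-1254 and down: let-7e.
The packaged direction table is the default because the screen's two
genotypes disagree in direction for some signature members, so neither
genotype column alone reproduces the intended pattern.

The ATM comparison is a two-sided Welch t-test on RPPA-scale protein
levels, responders vs progressors, with the sign of the mean difference
reported; nothing is hard-coded about its direction.

## Sample-size formula

`n = z_sum_sq / C(r)² + 3` with `C(r) = ½·ln[(1+r)/(1−r)]` (Fisher z) and
`z_sum_sq = 8.52` by default (≈ 2.92², a (z_α+z_β)² constant; the +3 is the
standard correction for the z-transform's variance `1/(n−3)`). The source
prints the formula in a typographically garbled form,
`n=(8.52{12(ln[1+R(y,x)])−ln[1−R(y,x)])}2)+3`; the Fisher-z reading is the
only one consistent with the constant and the +3 term. Default rounding is
`ceil` (conservative); `nearest` gives n = 10 at r = 0.80, consistent with
the 10-patient arms — a consistency note, not a claim about how the arm
size was chosen. n is strictly decreasing in r with infimum 3.

## Synthetic data

**Array generator.** True gene abundance is lognormal
(`baseline_log_mean = 6.5`, `baseline_log_sd = 1.0`, natural-log a.u.),
shared across cell lines; irradiation multiplies it by a planted per-
(genotype, miRNA) effect (0 = dropout); spots get multiplicative lognormal
noise with mean 1 and CV `spot_cv` (default 0.05, a tight-replicate
regime); positive controls sit at 2000 a.u., negatives at 30 a.u. With zero
spot noise the pipeline recovers planted effects exactly because the
positive-control ratio cancels.

**Cohort generator.** Per-miRNA baselines are 2^N(8, 1.5) on a
normalized-count-like scale; patient expression is baseline × group
multiplier × lognormal noise with CV 0.3 (defaults chosen as a realistic
biological-variability regime at the 10-patients-per-arm design); ATM is
Gaussian (RPPA scores are normalized and may be negative) with baseline 0,
SD 0.2, and a +0.5 shift in progressors. Expression noise is lognormal
because expression is multiplicative and strictly positive. Truth tables
are returned alongside the data so tests never re-derive ground truth.

What the generators do **not** emulate: batch effects, probe-specific
biases, count discreteness of miRNA-Seq, censoring/missingness of clinical
follow-up, and correlation between miRNAs. Recovery results on synthetic
cohorts therefore demonstrate that the screening logic is correct and
adequately powered under the stated noise model — not that real TCGA data
would yield the same signature.

## Numerical choices and degenerate inputs

- Welch p-value NaN (zero variance in both groups with equal means) is
  reported as 1.0.
- Undefined ratios (untreated mean + pseudo = 0) are flagged, not dropped.
- Thresholds are reported to full input precision; no rounding anywhere in
  the numeric path.
- Outputs are staged in a temp directory and renamed in, so failed runs
  leave no partial files.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from the config; identical inputs + config + seed give
  byte-identical output trees.

## Problem sizes

Recovery and power checks use 100 simulated cohorts (30 patients × 28
miRNAs each) and 1000 random threshold instances; the whole suite runs in
well under a minute. These sizes give binomial standard errors of ~2% on
the reported recovery rates, adequate for the ≥95% claims tested.

## Known limitations

- The screen stage assumes exactly one ATM-proficient and one ATM-deficient
  cell line per experiment.
- The hit rule's literal-rule edge cases (`fc = 0, sd > 0`) follow the
  stated inequality rather than any biological judgment.
- No survival analysis, qRT-PCR normalization, pathway analysis, or TCGA
  download tooling; heatmap rendering is left to external tools (the
  relative-expression matrix is emitted as TSV).
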