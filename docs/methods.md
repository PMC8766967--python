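# Methods

## The mixture model

A buffy coat is, physically, the mixture of the leukocyte fractions it was
separated into. For each subject we therefore fit, across all post-QC probes,

    beta_buffy = w_P * beta_PMN + w_L * beta_lymph + error

by ordinary least squares **without intercept** and **without** sum-to-one or
nonnegativity constraints. Both omissions are deliberate: an intercept would
absorb part of the mixture signal and make the coefficient sum
uninterpretable, and leaving the coefficients unconstrained turns the fitted
sum into a diagnostic — it lands near 1 exactly when the mixture premise
holds. Coefficients outside [0, 1] are reported unclipped with a warning
(an interpretability guard, not a constraint). The fit refuses collinear
fraction profiles (condition number above 1e8) and requires at least two
complete-case probes; within a cohort, per-subject failures are recorded and
do not abort the remaining subjects.

Two properties of the estimate are worth knowing. First, measurement noise in
the *regressors* (the fraction profiles) attenuates both coefficients
slightly; at noise sd 0.02 on ~20,000 bimodal probes this costs roughly
0.001 of the coefficient sum. Second, probes that violate the mixture premise
(see below) drag the fit further: with 1% of probes discordant at full
effect, fitted sums drop to ≈ 0.98 — the same range observed when the model
is applied to real trio cohorts, which is why the synthetic generator
reproduces that range through contamination rather than building a deficit
into the true weights.

## Residuals and discordance

Applying each subject's fitted weights to every probe gives the residual
matrix r(g, i) = beta_buffy − (w_P·beta_PMN + w_L·beta_lymph), bounded in
[−1.01, 1] for weights in [0, 1] summing to at most 1.01. Residuals are
pooled over all probe×subject trios and standardized by the pooled mean and
(plain, ddof = 1) standard deviation; a median/MAD option exists because
gross outliers inflate the plain sigma, but it is not the default — the
pooled plain moments are what make the flagged fraction interpretable
against the Bonferroni bound.

A trio is flagged when |z| exceeds the two-sided standard-normal critical
value at family level alpha = 0.05 divided by the **number of probes**
(per-probe standardization from ~29 subjects would be far too unstable, and
per-trio Bonferroni would give z ≈ 5.87 instead of the 5.29 that 412,481
probes produce; the denominator is configurable). A *discordant probe* has at
least one flagged trio and is counted once however many trios flag it;
trio-level and probe-level counts are kept strictly separate throughout.
*Peak probes* are those with any residual below −0.6 — the extreme-negative
cluster produced when both isolated fractions are (near-)fully methylated at
a probe whose buffy-coat value is low, i.e. methylation gained during or
after separation. A −0.8 threshold is reachable by argument; peak sets nest
monotonically in the threshold.

## Moderated paired testing

Each pairwise comparison (BP = buffy−PMN, BL = buffy−lymphocyte,
PL = PMN−lymphocyte) is a within-subject paired design: the samples are
matched trios from the same subject, so subject-level pairing is the correct
error structure. Per probe we take the mean and unbiased variance of the
subject-wise differences (complete cases; probes with fewer than two pairs
are marked untestable and counted), shrink the variance toward an
empirical-Bayes prior, and test with

    s2_post = (d0*s0^2 + d*s^2) / (d0 + d),   t = mean / sqrt(s2_post/n),
    df = d0 + d.

The prior (d0, s0²) comes from the method of moments on log-variances: with
z = log s², E[z] = log s0² + ψ(d/2) − log(d/2) − ψ(d0/2) + log(d0/2) and
Var[z] = ψ′(d/2) + ψ′(d0/2); ψ′(d0/2) = Var̂(z) − ψ′(d/2) is solved by a
Newton iteration on the trigamma inverse. When the observed log-variance
dispersion does not exceed ψ′(d/2), d0 = ∞ and every posterior variance is
s0² (tested in the normal limit, df 10⁶). Note the mean equation's log-scale
bias correction: for *constant* variances the fitted s0² is the common value
times exp(log(d/2) − ψ(d/2)) ≈ 1 + 1/d, not the common value itself — this
matches the Bioconductor implementation (`limma::squeezeVar`), against which
the estimator is cross-checked in the test suite. Zero sample variances
receive a 1e-8 offset before logging (discrete beta ties occur in synthetic
data); a zero posterior variance maps t to ±inf and p to 0 with a warning.

P-values are Benjamini-Hochberg adjusted (the "p < 0.05" vocabulary of array
count tables refers to the adjusted value, and output headers say so).
Significance is thresholded on q < 0.05, optionally combined with the
effect filter |Δβ| > 0.1. Tests run on beta values, not M-values, because
the downstream residual analysis and all thresholds are on the beta scale.
The whole analysis is repeated after discordant-probe removal and reported
as side-by-side count blocks with per-cell relative changes.

## Probe characterization

Probe groups are deduplicated before counting. Uniqueness is reported as the
percentage of uniquely mapping 50-mers to four significant digits; GC content
as group means and their difference in percentage points with a Welch test;
region composition as one 2×2 Pearson chi-squared (1 df, no continuity
correction by default) per region class, group vs reference. The default
reference is the pool of **all** probes — the group is a subset of its own
reference, matching how a discordant-vs-all comparison is conventionally
reported; a disjoint-reference mode (group vs complement) is available and
statistically cleaner. Expected cells below 5 attach a warning but do not
suppress the test.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
defaults fixed at the study conditions the package is designed around:

| parameter | default | meaning |
|---|---|---|
| n_subjects | 29 | trio count |
| n_probes | 20,000 | array scale (reduced from ~450k for practical runtimes) |
| frac_dmp_pl | 0.30 | fraction of probes truly PMN≠lymphocyte |
| delta_range | (0.1, 0.5) | magnitude of true cell-type differences |
| lymph_weight_range | (0.20, 0.40) | w_L ~ Uniform; w_P = 1 − w_L |
| noise_sd | 0.02 | additive truncated-Gaussian noise on the beta scale |
| n_discordant_probes | 200 | injected methylation-gain probes (1% of probes) |
| discordance_effect | 0.9 | beta level imposed on isolated fractions |
| region_weights | open_sea 3, shelf 2, shore 1, island 0.5 | injection sampling bias |
| region_proportions | island .31, shore .23, shelf .10, open_sea .36 | annotation composition |

Baseline probe means come from a three-component mixture — 45% low
(Beta(1,10)), 45% high (Beta(10,1)), 10% intermediate (Uniform(0.2,0.8)) —
identical for both cell types, which reproduces the strongly bimodal
beta-density of methylation arrays (well over 60% of mass in
[0,0.2] ∪ [0.8,1]). True PL differences shift the lymphocyte mean by ± a
draw from `delta_range`; the sign is drawn uniformly among directions that
keep the mean inside [0,1], so the realized differentially-methylated
fraction equals `frac_dmp_pl` rather than collapsing by clipping. Probe GC
is drawn per region (islands highest), and ~0.05% of probes are marked
multi-mapped. Noise is additive Gaussian clipped to [0,1] (beta scale, not
logit scale — the analysis itself operates on betas). Weights sum to exactly
1 by default; an `other_cell_fraction` adds a third unmodeled component for
robustness experiments.

Discordance injection targets *unmethylated* probes (baseline mean < 0.3),
sampled with probability proportional to their region weight times an
inverse-GC-rank factor computed **within** each region — GC correlates with
region class, so ranking globally would double-count the region preference
and equal region weights would no longer yield annotation-proportional
injection. At each injected probe the measured PMN and lymphocyte betas of
the affected subjects (all, by default) are raised to `discordance_effect`
plus noise while the buffy coat keeps its pre-separation mixture value,
producing residuals near −0.8. Injection is methylation-gain only by
default, mirroring the one-sided negative residual peak seen in practice; a
`symmetric` mode (half the probes raise the buffy coat instead) exists for
null calibration. One seeded generator stream drives every draw, so a cohort
is reproducible as a unit and bit-identical under a repeated seed.

**What passing tests on this generator do not show:** the simulation has no
chromosomal spatial autocorrelation, no SNP-under-probe artifacts, no
batch/chip effects, and a single homogeneous noise level; real-data
discordance is unlikely to be as cleanly separable as an injected 0.9-level
switch, so recall/false-flag rates measured here are upper bounds on
real-data performance, not estimates of it.

## Design notes and numerical choices

- **QC thresholds.** The call-rate rule drops a probe (then, on the reduced
  matrix, a sample) when more than 5% of its calls are unreliable; the
  per-call detection p-value cutoff defaults to 0.01 (platform convention)
  and is exposed as `p_threshold` because conventions differ on whether the
  per-call rule is p > 0.01 or p > 0.05. Probes are filtered before samples
  because array QC is probe-dominated. Without detection p-values QC is
  explicitly *skipped*, never silently invented.
- **Missing data.** Missing betas are NA/empty on disk and NaN in memory;
  trios with a missing value are excluded from that subject's fit, residual
  and paired difference (complete-case per subject).
- **Ordering claim for DMP counts.** On synthetic defaults the expected
  ordering BP < BL ≤ PL holds in the effect-filtered (q < 0.05 and
  |Δβ| > 0.1) count cells: the measured BP effect at a true-difference probe
  is w̄_L·δ ≈ 0.3δ, BL is ≈ 0.7δ, PL is δ, so the Δβ > 0.1 filter separates
  the comparisons cleanly. The q-only cells saturate instead — with a 0.1
  floor on true effects and 29 paired subjects, essentially every true
  difference is detectable in all three comparisons — so q-only counts are
  near-equal on synthetic data and do not carry the ordering.
- **Alignment.** Any operation combining matrix, design and annotation first
  intersects probe/sample universes, order-stably (matrix order wins), with
  dropped counts logged.
- **Text formats.** Betas are written at 6 decimals (the platform's beta
  resolution is coarser); probes are rows and samples columns, and a
  transposed-looking table is rejected rather than auto-fixed. All readers
  accept gzip. Coordinates are 1-based; there is no strand handling
  (probe-level analysis) and no IDAT parsing or normalization — the pipeline
  starts from normalized betas.
- **Reporting.** Every percentage goes through one rounding path (2 decimal
  places; uniqueness at 4 significant digits), and the pipeline report
  reconciles probe counts exactly: input = failed-QC + discordant +
  concordant. Residual histograms use a fixed 0.001 bin width. Reports
  contain no timestamps or hardware-dependent values; a repeated (config,
  seed) reproduces `report.json` byte for byte.

## Problem sizes

Default simulated cohorts use 20,000 probes — large enough that the pooled
residual standardization, the empirical-Bayes prior and the enrichment tests
operate in their intended regime, while a full pipeline run completes in a
few seconds. The test suite's multi-seed properties (mixture recovery,
discordance sensitivity/specificity, DMP recall) average over up to 50
seeded cohorts at that scale.

## Known limitations

- The model cannot attribute discordance to a specific fraction; a flagged
  trio says only that at least one fraction's measured state is inconsistent
  with the pre-separation mixture.
- With two highly correlated fraction profiles the mixture fit is
  ill-conditioned in the difference direction; noise in the regressors
  biases fitted weights slightly toward equality (errors-in-variables), so
  coefficient sums below 1 should not be over-interpreted as a missing cell
  population without the robustness check (`other_cell_fraction`).
- Region-level (DMR) statistics, gene-set enrichment and reference-based
  cell-composition estimation are out of scope.
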