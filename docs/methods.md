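# Methods

This note documents the statistical models implemented in `methmark`,
the defaults and why they were chosen, what the synthetic cohorts do and
do not emulate, and the numerical conventions.

## Paired differential methylation

Per probe, tumor−normal β differences over complete pairs feed a
two-sided Wilcoxon signed-rank test. For n ≤ 25 informative pairs the
null distribution of W⁺ is computed exactly by dynamic programming over
doubled midranks (polynomial multiplication of (1 + z^{2r})/2 factors),
so tied absolute differences are handled without approximation; the
two-sided p is 2·min{P(W ≤ w), P(W ≥ w)} capped at 1. Beyond 25 pairs a
normal approximation with continuity correction and the midrank variance
Σr²/4 is used. Zero differences are discarded by default (classic
Wilcoxon); the Pratt variant (rank with zeros, then drop them) is
available via `zero_method="pratt"`. All-zero differences return p = 1
with a degeneracy flag rather than an error, so genome-scale scans do
not abort on flat probes. Probes need at least 3 complete pairs; others
are skipped and counted.

**The FDR gate at small n.** A DMP is called when |Δβ| > 0.2 and the
gate statistic is below α = 0.05. With six pairs the exact two-sided
signed-rank p cannot fall below 2/2⁶ = 0.03125, so a genome-wide BH-FDR
gate at 0.05 returns zero calls at that cohort size. The default gate is
therefore the raw p (with the |Δβ| > 0.2 effect-size gate doing most of
the work), and the FDR gate remains selectable for larger cohorts. BH
adjustment itself delegates to `statsmodels` (step-up, monotone,
order-preserving).

Probe QC removes a probe if its detection p exceeds 0.05 in *any*
sample (removal, not masking, is the strictest reading), if it maps to
chrX/Y, or if its SNP or multi-mapping flag is set; removals are tallied
per rule. Context summaries count each called DMP once per distinct
region class it carries (gene-less probes count as Intergenic); the
promoter fraction is the fraction of DMPs with at least one promoter
assignment. Sample clustering is average linkage on 1 − Pearson
correlation with lexicographic sample order fixing tie-breaks.

## Moderated paired differential expression

Expression intensities are quantile-normalized (mean empirical
distribution), moved to log2(x + 1), and collapsed to one feature per
gene (highest mean intensity). The paired moderated t shrinks each
gene's variance of paired differences toward a prior:

    s̃² = (d₀·s₀² + (n−1)·s²) / (d₀ + n − 1),  t̃ = mean(d)/(s̃/√n),
    df = n − 1 + d₀.

Hyperparameters come from moment matching on z = log s² under the
scaled-F model: Var(z) = ψ′((n−1)/2) + ψ′(d₀/2) gives d₀ by Newton
inversion of the trigamma function on the excess variance of z, and s₀²
follows from the mean of z after removing the chi-square bias terms.
When the observed spread of z does not exceed its chi-square sampling
component, d₀ = ∞ and s₀² is set to the geometric mean of the observed
variances, so homogeneous-variance data reproduce the ordinary paired t
statistic exactly; d₀ = 0 recovers the plain paired t (verified against
`scipy.stats.ttest_rel`). Moment matching was preferred over marginal
maximum likelihood because it is deterministic, closed-form apart from
one scalar Newton solve, and adequate at the scale this package targets.
DE calls require |log2FC| ≥ log2(2) — the fold-change boundary is
inclusive — and BH-FDR < 0.05.

## Integration and marker selection

A gene's methylation proxy is the unweighted mean of the per-probe group
means over its *called* promoter DMPs (TSS1500, TSS200, 5′UTR, 1st
exon). A probe annotated to several genes contributes to each under that
gene's own region class; duplicate probe-gene assignments count once.
Direction consistency among a gene's promoter DMPs is not required: the
sign of the aggregated Δβ defines the gene's methylation direction and
mixed-direction genes are flagged. A candidate is *inverse* iff
(hyper ∧ expression down) ∨ (hypo ∧ expression up); genes without a DE
call are not inverse. The panel keeps inverse candidates with strictly
more than 2 differential promoter CpGs ("more than 2" read as
exclusive — the packaged candidate table's minimum listed count is 3),
sorted by probe count descending then gene name. The packaged 36-gene
fixture carries the printed probe counts and group means; directions are
re-derived at load time from the sign of Δβ.

## MS-HRM quantification and validation statistics

Simulated melt curves are two-component mixtures
F(T) = m·S(T; Tm_meth) + (1−m)·S(T; Tm_unmeth) + ε with S a decreasing
logistic, Tm_unmeth = 78 °C, Tm_meth = 82 °C, slope 1.5 /°C on a
70–90 °C grid at 0.1 °C — typical HRM ranges; these constants shape only
the simulator, not the quantifier's contract. Curves are normalized
affinely so the first point is 1 and the last 0. The quantifier searches
m on a 0.1 % grid, predicting each candidate by linear interpolation *in
m* between the bracketing standards (0, 1, 5, 10, 25, 50, 75, 85, 100 %)
and minimizing the summed squared deviation; ties resolve to the lower
m, and non-monotone normalized curves beyond a 0.05 tolerance warn.
Interval scores use right-closed bins [0,10], (10,25], (25,50], (50,75],
(75,85], (85,100]: the printed integer interval labels leave non-integer
gaps such as (10, 11) undefined, and right-closure preserves every
printed integer endpoint.

Group comparison of interval scores reuses the exact signed-rank test
(n ≥ 5 pairs). κ = (p_o − p_e)/(1 − p_e) with p_e from marginal
products; two constant, equal raters get κ = 1. qPCR fold change is
2^−ΔΔCt against a reference gene. Correlation defaults to Pearson (t
p-value) with Spearman available (exact permutation p for n ≤ 8). ROC
curves sweep midpoint thresholds between adjacent distinct scores;
trapezoid AUC equals the Mann–Whitney concordance with ties counted ½,
and the reported cutoff maximizes Youden's J (ties → lower threshold).
Hypermethylated markers score with `higher_is_case`, hypomethylated ones
with `lower_is_case`. Clinicopathological association uses Welch's t by
default, Student's only when a two-sided F-test of variance equality
gives p > 0.05, and Fisher's exact test for 2×2 counts.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not raw array
physics. Normal-tissue β is Beta(μφ, (1−μ)φ) with precision φ = 60
(SD ≈ 0.064 at μ = 0.5, 450K-like heteroscedasticity with variance
maximal mid-range) and context-dependent baselines: islands 0.05–0.25,
shores 0.15–0.45, shelves 0.40–0.70, open sea 0.60–0.90. Defaults:
6 pairs (screening-cohort size), 20,000 probes, 1,500 genes, 5% of
probes differential with 43.4% hypermethylated, planted shift
N(0.30, 0.05) clipped into [0, 1], hyper DMPs biased 51% promoter /
94.9% CGI-related and hypo DMPs 22.2% promoter / 32.7% CGI-related,
5% driver genes, expression effect |log2FC| = 2 with noise SD 0.5 on the
log2 scale plus a subject intercept (SD 0.3), and 0.1% of detection
p-values failed. Planted promoter hypomethylation re-draws its baseline
from 0.55–0.90 (methylated-in-normal promoters, as real hypomethylated
markers show) so the shift has room in [0, 1]; hyper DMPs start from
0.08–0.45. Driver genes are drawn among genes with ≥ 4 promoter probes
and *all* their promoter probes are planted in one direction —
contiguous promoter methylation — which also keeps a driver's probe
count above the selection gate when the detection filter removes an
occasional probe. Each output object (annotation, planting, β,
detection, expression) uses its own random stream derived from the
master seed by a fixed label, so changing the probe count does not
perturb the expression draws.

Not emulated: chip/batch effects, cell-type composition, probe-type
(Infinium I/II) differences, spatial autocorrelation along the genome,
copy-number contamination of β, and expression heteroscedasticity beyond
a common noise SD. Passing recovery tests therefore demonstrates that
the pipeline's inference chain is correct under its own model, not that
it is robust to those real-data artifacts.

Problem sizes in the test and acceptance runs (20,000 probes × 20 pairs
for recovery and null calibration, 3,000 × 8 for shared unit fixtures)
were chosen as the smallest scales at which the binomial/multinomial
tolerances of the checks are meaningful.

## Numerical conventions and edge cases

- β and detection p outside [0, 1] are parse errors naming probe and
  sample; missing β propagates and paired tests drop incomplete pairs.
- Results tables are written deterministically: rows sorted by key,
  floats at six significant digits, `NA` for missing.
- The null-calibration check uses 20 pairs because the exact signed-rank
  test is discrete: its attained size at nominal 0.05 is 0.03125 at
  n = 6 but 0.0484 at n = 20, which is what a calibration claim can
  meaningfully test.
- A fully degenerate variance vector (all genes s² = 0) makes the prior
  fit impossible and is an error; single zero-variance genes shrink
  toward s₀².
- `trapezoid AUC` integrates vertices in descending-threshold order so
  tied false-positive rates stay in curve order.

## Known limitations

- The raw-p default gate trades type-I control for usable power at very
  small n; users with ≥ 15–20 pairs should switch to `gate="fdr"`.
- The promoter proxy weights every differential CpG equally; no CpG is
  privileged by position relative to the TSS.
- MS-HRM quantification assumes the sample's chemistry matches the
  standards (same amplicon, same normalization window); heteroduplex
  effects that make real mixtures melt non-linearly in m are not
  modelled.
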