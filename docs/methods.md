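# Methods

## Coordinate and spike-in conventions

Genomic coordinates are 0-based half-open throughout; BED and bedGraph are
read and written natively and any 1-based table is converted at the
boundary. Gene-relative coordinates follow the biology convention: 1-based
with no position 0, TSS = +1, strand-oriented (mirror-mapped on the minus
strand), so the window −50..+100 spans 150 contiguous bases. Interval
overlap everywhere means ≥ 1 bp in half-open arithmetic; book-ended
regions `[a,b)`, `[b,c)` never overlap, never merge, and never blacklist
each other.

Spike-in reads are recognised by a chromosome-name prefix (default
`spike_`) rather than by a second alignment pass; a read on a
spike-prefixed chromosome counts toward the sample's spike total and
toward nothing else. This preserves the accounting of a dual-genome
alignment (reads mapping only to the foreign genome) without putting
alignment in scope.

One transcript per gene is selected before any quantification: longest
CDS, ties broken by longest transcript, then lexicographically smallest
transcript id (the tie-breaks are this package's choice; any deterministic
rule would do, but it must be fixed). Genes shorter than `min_length`
(default 700 bp) are flagged and excluded from pausing-index and
differential analyses with a logged count, because the +500..TES−100 body
window of a shorter gene is empty; they remain in the annotation.

## Quantification

Window counts sum 3′-end reads on the gene's strand over a relative
window. The per-region "TPM" is a density — reads per kilobase of window
per million primary-genome mapped reads — not the transcript-sum TPM,
which has no per-window analogue; the density form gives the pausing
index PI = promoter density / body density its depth- and
length-invariance. The expressed-gene filter applies a +1 pseudocount
inside the log (mean over samples of log₂(TPM+1) > 3) so all-zero genes
stay finite and excluded; the threshold is strict.

The PI body window defaults to +500..TES−100; a `to_tes` variant
(+500..TES) is available by flag since both conventions circulate. Whether
PI should be restricted to expressed genes is left to the caller; nothing
in the computation requires it.

## Differential testing

Counts are divided by spike-in size factors `s_j = spike_j /
geomean(spike)` and the normalized counts `y_ij` are modelled per feature
as negative-binomial with group means `m_A, m_B` and variance `m + αm²`.
Fitting on normalized counts with equal weights — rather than raw counts
with log-offsets — is a deliberate choice: for the saturated two-group
design the MLE of each group mean is then exactly the arithmetic mean of
its normalized counts for any fixed dispersion, so the iterative fit has a
closed form, and the log2 fold change becomes *exactly* invariant to
rescaling any one sample's counts together with its spike total (the
offset parameterization violates this invariance because renormalized
factors re-weight the group means). The cost is treating scaled counts as
NB, a quasi-likelihood approximation that is standard and accurate at the
spike-in precisions involved (spike totals of 10³–10⁵ reads make the size
factors nearly noiseless).

Dispersion: with two replicates per condition there are two residual
degrees of freedom per feature, which is not enough to estimate a
per-feature dispersion that can safely enter a test statistic — the
log of the moment estimate is severely median-biased downward, and any
blend that keeps a per-feature component (we measured a 50/50 log-space
blend with a hard floor) inflates the null fraction of p < 0.05 from
~0.05 to ~0.11 and produces dozens of false discoveries per 2000 null
genes. The package therefore pools: per-feature method-of-moments values
`(within-condition residual variance − mean)/mean²` are fitted with a
mean–dispersion trend `α(μ) = a/μ + b`, and the trend value at a feature's
mean is its test dispersion. The trend fit is iteratively reweighted
(three passes, weights = inverse sampling s.d. of the moment estimate,
`μ/(1+αμ)`): an unweighted fit is dominated by the huge-variance low-mean
features and its intercept wanders enough between datasets to distort
far-tail p-values. The fitted values are clamped at 1e-8. The limitation
to note is that genuine feature-to-feature dispersion spread is not
captured — with two replicates there is no information with which to
capture it.

The Wald statistic is `log(m̂_B/m̂_A)` over its delta-method standard
error `√(Σ_g (1+αm̂_g)/(n_g m̂_g))`, two-sided against a standard normal;
this matches the closed-form Poisson GLM exactly in the α→0 limit. A
group mean of zero (with signal elsewhere) is floored at half a normalized
count, which blows up the matching SE term and keeps such features
conservative rather than infinite. All-zero features are reported
untested (NaN) and excluded from the number of BH tests.
Benjamini–Hochberg adjustment is delegated to statsmodels. Classes follow
the study conventions: up/down at FDR < 0.1 by fold-change sign, unchanged
at FDR > 0.5, indeterminate between. No independent filtering and no
fold-change shrinkage are applied, keeping the statistic auditable.

Residual calibration: under the package's own null simulations (2000
genes, 2 vs 2, dispersion 0.05, 20 seeds) the pooled fraction of Wald
p < 0.05 is 0.050 and ~0.15 of runs produce any FDR < 0.1 call — the same
runs flagged by a Wald test given the *true* dispersion, i.e. the residual
far-tail excess is intrinsic to a four-sample normal-reference Wald, not
to the dispersion estimate; a likelihood-ratio reference was checked and
makes the identical calls here.

## Metagene profiles and window tests

Per gene and relative offset, the spike-scaled 3′-end count is averaged
over replicates of a condition; minus-strand genes are mirror-mapped, and
offsets beyond the annotated gene are masked and excluded from profile
means (so a union profile is the size-weighted average of subset
profiles, exactly). The paired test sums signal per gene over a relative
window in each condition and applies a two-tailed paired t-test to the
differences; genes with any masked offset in the window are dropped, and
a zero-variance difference vector is flagged degenerate rather than given
a p-value. The default windows +1..+70 (pause site) and +70..+200 (early
body) share their printed boundary, assigned to both — fidelity to the
convention over tidiness. Replicates are averaged before pairing: the
gene is the pairing unit.

## Peak and region analysis

Peak merging is a sorted sweep implementing overlap-requiring union-merge
with provenance (each merged region lists its contributing source peaks).
Peak→gene assignment keeps, per gene, the promoter-overlapping
(TSS ± 1 kb) peak with the largest |log2FC|, ties broken toward the larger
signed change then the lexicographically first peak id. Enhancer
classification measures summit-to-TSS distance (> 100 bp = enhancer); the
summit is the sharper anchor, with an edge-distance mode available by
flag. Enrichment z-scores standardize each feature by mean and sample
standard deviation; constant features become all-zero and are flagged
instead of dividing by zero. Fold-change coupling reports Pearson r as the
headline (the relationship examined is a linear-trend scatter) with
Spearman ρ always alongside; non-finite pairs are dropped and counted.
The >1.5-fold acetylation-gain set uses a strict threshold on log2FC.

## The synthetic generator

`simulate_experiment` emulates a two-condition (solvent control vs HDAC
inhibitor), two-replicate spike-in PRO-seq experiment at desk scale. Per
gene: length ~ lognormal(8.0, 0.4) bp (median ≈ 3 kb, redrawn below
700 bp), initiation `I_g` ~ lognormal(0, 0.5), release probability
`r_g` ~ Beta(2, 8) (mean 0.2) for ordinary genes and Beta(2, 38)
(mean 0.05) for the 10% of genes designated targets — the highly paused
class. At steady state, paused occupancy ∝ `I_g/r_g` and body flux ∝
`I_g·L·r_g/(r_g+t)` with termination weight t = 0.5: the simplest model in
which raising release depletes the pause site and fills the body.
Treatment multiplies target release by f (default 3, capped at 1), giving
true body changes of ~1.3 log2 units for typical targets. Allocation is
calibrated on the control condition so that a sample carries 200,000
reads, 40% of them at pause sites. Counts are NB with dispersion
α = 0.05 (variance μ + αμ²) via a gamma–Poisson mixture; paused-read 3′
ends are uniform over +20..+60 (the pause site), elongating reads uniform
over +70..TES−100 so that early-body density responds to release (the
differential/PI body *windows* remain +500..TES−100). Each sample's
counts are scaled by a depth distortion λ_j ~ lognormal(0, 0.25), and
spike reads are Poisson(S·λ_j), S = 20,000: condition-independent by
construction, but riding the same sequencing depth as the primary reads —
which is precisely what makes spike totals informative about cross-sample
scale. All randomness derives from one master seed with per-sample spawned
streams; identical seeds give byte-identical output files.

`simulate_chip_peaks` is the peak-level analogue: baseline peak counts
~ lognormal, treated means multiplied by `(1+γ)` globally and `(1+δ)` at
target peaks, NB noise, the same λ/spike structure. Setting γ = 1 with
treated λ = 1/2 reproduces the situation where raw library sizes are
equal and only spike-in normalization can see the global gain.

What the generator does *not* emulate: base-level sequence, mappability,
GC or fragment-length effects, replicate batch effects, gene-specific
dispersion spread, multiple chromosomes, overlapping or nested genes, and
internal pause sites. Passing tests therefore demonstrate the statistical
machinery under the stated model, not robustness to those real-data
complications.

## Problem sizes

The calibration and recovery suites use 2000-gene null and 500-gene
recovery designs over 20 seeds (10 in the acceptance script), sizes at
which the Monte-Carlo fractions reported are stable to a few percent;
they complete in seconds because all window counting and testing is
vectorized over sorted position arrays.

## Known limitations

- Two-group contrasts only; no multi-factor designs, covariates or
  outlier handling.
- The Wald/normal reference is slightly anticonservative in the extreme
  tail at n = 4 (see calibration note above); the FDR-class counts
  reported on real minimal designs should be read with that in mind.
- ΔΔCt assumes amplification efficiency exactly 2 and averages in Cq
  space across replicates.
- The ChIP-qPCR background correction uses the arithmetic mean of the
  background loci (with two background loci the corrected value at each
  background locus is mean-centred, not exactly 1).
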