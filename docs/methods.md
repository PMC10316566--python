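# Methods

`degrecap` asks a design question that comes up whenever a single-cell
experiment is planned on a budget: **given that bulk RNA-seq of sorted
populations is the accepted reference for differential expression, how many
cells — and how many reads — does scRNA-seq need before it recovers the DEGs
the bulk comparison finds?** The package answers it on synthetic data with
known ground truth, using the same two analysis routes practitioners apply
to real data.

## The generative model

Real paired datasets of this kind are produced by splitting each of three
replicate rounds of cell culture into a single-cell library and a bulk
RNA-seq sample, for each of two cell types. The simulator reproduces that
design with a negative-binomial (NB) hierarchy — the model family both
downstream tests assume:

1. **Gene baselines.** Per-gene expression rates `lambda_g` are log-normal
   across genes (`baseline_meanlog = 1`, `baseline_sdlog = 2`), spanning the
   several orders of magnitude seen in transcriptomes. Rates are normalized
   to proportions, so only their ratios matter.
2. **True effects.** A fraction `frac_de` (default 0.3) of genes is truly
   differential between the two types. True |log2FC| values come from an
   equal-weight mixture of modest effects, uniform on [0.5, 2], and large
   effects, uniform on [2, 5], with random sign. This deliberately populates
   both the easy (cell-type-vs-cell-type) and hard
   (condition-vs-condition-like) ends of the effect-size spectrum.
3. **Replicate effects.** Each (gene, replicate) pair receives a log-normal
   perturbation (`replicate_noise_sd = 0.1`, natural-log scale) that is
   **shared by the two cell types and by both assays of that replicate**,
   because one round of culture feeds all of them. Sharing across types is
   load-bearing: it makes the two types exactly exchangeable when
   `frac_de = 0`, so null calibration of the cell-level test is a
   well-posed question. (Type-specific replicate noise would instead
   manufacture true between-group differences for every gene — the
   pseudoreplication regime — and no cell-level test could stay calibrated.)
4. **Single-cell counts.** Each cell draws a library size from a log-normal
   (median 8,000 total counts, `sdlog = 0.35` — typical of current
   droplet-based 3' chemistry) and then per-gene NB counts with mean
   `libsize x proportion` and a per-gene dispersion
   `alpha_g = (0.1 + 1/m_g) x LogNormal(0, 0.25)`, where `m_g` is the
   expected per-cell count. Dropout is implicit: at these depths most NB
   means are far below one, so zeros dominate without a zero-inflation term.
5. **Bulk counts.** Each bulk replicate draws NB counts at `bulk_depth`
   (default 100 M) around the same perturbed per-replicate proportions, with
   a small constant dispersion (0.005) on top of the shared replicate
   noise.

All randomness flows from a single root seed through independent spawned
streams (truth, replicate effects, single-cell draws, bulk draws, gene
lengths), so identical configurations are bit-identical and enlarging one
part of the experiment never perturbs another. Gene lengths are uniform on
[500, 10,000] bases and exist only to give TPM a denominator.

### What the simulator does not emulate

No ambient RNA, doublets, UMI collisions, batch chemistry effects, 3'-end
coverage bias, or cell-type-specific library-size differences. Passing tests
therefore demonstrate that the *analysis pipeline* behaves as specified on
data drawn from its own model family — they say nothing about robustness to
the artifacts real droplet data add, and recapitulation rates on real data
should be expected to be somewhat lower at equal scale.

## Preprocessing

* **Cell filter:** keep cells detecting between 200 and 5,000 genes,
  inclusive. Filtering happens once, before any subsampling.
* **Pseudo-bulk:** per-gene integer sums over the cells of each
  (type x replicate library) group — three pseudo-bulk samples per type, so
  the replicate-level NB test has the same 3 vs 3 design as the bulk data.
* **TPM:** counts divided by gene length in kb, rescaled so each column sums
  to 1e6. The same full-length gene lengths are used for bulk and
  pseudo-bulk; with 3'-biased single-cell protocols this is a simplification,
  and TPM here serves only ranking and detection (TPM > 0) purposes.
* **LogNormalize:** `ln(1 + 10,000 x count / cell_total)` per cell, the
  standard depth-normalization of cell-level marker testing.

## The two DE procedures

**NB Wald test** (bulk and pseudo-bulk): median-of-ratios size factors
(reference = per-gene geometric mean over the genes positive in every
sample); per-gene dispersion by method of moments on normalized counts,
floored at 1e-8, with a least-squares `a0 + a1/mu` trend substituted where
the gene-wise moment estimate is non-positive or undefined; per-gene IRLS
fit of `log mu = log s_j + b0 + b1*[group B]`, Wald statistic `b1/SE(b1)`
against a standard normal, `log2FC = b1/ln 2`. This is a deliberately
self-contained member of the DESeq2 family — **no** Cox-Reid dispersion
shrinkage, LFC shrinkage, independent filtering, or outlier handling — so
every step is verifiable in isolation; results are labeled "DESeq2-style",
never "DESeq2". On simulated 3 vs 3 bulk data it tracks the reference
implementation (pydeseq2) with near-identical fold changes and >0.95 DEG
Jaccard agreement (see `tests/test_de.py`).

**Wilcoxon rank-sum** (cell level): per-gene two-sided rank-sum test on
log-normalized values, group B vs group A. For untied samples with both
groups of size <= 8 the exact rank-sum distribution is used; otherwise the
normal approximation with midranks, tie-corrected variance and continuity
correction. (This is the switch the standard R implementation makes by
default; a pure normal approximation deviates from the exact p-value by up
to 0.09 for the smallest groups, which is why the exact branch exists.)
`log2FC` follows the marker-test convention:
`log2((mean(expm1(x_B)) + 1)/(mean(expm1(x_A)) + 1))`, pseudocount 1 on the
depth-normalized scale — fold-change quartiles downstream depend on this
choice, hence it is fixed and documented. The `min_pct`/`logfc_threshold`
prefilters exist but default to 0 so all genes are tested. Genes constant
across all cells get p = 1 by convention.

**Adjustment:** BH step-up and Bonferroni, NA p-values excluded from the
number of tests and propagated. DEG calls use adjusted p <= 0.05,
inclusive. Within the evaluation grid the reference is always the bulk NB
test with BH; Bonferroni is reported for the cell-level route only, as the
historical default of marker testing.

## Data reduction

* **Cell subsampling:** `round(fraction x n)` cells per replicate library,
  without replacement, stratified by library; three independent draws per
  fraction. Seeds derive as `hash(root, fraction, repeat, library)`, so
  adding a fraction to a plan never changes existing draws. Fraction 1.0
  returns the data unchanged and its repeats are copies by construction.
* **Read thinning:** each bulk column is replaced by a without-replacement
  sample of exactly `target_total` reads, i.e. a multivariate
  hypergeometric draw over genes — the exact count-level image of
  read-level subsampling followed by identical alignment. Requested depths
  at or above a column's total leave the data unchanged.

## Evaluation statistics

For every (method, reduction level, repeat): reference and test DEG counts,
their overlap, the recapitulation rate (|ref ∩ test| / |ref|), DEGs unique
to the test side, quartile-stratified recapitulation (reference DEGs split
into quartiles by unadjusted p ascending, |log2FC| descending, and mean TPM
descending; ties broken by gene id; leading quartiles take the extra genes
when n is not divisible by 4), the modest-DEG recapitulation (reference DEGs
with unadjusted p in [3.1e-5, 0.025], BH p in [1e-4, 0.05] and |log2FC| in
[0.5, 2], all bounds inclusive), the Spearman correlation of unadjusted
p-values over the fixed reference DEG set (test-side missing p set to 1, so
the gene set is identical across levels and correlations are comparable),
and the Spearman correlation of log2(TPM+1) abundance profiles with
undetected genes entered as 0.

Quartile boundaries are always computed on the reference DEG set, not all
genes. Up- and down-regulated DEGs are pooled throughout.

## Problem sizes and numerical choices

The full-scale synthetic study uses the default configuration: 10,000
genes, 5,000 cells per type over three libraries, three bulk replicates at
100 M counts, 30% DE. The acceptance script runs that grid plus a
2,000-gene null-calibration series; unit tests use smaller draws of the
same model. IRLS runs at most 50 iterations to 1e-10 with coefficients
clipped to |b0| <= 50, |b1| <= 30 (a gene entirely absent from one group has
no finite MLE; the clip leaves it testable with an honest, large SE).
Dispersion trend fitting clips gene-wise moment estimates at their 1st/99th
percentiles so a few wild genes cannot steer the trend. The size-factor
estimator requires at least one gene positive in every sample and errors
otherwise rather than guessing.

## Known limitations

* The NB test's moment-based dispersions are noisier than profile-likelihood
  estimates at n = 3 per group; in practice this makes the test mildly
  conservative on simulated data (null BH discovery fractions well below
  0.05) at some cost in power relative to DESeq2 proper.
* Shared replicate effects mean the 3 vs 3 design is effectively paired,
  which the unpaired tests do not exploit; between-replicate noise inflates
  dispersion estimates slightly rather than biasing fold changes.
* TPM on pseudo-bulk uses full gene lengths (see above).
* Whether cell filtering should be repeated after subsampling is a judgment
  call; the pipeline filters once, before subsampling, and subsamples from
  the filtered pool.
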