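# Methods

This note documents the models implemented in `wregion`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## The masculinization statistic

For a panel *P* of sex-related genes and two contrasts X and Y (each a
vector of per-gene log2 fold changes, with wildtype-female expression as
the reference), the statistic is the correlation of the paired panel values
after outlier exclusion:

1. Restrict to panel genes with finite log2FC in both contrasts; genes
   missing from either analysis are reported, never silently dropped.
2. Flag outliers in each coordinate with Tukey fences — values beyond
   1.5 × IQR below Q1 or above Q3, quartiles by linear interpolation of
   order statistics — and drop a gene if it is an outlier in **either**
   coordinate (the union rule). The correlation must hold in both
   coordinates for a point to contribute, and whether the original fences
   were marginal or joint is not determinable; the quantile estimator is
   exposed as an option.
3. Correlate the survivors. Spearman (Pearson on average-tie ranks) is the
   default because it is distribution-free under independence, which is
   what makes the permutation null calibrate cleanly; Pearson is available
   for figure-style summaries. Both an analytic p (t transform on n − 2 df)
   and the permutation p are reported.

The permutation null draws |P| genes without replacement from the universe
of genes finite in both contrasts (panel genes are not excluded — the draw
is from "all genes"), re-applies the outlier rule inside each draw, and
correlates the survivors. Replicates degenerating to fewer than three
points or a constant vector are redrawn and counted. The p-value is
`1 − r/(n_perm + 1)` with `r` the number of permutation correlations
**strictly** below the observed one: ties count against significance, the
denominator is `n_perm + 1` (1001 at the default 1000 permutations), and p
is bounded below by `1/(n_perm + 1)` and can never be zero.

### Why the comparison design matters

Two contrasts that share reference samples are positively correlated under
the null: the shared reference noise enters both fold-change vectors with
the same sign. For random gene panels this inflates the null correlation,
while a true panel whose X-values carry large real effects has that shared
component diluted — so pairing contrasts with shared references makes the
permutation test *conservative*, not anticonservative. The package's
simulated study conditions therefore mirror the informative design: the
knockout contrast uses the knockouts' wildtype sisters, and the
male-vs-female contrast uses an independent clutch
(`wt_female_mf`), so the two fold-change vectors share no samples. A test
(`test_shared_reference_samples_inflate_correlation`) demonstrates the
shared-reference inflation directly.

## The differential-expression stage

This stage is deliberately small and analyzable; parity with full GLM-based
DE packages is a non-goal. Per contrast (two groups, reference second):

- **Filter**: drop genes whose raw-count mean across the contrast's samples
  is below 2 (the threshold and the per-contrast scope are configurable;
  a global pre-filter can be applied by calling `filter_low_counts` on the
  full matrix first). Filtered genes stay in the output with a `filtered`
  marker and NaN statistics.
- **Normalize**: median-of-ratios size factors computed from genes with
  all-positive counts (the plain linear-space median of count/geometric-mean
  ratios, per its definition).
- **Estimate**: `log2FC = log2((μ̂_t + c)/(μ̂_r + c))` with prior count
  c = 0.5 on normalized group means; per-gene NB dispersion φ by method of
  moments (φ̂ = (s² − m̄)/m̄², clipped at 0, pooled across groups by degrees
  of freedom) and shrunk toward the trend-free common dispersion with
  prior weight 10 against the residual df.
- **Test**: two-sided Wald z on the natural-log fold change with
  delta-method variance `(1/(μ̂_t + c) + φ)/n_t + (1/(μ̂_r + c) + φ)/n_r`.
  The prior count also stabilizes the variance term so genes expressed in
  only one group get finite (large-|z|) statistics rather than NaN. Genes
  with zero counts in both groups are defined to have log2FC = 0, p = 1.
- **Call**: Benjamini–Hochberg step-up adjustment (missing values propagate
  and do not count toward the number of tests); DE at FDR < 0.10.

Simulations in the acceptance suite show this stage holds its nominal
type-I error (raw-p rejection at 0.05 within [0.03, 0.07] under a 6 vs 6
null with 2000 genes) and that panel log2FC RMSE drops by more than half
from n = 3 to n = 20 per group.

## The cross model

Each parent transmits either sex-chromosome allele with probability 1/2;
probabilities are exact `Fraction`s and unordered genotypes are merged, so
ZW × ZW\* gives the four classes {W\*Z, WW\*, WZ, ZZ} at exactly 1/4 each.
Phenotype is female iff at least one allele carries functional *dm-w* (the
intact W); W\*Z, W\*W\* and ZZ are male. Classes a sequencing assay cannot
separate (W\*Z vs W\*W\*, identical at the mutant allele) are pooled by
summing probabilities over a user-supplied partition. Goodness of fit uses
Pearson's chi-square with df = #classes − 1, plus an exact multinomial p by
full enumeration (outcomes ordered by the chi-square statistic) when n ≤ 40
and there are at most 4 classes. No viability or transmission-distortion
parameters are modelled; the distribution type is the natural extension
point if brood data ever demanded them. Genotype labels are canonicalized
W before W\* before Z (so "W\*W" displays as "WW\*"); parsers accept either
order.

## Dollo parsimony

Each W-linked component is assumed to have arisen exactly once (by
duplication/insertion), so reversals to presence are disallowed: a
character history is a single gain node plus loss edges below it. For a
fixed gain node, the minimal loss set puts one loss on the edge above each
maximal present-free subtree that contains at least one "absent" tip;
all-"unknown" subtrees cost nothing (unknown tips — species not assayed, or
possible capture false negatives — impose no constraint in either
direction). The optimal gain placement scores every admissible node (the
MRCA of present tips and its ancestors up to the root); ties break toward
the shallowest (most recent) node, with the full tied set reported.
Scenarios are compared by total event count (1 gain + losses); for
multi-locus deletion scenarios, per-locus loss counts are summed and
co-located losses can be read off the per-locus loss edges. Physical
deletion tracts, reticulate (allopolyploid) relationships and tree
estimation are out of scope — the tree is an input.

The worked example encodes the *dm-w* exon 4 pattern: present in ten
species, absent in *X. vestitus* (nested inside the carrier clade) and
*X. clivii* (outside it). The optimum is a single gain at the carrier
clade's ancestor with one loss on the *X. vestitus* lineage; forcing the
gain into the older ancestor shared with *X. clivii* costs a second loss,
i.e. strictly more events. The shipped topology encodes only the
relationships this comparison needs (carrier clade membership, the nested
position of *X. vestitus*, *X. clivii* outside); finer within-clade
arrangement does not affect the reconstruction.

## The synthetic-data generator

Counts for gene g, sample j are negative binomial with
`μ_gj = 2^(b_g + e_g(group_j) + β_batch(j)) · s_j` and
`Var = μ + φμ²` (Poisson at φ = 0), where

| parameter | default | meaning |
|---|---|---|
| `baseline_log2_mean`, `baseline_log2_sd` | 6, 2 | per-gene baseline b_g ~ N, log2 scale (median ≈ 64 counts, wide dynamic range) |
| `dispersion` φ | 0.1 | constant, or gamma(shape, scale) per gene; 0.1 is typical for bulk RNA-seq biological replicates |
| `panel_size` | 74 | sex-biased panel size, matching the motivating design |
| `sex_effect_mean`, `sex_effect_sd` | 1.5, 0.5 | panel \|log2FC\| ~ \|N\| in males, random sign per gene |
| `masc_coefficient` m | 0.8 | knockout panel log2FC = m × male log2FC + N(0, `ko_noise_sd`); 0 = no masculinization |
| `ko_noise_sd` | 0.1 | gene-level wobble around the proportional shift |
| `batch_sd`, `n_batches` | 0.3, 3 | additive per-batch log2 offset shared by all genes; samples assigned round-robin within groups, like clutches mixing sexes |
| `libsize_log_sd` | 0.2 | per-sample log-normal library-size factor (~±40% spread) |
| `group_sizes` | 6/6/6 | samples per group; groups are classified by label prefix (`wt_male*` → sex effect, `ko_*` → knockout effect, else baseline female) |

One top-level seed drives everything; identical configs give bitwise
identical output. Defining the knockout shift on the log2 scale as
m × (male effect) + noise makes the expected panel correlation a monotone
function of m, giving a clean power surface (verified over
m ∈ {0, 0.25, …, 1}).

**What the generator does not emulate.** Batch offsets are shared by all
genes within a batch, which is exactly the kind of scaling that
median-of-ratios normalization absorbs — so the simulator does not
reproduce gene-specific batch interactions, i.e. the among-batch variation
in the *identity* of DE genes seen in real clutch data. It also has no
read-level structure (no FASTQ, isoforms, GC/length bias), no correlation
between genes beyond the shared batch/library factors, and no
mean-dispersion trend. Passing tests therefore certify the statistics'
behaviour under a clean NB model with the stated design, not robustness to
those real-data complications.

## Numerical choices and degenerate inputs

- Quartiles: linear interpolation (`numpy.quantile` default), configurable.
- Outlier masking with fewer than 4 finite values is undefined; the paired
  panel builder treats < 4 usable genes as having no outliers (≥ 3 genes
  remain the hard minimum), and the mask function itself raises.
- Correlation of a constant vector raises; |r| = 1 in the analytic p-value
  returns p = 0 with a warning instead of raising.
- Degenerate permutation replicates (constant after masking) are redrawn,
  counted, and reported; a runaway redraw loop aborts after 10 000.
- BH adjustment: missing p-values propagate as missing; output is clipped
  at 1 and never below the raw p.
- Exact multinomial enumeration is guarded (n ≤ 40, ≤ 4 classes) and falls
  back to chi-square.
- All-zero samples and empty matrices raise named errors before any
  statistic is computed.

## Problem sizes used by the test and acceptance runs

The calibration check uses 200 replicate experiments (2000 genes, panel of
74, groups of six, 1000 permutations each) for the Kolmogorov–Smirnov
uniformity test at the 1% level; power uses 50 replicates at m = 0.8;
monotonicity uses 50 replicates per m value; the null DE check pools five
2000-gene datasets; RMSE pools eight datasets per group size; Dollo
inference is validated against exhaustive enumeration on 100 random trees
of up to six tips. `scripts/acceptance.py` re-runs the same computations at
moderately reduced replicate counts (reported in its output as `n`) so a
full reproduction stays within a few minutes on a single CPU.
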