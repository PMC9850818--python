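# Methods

## Model and rationale

The package treats within-species variation in allele-specific expression
(ASE) as an empirical yardstick for evolutionary constraint on a gene's
*cis*-regulation. Two alleles inside one individual share every *trans*
factor and every environmental exposure, so the spread of allelic ratios
across a population cohort reflects tolerated *cis* variation. A gene whose
between-species allelic shift (measured in an interspecies hybrid, where
both genomes again share one *trans* environment) stands outside that
tolerated range is a credible candidate for phenotypic divergence; a gene
whose shift sits comfortably inside it is not, however large the fold
change.

The per-gene statistic is a two-sided Mann-Whitney U test of the hybrid
log2 allelic ratios against the population log2 ratio distribution. A rank
test is used deliberately: ASE ratio distributions are heavy-tailed and
asymmetric, and the statistic must be invariant to the scale (ratio vs log
ratio) on which the distributions are formed.

## Pipeline definitions

**Population profiles.** For each gene: samples with fewer than
`min_reads = 10` raw reads from *either* allele are dropped (the filter is
per gene — a sample can pass for one gene and fail for another); a
pseudocount of 1 read is added per allele; ratios are divided by their
median so the retained median is exactly 1; genes retaining fewer than
`min_samples = 50` samples are excluded. The constraint proxy is the sample
variance (denominator n−1) of the normalized ratios. Filtering precedes
normalization: normalizing over samples that are subsequently discarded
would leave the retained median off 1, defeating the normalization's
purpose (isolating variance from consistent allelic bias). A config switch
(`variance_scale="log2"`) exposes the log-scale variance instead.

**Hybrid records.** Per-replicate log2((c1+1)/(c2+1)) with *no* coverage
filter and *no* median normalization — extreme, consistent skews are the
between-species signal, and dropping low-count replicates would censor
exactly the strongest divergences. Genes are removed only when the mean
counts of *both* alleles fall below `min_mean_count = 25`. External
differential-expression summaries (mean log2 fold change, FDR) are inputs,
not computed here; an exclusion list handles mapping-bias or
structural-artifact genes.

**Mann-Whitney p-values** use the exact null distribution when
n1·n2 ≤ 400 and the pooled data are tie-free, otherwise the normal
approximation with tie and continuity corrections. A fully tied input
(all observations equal) returns p = 1 by definition. p-values are floored
at 1e-300 before taking log10 in the signed score.

**Rankings.** Ties in any score are broken lexicographically by gene id so
ranks are a deterministic permutation of 1..N. The signed score is
−log10(p)·sign(mean log2FC) — the orientation that places significant
species-1-biased genes at the top. The difference-in-ranks score is
de_rank − mwu_rank, descending, so genes promoted by the constraint
comparison relative to a traditional DE ranking surface at the top.

**GSEA-preranked** implements the weighted Kolmogorov-Smirnov running sum
with weight exponent 1 (the standard default; weight 0 recovers the
classical KS statistic). Hit increments are |score|^w normalized to the set
total; misses decrement 1/(N − N_hits); the enrichment score (ES) is the
maximum-magnitude deviation, with exact |max| = |min| ties resolved to the
positive side. The null permutes gene labels (`n_perm = 1000`, seed 6 by
default): for each set size the null draws random same-size subsets and
scores them with a vectorized member-position formula (the running sum is
piecewise linear between hits, so its extrema occur adjacent to hits).
NES divides ES by the mean |null ES| of matching sign; the nominal p is the
same-sign null exceedance floored at 1/n_perm; the FDR q compares each
observed NES against the sign-matched pool of normalized null NES values,
capped at 1. Set eligibility is 10 ≤ |set ∩ list| ≤ 300. Everything is
bit-deterministic given the seed.

**Sign test.** A set is a candidate if its GSEA FDR < 0.25 somewhere and
its leading edge has more than 5 genes; each set is tested once, at its
lowest-FDR time point (ties → earliest time point). Leading-edge genes are
counted by the sign of their external mean log2 fold change (exact zeros
excluded with a log message; "driving genes" means leading-edge members,
with no additional per-gene significance filter). The exact two-sided
binomial test at p0 = 0.5 is applied, then Benjamini-Hochberg across all
tested sets; significance is q < 0.1. Published descriptions of this
procedure quote both 0.05 and 0.1 as the corrected threshold; 0.1 is the
default here and is exposed as `bh_threshold`.

## Synthetic data

`generate_population` draws, per gene g and sample s, a depth
N_gs ~ Poisson(d_g) with d_g log-normal (median `median_depth = 100`,
sigma 0.5), an allele-1 fraction f_gs ~ Beta(α_g, α_g), and
counts1 ~ Binomial(N_gs, f_gs). The symmetric Beta concentration α_g is
the single interpretable constraint knob: α = 200 produces the tight
allelic balance of a dosage-sensitive gene, α = 2 the wide overdispersion
of an unconstrained one; by default α is log-uniform on [2, 200].

`generate_hybrid` centres the species-1 fraction at 2^δ/(1+2^δ) for a true
log2 shift δ, jittered per replicate by Beta(2α·p, 2α·(1−p)) (the
concentration reduces to the population's at δ = 0), with 8 replicates by
default. The DE surrogate is a per-gene one-sample t-test of replicate
log2 ratios against 0, BH-corrected — standing in for an external
differential-expression analysis, which is out of scope by design.
Constraint scores are α/(α + √(α_lo·α_hi)) plus clipped Gaussian noise
(sd 0.05), i.e. monotone in α; the expression summary is the gene's mean
depth. Gene sets are disjoint blocks; "injected" sets assign their members
a common signed δ.

All generators are bit-reproducible from `SimulationConfig.seed` via
independent named substreams, so each generator is individually
deterministic. The pipeline derives stage seeds from one global seed by
fixed offsets.

What the generator does *not* emulate: tissue and donor structure (GTEx
pools 54 tissues; the cohort here is exchangeable samples), linkage between
variants, mapping bias, reference bias, depth-expression correlations
beyond the shared depth model, and DESeq2's shrinkage behaviour. Passing
tests therefore demonstrate that the statistics behave correctly under the
assumed beta-binomial overdispersion model — not that any particular real
cohort satisfies that model.

## Study conditions used by the test suite

Chosen once, as desk-scale versions of the cohorts this method is used on:

- **Reference cohort** (`default_cohort`): 500 genes × 2000 samples,
  median depth 100, shifts ~ Normal(0, 0.5 log2). Population ASE panels
  have thousands of quantifiable samples per gene, and the sample count
  matters mechanistically: allele-flip invariance of the rankings rests on
  the symmetry of the empirical median-normalized distribution, which
  sharpens as the cohort grows (flip rank-correlation ≈ 0.99 at 500
  samples, ≈ 0.996 at 2000).
- **Parameter recovery** (`constrained_shift_cohort`): 100 genes, all with
  δ = 0.5, half α = 200 / half α = 2, 500 samples at fixed depth 100.
- **Down-sampling** (`downsample_cohort`): 300 genes × 600 samples, grid
  [600, 100, 25], 20 repetitions, genes restricted to those quantifiable in
  ≥ 600 samples so every condition uses equal per-gene n.
- **Neutral null** (`neutral_null_cohort`): 300 genes × 200 samples, 20
  random 12-gene sets, no injected direction, 20 seeded replicates.

## Validation procedures

- `constraint_correlation`: Spearman rho between per-gene ASE variance and
  an external constraint score (errors on constant inputs rather than
  returning an undefined coefficient).
- `downsample_experiment`: draws n samples per gene without replacement
  (equal n for every gene in a condition), rebuilds normalized ratios, and
  reports the mean (and mean absolute) correlation over repetitions;
  reproducible from its seed.
- `expression_matched_comparison`: the n_top highest- and lowest-constraint
  genes are each ranked by expression and paired rank-for-rank; a classical
  two-sided paired t-test is applied to the per-pair variance differences
  (pairs share one difference vector, so no Welch correction applies).
- `cohort_split_robustness`: the supplied ranking function is re-run on
  each half of a sample partition and the rankings compared by Spearman
  correlation on the common gene set.

## Numerical choices and degenerate inputs

- Pseudocount 1 per allele per sample (configurable) keeps ratios finite;
  (0, 0) maps to ratio 1 / log2 ratio 0.
- Missing (NA) cells are sample-absent, never zero: a zero count is
  informative in ASE, absence is not. Absent cells fail every coverage
  filter and are dropped from hybrid replicate vectors.
- Median normalization uses the mean-of-middle-two convention for even n;
  the normalized median is exact for odd n and within 1e-12 for even n.
- ES |max|=|min| ties resolve positive, with a 1e-12 tolerance absorbing
  float noise so the vectorized null and the O(N) running sum agree.
- If every member score is 0 (an all-tied ranking), GSEA hit increments
  fall back to unweighted 1/N_hits.
- BH q-values are computed with the standard step-up procedure via
  statsmodels and returned in input order.

## Known limitations

- Variant-to-gene collapsing of population ASE releases is the caller's
  responsibility; the readers accept gene-level tables only.
- The binomial sign test assumes independent *cis* changes; neighboring
  genes sharing regulatory elements violate this, and no distance-based
  pruning is implemented.
- GSEA FDR follows the published positive/negative-pool procedure; other
  implementations differ in small numeric details, so agreement with them
  is expected at the level of eligibility decisions (FDR < 0.25), not to
  the last digit of q.
- Under a neutral generator, the few sets that reach GSEA eligibility on a
  signed ranking are selected *because* their members cluster directionally,
  so their subsequent binomial p-values are small by construction; the
  false-discovery guarantee is therefore stated over the whole collection,
  not over the eligible subset.
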