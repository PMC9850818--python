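# cisconstraint

Constraint-aware prioritization of interspecies *cis*-regulatory expression
differences from allele-specific read counts.

## The problem

Interspecies hybrids place both parental genomes in one nucleus, so
allele-specific expression (ASE) differences between the two alleles isolate
the *cis*-regulatory component of expression divergence, free of
environmental, batch, and *trans* confounders. But a large, significant
allelic fold change is not evidence of functional importance on its own: a
gene whose expression varies two-fold *within* a species is unlikely to
explain species-specific traits even if it also varies two-fold *between*
species. What matters is divergence relative to constraint.

`cisconstraint` implements that comparison. For each gene it contrasts the
between-species ASE distribution (hybrid replicates) with the within-species
population ASE distribution (a GTEx-like cohort) and ranks genes by how far
their *cis* divergence stands outside within-species variation. Ranked lists
feed a gene-set enrichment analysis and a binomial sign test that detects
lineage-specific polygenic selection.

## The method

Per gene, with allele read counts $c_1, c_2$:

- **Population profile** — drop samples with $<10$ reads from either allele;
  form ratios $(c_1+1)/(c_2+1)$; divide by the cohort median (median
  $\equiv 1$, removing any consistent allelic bias); keep genes with
  $\geq 50$ retained samples. The sample variance of the normalized ratios
  is the constraint proxy: constrained genes have tight distributions.
- **Hybrid profile** — per-replicate $\log_2\!\big((c_1+1)/(c_2+1)\big)$,
  deliberately with no coverage filter and no median normalization; genes
  with mean counts $<25$ on both alleles are removed.
- **Ranking** — a two-sided Mann-Whitney $U$ test compares the hybrid
  $\log_2$ ratios with the population distribution; genes are ranked by
  ascending $p$. A *signed* variant, $-\log_{10}p \times
  \mathrm{sign}(\overline{\log_2 FC})$, puts significant species-1-biased
  genes at the top and species-2-biased genes at the bottom; a
  *difference-in-ranks* variant ($\mathrm{rank}_{DE} - \mathrm{rank}_{MWU}$)
  highlights genes a traditional differential-expression ranking buries.
- **Enrichment + sign test** — preranked GSEA (weighted-KS running sum,
  1000 gene permutations, seed 6, set sizes 10–300) on the signed list; every
  set with FDR $<0.25$ and more than 5 leading-edge genes is tested once (at
  its lowest-FDR time point) with an exact binomial test on the direction of
  its leading-edge genes at $p_0 = 0.5$, Benjamini–Hochberg corrected
  (significant at $q < 0.1$). Because *cis* changes at different genes are
  (near-)independent genetic events, a directional excess is evidence of
  lineage-specific selection.

A beta-binomial synthetic-data module generates population cohorts, hybrid
experiments, surrogate DE summaries, constraint scores, and gene sets with
known ground truth, so the whole pipeline is testable without any external
download. See `docs/methods.md` for models, parameters and limitations.

## Worked example

`examples/03_enrichment_sign_test.py` injects one species-1-biased gene set
(12 genes, +0.6 log2 shift) among 20 neutral sets, runs the full chain
(population profiles → hybrid records → signed MWU ranking → GSEA → sign
test), and prints:

```
gene sets tested (GSEA FDR < 0.25, > 5 driving genes): 1
  selected_pathway: 10/10 species1-biased, binomial p = 0.001953, BH q = 0.001953  << selection
a set with nearly all driving genes biased one way departs from the fair coin
```

Only the injected set survives GSEA eligibility; all 10 of its leading-edge
genes are biased toward species 1, so the binomial test gives
$p = 2 \cdot 0.5^{10} \approx 0.002$ — a clean recovery of the planted
selection signal. The other scripts in `examples/` demonstrate the
constraint–variance correlation, constrained-vs-unconstrained gene ranking
(AUC 0.97), and the robustness checks (allele-flip and cohort-split rank
correlations ≈ 0.996).

## Command line

A thin CLI wraps the library: `cisconstraint simulate | population-dist |
hybrid-ase | rank | gsea | signtest | validate | run`. `run` executes the
whole pipeline from a YAML config (all thresholds overridable, defaults as
above) and writes result TSVs plus a `manifest.json` recording config, seed
and version; re-runs with the same config are bit-identical.

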