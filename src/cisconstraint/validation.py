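"""Validation procedures for the population-ASE constraint proxy.

Four checks that the within-species ASE variance behaves like an
evolutionary-constraint measure:

* correlation of per-gene ASE variance with an external constraint score
  (haploinsufficiency-probability-like, higher = more dosage-sensitive) —
  expected negative;
* a down-sampling experiment measuring how that correlation decays as the
  per-gene sample count shrinks;
* an expression-matched paired comparison: high- vs low-constraint genes
  paired by expression rank, paired t-test on the variance differences —
  controls for the mechanical depth-variance relationship;
* cohort-split robustness: the full ranking pipeline run on two sample
  partitions should produce nearly identical gene rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constraint_ranking import RankedGeneList
from .io_formats import AlleleCountTable
from .population_ase import build_population_profiles, PopulationASEProfile

logger = logging.getLogger(__name__)


@dataclass
class ConstraintScoreTable:
    """gene -> (constraint score in [0,1], expression summary >= 0)."""

    scores: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for gene, (score, expr) in self.scores.items():
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{gene}: constraint score {score} outside [0, 1]")
            if expr < 0:
                raise ValueError(f"{gene}: negative expression summary")

    def __len__(self) -> int:
        return len(self.scores)

    def constraint_of(self, gene: str) -> float:
        return self.scores[gene][0]

    def expression_of(self, gene: str) -> float:
        return self.scores[gene][1]

    @classmethod
    def from_tsv(cls, path) -> "ConstraintScoreTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                str(r.gene_id): (float(r.constraint), float(r.expression))
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tconstraint\texpression\n")
            for gene, (score, expr) in self.scores.items():
                fh.write(f"{gene}\t{score:.10g}\t{expr:.10g}\n")


def constraint_correlation(
    profiles: Mapping[str, PopulationASEProfile], scores: ConstraintScoreTable
) -> tuple[float, float, int]:
    """Spearman correlation between per-gene ASE variance and constraint
    score over the gene intersection. Returns (rho, p, n_genes)."""
    genes = sorted(set(profiles) & set(scores.scores))
    if len(genes) < 3:
        raise ValueError(f"need >= 3 overlapping genes, got {len(genes)}")
    variance = np.array([profiles[g].ase_variance for g in genes])
    score = np.array([scores.constraint_of(g) for g in genes])
    if np.unique(score).size == 1 or np.unique(variance).size == 1:
        raise ValueError("correlation undefined: one input is constant")
    rho, p = stats.spearmanr(variance, score)
    return float(rho), float(p), len(genes)


def downsample_experiment(
    table: AlleleCountTable,
    scores: ConstraintScoreTable,
    n_grid: Sequence[int] = (5000, 4000, 3000, 2000, 1000, 500, 250, 100, 50, 25, 10),
    reps: int = 100,
    seed: int = 0,
    min_reads: int = 10,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Mean constraint correlation as a function of per-gene sample count.

    Only genes with at least ``max(n_grid)`` quantifiable samples (passing
    the per-allele coverage filter) participate, so every gene contributes
    exactly ``n`` samples in every condition. For each n and repetition,
    n samples are drawn per gene without replacement, ratios are rebuilt
    and median-normalized, and the Spearman correlation with the constraint
    score recomputed; rows report the mean rho and mean |rho| over reps.
    """
    n_grid = list(n_grid)
    if sorted(n_grid, reverse=True) != n_grid:
        raise ValueError("n_grid must be sorted descending")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    from .population_ase import filter_low_coverage

    mask = filter_low_coverage(table, min_reads)
    n_max = max(n_grid)
    gene_ratios: dict[str, np.ndarray] = {}
    for i, gene in enumerate(table.gene_ids):
        if gene not in scores.scores:
            continue
        keep = mask[i]
        if keep.sum() >= n_max:
            gene_ratios[gene] = (table.counts1[i, keep] + pseudocount) / (
                table.counts2[i, keep] + pseudocount
            )
    if not gene_ratios:
        raise ValueError(f"no gene has >= {n_max} quantifiable samples")
    genes = sorted(gene_ratios)
    score = np.array([scores.constraint_of(g) for g in genes])
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        rhos = []
        for _ in range(reps):
            variances = np.empty(len(genes))
            for j, g in enumerate(genes):
                ratios = gene_ratios[g]
                draw = (
                    ratios
                    if ratios.size == n
                    else ratios[rng.choice(ratios.size, n, replace=False)]
                )
                norm = draw / np.median(draw)
                variances[j] = np.var(norm, ddof=1)
            rho, _ = stats.spearmanr(variances, score)
            rhos.append(rho)
        rows.append(
            {
                "n": n,
                "mean_rho": float(np.mean(rhos)),
                "mean_abs_rho": float(np.mean(np.abs(rhos))),
                "reps": reps,
                "n_genes": len(genes),
            }
        )
        logger.info("downsample n=%d: mean |rho| = %.4f over %d reps", n, rows[-1]["mean_abs_rho"], reps)
    return pd.DataFrame(rows)


def expression_matched_comparison(
    profiles: Mapping[str, PopulationASEProfile],
    scores: ConstraintScoreTable,
    n_top: int = 2500,
) -> tuple[np.ndarray, float, float]:
    """Paired high- vs low-constraint variance comparison at matched expression.

    The ``n_top`` highest- and lowest-constraint genes are each ranked by
    the expression summary and paired rank-for-rank; the paired difference
    is variance(high-constraint) − variance(low-constraint). Returns
    (differences, t statistic, two-sided p).
    """
    genes = sorted(set(profiles) & set(scores.scores))
    if len(genes) < 2 * n_top:
        raise ValueError(f"need >= {2 * n_top} genes with both measures, got {len(genes)}")
    by_score = sorted(genes, key=lambda g: (scores.constraint_of(g), g))
    low, high = by_score[:n_top], by_score[-n_top:]
    expr_key = lambda g: (scores.expression_of(g), g)
    high_by_expr = sorted(high, key=expr_key)
    low_by_expr = sorted(low, key=expr_key)
    diffs = np.array(
        [
            profiles[h].ase_variance - profiles[l].ase_variance
            for h, l in zip(high_by_expr, low_by_expr)
        ]
    )
    t, p = stats.ttest_rel(
        [profiles[h].ase_variance for h in high_by_expr],
        [profiles[l].ase_variance for l in low_by_expr],
    )
    return diffs, float(t), float(p)


def cohort_split_robustness(
    table: AlleleCountTable,
    split: Mapping[str, int] | Sequence[int],
    ranking_fn: Callable[[Mapping[str, PopulationASEProfile]], RankedGeneList],
    min_reads: int = 10,
    min_samples: int = 50,
    pseudocount: float = 1.0,
) -> tuple[float, float, int]:
    """Rank-correlation of the downstream ranking across a sample partition.

    ``split`` assigns each sample to partition 0 or 1 (mapping by sample id
    or a sequence in column order). ``ranking_fn`` maps population profiles
    to a RankedGeneList (typically closing over a fixed hybrid dataset).
    Returns (spearman rho, p, n common genes).
    """
    if isinstance(split, Mapping):
        labels = np.array([split[s] for s in table.sample_ids])
    else:
        labels = np.asarray(list(split))
        if labels.size != table.n_samples:
            raise ValueError("split length != number of samples")
    rankings = []
    for part in (0, 1):
        cols = np.where(labels == part)[0]
        if cols.size == 0:
            raise ValueError(f"partition {part} contains no samples")
        sub = AlleleCountTable(
            list(table.gene_ids),
            [table.sample_ids[j] for j in cols],
            table.counts1[:, cols],
            table.counts2[:, cols],
        )
        profiles = build_population_profiles(
            sub, min_reads=min_reads, min_samples=min_samples, pseudocount=pseudocount
        )
        if not profiles:
            raise ValueError(f"partition {part}: no gene passed the sample filters")
        rankings.append(ranking_fn(profiles))
    ranks0, ranks1 = rankings[0].rank_of(), rankings[1].rank_of()
    common = sorted(set(ranks0) & set(ranks1))
    if len(common) < 3:
        raise ValueError("fewer than 3 genes ranked in both partitions")
    rho, p = stats.spearmanr(
        [ranks0[g] for g in common], [ranks1[g] for g in common]
    )
    return float(rho), float(p), len(common)
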