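"""Constraint-aware gene ranking.

The core statistic: for each gene, a two-sided Mann-Whitney U test compares
the hybrid (between-species) log2 ASE ratios against the gene's population
(within-species) log2 ASE distribution. A small p-value means the
interspecies *cis* shift stands outside the within-species variation — a
divergence that constraint makes phenotypically credible — so genes are
ranked by ascending p.

Three derived rankings:

* ``mwu`` — ascending MWU p-value.
* ``signed`` — −log10(p) × sign(mean log2 fold change), descending, so
  significant species1-biased genes sit at the top and significant
  species2-biased genes at the bottom of one list.
* ``diff_in_ranks`` — DE-FDR rank minus MWU rank, descending: genes the
  traditional differential-expression ranking buries but the constraint
  comparison promotes rise to the top.

All rankings break score ties lexicographically by gene id, so ranks are a
deterministic permutation 1..N.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interspecies_ase import InterspeciesASERecord
from .population_ase import PopulationASEProfile

logger = logging.getLogger(__name__)

EXACT_PRODUCT_LIMIT = 400
P_FLOOR = 1e-300


@dataclass
class RankedGeneList:
    """Genes with scores and deterministic integer ranks (1 = top)."""

    entries: pd.DataFrame  # columns: gene_id, score, mwu_p, rank
    ranking_kind: str

    def __post_init__(self) -> None:
        required = {"gene_id", "score", "mwu_p", "rank"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"entries needs columns {sorted(required)}")
        n = len(self.entries)
        if sorted(self.entries["rank"]) != list(range(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..N")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries["gene_id"])

    def rank_of(self) -> dict[str, int]:
        return dict(zip(self.entries["gene_id"], self.entries["rank"]))

    def score_of(self) -> dict[str, float]:
        return dict(zip(self.entries["gene_id"], self.entries["score"]))


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mwu_compare(
    population_log2_ratios: np.ndarray, hybrid_log2_ratios: np.ndarray
) -> float:
    """Two-sided Mann-Whitney U p-value, hybrid vs population distribution.

    Tie-free inputs with n1*n2 <= 400 use the exact null distribution;
    larger or tied inputs use the normal approximation with tie and
    continuity corrections. Being a rank test, the result is identical on
    the ratio and log2-ratio scales.
    """
    x = np.asarray(population_log2_ratios, dtype=float)
    y = np.asarray(hybrid_log2_ratios, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both input vectors must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0  # all observations tied: no evidence of a shift
    if x.size * y.size <= EXACT_PRODUCT_LIMIT and not _has_ties(x, y):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        y, x, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(res.pvalue)
    if not np.isfinite(p):  # fully degenerate tie structure
        return 1.0
    return min(max(p, 0.0), 1.0)


def mwu_compare_bruteforce(
    population_values: np.ndarray, hybrid_values: np.ndarray
) -> float:
    """Exact two-sided MWU p by enumerating every assignment of the pooled
    values into groups of the observed sizes. O(C(n1+n2, n2)); tie-free
    inputs only. Serves as an independent oracle for :func:`mwu_compare`."""
    x = list(map(float, population_values))
    y = list(map(float, hybrid_values))
    pooled = x + y
    n2 = len(y)

    def u_stat(group2: tuple[float, ...], group1: tuple[float, ...]) -> int:
        return sum(1 for b in group2 for a in group1 if b > a)

    observed = u_stat(tuple(y), tuple(x))
    mean_u = len(x) * n2 / 2.0
    obs_dev = abs(observed - mean_u)
    total = 0
    extreme = 0
    indices = range(len(pooled))
    for comb in itertools.combinations(indices, n2):
        g2 = tuple(pooled[i] for i in comb)
        g1 = tuple(pooled[i] for i in indices if i not in comb)
        total += 1
        if abs(u_stat(g2, g1) - mean_u) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total


def rank_by_mwu(
    profiles: dict[str, PopulationASEProfile],
    records: dict[str, InterspeciesASERecord],
) -> RankedGeneList:
    """MWU ranking over genes present in both inputs; rank 1 = smallest p."""
    genes = [g for g in profiles if g in records]
    dropped = (set(profiles) | set(records)) - set(genes)
    if dropped:
        logger.info("%d genes absent from one input excluded from ranking", len(dropped))
    if not genes:
        raise ValueError("no genes present in both profiles and records")
    pvals = {
        g: mwu_compare(profiles[g].log2_ratios, records[g].hybrid_log2_ratios)
        for g in genes
    }
    df = pd.DataFrame({"gene_id": genes, "mwu_p": [pvals[g] for g in genes]})
    df["score"] = df["mwu_p"]
    df = df.sort_values(["score", "gene_id"], ascending=[True, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedGeneList(df.reset_index(drop=True), "mwu")


def signed_score(mwu_p: float, mean_log2fc: float) -> float:
    """−log10(p) × sign(mean log2FC); 0 when the fold change is exactly 0."""
    if not (0.0 < mwu_p <= 1.0):
        raise ValueError("mwu_p must be in (0, 1]")
    return -math.log10(max(mwu_p, P_FLOOR)) * float(np.sign(mean_log2fc))


def rank_by_signed(
    mwu_list: RankedGeneList, records: dict[str, InterspeciesASERecord]
) -> RankedGeneList:
    """Signed ranking: descending signed score. Genes without a DE fold
    change are excluded (and logged)."""
    rows = []
    excluded = []
    for r in mwu_list.entries.itertuples():
        rec = records.get(r.gene_id)
        if rec is None or rec.mean_log2fc is None:
            excluded.append(r.gene_id)
            continue
        rows.append((r.gene_id, signed_score(r.mwu_p, rec.mean_log2fc), r.mwu_p))
    if excluded:
        logger.info("%d genes lack mean_log2fc; excluded from signed ranking", len(excluded))
    if not rows:
        raise ValueError("no genes with a mean_log2fc available")
    df = pd.DataFrame(rows, columns=["gene_id", "score", "mwu_p"])
    df = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedGeneList(df.reset_index(drop=True), "signed")


def rank_by_de_fdr(records: dict[str, InterspeciesASERecord]) -> RankedGeneList:
    """Traditional ranking: ascending differential-expression FDR."""
    rows = [
        (g, r.de_fdr) for g, r in records.items() if r.de_fdr is not None
    ]
    if not rows:
        raise ValueError("no genes with a de_fdr available")
    df = pd.DataFrame(rows, columns=["gene_id", "score"])
    df["mwu_p"] = np.nan
    df = df.sort_values(["score", "gene_id"], ascending=[True, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedGeneList(df.reset_index(drop=True), "de_fdr")


def diff_in_ranks(mwu_list: RankedGeneList, de_list: RankedGeneList) -> RankedGeneList:
    """Difference-in-ranks list: score = de_rank − mwu_rank, descending.

    A gene the constraint comparison ranks highly (small MWU rank) but the
    DE-FDR ranking buries (large DE rank) gets a large positive score and
    sits at the top.
    """
    mwu_ranks = mwu_list.rank_of()
    de_ranks = de_list.rank_of()
    if set(mwu_ranks) != set(de_ranks):
        diff = sorted(set(mwu_ranks) ^ set(de_ranks))
        raise ValueError(f"gene universes differ; symmetric difference: {diff[:10]}")
    mwu_p = dict(zip(mwu_list.entries["gene_id"], mwu_list.entries["mwu_p"]))
    rows = [
        (g, float(de_ranks[g] - mwu_ranks[g]), mwu_p.get(g, np.nan))
        for g in mwu_ranks
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "score", "mwu_p"])
    df = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedGeneList(df.reset_index(drop=True), "diff_in_ranks")
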