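"""Gene-set sign test for lineage-specific polygenic selection.

In a hybrid, each gene's *cis*-regulatory divergence is (to first
approximation) an independent genetic change, so under neutrality the
direction of allelic bias among the genes driving an enrichment should be
a fair coin. A gene set in which nearly all driving genes are biased
toward the same species is evidence of lineage-specific selection on the
set's expression.

Procedure: take every gene set nominally enriched in the signed GSEA run
(FDR below the eligibility cutoff in at least one time point, with more
than ``min_driving_genes`` leading-edge genes), test each set once at its
lowest-FDR time point, count species-1- vs species-2-biased leading-edge
genes by the sign of the external mean log2 fold change, apply the exact
two-sided binomial test at p = 0.5, and Benjamini-Hochberg-correct across
all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gsea_preranked import EnrichmentRecord
from .interspecies_ase import InterspeciesASERecord

logger = logging.getLogger(__name__)


@dataclass
class SignTestRecord:
    """Directional counts and binomial sign-test result for one gene set."""

    set_name: str
    k_species1: int
    n_total: int
    direction: str  # species1-biased | species2-biased | balanced
    binom_p: float
    bh_q: float
    source_timepoint: str
    significant: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.k_species1 <= self.n_total:
            raise ValueError("need 0 <= k_species1 <= n_total")
        if not 0.0 < self.binom_p <= 1.0:
            raise ValueError("binom_p must be in (0, 1]")


def count_directions(
    leading_edge: Sequence[str], records: Mapping[str, InterspeciesASERecord]
) -> tuple[int, int]:
    """Count species-1- and species-2-biased genes in a leading edge by the
    sign of the mean log2 fold change; exact zeros are excluded (logged)."""
    k1 = k2 = 0
    for gene in leading_edge:
        rec = records.get(gene)
        if rec is None or rec.mean_log2fc is None:
            raise ValueError(f"gene {gene!r} has no mean_log2fc")
        if rec.mean_log2fc > 0:
            k1 += 1
        elif rec.mean_log2fc < 0:
            k2 += 1
        else:
            logger.info("gene %s has mean_log2fc == 0; excluded from counts", gene)
    return k1, k2


def binomial_sign_test(k: int, n: int) -> float:
    """Exact two-sided binomial p-value at success probability 0.5.

    By symmetry this equals 2·P(X >= max(k, n−k)) capped at 1.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need n >= 1 and 0 <= k <= n")
    return float(stats.binomtest(k, n, p=0.5, alternative="two-sided").pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_sign_test(
    enrichments: Mapping[str, Sequence[EnrichmentRecord]],
    records: Mapping[str, Mapping[str, InterspeciesASERecord]],
    fdr_eligibility: float = 0.25,
    min_driving_genes: int = 5,
    bh_threshold: float = 0.1,
) -> list[SignTestRecord]:
    """Apply the sign test across one or more time points.

    ``enrichments`` and ``records`` map time-point label -> GSEA records /
    hybrid ASE records. Each candidate set (GSEA FDR < ``fdr_eligibility``
    somewhere, leading edge larger than ``min_driving_genes``) is tested
    exactly once, at the time point where its FDR is lowest (ties broken by
    the earliest time point in input order).
    """
    if not enrichments:
        raise ValueError("need at least one time point")
    timepoints = list(enrichments)

    best: dict[str, tuple[float, str, EnrichmentRecord]] = {}
    for tp in timepoints:
        for rec in enrichments[tp]:
            cur = best.get(rec.set_name)
            if cur is None or rec.fdr_q < cur[0]:
                best[rec.set_name] = (rec.fdr_q, tp, rec)

    candidates = []
    for name, (fdr, tp, rec) in best.items():
        if fdr < fdr_eligibility and len(rec.leading_edge) > min_driving_genes:
            candidates.append((name, tp, rec))
    if not candidates:
        logger.warning("no gene set passed the sign-test eligibility rules")
        return []
    candidates.sort(key=lambda c: c[0])

    results: list[SignTestRecord] = []
    for name, tp, rec in candidates:
        k1, k2 = count_directions(rec.leading_edge, records[tp])
        n = k1 + k2
        if n == 0:
            logger.warning("set %s: all driving genes have zero fold change", name)
            continue
        direction = (
            "species1-biased" if k1 > k2 else "species2-biased" if k2 > k1 else "balanced"
        )
        results.append(
            SignTestRecord(
                set_name=name,
                k_species1=k1,
                n_total=n,
                direction=direction,
                binom_p=binomial_sign_test(k1, n),
                bh_q=1.0,
                source_timepoint=tp,
            )
        )
    qvals = bh_adjust([r.binom_p for r in results])
    for rec, q in zip(results, qvals):
        rec.bh_q = float(q)
        rec.significant = bool(q < bh_threshold)
    return results


def sign_test_to_frame(results: list[SignTestRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "timepoint": [r.source_timepoint for r in results],
            "k_species1": [r.k_species1 for r in results],
            "n_total": [r.n_total for r in results],
            "direction": [r.direction for r in results],
            "binom_p": [r.binom_p for r in results],
            "bh_q": [r.bh_q for r in results],
            "significant": [r.significant for r in results],
        }
    )
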