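"""Hybrid (between-species) ASE distributions.

In an interspecies hybrid both genomes share one nucleus and one *trans*
environment, so allele-specific read-count differences isolate the *cis*
component of expression divergence. The per-gene hybrid distribution is the
log2 allelic ratio across replicates. Unlike the population pipeline there
is deliberately no per-replicate coverage filter and no median
normalization: extreme allelic skews are expected between species and a
consistent bias is exactly the signal.

Differential-expression summaries (mean log2 fold change and FDR, e.g. from
DESeq2) are external inputs attached to each record, not computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io_formats import AlleleCountTable

logger = logging.getLogger(__name__)


@dataclass
class InterspeciesASERecord:
    """One gene's hybrid ASE replicates plus external DE summary."""

    gene_id: str
    hybrid_log2_ratios: np.ndarray
    mean_log2fc: float | None
    de_fdr: float | None
    mean_count1: float
    mean_count2: float

    def __post_init__(self) -> None:
        self.hybrid_log2_ratios = np.asarray(self.hybrid_log2_ratios, dtype=float)
        if self.hybrid_log2_ratios.size < 1:
            raise ValueError("need at least one hybrid replicate")
        if not np.isfinite(self.hybrid_log2_ratios).all():
            raise ValueError("hybrid_log2_ratios must be finite")
        if self.de_fdr is not None and not (0.0 <= self.de_fdr <= 1.0):
            raise ValueError("de_fdr must be in [0, 1]")

    @property
    def n_replicates(self) -> int:
        return self.hybrid_log2_ratios.size


def build_interspecies_records(
    table: AlleleCountTable,
    de_summary: Mapping[str, tuple[float, float]] | None = None,
    pseudocount: float = 1.0,
) -> dict[str, InterspeciesASERecord]:
    """Per-gene hybrid records: log2((count1+pc)/(count2+pc)) per replicate.

    Every replicate with observed counts is kept regardless of depth.
    Genes missing from ``de_summary`` carry ``None`` markers.
    """
    de_summary = de_summary or {}
    records: dict[str, InterspeciesASERecord] = {}
    for i, gene in enumerate(table.gene_ids):
        c1, c2 = table.counts1[i], table.counts2[i]
        present = ~np.isnan(c1) & ~np.isnan(c2)
        if not present.any():
            logger.warning("gene %s has no observed hybrid replicates; skipped", gene)
            continue
        c1, c2 = c1[present], c2[present]
        log2_ratios = np.log2((c1 + pseudocount) / (c2 + pseudocount))
        l2fc, fdr = de_summary.get(gene, (None, None))
        records[gene] = InterspeciesASERecord(
            gene_id=gene,
            hybrid_log2_ratios=log2_ratios,
            mean_log2fc=l2fc,
            de_fdr=fdr,
            mean_count1=float(c1.mean()),
            mean_count2=float(c2.mean()),
        )
    return records


def filter_expressed(
    records: dict[str, InterspeciesASERecord], min_mean_count: float = 25.0
) -> dict[str, InterspeciesASERecord]:
    """Drop genes lowly expressed in the hybrid: a gene is removed only when
    BOTH alleles' mean counts fall below ``min_mean_count``."""
    if min_mean_count < 0:
        raise ValueError("min_mean_count must be >= 0")
    kept = {
        g: r
        for g, r in records.items()
        if r.mean_count1 >= min_mean_count or r.mean_count2 >= min_mean_count
    }
    logger.info(
        "expression filter (mean count >= %g on either allele): %d/%d genes kept",
        min_mean_count,
        len(kept),
        len(records),
    )
    return kept


def apply_exclusion_list(
    records: dict[str, InterspeciesASERecord], excluded: Iterable[str]
) -> dict[str, InterspeciesASERecord]:
    """Remove listed genes (mapping-bias or structural-artifact lists)."""
    excluded = set(excluded)
    missing = excluded - records.keys()
    if missing:
        logger.warning(
            "%d exclusion ids not present in records (e.g. %s)",
            len(missing),
            sorted(missing)[:3],
        )
    kept = {g: r for g, r in records.items() if g not in excluded}
    logger.info("exclusion list removed %d genes", len(records) - len(kept))
    return kept


def records_to_frame(records: dict[str, InterspeciesASERecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": list(records),
            "n_replicates": [r.n_replicates for r in records.values()],
            "mean_hybrid_log2_ratio": [
                float(r.hybrid_log2_ratios.mean()) for r in records.values()
            ],
            "mean_count1": [r.mean_count1 for r in records.values()],
            "mean_count2": [r.mean_count2 for r in records.values()],
            "mean_log2fc": [r.mean_log2fc for r in records.values()],
            "de_fdr": [r.de_fdr for r in records.values()],
        }
    )
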