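"""Per-gene population allele-specific-expression (ASE) distributions.

The within-species ASE distribution of a gene — the spread of
(allele1 + 1)/(allele2 + 1) read-count ratios across a cohort — serves as
an empirical proxy for evolutionary constraint on the gene's *cis*-regulation:
genes under strong stabilizing selection show narrow ratio distributions,
weakly constrained genes show wide ones.

Pipeline per gene: drop samples with fewer than ``min_reads`` reads from
either allele, add a pseudocount to each allele, form ratios, divide by the
retained-sample median (so the median is exactly 1 and a consistent allelic
bias of the cohort cannot masquerade as divergence), and keep the gene only
if at least ``min_samples`` samples survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import AlleleCountTable

logger = logging.getLogger(__name__)


@dataclass
class PopulationASEProfile:
    """Median-normalized ASE ratios of one gene across a cohort."""

    gene_id: str
    ratios: np.ndarray
    log2_ratios: np.ndarray
    n_samples: int
    ase_variance: float

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.log2_ratios = np.asarray(self.log2_ratios, dtype=float)
        if self.n_samples != self.ratios.size:
            raise ValueError("n_samples != len(ratios)")
        if (self.ratios <= 0).any():
            raise ValueError("ratios must be positive")
        if self.ase_variance < 0:
            raise ValueError("ase_variance must be non-negative")


def compute_ase_ratio(count1: float, count2: float, pseudocount: float = 1.0) -> float:
    """(count1 + pseudocount) / (count2 + pseudocount).

    The pseudocount (default 1 read per allele) keeps the ratio finite and
    positive when one allele has zero reads.
    """
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return (count1 + pseudocount) / (count2 + pseudocount)


def filter_low_coverage(table: AlleleCountTable, min_reads: int = 10) -> np.ndarray:
    """Boolean genes x samples mask: sample retained for a gene iff BOTH
    alleles have at least ``min_reads`` raw reads (pseudocount excluded).

    Masks are per gene: a sample can pass for one gene and fail for another.
    NaN (absent) cells never pass.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    with np.errstate(invalid="ignore"):
        mask = (table.counts1 >= min_reads) & (table.counts2 >= min_reads)
    mask &= ~np.isnan(table.counts1) & ~np.isnan(table.counts2)
    return mask


def normalize_median(ratios: np.ndarray) -> np.ndarray:
    """Divide by the median so the normalized median is 1.

    Even-length inputs use the usual mean-of-middle-two median.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("cannot normalize an empty ratio vector")
    if (ratios <= 0).any():
        raise ValueError("ratios must be positive")
    return ratios / np.median(ratios)


def build_population_profiles(
    table: AlleleCountTable,
    min_reads: int = 10,
    min_samples: int = 50,
    pseudocount: float = 1.0,
    variance_scale: str = "ratio",
) -> dict[str, PopulationASEProfile]:
    """Build a :class:`PopulationASEProfile` for every gene that retains at
    least ``min_samples`` samples after coverage filtering.

    ``variance_scale`` selects whether ``ase_variance`` is the sample
    variance (ddof=1) of the normalized ratios (default) or of their log2.
    """
    if variance_scale not in ("ratio", "log2"):
        raise ValueError("variance_scale must be 'ratio' or 'log2'")
    mask = filter_low_coverage(table, min_reads)
    profiles: dict[str, PopulationASEProfile] = {}
    for i, gene in enumerate(table.gene_ids):
        keep = mask[i]
        n = int(keep.sum())
        if n < min_samples:
            continue
        ratios = (table.counts1[i, keep] + pseudocount) / (
            table.counts2[i, keep] + pseudocount
        )
        ratios = normalize_median(ratios)
        log2_ratios = np.log2(ratios)
        values = ratios if variance_scale == "ratio" else log2_ratios
        variance = float(np.var(values, ddof=1)) if n > 1 else 0.0
        profiles[gene] = PopulationASEProfile(gene, ratios, log2_ratios, n, variance)
    if not profiles:
        logger.warning(
            "no genes retained >= %d samples with >= %d reads per allele",
            min_samples,
            min_reads,
        )
    logger.info("population profiles: %d/%d genes retained", len(profiles), table.n_genes)
    return profiles


def flip_allele_orientation(
    profiles: dict[str, PopulationASEProfile]
) -> dict[str, PopulationASEProfile]:
    """Swap allele roles: reciprocal ratios, re-normalized to median 1.

    Rankings downstream of the population distribution should be nearly
    invariant to which allele is the numerator; this rebuilds the profiles
    in the flipped orientation so that robustness can be measured.
    """
    flipped: dict[str, PopulationASEProfile] = {}
    for gene, p in profiles.items():
        ratios = normalize_median(1.0 / p.ratios)
        log2_ratios = np.log2(ratios)
        variance = float(np.var(ratios, ddof=1)) if p.n_samples > 1 else 0.0
        flipped[gene] = PopulationASEProfile(
            gene, ratios, log2_ratios, p.n_samples, variance
        )
    return flipped


def profiles_to_frame(profiles: dict[str, PopulationASEProfile]):
    """Summary table: gene_id, n_samples, ase_variance."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": list(profiles),
            "n_samples": [p.n_samples for p in profiles.values()],
            "ase_variance": [p.ase_variance for p in profiles.values()],
        }
    )
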