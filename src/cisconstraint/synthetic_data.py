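"""Synthetic allele-count data with the structure the method assumes.

The generator emulates two kinds of experiment:

* a **population cohort** (GTEx-like): per gene g and sample s a total
  depth N_gs is drawn from a log-normal-Poisson depth model, an allele-1
  fraction f_gs from a symmetric Beta(alpha_g, alpha_g), and counts from
  Binomial(N_gs, f_gs). The concentration alpha_g is the per-gene knob for
  *cis*-regulatory constraint: large alpha means tight allelic balance
  (strong constraint), small alpha means overdispersed allelic ratios.
* a **hybrid experiment**: each gene carries a true interspecies shift
  delta_g in log2 units, so the species-1 allele fraction centres on
  2^delta / (1 + 2^delta), jittered per replicate by the same Beta
  dispersion (concentration 2*alpha_g). A replicate-level location test on
  the log2 ratios stands in for an external differential-expression
  summary (mean log2 fold change + BH FDR).

Gene sets can inject a directional shift into disjoint blocks of genes,
creating the ground truth for enrichment and sign-test recovery. All draws
are bit-reproducible given ``SimulationConfig.seed``; independent substreams
(alphas, depths, population counts, hybrid counts, score noise, set
assignment) keep each generator individually deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import AlleleCountTable, GeneSetCollection
from .sign_test import bh_adjust


@dataclass
class GeneSetSpec:
    """One synthetic gene set: size, injected direction (+/-/none), |shift|."""

    name: str
    size: int
    direction: str = "none"  # '+', '-', or 'none'
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("set size must be >= 1")
        if self.direction not in ("+", "-", "none"):
            raise ValueError("direction must be '+', '-', or 'none'")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort + hybrid experiment.

    ``median_depth`` is the median of the log-normal per-gene mean depth
    (reads per gene per sample); per-sample totals are Poisson around it.
    ``alpha_low``/``alpha_high`` bound the log-uniform draw of the per-gene
    Beta concentration when ``alphas`` is not given explicitly.
    """

    n_genes: int = 300
    n_samples: int = 500
    median_depth: float = 100.0
    depth_sigma: float = 0.5
    alpha_low: float = 2.0
    alpha_high: float = 200.0
    alphas: np.ndarray | None = None
    baseline_shifts: np.ndarray | None = None  # log2 units; default all zero
    shift_sd: float = 0.0  # Normal(0, sd) baseline shifts when none given
    n_hybrid_replicates: int = 8
    gene_sets: list[GeneSetSpec] = field(default_factory=list)
    score_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_hybrid_replicates) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.alphas is not None:
            self.alphas = np.asarray(self.alphas, dtype=float)
            if self.alphas.shape != (self.n_genes,):
                raise ValueError("alphas must have length n_genes")
            if (self.alphas <= 0).any():
                raise ValueError("alphas must be positive")
        elif not (0 < self.alpha_low <= self.alpha_high):
            raise ValueError("need 0 < alpha_low <= alpha_high")
        if self.baseline_shifts is not None:
            self.baseline_shifts = np.asarray(self.baseline_shifts, dtype=float)
            if self.baseline_shifts.shape != (self.n_genes,):
                raise ValueError("baseline_shifts must have length n_genes")
        if sum(s.size for s in self.gene_sets) > self.n_genes:
            raise ValueError("gene sets cannot cover more than n_genes genes")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def resolve_alphas(self) -> np.ndarray:
        if self.alphas is not None:
            return self.alphas
        rng = self._rng(0)
        lo, hi = np.log(self.alpha_low), np.log(self.alpha_high)
        return np.exp(rng.uniform(lo, hi, self.n_genes))

    def resolve_depth_means(self) -> np.ndarray:
        rng = self._rng(1)
        return np.exp(rng.normal(np.log(self.median_depth), self.depth_sigma, self.n_genes))

    def resolve_set_assignments(self) -> dict[str, list[str]]:
        """Disjoint member blocks for every configured gene set."""
        genes = self.gene_ids()
        order = self._rng(5).permutation(self.n_genes)
        assignments: dict[str, list[str]] = {}
        cursor = 0
        for spec in self.gene_sets:
            members = [genes[i] for i in order[cursor : cursor + spec.size]]
            assignments[spec.name] = sorted(members)
            cursor += spec.size
        return assignments

    def resolve_shifts(self) -> np.ndarray:
        """Per-gene true log2 interspecies shift, with set injections applied."""
        if self.baseline_shifts is not None:
            shifts = self.baseline_shifts.copy()
        elif self.shift_sd > 0:
            shifts = self._rng(6).normal(0.0, self.shift_sd, self.n_genes)
        else:
            shifts = np.zeros(self.n_genes)
        index = {g: i for i, g in enumerate(self.gene_ids())}
        assignments = self.resolve_set_assignments()
        for spec in self.gene_sets:
            if spec.direction == "none":
                continue
            sign = 1.0 if spec.direction == "+" else -1.0
            for g in assignments[spec.name]:
                shifts[index[g]] = sign * spec.shift
        return shifts


def generate_population(config: SimulationConfig) -> AlleleCountTable:
    """Beta-binomial population cohort; deterministic given ``config.seed``."""
    alphas = config.resolve_alphas()
    depth_means = config.resolve_depth_means()
    rng = config._rng(2)
    shape = (config.n_genes, config.n_samples)
    depth = rng.poisson(depth_means[:, None], shape)
    frac = rng.beta(alphas[:, None], alphas[:, None], shape)
    counts1 = rng.binomial(depth, frac)
    counts2 = depth - counts1
    samples = [f"s{j:04d}" for j in range(1, config.n_samples + 1)]
    return AlleleCountTable(config.gene_ids(), samples, counts1.astype(float), counts2.astype(float))


def generate_hybrid(
    config: SimulationConfig,
) -> tuple[AlleleCountTable, dict[str, tuple[float, float]]]:
    """Hybrid replicate counts plus a surrogate DE summary.

    The DE surrogate is a per-gene one-sample t-test of the replicate log2
    ratios against 0, BH-corrected across genes — a stand-in for an
    external differential-expression analysis.
    """
    alphas = config.resolve_alphas()
    depth_means = config.resolve_depth_means()
    shifts = config.resolve_shifts()
    rng = config._rng(3)
    n_rep = config.n_hybrid_replicates
    shape = (config.n_genes, n_rep)
    p_true = 2.0**shifts / (1.0 + 2.0**shifts)
    conc = 2.0 * alphas
    a = conc * p_true
    b = conc * (1.0 - p_true)
    depth = rng.poisson(depth_means[:, None], shape)
    frac = rng.beta(a[:, None], b[:, None], shape)
    counts1 = rng.binomial(depth, frac)
    counts2 = depth - counts1
    replicates = [f"rep{j:02d}" for j in range(1, n_rep + 1)]
    table = AlleleCountTable(
        config.gene_ids(), replicates, counts1.astype(float), counts2.astype(float)
    )

    log2_ratios = np.log2((counts1 + 1.0) / (counts2 + 1.0))
    mean_l2fc = log2_ratios.mean(axis=1)
    if n_rep > 1:
        tres = stats.ttest_1samp(log2_ratios, 0.0, axis=1)
        pvals = np.where(np.isfinite(tres.pvalue), tres.pvalue, 1.0)
    else:
        pvals = np.ones(config.n_genes)
    fdrs = bh_adjust(pvals)
    de_summary = {
        g: (float(mean_l2fc[i]), float(fdrs[i]))
        for i, g in enumerate(config.gene_ids())
    }
    return table, de_summary


def generate_constraint_scores(config: SimulationConfig):
    """Constraint scores (haploinsufficiency-like, in [0, 1]) increasing in
    the generator's concentration alpha, plus a depth-proportional
    expression summary. With ``score_noise`` 0 the score is a strictly
    monotone function of alpha."""
    from .validation import ConstraintScoreTable

    alphas = config.resolve_alphas()
    depth_means = config.resolve_depth_means()
    mid = float(np.sqrt(config.alpha_low * config.alpha_high))
    score = alphas / (alphas + mid)
    if config.score_noise > 0:
        score = score + config._rng(4).normal(0.0, config.score_noise, config.n_genes)
        score = np.clip(score, 0.0, 1.0)
    return ConstraintScoreTable(
        dict(zip(config.gene_ids(), zip(score.tolist(), depth_means.tolist())))
    )


def default_cohort(seed: int = 0, n_genes: int = 500) -> SimulationConfig:
    """The package's reference cohort: 2000 samples per gene at median depth
    100, per-gene constraint spanning two orders of magnitude (alpha 2-200)
    and interspecies shifts of realistic size (sd 0.5 log2 units).

    Population ASE panels of the kind this method consumes have thousands
    of quantifiable samples per gene; the sample count matters because the
    symmetry of the empirical ASE distribution around its median — and with
    it the allele-orientation invariance of downstream rankings — improves
    as the cohort grows. The gene count is a desk-scale stand-in for the
    ~10,000-gene lists the method is run on in practice."""
    return SimulationConfig(
        n_genes=n_genes, n_samples=2000, median_depth=100.0, shift_sd=0.5, seed=seed
    )


def constrained_shift_cohort(seed: int = 0) -> SimulationConfig:
    """Parameter-recovery conditions: 100 genes all carrying the same
    interspecies shift (0.5 log2), half with tight allelic constraint
    (alpha 200), half overdispersed (alpha 2); 500 samples, depth 100.
    The first 50 genes are the constrained class."""
    alphas = np.concatenate([np.full(50, 200.0), np.full(50, 2.0)])
    return SimulationConfig(
        n_genes=100,
        n_samples=500,
        median_depth=100.0,
        depth_sigma=0.0,
        alphas=alphas,
        baseline_shifts=np.full(100, 0.5),
        seed=seed,
    )


def downsample_cohort(seed: int = 0) -> SimulationConfig:
    """Down-sampling conditions: 600 samples so the grid [600, 100, 25]
    spans full-cohort to sparse coverage; moderate depth spread."""
    return SimulationConfig(
        n_genes=300, n_samples=600, median_depth=100.0, depth_sigma=0.3, seed=seed
    )


def neutral_null_cohort(seed: int = 0, n_sets: int = 20, set_size: int = 12) -> SimulationConfig:
    """No injected direction anywhere: every gene's shift is 0 and all gene
    sets are random blocks, for false-discovery smoke tests."""
    sets = [GeneSetSpec(f"null{i:02d}", set_size) for i in range(n_sets)]
    return SimulationConfig(
        n_genes=max(300, n_sets * set_size),
        n_samples=200,
        median_depth=100.0,
        gene_sets=sets,
        seed=seed,
    )


def generate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    assignments = config.resolve_set_assignments()
    if not assignments:
        raise ValueError("config defines no gene sets")
    source = {spec.name: f"synthetic:{spec.direction}{spec.shift:g}" for spec in config.gene_sets}
    return GeneSetCollection(assignments, source)
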