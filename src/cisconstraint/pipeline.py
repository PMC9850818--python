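"""End-to-end orchestration: simulate/load -> population profiles -> hybrid
records -> rankings -> GSEA -> sign test (-> validation), with one shared
config, per-stage logging, and a JSON run manifest.

Threshold defaults are the method's published operating point: 10 reads per
allele, 50 samples, pseudocount 1, 25 mean hybrid counts, GSEA with 1000
gene permutations (seed 6, set sizes 10-300), enrichment eligibility
FDR < 0.25 with more than 5 driving genes, and sign-test significance at
BH FDR < 0.1.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .constraint_ranking import diff_in_ranks, rank_by_de_fdr, rank_by_mwu, rank_by_signed
from .gsea_preranked import enrichment_to_frame, gsea_preranked
from .interspecies_ase import (
    apply_exclusion_list,
    build_interspecies_records,
    filter_expressed,
    records_to_frame,
)
from .io_formats import (
    read_allele_counts,
    read_de_summary,
    read_exclusion_list,
    read_gmt,
    write_allele_counts,
    write_de_summary,
    write_gmt,
    write_table,
)
from .population_ase import build_population_profiles, profiles_to_frame
from .sign_test import run_sign_test, sign_test_to_frame
from .synthetic_data import (
    GeneSetSpec,
    SimulationConfig,
    generate_constraint_scores,
    generate_gene_sets,
    generate_hybrid,
    generate_population,
)
from .validation import ConstraintScoreTable, constraint_correlation

logger = logging.getLogger(__name__)

# fixed offsets deriving per-stage seeds from the global one
SIM_SEED_OFFSET = 0
VALIDATION_SEED_OFFSET = 17


@dataclass
class PipelineConfig:
    """All thresholds and paths for one pipeline run."""

    # population stage
    min_reads: int = 10
    min_samples: int = 50
    pseudocount: float = 1.0
    variance_scale: str = "ratio"
    # hybrid stage
    min_mean_count: float = 25.0
    # gsea stage
    nperm: int = 1000
    gsea_seed: int = 6
    min_size: int = 10
    max_size: int = 300
    ranking: str = "signed"  # ranking fed to GSEA: mwu | signed | diff
    # sign-test stage
    gsea_fdr: float = 0.25
    min_driving_genes: int = 5
    bh_threshold: float = 0.1
    # inputs (either simulate or load)
    simulate: SimulationConfig | None = None
    population_path: str | None = None
    population_dialect: str = "paired-column"
    hybrid_path: str | None = None
    hybrid_dialect: str = "paired-column"
    de_summary_path: str | None = None
    gmt_path: str | None = None
    exclude_path: str | None = None
    scores_path: str | None = None
    # run control
    seed: int = 0
    outdir: str = "cisconstraint_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            sets = [GeneSetSpec(**s) for s in sim.pop("gene_sets", [])]
            cfg.simulate = SimulationConfig(gene_sets=sets, **sim)
        return cfg

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = d["simulate"]
            for key in ("alphas", "baseline_shifts"):
                if sim.get(key) is not None:
                    sim[key] = list(map(float, sim[key]))
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage in order, writing result TSVs and a
    manifest under ``config.outdir``. Returns a summary dict of outputs.

    Raises with the failing stage named; the CLI maps that to a nonzero
    exit code.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed + SIM_SEED_OFFSET)
            logger.info("stage simulate: %d genes, %d samples", sim.n_genes, sim.n_samples)
            population = generate_population(sim)
            hybrid, de_summary = generate_hybrid(sim)
            collection = generate_gene_sets(sim) if sim.gene_sets else None
            scores = generate_constraint_scores(sim)
            write_allele_counts(population, out / "population_counts.tsv")
            write_allele_counts(hybrid, out / "hybrid_counts.tsv")
            write_de_summary(de_summary, out / "de_summary.tsv")
            scores.to_tsv(out / "constraint_scores.tsv")
            if collection is not None:
                write_gmt(collection, out / "gene_sets.gmt")
        else:
            if not (config.population_path and config.hybrid_path):
                raise ValueError("need population_path and hybrid_path (or a simulate block)")
            population = read_allele_counts(config.population_path, config.population_dialect)
            hybrid = read_allele_counts(config.hybrid_path, config.hybrid_dialect)
            de_summary = (
                read_de_summary(config.de_summary_path) if config.de_summary_path else {}
            )
            collection = read_gmt(config.gmt_path) if config.gmt_path else None
            scores = (
                ConstraintScoreTable.from_tsv(config.scores_path)
                if config.scores_path
                else None
            )

        stage = "population-dist"
        profiles = build_population_profiles(
            population,
            min_reads=config.min_reads,
            min_samples=config.min_samples,
            pseudocount=config.pseudocount,
            variance_scale=config.variance_scale,
        )
        logger.info("stage %s: %d genes in, %d retained", stage, population.n_genes, len(profiles))
        write_table(profiles_to_frame(profiles), out / "population_profiles.tsv")

        stage = "hybrid-ase"
        records = build_interspecies_records(hybrid, de_summary, config.pseudocount)
        records = filter_expressed(records, config.min_mean_count)
        if config.exclude_path:
            records = apply_exclusion_list(records, read_exclusion_list(config.exclude_path))
        logger.info("stage %s: %d genes in, %d retained", stage, hybrid.n_genes, len(records))
        write_table(records_to_frame(records), out / "hybrid_records.tsv")

        stage = "rank"
        mwu_list = rank_by_mwu(profiles, records)
        write_table(mwu_list.entries, out / "ranking_mwu.tsv")
        rankings = {"mwu": mwu_list}
        if any(r.mean_log2fc is not None for r in records.values()):
            signed_list = rank_by_signed(mwu_list, records)
            write_table(signed_list.entries, out / "ranking_signed.tsv")
            rankings["signed"] = signed_list
        if any(r.de_fdr is not None for r in records.values()):
            universe = set(mwu_list.gene_ids)
            de_list = rank_by_de_fdr(
                {g: r for g, r in records.items() if g in universe}
            )
            if set(de_list.gene_ids) == universe:
                diff_list = diff_in_ranks(mwu_list, de_list)
                write_table(diff_list.entries, out / "ranking_diff_in_ranks.tsv")
                rankings["diff"] = diff_list
        logger.info("stage %s: rankings over %d genes", stage, len(mwu_list))
        summary["n_ranked_genes"] = len(mwu_list)

        if collection is not None:
            stage = "gsea"
            ranked = rankings.get(config.ranking, rankings["mwu"])
            enrichments = gsea_preranked(
                ranked,
                collection,
                n_perm=config.nperm,
                seed=config.gsea_seed,
                min_size=config.min_size,
                max_size=config.max_size,
            )
            write_table(enrichment_to_frame(enrichments), out / "enrichment.tsv")
            logger.info("stage %s: %d sets scored", stage, len(enrichments))
            summary["n_enriched_sets"] = len(enrichments)

            stage = "signtest"
            results = run_sign_test(
                {"t0": enrichments},
                {"t0": records},
                fdr_eligibility=config.gsea_fdr,
                min_driving_genes=config.min_driving_genes,
                bh_threshold=config.bh_threshold,
            )
            write_table(sign_test_to_frame(results), out / "signtest.tsv")
            logger.info("stage %s: %d sets tested", stage, len(results))
            summary["n_sign_tested_sets"] = len(results)
            summary["n_significant_sets"] = sum(r.significant for r in results)

        if scores is not None and profiles:
            stage = "validate"
            try:
                rho, p, n = constraint_correlation(profiles, scores)
                summary["constraint_rho"] = rho
                summary["constraint_p"] = p
                summary["constraint_n_genes"] = n
                logger.info("stage %s: Spearman rho = %.3f (p = %.3g, n = %d)", stage, rho, p, n)
            except ValueError as exc:
                logger.warning("stage %s skipped: %s", stage, exc)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "package": "cisconstraint",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_manifest(),
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
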