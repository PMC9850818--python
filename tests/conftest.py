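import numpy as np
import pandas as pd
import pytest

import cisconstraint as cc
from cisconstraint.constraint_ranking import RankedGeneList
from cisconstraint.synthetic_data import constrained_shift_cohort, default_cohort


@pytest.fixture
def small_table():
    """2 genes x 3 samples with simple counts."""
    return cc.AlleleCountTable(
        gene_ids=["geneA", "geneB"],
        sample_ids=["s1", "s2", "s3"],
        counts1=np.array([[3.0, 4.0, 10.0], [0.0, 50.0, 100.0]]),
        counts2=np.array([[5.0, 2.0, 10.0], [1.0, 60.0, 90.0]]),
    )


@pytest.fixture
def graded_ranking():
    """5 genes with strictly decreasing scores 5..1 (g1 at the top)."""
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(1, 6)],
            "score": [5.0, 4.0, 3.0, 2.0, 1.0],
            "mwu_p": np.nan,
            "rank": np.arange(1, 6),
        }
    )
    return RankedGeneList(df, "signed")


def make_ranking(genes, scores, kind="signed"):
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    df = pd.DataFrame(
        {
            "gene_id": [genes[i] for i in order],
            "score": [float(scores[i]) for i in order],
            "mwu_p": np.nan,
            "rank": np.arange(1, len(genes) + 1),
        }
    )
    return RankedGeneList(df, kind)


@pytest.fixture(scope="session")
def default_cohort_run():
    """Reference cohort built through the population + hybrid stages."""
    cfg = default_cohort(seed=0)
    population = cc.generate_population(cfg)
    hybrid, de_summary = cc.generate_hybrid(cfg)
    profiles = cc.build_population_profiles(population)
    records = cc.filter_expressed(cc.build_interspecies_records(hybrid, de_summary))
    return cfg, population, profiles, records


@pytest.fixture(scope="session")
def constrained_cohort_run():
    """Parameter-recovery cohort: 50 constrained + 50 unconstrained genes,
    all with the same 0.5 log2 interspecies shift."""
    cfg = constrained_shift_cohort(seed=0)
    population = cc.generate_population(cfg)
    hybrid, de_summary = cc.generate_hybrid(cfg)
    profiles = cc.build_population_profiles(population)
    records = cc.filter_expressed(cc.build_interspecies_records(hybrid, de_summary))
    return cfg, profiles, records
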