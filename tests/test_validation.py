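import numpy as np
import pytest

import cisconstraint as cc
from cisconstraint.population_ase import PopulationASEProfile
from cisconstraint.synthetic_data import SimulationConfig, downsample_cohort


def _profile(gene, variance, n=50):
    ratios = np.ones(n)
    return PopulationASEProfile(gene, ratios, np.zeros(n), n, variance)


def _scores(mapping):
    return cc.ConstraintScoreTable(mapping)


class TestConstraintCorrelation:
    def test_perfectly_decreasing_gives_minus_one(self):
        profiles = {f"g{i}": _profile(f"g{i}", variance=1.0 - 0.2 * i) for i in range(5)}
        scores = _scores({f"g{i}": (0.1 + 0.2 * i, 10.0) for i in range(5)})
        rho, p, n = cc.constraint_correlation(profiles, scores)
        assert rho == pytest.approx(-1.0) and n == 5

    def test_constant_score_errors(self):
        profiles = {f"g{i}": _profile(f"g{i}", variance=0.1 * i) for i in range(5)}
        scores = _scores({f"g{i}": (0.5, 10.0) for i in range(5)})
        with pytest.raises(ValueError, match="constant"):
            cc.constraint_correlation(profiles, scores)

    def test_too_few_overlapping_genes_errors(self):
        profiles = {"g0": _profile("g0", 0.1), "g1": _profile("g1", 0.2)}
        scores = _scores({"g0": (0.5, 1.0), "g1": (0.6, 1.0)})
        with pytest.raises(ValueError):
            cc.constraint_correlation(profiles, scores)

    def test_synthetic_cohort_negative_correlation(self):
        """Constraint scores increase with the generator's concentration, so
        measured ASE variance must correlate negatively with them."""
        cfg = SimulationConfig(n_genes=200, n_samples=150, seed=4)
        profiles = cc.build_population_profiles(cc.generate_population(cfg))
        scores = cc.generate_constraint_scores(cfg)
        rho, p, n = cc.constraint_correlation(profiles, scores)
        assert rho < 0 and p < 0.01


class TestDownsampleExperiment:
    def test_full_draw_single_rep_equals_full_data(self):
        cfg = SimulationConfig(n_genes=60, n_samples=80, median_depth=120.0, seed=6)
        table = cc.generate_population(cfg)
        scores = cc.generate_constraint_scores(cfg)
        df = cc.downsample_experiment(table, scores, n_grid=[80], reps=1, seed=0)
        profiles = cc.build_population_profiles(table, min_samples=80)
        rho_full, _, _ = cc.constraint_correlation(
            {g: profiles[g] for g in profiles}, scores
        )
        # only genes quantifiable in all 80 samples enter; recompute on them
        assert df.loc[0, "n"] == 80
        assert df.loc[0, "mean_rho"] == pytest.approx(rho_full, abs=0.05)

    def test_reproducible_given_seed(self):
        cfg = downsample_cohort(seed=1)
        table = cc.generate_population(cfg)
        scores = cc.generate_constraint_scores(cfg)
        a = cc.downsample_experiment(table, scores, n_grid=[100, 25], reps=3, seed=9)
        b = cc.downsample_experiment(table, scores, n_grid=[100, 25], reps=3, seed=9)
        assert a.equals(b)

    def test_unsorted_grid_rejected(self):
        cfg = SimulationConfig(n_genes=5, n_samples=30, seed=0)
        table = cc.generate_population(cfg)
        scores = cc.generate_constraint_scores(cfg)
        with pytest.raises(ValueError):
            cc.downsample_experiment(table, scores, n_grid=[10, 25], reps=1)


class TestExpressionMatched:
    def test_identical_variances_give_zero_t(self):
        profiles = {f"g{i:03d}": _profile(f"g{i:03d}", 0.5) for i in range(40)}
        scores = _scores(
            {f"g{i:03d}": (i / 40.0, float(i % 7)) for i in range(40)}
        )
        diffs, t, p = cc.expression_matched_comparison(profiles, scores, n_top=10)
        assert np.allclose(diffs, 0.0)
        assert np.isnan(t) or abs(t) < 1e-9

    def test_insufficient_genes_errors(self):
        profiles = {f"g{i}": _profile(f"g{i}", 0.5) for i in range(10)}
        scores = _scores({f"g{i}": (i / 10, 1.0) for i in range(10)})
        with pytest.raises(ValueError, match="12"):
            cc.expression_matched_comparison(profiles, scores, n_top=6)

    def test_constrained_genes_have_lower_variance_at_matched_depth(self):
        """High-constraint genes generated with tight allelic dispersion at
        the same depth: paired variance differences are negative."""
        n = 200
        alphas = np.concatenate([np.full(n // 2, 100.0), np.full(n // 2, 10.0)])
        cfg = SimulationConfig(
            n_genes=n, n_samples=120, median_depth=100.0, depth_sigma=0.0,
            alphas=alphas, score_noise=0.0, seed=13,
        )
        profiles = cc.build_population_profiles(cc.generate_population(cfg))
        scores = cc.generate_constraint_scores(cfg)
        diffs, t, p = cc.expression_matched_comparison(profiles, scores, n_top=50)
        assert diffs.mean() < 0
        assert t < 0 and p < 0.01

    def test_invariant_to_gene_input_order(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:03d}" for i in range(60)]
        profiles = {g: _profile(g, float(rng.uniform(0, 1))) for g in genes}
        scores = _scores({g: (float(rng.uniform(0, 1)), float(rng.uniform(1, 9))) for g in genes})
        shuffled_profiles = {g: profiles[g] for g in reversed(genes)}
        d1, t1, p1 = cc.expression_matched_comparison(profiles, scores, n_top=20)
        d2, t2, p2 = cc.expression_matched_comparison(shuffled_profiles, scores, n_top=20)
        np.testing.assert_allclose(d1, d2)
        assert t1 == pytest.approx(t2)


class TestCohortSplit:
    def _ranking_fn(self, records):
        return lambda profiles: cc.rank_by_mwu(profiles, records)

    def test_identical_partitions_give_rho_one(self):
        cfg = SimulationConfig(n_genes=60, n_samples=240, shift_sd=0.5, seed=3)
        table = cc.generate_population(cfg)
        hybrid, de = cc.generate_hybrid(cfg)
        records = cc.build_interspecies_records(hybrid, de)
        # duplicate every sample into both partitions
        doubled = cc.AlleleCountTable(
            list(table.gene_ids),
            [f"{s}_p{p}" for p in (0, 1) for s in table.sample_ids],
            np.hstack([table.counts1, table.counts1]),
            np.hstack([table.counts2, table.counts2]),
        )
        split = [0] * table.n_samples + [1] * table.n_samples
        rho, p, n = cc.cohort_split_robustness(
            doubled, split, self._ranking_fn(records), min_samples=50
        )
        assert rho == pytest.approx(1.0)

    def test_random_split_highly_correlated(self, default_cohort_run):
        """50/50 split of the reference cohort: the two half-cohort rankings
        agree closely (within-species variance is a stable gene property)."""
        cfg, population, _, records = default_cohort_run
        rng = np.random.default_rng(10)
        split = rng.integers(0, 2, population.n_samples)
        rho, p, n = cc.cohort_split_robustness(
            population, split, self._ranking_fn(records)
        )
        assert rho >= 0.9 and n >= 200

    def test_empty_partition_errors(self, small_table):
        with pytest.raises(ValueError):
            cc.cohort_split_robustness(
                small_table, [0, 0, 0], lambda profiles: None, min_samples=1
            )
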