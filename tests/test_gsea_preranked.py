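import numpy as np
import pytest
from scipy import stats

import cisconstraint as cc
from cisconstraint.io_formats import GeneSetCollection

from conftest import make_ranking


def brute_force_es(ranked, gene_set, weight=1.0):
    """Direct O(N*|S|) evaluation of the weighted-KS enrichment score."""
    genes = ranked.gene_ids
    scores = np.asarray(ranked.entries["score"], dtype=float)
    hit = np.array([g in gene_set for g in genes])
    w = np.abs(scores) ** weight
    nr = w[hit].sum()
    n_miss = len(genes) - hit.sum()
    running = 0.0
    hi = lo = 0.0
    for i in range(len(genes)):
        if hit[i]:
            running += (w[i] / nr) if nr > 0 else 1.0 / hit.sum()
        else:
            running -= 1.0 / n_miss
        hi = max(hi, running)
        lo = min(lo, running)
    # exact |max| == |min| ties resolve to the positive deviation
    return hi if hi >= -lo - 1e-12 else lo


class TestEnrichmentScore:
    def test_top_block_reaches_one(self, graded_ranking):
        es, peak, leading, _ = cc.enrichment_score(graded_ranking, {"g1", "g2"})
        assert es == pytest.approx(1.0)
        assert peak == 2 and leading == ["g1", "g2"]

    def test_bottom_singleton_reaches_minus_one(self, graded_ranking):
        es, peak, leading, _ = cc.enrichment_score(graded_ranking, {"g5"})
        assert es == pytest.approx(-1.0)
        assert leading == ["g5"]

    def test_split_set_weighted_peak(self, graded_ranking):
        es, peak, leading, _ = cc.enrichment_score(graded_ranking, {"g1", "g5"})
        assert es == pytest.approx(5 / 6)
        assert peak == 1 and leading == ["g1"]

    def test_no_member_in_list_errors(self, graded_ranking):
        with pytest.raises(ValueError):
            cc.enrichment_score(graded_ranking, {"absent"})

    def test_increment_normalization(self, graded_ranking):
        """Hit increments sum to 1 and miss decrements sum to 1."""
        for members in ({"g1", "g3"}, {"g2", "g4", "g5"}):
            _, _, _, running = cc.enrichment_score(graded_ranking, members)
            inc = np.diff(np.concatenate([[0.0], running]))
            assert inc[inc > 0].sum() == pytest.approx(1.0)
            assert -inc[inc < 0].sum() == pytest.approx(1.0)

    def test_weight_zero_is_classical_ks(self):
        """With weight 0 the statistic depends only on member positions."""
        rng = np.random.default_rng(8)
        genes = [f"g{i:02d}" for i in range(30)]
        ranked_a = make_ranking(genes, np.sort(rng.normal(0, 1, 30))[::-1])
        ranked_b = make_ranking(genes, np.sort(rng.lognormal(0, 1, 30))[::-1])
        members = set(rng.choice(genes, 6, replace=False))
        es_a, _, _, _ = cc.enrichment_score(ranked_a, members, weight=0.0)
        es_b, _, _, _ = cc.enrichment_score(ranked_b, members, weight=0.0)
        assert es_a == pytest.approx(es_b)

    def test_reversal_negates_classical_es(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i:02d}" for i in range(20)]
        scores = np.sort(rng.normal(0, 1, 20))[::-1]
        fwd = make_ranking(genes, scores)
        rev = make_ranking(genes[::-1], scores)  # same scores, reversed genes
        for _ in range(5):
            members = set(rng.choice(genes, 5, replace=False))
            es_f, _, _, _ = cc.enrichment_score(fwd, members, weight=0.0)
            es_r, _, _, _ = cc.enrichment_score(rev, members, weight=0.0)
            assert es_f == pytest.approx(-es_r)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(8, 51))
            k = int(rng.integers(2, min(n - 1, 10)))
            genes = [f"g{i:03d}" for i in range(n)]
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            ranked = make_ranking(genes, scores)
            members = set(rng.choice(genes, k, replace=False))
            es, _, _, _ = cc.enrichment_score(ranked, members)
            assert es == pytest.approx(brute_force_es(ranked, members), abs=1e-9)

    def test_matches_external_reference_implementation(self):
        """Spot-check the weighted-KS score against gseapy's prerank ES."""
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 60
        genes = [f"G{i:03d}" for i in range(n)]
        scores = np.sort(rng.normal(0, 2, n))[::-1]
        sets = {f"S{i}": list(rng.choice(genes, 12, replace=False)) for i in range(4)}
        res = gseapy.prerank(
            rnk=pd.Series(scores, index=genes), gene_sets=sets, permutation_num=10,
            seed=6, min_size=5, max_size=50, outdir=None, no_plot=True, threads=1,
        )
        ranked = make_ranking(genes, scores)
        for _, row in res.res2d.iterrows():
            es, _, _, _ = cc.enrichment_score(ranked, set(sets[row["Term"]]))
            assert es == pytest.approx(float(row["ES"]), abs=1e-9)


class TestGseaPreranked:
    def _graded_instance(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n)]
        scores = np.sort(rng.normal(0, 2, n))[::-1]
        return genes, make_ranking(genes, scores)

    def test_top_block_set_clears_eligibility_fdr(self):
        genes, ranked = self._graded_instance()
        coll = GeneSetCollection({"top": genes[:10], "rand": genes[30:42]})
        records = {r.set_name: r for r in cc.gsea_preranked(ranked, coll, n_perm=500)}
        assert records["top"].fdr_q < 0.25
        assert records["top"].es > 0.9

    def test_same_seed_bit_identical(self):
        genes, ranked = self._graded_instance(seed=2)
        coll = GeneSetCollection(
            {f"S{i}": genes[i * 12 : i * 12 + 12] for i in range(4)}
        )
        a = cc.gsea_preranked(ranked, coll, n_perm=200, seed=6)
        b = cc.gsea_preranked(ranked, coll, n_perm=200, seed=6)
        for x, y in zip(a, b):
            assert (x.es, x.nes, x.nominal_p, x.fdr_q, x.peak_rank) == (
                y.es, y.nes, y.nominal_p, y.fdr_q, y.peak_rank
            )
            assert x.leading_edge == y.leading_edge

    def test_null_pvalues_roughly_uniform(self):
        """Random sets on a random ranking: nominal p has no systematic
        enrichment (KS test against uniform not rejected at 0.01)."""
        rng = np.random.default_rng(123)
        n = 300
        genes = [f"g{i:03d}" for i in range(n)]
        scores = rng.normal(0, 1, n)
        order = np.argsort(-scores)
        ranked = make_ranking([genes[i] for i in order], scores[order])
        coll = GeneSetCollection(
            {f"S{i:02d}": list(rng.choice(genes, 15, replace=False)) for i in range(50)}
        )
        records = cc.gsea_preranked(ranked, coll, n_perm=1000, seed=6)
        pvals = [r.nominal_p for r in records]
        assert len(pvals) == 50
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_leading_edge_consistent_with_peak(self):
        genes, ranked = self._graded_instance(seed=5)
        coll = GeneSetCollection({"mid": genes[20:35]})
        rec = cc.gsea_preranked(ranked, coll, n_perm=100, min_size=5)[0]
        rank_of = {g: i + 1 for i, g in enumerate(ranked.gene_ids)}
        if rec.es > 0:
            assert all(rank_of[g] <= rec.peak_rank for g in rec.leading_edge)
        else:
            assert all(rank_of[g] >= rec.peak_rank for g in rec.leading_edge)
        assert set(rec.leading_edge) <= set(coll.sets["mid"])

    def test_size_filter_and_errors(self):
        genes, ranked = self._graded_instance()
        coll = GeneSetCollection({"tiny": genes[:3], "ok": genes[5:20]})
        records = cc.gsea_preranked(ranked, coll, n_perm=50, min_size=10, max_size=300)
        assert [r.set_name for r in records] == ["ok"]
        with pytest.raises(ValueError):
            cc.gsea_preranked(ranked, coll, n_perm=0)
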