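"""Robustness checks on the population ASE distribution.

Three diagnostics a new cohort should pass before its ASE variance is
trusted as a constraint measure: (1) rankings barely change when the
allele orientation of the population ratios is flipped; (2) a random 50/50
cohort split reproduces the ranking; (3) the constraint correlation decays
smoothly — not catastrophically — as per-gene sample counts shrink.
"""

import numpy as np
from scipy import stats

import cisconstraint as cc
from cisconstraint.synthetic_data import default_cohort, downsample_cohort

cfg = default_cohort(seed=3, n_genes=200)
population = cc.generate_population(cfg)
hybrid, de_summary = cc.generate_hybrid(cfg)
profiles = cc.build_population_profiles(population)
records = cc.filter_expressed(cc.build_interspecies_records(hybrid, de_summary))

fwd = cc.rank_by_mwu(profiles, records)
flp = cc.rank_by_mwu(cc.flip_allele_orientation(profiles), records)
ra, rb = fwd.rank_of(), flp.rank_of()
common = sorted(set(ra) & set(rb))
rho_flip, _ = stats.spearmanr([ra[g] for g in common], [rb[g] for g in common])
print(f"allele-flip rank correlation: rho = {rho_flip:.4f} over {len(common)} genes")

split = np.random.default_rng(0).integers(0, 2, population.n_samples)
rho_split, _, n = cc.cohort_split_robustness(
    population, split, lambda p: cc.rank_by_mwu(p, records)
)
print(f"random 50/50 cohort split: rho = {rho_split:.4f} over {n} genes")

dcfg = downsample_cohort(seed=3)
table = cc.generate_population(dcfg)
scores = cc.generate_constraint_scores(dcfg)
df = cc.downsample_experiment(table, scores, n_grid=[600, 100, 25], reps=10, seed=5)
for row in df.itertuples():
    print(f"  n = {row.n:4d} samples/gene: mean |rho| with constraint = {row.mean_abs_rho:.3f}")
print("correlations near 1 across checks mean the variance estimate, not noise, drives ranks")
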