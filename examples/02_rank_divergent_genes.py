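"""Constraint-aware gene ranking.

Two classes of genes carry the same 0.5-log2 interspecies shift, but one
class has tightly constrained within-species ASE and the other is highly
variable. A traditional fold-change ranking cannot tell them apart; the
Mann-Whitney comparison of hybrid vs population ASE puts the constrained
ones on top, because their shift stands outside within-species variation.
"""

from scipy import stats

import cisconstraint as cc
from cisconstraint.synthetic_data import constrained_shift_cohort

cfg = constrained_shift_cohort(seed=1)
population = cc.generate_population(cfg)
hybrid, de_summary = cc.generate_hybrid(cfg)

profiles = cc.build_population_profiles(population)
records = cc.filter_expressed(cc.build_interspecies_records(hybrid, de_summary))
ranked = cc.rank_by_mwu(profiles, records)

constrained = set(cfg.gene_ids()[:50])  # alpha = 200; the rest have alpha = 2
ranks = ranked.rank_of()
pos = [-ranks[g] for g in ranks if g in constrained]
neg = [-ranks[g] for g in ranks if g not in constrained]
auc = stats.mannwhitneyu(pos, neg, alternative="greater").statistic / (len(pos) * len(neg))

print("top 5 genes by MWU p-value:")
for row in ranked.entries.head(5).itertuples():
    tag = "constrained" if row.gene_id in constrained else "unconstrained"
    print(f"  rank {row.rank}: {row.gene_id}  p = {row.mwu_p:.2e}  ({tag})")
print(f"AUC separating constrained from unconstrained shifted genes: {auc:.3f}")
print("AUC near 1: identical fold changes, but only constrained genes rank highly")
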