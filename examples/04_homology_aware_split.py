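"""Temporal test split plus homology-clustered cross-validation folds.

The most recent ~15% of proteins form an independent test set; the rest
are clustered at 30% sequence identity and whole clusters are balanced
over 5 folds, so homologous sequences never straddle a fold boundary.
"""

from locforge import build_split_plan
from locforge.synthetic import SyntheticSpec, generate_dataset

spec = SyntheticSpec(n_proteins=100, n_families=6, family_size=3, seed=3)
records = generate_dataset(spec)
plan = build_split_plan(records, test_fraction=0.15, identity_threshold=0.30, folds=5)

print(f"{len(records)} proteins -> {len(plan.test_ids)} temporal test, "
      f"{len(plan.fold_of)} CV in {len(plan.clusters)} homology clusters")
for k in range(1, 6):
    print(f"  fold {k}: {len(plan.fold_ids(k))} proteins")
multi = [c for c in plan.clusters if len(c) > 1]
print(f"{len(multi)} multi-member clusters; each stays inside a single fold")
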