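"""Clean a synthetic database and split it by stoichiometry.

Shows the six cleaning rules firing on purpose-built probe molecules, then
the grouped train/test split: singleton formulas stay out, pairs split 1/1,
larger groups split at the 33% test fraction.
"""

from collections import Counter

from mole8.curation import apply_filters, split_by_stoichiometry
from mole8.fixtures import make_filter_probes, make_toy_dataset

probes = make_filter_probes()
pool = make_toy_dataset(2000, seed=0)

report = apply_filters(probes + pool)
print("removed probes and reasons:")
for mol_id, reason in sorted(report.removed.items()):
    print(f"  {mol_id:28s} -> {reason}")
print(f"kept {len(report.kept)} of {len(probes) + len(pool)} molecules")

kept = report.kept_molecules(probes + pool)
split = split_by_stoichiometry(kept, test_fraction=0.33, seed=1)
share = len(split.test) / (len(split.train) + len(split.test))
print(f"train {len(split.train)}, test {len(split.test)}, "
      f"unassigned (singleton formulas) {len(split.unassigned)}")
print(f"aggregate test share: {share:.3f}  (target 0.33, rounded up per group)")
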