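"""Simulate a germplasm collection with known clones, families and triploids.

The default configuration emulates a ~350-accession apple-style gene bank:
unrelated founders under HWE, 42 clonal groups (largest 15), 30 offspring
from founder crosses, and 66 triploids from unreduced-gamete fusions.
"""

from collections import Counter

from clonekin import SimulationConfig, simulate_collection

cfg = SimulationConfig(seed=1)
genotypes, truth = simulate_collection(cfg)

print(f"samples x loci      : {genotypes.n_samples} x {genotypes.n_loci}")
print(f"missing call rate   : {genotypes.missing_mask().mean():.3f}")
print(f"clonal groups       : {len(truth.clone_groups)}")
sizes = Counter(len(m) for m in truth.clone_groups.values())
print(f"group size spectrum : {dict(sorted(sizes.items()))}")
print(f"triploids           : {sum(1 for p in truth.ploidy.values() if p == 3)}")
print(f"parent-offspring    : {len(truth.parent_offspring)} ordered pairs")

# The size spectrum shows mostly pairs (grafted duplicates / sports) with a
# long tail up to the most propagated cultivar; the missing rate reflects
# typical reduced-representation sequencing dropout.
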