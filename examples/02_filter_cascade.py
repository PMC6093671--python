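"""Run the SNP quality-filter cascade and print survivor counts per step.

Order: distance thinning -> missingness caps -> mean-depth percentile cap
-> Hardy-Weinberg exact test -> minor-allele-frequency threshold.
"""

from clonekin import (
    FilterReport,
    SimulationConfig,
    filter_depth_percentile,
    filter_hwe,
    filter_maf,
    filter_missingness,
    simulate_collection,
    thin_by_distance,
)

genotypes, _ = simulate_collection(SimulationConfig(n_loci=2000, seed=2))

report = FilterReport()
g = thin_by_distance(genotypes, 10, report)
g = filter_missingness(g, 0.20, report)
g = filter_depth_percentile(g, 90.0, report)
g = filter_hwe(g, 1e-4, report=report)
g = filter_maf(g, 0.05, report)

print(report.to_frame().to_string(index=False))
print(f"\nfinal matrix: {g.n_samples} samples x {g.n_loci} loci")

# Each row shows loci/samples before and after one step.  The depth cap
# removes the deepest ~10% of loci (collapsed-paralogue suspects); the HWE
# test removes loci with extreme heterozygote excess, which in this
# simulation flags loci where the triploids' diploid-coded calls distort
# genotype proportions.
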