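"""Drive the whole workflow on one simulated collection and print the run
report's headline counts.
"""

from collections import Counter

from clonekin import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(seed=7), seed=7)
report = run_pipeline(cfg)

cs = report.clone_summary
ps = report.ploidy_summary
fs = report.first_degree_summary
print(f"samples analysed          : {cs.n_samples}")
print(f"with clonal relationship  : {cs.n_clonal} "
      f"({cs.n_clonal / cs.n_samples:.0%})")
print(f"clonal groups (largest)   : {cs.n_groups} ({cs.largest_group})")
print(f"unique genotypes          : {cs.n_unique} "
      f"({cs.n_unique / cs.n_samples:.0%})")
print(f"diploid / triploid        : {ps.n_diploid} / {ps.n_triploid} "
      f"(split {ps.low:.3f} / {ps.high:.3f})")
print(f"first-degree edges        : {fs.n_edges}, "
      f"{fs.n_with_edge} samples with a relative "
      f"({fs.n_with_edge / fs.n_samples:.0%})")
print(f"largest family network    : {fs.largest_component}")
print("disposition               :", dict(Counter(report.disposition.values())))

# Stage order mirrors gene-bank curation: find clones on everything, keep
# one representative per group, drop triploids flagged by excess
# heterozygosity, then look for parent-offspring pairs among the unique
# diploids and summarize population structure by PCA.
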