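"""End-to-end gene-bank analysis pipeline.

Stage order: filter cascade -> pairwise IBD -> clone network -> one
representative per clonal group -> per-sample heterozygosity and ploidy
classification -> exclusion of triploid/ambiguous samples -> pairwise IBD
recomputed on the unique diploids -> first-degree network -> PCA with
group-difference tests.  Every stage logs survivor counts and the final
:class:`RunReport` carries the counts a curator needs: unique genotypes,
clonal groups, ploidy classes, first-degree families and PCA summaries.

Each sample ends in exactly one disposition: unique-diploid,
clone-duplicate, triploid-excluded, ambiguous-excluded or filtered-out.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .filters import (
    FilterReport,
    filter_depth_percentile,
    filter_hwe,
    filter_maf,
    filter_missingness,
    ld_prune,
    thin_by_distance,
)
from .matrix import GenotypeMatrix, read_vcf
from .networks import (
    CLONE_THRESHOLD,
    FIRST_DEGREE_BAND,
    clone_network,
    connected_components,
    degree_distribution,
    first_degree_network,
    select_representatives,
)
from .pca import center_scale, group_difference_tests, mean_impute, pca
from .ploidy import classify_fixed, classify_valley
from .relate import (
    het_to_frame,
    pairwise_ibd,
    per_individual_heterozygosity,
    records_to_frame,
)
from .simulate import SimulationConfig, simulate_collection

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration of the full pipeline.

    Defaults are the pipeline's canonical operating point: min depth 8,
    10 bp thinning, 20% missingness cap, 90th-percentile depth cap, HWE
    alpha 1e-4, MAF > 0.05 for relatedness and > 0.01 for PCA, LD pruning
    10/3/0.5, clone threshold 0.85, first-degree band [0.43, 0.52].
    """

    input_vcf: str | None = None
    metadata: str | None = None
    simulation: SimulationConfig | None = None
    seed: int = 0

    min_genotype_depth: int = 8
    thin_bp: int = 10
    max_missing_rate: float = 0.20
    depth_percentile: float = 90.0
    hwe_alpha: float = 1e-4
    ibd_maf: float = 0.05

    clone_threshold: float = CLONE_THRESHOLD
    first_degree_low: float = FIRST_DEGREE_BAND[0]
    first_degree_high: float = FIRST_DEGREE_BAND[1]
    representative_rule: str = "random"

    ploidy_method: str = "valley-split"  # or "fixed-thresholds"
    ploidy_low: float = 0.335
    ploidy_high: float = 0.345

    pca_maf: float = 0.01
    prune_window: int = 10
    prune_step: int = 3
    prune_r2: float = 0.5
    pca_components: int = 5
    group_by: str | None = None  # metadata column for group tests

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key-value (YAML mapping) config file.

        Keys under ``simulation.*`` populate a :class:`SimulationConfig`.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_keys = {
            k.split(".", 1)[1]: v for k, v in raw.items() if k.startswith("simulation.")
        }
        kwargs = {k: v for k, v in raw.items() if "." not in k}
        if sim_keys:
            kwargs["simulation"] = SimulationConfig(**sim_keys)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class CloneSummary:
    n_samples: int
    n_clonal: int  # samples with >= 1 clonal relationship
    n_unique: int  # singletons + one per multi-member group
    n_groups: int  # multi-member components
    largest_group: int


@dataclass
class PloidySummary:
    n_diploid: int
    n_triploid: int
    n_ambiguous: int
    method: str
    low: float
    high: float


@dataclass
class FirstDegreeSummary:
    n_samples: int
    n_with_edge: int
    n_edges: int
    largest_component: int


@dataclass
class PcaSummary:
    n_samples: int
    n_loci: int
    explained_variance_fraction: list[float]
    tests: list[dict]


@dataclass
class RunReport:
    version: str
    config: dict
    filter_steps: list[dict]
    clone_summary: CloneSummary
    ploidy_summary: PloidySummary
    first_degree_summary: FirstDegreeSummary
    pca_summary: PcaSummary | None
    disposition: dict[str, str]

    def to_json(self, indent: int = 2) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"cannot serialize {type(o)}")

        return json.dumps(dataclasses.asdict(self), indent=indent, default=default,
                          sort_keys=True)


def summarize_clonality(components: list[frozenset[str]], n_samples: int) -> CloneSummary:
    """Clone-stage bookkeeping from the clone network's components.

    "Unique genotypes" counts singletons plus one representative per
    multi-member group, i.e. n_samples - sum(size - 1) over clonal groups.
    """
    multi = [c for c in components if len(c) > 1]
    n_clonal = sum(len(c) for c in multi)
    n_unique = n_samples - sum(len(c) - 1 for c in multi)
    return CloneSummary(
        n_samples=n_samples,
        n_clonal=n_clonal,
        n_unique=n_unique,
        n_groups=len(multi),
        largest_group=max((len(c) for c in multi), default=0),
    )


def _filter_cascade(g: GenotypeMatrix, cfg: PipelineConfig, report: FilterReport) -> GenotypeMatrix:
    g = thin_by_distance(g, cfg.thin_bp, report)
    g = filter_missingness(g, cfg.max_missing_rate, report)
    g = filter_depth_percentile(g, cfg.depth_percentile, report)
    g = filter_hwe(g, cfg.hwe_alpha, report=report)
    return g


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Run the full workflow and return (optionally also write) the report.

    Exactly one of ``cfg.input_vcf`` and ``cfg.simulation`` must be set.
    With an ``outdir``, each stage writes its table as delimited text and
    the report as JSON.
    """
    if (cfg.input_vcf is None) == (cfg.simulation is None):
        raise ValueError("configure exactly one of input_vcf and simulation")
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    metadata = None
    if cfg.input_vcf is not None:
        g0 = read_vcf(cfg.input_vcf, cfg.min_genotype_depth)
        if cfg.metadata:
            from .matrix import read_sample_metadata

            metadata = read_sample_metadata(cfg.metadata).set_index("sample_id")
    else:
        g0, truth = simulate_collection(cfg.simulation)
        if cfg.simulation.n_divergent_founders:
            metadata = pd.DataFrame(
                {"population": pd.Series(truth.population)}
            )

    all_samples = list(g0.sample_ids)
    disposition = {s: "filtered-out" for s in all_samples}

    report = FilterReport()
    g = _filter_cascade(g0, cfg, report)
    g_ibd = filter_maf(g, cfg.ibd_maf, report)
    for s in g_ibd.sample_ids:
        disposition[s] = "unique-diploid"  # provisional; refined below

    # -- clone stage ----------------------------------------------------
    records = pairwise_ibd(g_ibd)
    net = clone_network(records, cfg.clone_threshold, nodes=list(g_ibd.sample_ids))
    components = connected_components(net)
    clone_summary = summarize_clonality(components, g_ibd.n_samples)
    representatives = set(
        select_representatives(components, cfg.representative_rule, cfg.seed)
    )
    for comp in components:
        for s in comp - representatives:
            disposition[s] = "clone-duplicate"

    # -- ploidy stage (on clone representatives) ------------------------
    g_unique = g_ibd.subset_samples(sorted(representatives))
    het_records = per_individual_heterozygosity(g_unique)
    if cfg.ploidy_method == "fixed-thresholds":
        ploidy_calls = classify_fixed(het_records, cfg.ploidy_low, cfg.ploidy_high)
        split_low, split_high = cfg.ploidy_low, cfg.ploidy_high
    else:
        ploidy_calls, split = classify_valley(het_records)
        split_low, split_high = split.low, split.high
    by_class: dict[str, list[str]] = {"diploid": [], "triploid": [], "ambiguous": []}
    for c in ploidy_calls:
        by_class[c.ploidy_class].append(c.sample_id)
    for s in by_class["triploid"]:
        disposition[s] = "triploid-excluded"
    for s in by_class["ambiguous"]:
        disposition[s] = "ambiguous-excluded"
    if by_class["ambiguous"]:
        log.warning(
            "%d samples ambiguous between ploidy clusters; excluded downstream",
            len(by_class["ambiguous"]),
        )
    ploidy_summary = PloidySummary(
        n_diploid=len(by_class["diploid"]),
        n_triploid=len(by_class["triploid"]),
        n_ambiguous=len(by_class["ambiguous"]),
        method=cfg.ploidy_method,
        low=split_low,
        high=split_high,
    )

    # -- first-degree stage (unique diploids, IBD recomputed) ------------
    g_dip = g_ibd.subset_samples(by_class["diploid"])
    fd_records = pairwise_ibd(g_dip)
    fd_net = first_degree_network(
        fd_records, cfg.first_degree_low, cfg.first_degree_high,
        nodes=list(g_dip.sample_ids),
    )
    fd_components = connected_components(fd_net)
    fd_degrees, _ = degree_distribution(fd_net)
    first_degree_summary = FirstDegreeSummary(
        n_samples=g_dip.n_samples,
        n_with_edge=int((fd_degrees > 0).sum()),
        n_edges=len(fd_net.edges),
        largest_component=max((len(c) for c in fd_components), default=0),
    )

    # -- PCA stage -------------------------------------------------------
    pca_summary = None
    if g_dip.n_samples >= 3:
        g_pca = filter_maf(g_dip, cfg.pca_maf, report)
        g_pca = ld_prune(g_pca, cfg.prune_window, cfg.prune_step, cfg.prune_r2, report)
        table, _ = center_scale(mean_impute(g_pca))
        k = min(cfg.pca_components, g_pca.n_samples - 1, table.shape[1])
        result = pca(table, k, sample_ids=list(g_pca.sample_ids))
        tests: list[dict] = []
        group_col = cfg.group_by or ("population" if metadata is not None and
                                     "population" in getattr(metadata, "columns", []) else None)
        if metadata is not None and group_col in metadata.columns:
            labels = metadata[group_col].reindex(result.scores.index)
            comps = tuple(range(1, min(2, k) + 1))
            if labels.dropna().nunique() == 2:
                tests = [dataclasses.asdict(t) for t in group_difference_tests(
                    result.scores, labels, group_col, components=comps
                )]
        pca_summary = PcaSummary(
            n_samples=g_pca.n_samples,
            n_loci=g_pca.n_loci,
            explained_variance_fraction=[float(f) for f in
                                         result.explained_variance_fraction],
            tests=tests,
        )

    run_report = RunReport(
        version=__version__,
        config=_config_echo(cfg),
        filter_steps=[vars(s) for s in report.steps],
        clone_summary=clone_summary,
        ploidy_summary=ploidy_summary,
        first_degree_summary=first_degree_summary,
        pca_summary=pca_summary,
        disposition=disposition,
    )

    if out is not None:
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        records_to_frame(records).to_csv(out / "ibd_all.tsv", sep="\t", index=False)
        records_to_frame(fd_records).to_csv(out / "ibd_unique_diploid.tsv", sep="\t", index=False)
        het_to_frame(het_records).to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"sample_id": c.sample_id, "het": c.het, "class": c.ploidy_class,
              "method": c.method, "low": c.low, "high": c.high} for c in ploidy_calls]
        ).to_csv(out / "ploidy.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"id1": a, "id2": b, "pi_hat": w} for a, b, w in fd_net.edges]
        ).to_csv(out / "first_degree_edges.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"sample_id": s, "disposition": d} for s, d in disposition.items()]
        ).to_csv(out / "disposition.tsv", sep="\t", index=False)
        (out / "report.json").write_text(run_report.to_json() + "\n")

    return run_report


def _config_echo(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.simulation is not None:
        d["simulation"] = dataclasses.asdict(cfg.simulation)
    return d
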