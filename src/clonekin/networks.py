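"""Relationship networks from thresholded pairwise pi-hat values.

Two bands matter in germplasm curation: a clone band (pi-hat > 0.85, open
on the left — genotyping error and somatic mutation pull clonal pairs below
the theoretical 1.0) and a first-degree band (pi-hat in [0.43, 0.52],
closed — calibrated on known parent-offspring pedigrees).  Thresholding the
pairwise table gives an undirected graph whose connected components are
clonal groups or families; one representative per clonal group is kept for
downstream analyses.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .relate import RelatednessRecord

log = logging.getLogger(__name__)

CLONE_THRESHOLD = 0.85
FIRST_DEGREE_BAND = (0.43, 0.52)


@dataclass
class RelationshipNetwork:
    """Undirected graph of samples whose pi-hat falls in a band."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (id1, id2, pi_hat)
    band: tuple[float, float]
    inclusive: tuple[bool, bool]  # whether low/high ends are closed

    def graph(self) -> nx.Graph:
        gr = nx.Graph()
        gr.add_nodes_from(self.nodes)
        gr.add_weighted_edges_from(self.edges, weight="pi_hat")
        return gr

    def edge_pairs(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _ in self.edges}


def build_network(
    records: list[RelatednessRecord],
    low: float,
    high: float,
    inclusive: tuple[bool, bool] = (True, True),
    nodes: list[str] | None = None,
) -> RelationshipNetwork:
    """Threshold a pairwise pi-hat table into a relationship network.

    An edge joins a pair iff its pi-hat lies in the band; band-end
    inclusivity is controlled by ``inclusive`` (closed when True).  Isolated
    nodes are retained.  With an empty record set a ``nodes`` list must be
    supplied to define the (edgeless) network.
    """
    if low >= high:
        raise ValueError(f"band must satisfy low < high, got [{low}, {high}]")
    if not records and nodes is None:
        raise ValueError("empty record set and no node list supplied")
    node_set: list[str] = list(nodes) if nodes is not None else []
    if nodes is None:
        seen: set[str] = set()
        for r in records:
            for sid in (r.id1, r.id2):
                if sid not in seen:
                    seen.add(sid)
                    node_set.append(sid)
    lo_ok = (lambda v: v >= low) if inclusive[0] else (lambda v: v > low)
    hi_ok = (lambda v: v <= high) if inclusive[1] else (lambda v: v < high)
    edges = [
        (r.id1, r.id2, r.pi_hat)
        for r in records
        if r.defined and lo_ok(r.pi_hat) and hi_ok(r.pi_hat)
    ]
    return RelationshipNetwork(node_set, edges, (low, high), inclusive)


def clone_network(
    records: list[RelatednessRecord],
    threshold: float = CLONE_THRESHOLD,
    nodes: list[str] | None = None,
) -> RelationshipNetwork:
    """Clone network: edge iff pi-hat strictly above ``threshold``."""
    return build_network(records, threshold, 1.0, inclusive=(False, True), nodes=nodes)


def first_degree_network(
    records: list[RelatednessRecord],
    low: float = FIRST_DEGREE_BAND[0],
    high: float = FIRST_DEGREE_BAND[1],
    nodes: list[str] | None = None,
) -> RelationshipNetwork:
    """First-degree network: edge iff pi-hat in the closed band [low, high]."""
    return build_network(records, low, high, inclusive=(True, True), nodes=nodes)


def connected_components(net: RelationshipNetwork) -> list[frozenset[str]]:
    """Connected components, singletons included, in a deterministic order
    (decreasing size, then smallest member id)."""
    comps = [frozenset(c) for c in nx.connected_components(net.graph())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def select_representatives(
    components: list[frozenset[str]],
    rule: str = "random",
    seed: int | None = None,
) -> list[str]:
    """One representative per component (singletons keep themselves).

    ``rule="random"`` draws the representative with a seeded generator, as
    when deduplicating clonal groups at random; ``rule="lexicographic"``
    keeps the smallest id, for byte-reproducible outputs.
    """
    if rule not in ("random", "lexicographic"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for comp in components:
        members = sorted(comp)
        if rule == "lexicographic" or len(members) == 1:
            kept.append(members[0])
        else:
            kept.append(members[int(rng.integers(len(members)))])
    return sorted(kept)


def degree_distribution(net: RelationshipNetwork) -> tuple[pd.Series, Counter]:
    """Per-node degree plus a histogram over degree values."""
    gr = net.graph()
    degrees = pd.Series({n: d for n, d in gr.degree()}, dtype=int).sort_index()
    return degrees, Counter(degrees.values.tolist())


def compare_networks(
    edges_a: set[frozenset[str]], edges_b: set[frozenset[str]]
) -> tuple[set[frozenset[str]], set[frozenset[str]], set[frozenset[str]]]:
    """Edges shared by both networks, and those private to each."""
    shared = edges_a & edges_b
    return shared, edges_a - shared, edges_b - shared


def unclassified_high_relatedness(
    records: list[RelatednessRecord],
    low: float = FIRST_DEGREE_BAND[1],
    high: float = CLONE_THRESHOLD,
) -> pd.DataFrame:
    """Audit table of pairs with pi-hat strictly between the first-degree
    band and the clone threshold — related beyond first degree but not
    clonal; reported rather than silently dropped."""
    rows = [
        {"id1": r.id1, "id2": r.id2, "pi_hat": r.pi_hat}
        for r in records
        if r.defined and low < r.pi_hat < high
    ]
    return pd.DataFrame(rows, columns=["id1", "id2", "pi_hat"])
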