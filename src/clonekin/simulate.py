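"""Synthetic germplasm collections with known ground truth.

Emulates the composition of a clonally propagated fruit-tree gene bank:
unrelated founder accessions drawn under Hardy-Weinberg equilibrium (HWE),
clonal groups (grafted propagations of one genotype, diverging only through
genotyping error/somatic mutation), parent-offspring pairs from founder
crosses, and triploids formed by an unreduced diploid gamete fusing with a
normal haploid gamete and then genotyped through a diploid-style caller.

Loci are unlinked and positions are laid out on one synthetic chromosome at
1 kb spacing, so distance-based thinning is inert by default.  The default
configuration mirrors a collection of ~350 accessions: 42 clonal groups
(31 of size two, the largest of size 15; 119 clonal members in total),
30 offspring, 66 triploids (~19%) and unrelated founders making up the rest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, Locus


def _default_clone_sizes() -> list[int]:
    # 42 groups, 31 of them pairs, largest 15; 119 clonal members in total
    return [2] * 31 + [3, 3, 3, 4, 4, 4, 5, 5, 5, 6, 15]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic collection.

    Rates are per call; the allele-frequency law is uniform on
    (``freq_low``, ``freq_high``).  ``error_rate`` models the per-call
    discordance of a clonal propagation from its source genotype (genotyping
    error plus somatic mutation, not separated).  With
    ``n_divergent_founders`` > 0 and ``divergence`` > 0, that many founders
    are drawn from a second allele-frequency vector produced by a
    Balding-Nichols draw (FST-like parameter ``divergence``) — a simple
    two-subpopulation structure for PCA-based tests.
    """

    n_loci: int = 5000
    n_founders: int = 176
    freq_low: float = 0.05
    freq_high: float = 0.5
    clone_group_sizes: list[int] = field(default_factory=_default_clone_sizes)
    n_parent_offspring_pairs: int = 30
    n_triploids: int = 66
    error_rate: float = 0.002
    missing_rate: float = 0.05
    seed: int = 0
    chrom: str = "1"
    pos_step: int = 1000
    depth_mean: float = 30.0
    simulate_depth: bool = True
    n_divergent_founders: int = 0
    divergence: float = 0.0

    def __post_init__(self) -> None:
        for name in ("error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.freq_low < self.freq_high < 1.0):
            raise ValueError(
                f"frequency bounds must satisfy 0 < low < high < 1, "
                f"got ({self.freq_low}, {self.freq_high})"
            )
        if any(s < 1 for s in self.clone_group_sizes):
            raise ValueError("clone group sizes must be >= 1")
        if self.n_loci < 1 or self.n_founders < 1:
            raise ValueError("n_loci and n_founders must be >= 1")
        n_parents_needed = len(self.clone_group_sizes)
        if n_parents_needed > self.n_founders:
            raise ValueError("more clone groups than founders to source them from")
        if (self.n_parent_offspring_pairs > 0 or self.n_triploids > 0) and self.n_founders < 2:
            raise ValueError("crosses require at least two founders")
        if self.n_divergent_founders > self.n_founders:
            raise ValueError("n_divergent_founders exceeds n_founders")

    @property
    def n_samples(self) -> int:
        extra_clones = sum(s - 1 for s in self.clone_group_sizes)
        return (
            self.n_founders
            + extra_clones
            + self.n_parent_offspring_pairs
            + self.n_triploids
        )


@dataclass
class TruthTable:
    """Ground truth of a simulated collection.

    ``ploidy`` maps sample id -> 2 or 3; ``clone_groups`` maps group id ->
    member ids (source first); ``parent_offspring`` lists ordered
    (parent, child) pairs — two per offspring, and two per triploid (the
    unreduced-gamete parent first); ``founders`` flags unrelated HWE
    founders; ``population`` (optional) labels founders by subpopulation.
    """

    ploidy: dict[str, int]
    clone_groups: dict[str, list[str]]
    parent_offspring: list[tuple[str, str]]
    founders: set[str]
    population: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = [m for grp in self.clone_groups.values() for m in grp]
        if len(set(members)) != len(members):
            raise ValueError("clone groups must be disjoint")
        known = set(self.ploidy)
        for p, c in self.parent_offspring:
            if p not in known or c not in known:
                raise ValueError(f"parent-offspring pair ({p}, {c}) references unknown sample")

    def clone_group_of(self, sample_id: str) -> str | None:
        for gid, members in self.clone_groups.items():
            if sample_id in members:
                return gid
        return None

    def clone_pairs(self) -> set[frozenset[str]]:
        """All unordered within-group pairs implied by the clone groups."""
        pairs: set[frozenset[str]] = set()
        for members in self.clone_groups.values():
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pairs.add(frozenset((a, b)))
        return pairs

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, pl in self.ploidy.items():
            rows.append(
                {
                    "sample_id": sid,
                    "ploidy": pl,
                    "clone_group": self.clone_group_of(sid) or "",
                    "is_founder": sid in self.founders,
                    "population": self.population.get(sid, ""),
                }
            )
        return pd.DataFrame(rows)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_frequencies(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """I.i.d. uniform alt-allele frequencies on (freq_low, freq_high)."""
    rng = rng if rng is not None else _rng(cfg.seed)
    return rng.uniform(cfg.freq_low, cfg.freq_high, size=cfg.n_loci)


def simulate_founder(freqs: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """One unrelated diploid genotype under HWE: dosage ~ Binomial(2, p)."""
    rng = _rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("founder frequencies must lie strictly in (0, 1)")
    return rng.binomial(2, freqs).astype(np.int8)


def _gamete(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One haploid gamete: per locus, one allele drawn uniformly from the
    parent's two.  Alt-allele indicator ~ Bernoulli(dosage / 2)."""
    return (rng.random(parent.shape) < parent / 2.0).astype(np.int8)


def simulate_offspring(
    parent_a: np.ndarray, parent_b: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Mendelian cross of two diploids over unlinked loci."""
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must share one locus set")
    rng = _rng(seed)
    return _gamete(parent_a, rng) + _gamete(parent_b, rng)


def simulate_triploid(
    parent_a: np.ndarray, parent_b: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Triploid from an unreduced gamete of ``parent_a`` plus a haploid
    gamete of ``parent_b``, collapsed to a diploid-style call.

    The unreduced gamete carries both of parent_a's alleles, so the triple's
    alt count is ``dosage_a + Bernoulli(dosage_b / 2)``.  The collapsed call
    is heterozygous (dosage 1) unless all three alleles agree (dosage 0 or
    2) — a diploid caller sees both alleles whatever the 2:1 ratio.
    """
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must share one locus set")
    rng = _rng(seed)
    alt_triple = parent_a.astype(np.int16) + _gamete(parent_b, rng)
    collapsed = np.ones_like(parent_a, dtype=np.int8)
    collapsed[alt_triple == 0] = 0
    collapsed[alt_triple == 3] = 2
    return collapsed


def make_clone(
    source: np.ndarray, error_rate: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Clonal copy of ``source`` with symmetric per-call error.

    Each call is independently replaced with probability ``error_rate`` by a
    uniform draw from the other two dosage states.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must be in [0, 1], got {error_rate}")
    rng = _rng(seed)
    clone = source.copy()
    flip = rng.random(source.shape) < error_rate
    # orig + 1 + U{0,1} (mod 3) is uniform over the other two states
    offset = 1 + rng.integers(0, 2, size=source.shape)
    clone[flip] = ((source[flip].astype(np.int16) + offset[flip]) % 3).astype(np.int8)
    return clone


def _balding_nichols(freqs: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Drifted frequency vector: Beta(p(1-F)/F, (1-p)(1-F)/F) per locus."""
    scale = (1.0 - fst) / fst
    drifted = rng.beta(freqs * scale, (1.0 - freqs) * scale)
    return np.clip(drifted, 1e-6, 1.0 - 1e-6)


def simulate_collection(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Assemble a full collection: founders, clone groups, offspring,
    triploids, then i.i.d. missingness.  Fully reproducible under
    ``cfg.seed``.

    Clone-group sources, cross parents and triploid parents are drawn from
    the founders (sources without replacement, parents with).  Per-call
    error is applied by :func:`make_clone` to clonal copies only; founders,
    offspring and triploids carry their exact simulated genotypes.
    """
    rng = _rng(cfg.seed)
    freqs = draw_frequencies(cfg, rng)

    pop_freqs = freqs
    populations: dict[str, str] = {}
    if cfg.n_divergent_founders > 0 and cfg.divergence > 0.0:
        pop_freqs2 = _balding_nichols(freqs, cfg.divergence, rng)
    else:
        pop_freqs2 = None

    names: list[str] = []
    rows: list[np.ndarray] = []
    ploidy: dict[str, int] = {}
    founders: set[str] = set()

    founder_calls: dict[str, np.ndarray] = {}
    for i in range(cfg.n_founders):
        sid = f"F{i + 1:03d}"
        in_pop2 = i >= cfg.n_founders - cfg.n_divergent_founders
        use2 = pop_freqs2 is not None and in_pop2
        vec = simulate_founder(pop_freqs2 if use2 else pop_freqs, rng)
        populations[sid] = "P2" if in_pop2 else "P1"
        names.append(sid)
        rows.append(vec)
        founder_calls[sid] = vec
        ploidy[sid] = 2
        founders.add(sid)

    founder_ids = list(founder_calls)
    source_ids = [str(s) for s in rng.choice(founder_ids, size=len(cfg.clone_group_sizes), replace=False)]
    clone_groups: dict[str, list[str]] = {}
    k = 0
    for g, size in enumerate(cfg.clone_group_sizes):
        gid = f"G{g + 1:02d}"
        src = source_ids[g]
        members = [src]
        for _ in range(size - 1):
            k += 1
            sid = f"C{k:03d}"
            members.append(sid)
            names.append(sid)
            rows.append(make_clone(founder_calls[src], cfg.error_rate, rng))
            ploidy[sid] = 2
        clone_groups[gid] = members

    parent_offspring: list[tuple[str, str]] = []
    for i in range(cfg.n_parent_offspring_pairs):
        pa, pb = (str(s) for s in rng.choice(founder_ids, size=2, replace=False))
        sid = f"O{i + 1:03d}"
        names.append(sid)
        rows.append(simulate_offspring(founder_calls[pa], founder_calls[pb], rng))
        ploidy[sid] = 2
        parent_offspring += [(pa, sid), (pb, sid)]

    for i in range(cfg.n_triploids):
        pa, pb = (str(s) for s in rng.choice(founder_ids, size=2, replace=False))
        sid = f"T{i + 1:03d}"
        names.append(sid)
        rows.append(simulate_triploid(founder_calls[pa], founder_calls[pb], rng))
        ploidy[sid] = 3
        parent_offspring += [(pa, sid), (pb, sid)]

    calls = np.stack(rows, axis=0).astype(np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    depth = None
    if cfg.simulate_depth and cfg.depth_mean > 0:
        # called genotypes sit at/above a typical 8-read floor; missing below it
        called_extra = max(cfg.depth_mean - 8.0, 0.0)
        depth = 8 + rng.poisson(called_extra, size=calls.shape)
        depth[calls == MISSING] = rng.integers(0, 8, size=int((calls == MISSING).sum()))
        depth = depth.astype(np.int32)

    loci = []
    for j in range(cfg.n_loci):
        md = float("nan")
        if depth is not None:
            called = calls[:, j] != MISSING
            md = float(depth[called, j].mean()) if called.any() else float("nan")
        loci.append(Locus(cfg.chrom, (j + 1) * cfg.pos_step, "A", "C", md))

    matrix = GenotypeMatrix(sample_ids=names, loci=loci, calls=calls, depth=depth)
    truth = TruthTable(
        ploidy=ploidy,
        clone_groups=clone_groups,
        parent_offspring=parent_offspring,
        founders=founders,
        population=populations,
    )
    return matrix, truth


def write_truth(truth: TruthTable, path) -> None:
    """Serialize the truth table as a tab-delimited text file."""
    truth.to_frame().to_csv(path, sep="\t", index=False)
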