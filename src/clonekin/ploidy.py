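"""Diploid/triploid classification from per-sample heterozygosity.

A triploid genotyped through a diploid-style caller appears heterozygous at
any locus carrying both alleles.  Under Hardy-Weinberg proportions the
expected per-locus heterozygosity is 2pq for a disomic genotype and
1 - p^3 - q^3 = 3pq for a trisomic one — exactly 50% higher at every allele
frequency — so a mixed collection shows a bimodal distribution of observed
per-sample heterozygosity and can be split into ploidy classes either at
fixed thresholds or at the data-driven valley between the two modes.

Real collections deviate from HWE, which compresses the observed
triploid/diploid ratio below 1.5; the observed ratio is therefore reported,
never asserted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .relate import HetRecord

log = logging.getLogger(__name__)

#: Fixed split used when a collection's bimodality is already characterised:
#: diploids at het <= 0.335, triploids at het >= 0.345.
FIXED_THRESHOLDS = (0.335, 0.345)

DIPLOID = "diploid"
TRIPLOID = "triploid"
AMBIGUOUS = "ambiguous"


@dataclass
class PloidyCall:
    sample_id: str
    het: float
    ploidy_class: str  # diploid | triploid | ambiguous
    method: str  # fixed-thresholds | valley-split
    low: float
    high: float


@dataclass
class ValleySplit:
    """Result of the data-driven two-cluster split of heterozygosity values.

    ``low``/``high`` bound the between-cluster gap (max of the lower
    cluster, min of the upper); ``ok`` is False for degenerate inputs where
    no split exists (all values identical).
    """

    low: float
    high: float
    ok: bool
    within_ss: float = float("nan")


def _classify(
    records: list[HetRecord], low: float, high: float, method: str
) -> list[PloidyCall]:
    calls = []
    for r in records:
        if not r.defined or np.isnan(r.het):
            cls = AMBIGUOUS
        elif r.het <= low:
            cls = DIPLOID
        elif r.het >= high:
            cls = TRIPLOID
        else:
            cls = AMBIGUOUS
        calls.append(PloidyCall(r.sample_id, r.het, cls, method, low, high))
    n_high = sum(1 for c in calls if c.ploidy_class == TRIPLOID and c.het > high + 0.25)
    if n_high:
        log.warning(
            "%d samples far above the triploid cluster; higher ploidy not modelled", n_high
        )
    return calls


def classify_fixed(
    records: list[HetRecord],
    low: float = FIXED_THRESHOLDS[0],
    high: float = FIXED_THRESHOLDS[1],
) -> list[PloidyCall]:
    """Classify at fixed heterozygosity thresholds.

    het <= low -> diploid; het >= high -> triploid; strictly inside the open
    gap -> ambiguous.
    """
    if low >= high:
        raise ValueError("thresholds must satisfy low < high")
    return _classify(records, low, high, "fixed-thresholds")


def find_valley_split(values: np.ndarray) -> ValleySplit:
    """Optimal 1-D two-cluster split of heterozygosity values.

    Exhausts every split point of the sorted values and minimizes the total
    within-cluster sum of squares (the exact 1-D two-means solution, which
    always falls on a sorted gap); returns the boundary pair around the
    between-cluster gap.

    Two-means always produces a partition, so a degenerate unimodal input
    must be flagged rather than split: the result carries ``ok=False`` when
    all values are identical, or when the between-cluster gap is less than
    twice the pooled within-cluster standard deviation sqrt(WSS / n) — a
    separation any bimodal ploidy mixture clears by an order of magnitude.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("valley split needs at least 2 finite values")
    if v[0] == v[-1]:
        return ValleySplit(float(v[0]), float(v[0]), ok=False)
    csum = np.cumsum(v)
    csum2 = np.cumsum(v * v)
    total_n = v.size
    best: tuple[float, int] | None = None
    for k in range(1, total_n):  # left cluster v[:k], right v[k:]
        nl, nr = k, total_n - k
        sl, sr = csum[k - 1], csum[-1] - csum[k - 1]
        s2l, s2r = csum2[k - 1], csum2[-1] - csum2[k - 1]
        wss = (s2l - sl * sl / nl) + (s2r - sr * sr / nr)
        if best is None or wss < best[0] - 1e-15:
            best = (wss, k)
        elif abs(wss - best[0]) <= 1e-15 and v[k] - v[k - 1] > v[best[1]] - v[best[1] - 1]:
            best = (wss, k)  # equal WSS: prefer the wider gap
    wss, k = best
    gap = float(v[k] - v[k - 1])
    pooled_sd = float(np.sqrt(max(wss, 0.0) / total_n))
    separated = pooled_sd == 0.0 or gap >= 2.0 * pooled_sd
    return ValleySplit(float(v[k - 1]), float(v[k]), ok=separated, within_ss=float(wss))


def classify_valley(records: list[HetRecord]) -> tuple[list[PloidyCall], ValleySplit]:
    """Classify by the data-driven valley split of the het distribution.

    Degenerate (unimodal/identical) distributions produce an all-diploid
    call set with a warning, since no excess-heterozygosity cluster exists.
    """
    values = np.array([r.het for r in records if r.defined], dtype=float)
    split = find_valley_split(values)
    if not split.ok:
        log.warning("heterozygosity distribution has no split; all samples called diploid")
        calls = [
            PloidyCall(r.sample_id, r.het, DIPLOID if r.defined else AMBIGUOUS,
                       "valley-split", split.low, split.high)
            for r in records
        ]
        return calls, split
    return _classify(records, split.low, split.high, "valley-split"), split


def hwe_het_expectation(freqs: np.ndarray, ploidy: int) -> float:
    """Expected mean heterozygosity under HWE at the given ploidy.

    Disomic: mean(2pq).  Trisomic, seen through a diploid-style caller:
    mean(1 - p^3 - q^3) = mean(3pq).  Their ratio is exactly 3/2 for any
    frequency vector.
    """
    p = np.asarray(freqs, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("frequencies must lie strictly in (0, 1)")
    q = 1.0 - p
    if ploidy == 2:
        return float(np.mean(2.0 * p * q))
    if ploidy == 3:
        return float(np.mean(1.0 - p**3 - q**3))
    raise ValueError(f"ploidy must be 2 or 3, got {ploidy}")
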