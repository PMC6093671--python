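"""Method-of-moments identity-by-descent (IBD) estimation.

For every unordered pair of samples, loci where both genotypes are called
are classified by identity-by-state (IBS): IBS2 when the dosages are equal,
IBS0 for opposite homozygotes (0 vs 2), IBS1 otherwise.  Under random mating
with known allele frequencies, the expected number of loci in each IBS class
is a linear function of the unknown probabilities Z0/Z1/Z2 that the pair
shares 0/1/2 alleles identical by descent.  The moments cascade solves the
triangular system

    n_IBS0 = Z0 * S(0|0)
    n_IBS1 = Z0 * S(1|0) + Z1 * S(1|1)
    n_IBS2 = Z0 * S(2|0) + Z1 * S(2|1) + Z2 * N

where S(k|m) sums P(IBS k | IBD m) over the pair's complete loci, then
clamps each Z to [0, 1] and renormalizes to sum one.  The headline statistic
is pi-hat = Z1/2 + Z2, the expected genome fraction shared IBD: ~1 for
clones, ~0.5 for parent-offspring pairs, ~0 for unrelated individuals.

Allele frequencies are plug-in estimates from the full matrix, without
small-sample bias corrections; loci with fixed or undefined frequency are
excluded from both the counts and the expectations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, allele_frequencies

log = logging.getLogger(__name__)


@dataclass
class RelatednessRecord:
    """IBS counts and IBD estimates for one unordered sample pair."""

    id1: str
    id2: str
    n: int  # pairwise-complete locus count
    n_ibs0: int
    n_ibs1: int
    n_ibs2: int
    z0: float
    z1: float
    z2: float
    pi_hat: float
    defined: bool = True

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.id1, self.id2))


@dataclass
class HetRecord:
    """Observed heterozygosity of one sample."""

    sample_id: str
    n_het: int
    n_obs: int
    het: float
    defined: bool = True


def ibs_counts(g1: np.ndarray, g2: np.ndarray) -> tuple[int, int, int]:
    """IBS class counts over pairwise-complete loci of two dosage vectors."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    diff = np.abs(g1[ok].astype(np.int16) - g2[ok].astype(np.int16))
    return int((diff == 2).sum()), int((diff == 1).sum()), int((diff == 0).sum())


@dataclass
class IbsExpectation:
    """Per-locus P(IBS k | IBD m) terms for the moments system.

    Arrays are aligned with the locus axis; ``valid`` marks loci with
    frequency strictly inside (0, 1) — only those enter the estimator.
    """

    e00: np.ndarray  # P(IBS0 | IBD0) = 2 p^2 q^2
    e10: np.ndarray  # P(IBS1 | IBD0) = 4 p^3 q + 4 p q^3
    e20: np.ndarray  # P(IBS2 | IBD0) = p^4 + q^4 + 4 p^2 q^2
    e11: np.ndarray  # P(IBS1 | IBD1) = 2 p^2 q + 2 p q^2
    e21: np.ndarray  # P(IBS2 | IBD1) = p^3 + q^3 + p^2 q + p q^2
    valid: np.ndarray

    def sums(self, mask: np.ndarray | None = None) -> dict[str, float]:
        """Summed expectations over ``valid & mask`` loci (mask optional)."""
        m = self.valid if mask is None else (self.valid & mask)
        return {
            "S00": float(self.e00[m].sum()),
            "S10": float(self.e10[m].sum()),
            "S20": float(self.e20[m].sum()),
            "S11": float(self.e11[m].sum()),
            "S21": float(self.e21[m].sum()),
            "N": float(m.sum()),
        }


def expected_ibs_by_ibd(freqs: np.ndarray) -> IbsExpectation:
    """Per-locus IBS-class probabilities conditional on IBD state.

    Boundary or undefined frequencies are flagged invalid and skipped with a
    warning; every returned row satisfies the normalizations
    sum_k P(IBS k | IBD m) = 1 for m = 0, 1.
    """
    p = np.asarray(freqs, dtype=float)
    valid = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if (~valid).any():
        log.warning(
            "%d loci with fixed/undefined frequency excluded from IBD estimation",
            int((~valid).sum()),
        )
    q = 1.0 - p
    with np.errstate(invalid="ignore"):
        e00 = 2.0 * p**2 * q**2
        e10 = 4.0 * p**3 * q + 4.0 * p * q**3
        e20 = p**4 + q**4 + 4.0 * p**2 * q**2
        e11 = 2.0 * p**2 * q + 2.0 * p * q**2
        e21 = p**3 + q**3 + p**2 * q + p * q**2
    return IbsExpectation(e00, e10, e20, e11, e21, valid)


def mom_ibd(
    counts: tuple[int, int, int], sums: dict[str, float]
) -> tuple[float, float, float, float, tuple[float, float, float]]:
    """Moments cascade from IBS counts to (Z0, Z1, Z2, pi-hat).

    ``sums`` must come from :meth:`IbsExpectation.sums` over the same locus
    set as ``counts``.  Returns the constrained estimates plus the raw
    (pre-clamp) solution of the triangular moment system.

    Raises
    ------
    ValueError
        If the pairwise-complete locus count N is zero.
    """
    n0, n1, n2 = counts
    N = sums["N"]
    if N <= 0:
        raise ValueError("no pairwise-complete loci; IBD undefined")
    z0 = n0 / sums["S00"]
    z1 = (n1 - z0 * sums["S10"]) / sums["S11"]
    z2 = (n2 - z0 * sums["S20"] - z1 * sums["S21"]) / N
    raw = (float(z0), float(z1), float(z2))
    z = np.clip(raw, 0.0, 1.0)
    total = z.sum()
    z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pi_hat = float(z[1] / 2.0 + z[2])
    return float(z[0]), float(z[1]), float(z[2]), pi_hat, raw


def pairwise_ibd(
    g: GenotypeMatrix, freqs: np.ndarray | None = None
) -> list[RelatednessRecord]:
    """Method-of-moments IBD for every unordered sample pair.

    Frequencies default to plug-in estimates from ``g`` itself.  Missing
    data is handled by pairwise-complete deletion: each pair's counts and
    expectation sums run over the loci called in both samples.  The
    computation is symmetric in pair order and vectorized over pairs.
    """
    if g.n_samples < 2:
        raise ValueError("pairwise IBD needs at least two samples")
    if freqs is None:
        freqs = allele_frequencies(g)
    exp = expected_ibs_by_ibd(freqs)
    valid = exp.valid

    calls = g.calls[:, valid]
    called = (calls != MISSING)
    callf = called.astype(np.float64)
    # indicator matrices per dosage state -> IBS class counts by matmul
    a = [(calls == d).astype(np.float64) for d in (0, 1, 2)]
    n_pairs_ibs2 = a[0] @ a[0].T + a[1] @ a[1].T + a[2] @ a[2].T
    n_pairs_ibs0 = a[0] @ a[2].T
    n_pairs_ibs0 = n_pairs_ibs0 + n_pairs_ibs0.T
    n_complete = callf @ callf.T
    n_pairs_ibs1 = n_complete - n_pairs_ibs2 - n_pairs_ibs0

    # expectation sums over each pair's complete loci: (M * e) @ M^T
    ev = {k: arr[valid] for k, arr in
          (("S00", exp.e00), ("S10", exp.e10), ("S20", exp.e20),
           ("S11", exp.e11), ("S21", exp.e21))}
    esums = {k: (callf * v) @ callf.T for k, v in ev.items()}

    records: list[RelatednessRecord] = []
    for i, j in itertools.combinations(range(g.n_samples), 2):
        counts = (
            int(round(n_pairs_ibs0[i, j])),
            int(round(n_pairs_ibs1[i, j])),
            int(round(n_pairs_ibs2[i, j])),
        )
        sums = {k: float(esums[k][i, j]) for k in esums}
        sums["N"] = float(n_complete[i, j])
        if sums["N"] <= 0:
            records.append(
                RelatednessRecord(
                    g.sample_ids[i], g.sample_ids[j], 0, 0, 0, 0,
                    float("nan"), float("nan"), float("nan"), float("nan"),
                    defined=False,
                )
            )
            log.warning(
                "pair (%s, %s) has no pairwise-complete loci; flagged undefined",
                g.sample_ids[i], g.sample_ids[j],
            )
            continue
        z0, z1, z2, pi_hat, _ = mom_ibd(counts, sums)
        records.append(
            RelatednessRecord(
                g.sample_ids[i], g.sample_ids[j], int(sums["N"]),
                counts[0], counts[1], counts[2], z0, z1, z2, pi_hat,
            )
        )
    return records


def records_to_frame(records: list[RelatednessRecord]) -> pd.DataFrame:
    """Tabulate records with PLINK .genome-like column names."""
    return pd.DataFrame(
        {
            "IID1": [r.id1 for r in records],
            "IID2": [r.id2 for r in records],
            "N": [r.n for r in records],
            "IBS0": [r.n_ibs0 for r in records],
            "IBS1": [r.n_ibs1 for r in records],
            "IBS2": [r.n_ibs2 for r in records],
            "Z0": [r.z0 for r in records],
            "Z1": [r.z1 for r in records],
            "Z2": [r.z2 for r in records],
            "PI_HAT": [r.pi_hat for r in records],
        }
    )


def per_individual_heterozygosity(g: GenotypeMatrix) -> list[HetRecord]:
    """Observed heterozygosity per sample: het calls / non-missing calls.

    A sample with no non-missing calls is flagged undefined (het NaN) with a
    warning rather than dropped.
    """
    out: list[HetRecord] = []
    for i, sid in enumerate(g.sample_ids):
        row = g.calls[i]
        n_obs = int((row != MISSING).sum())
        n_het = int((row == 1).sum())
        if n_obs == 0:
            log.warning("sample %s has no non-missing calls; heterozygosity undefined", sid)
            out.append(HetRecord(sid, 0, 0, float("nan"), defined=False))
        else:
            out.append(HetRecord(sid, n_het, n_obs, n_het / n_obs))
    return out


def het_to_frame(records: list[HetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "IID": [r.sample_id for r in records],
            "N_HET": [r.n_het for r in records],
            "N_OBS": [r.n_obs for r in records],
            "HET": [r.het for r in records],
        }
    )
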