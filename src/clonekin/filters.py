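"""SNP filter cascade and LD pruning.

Implements the post-calling quality filters of a GBS genotyping pipeline:
distance thinning, per-locus/per-sample missingness caps, minor-allele-
frequency thresholds, a mean-depth percentile cap against collapsed
paralogues, an exact Hardy-Weinberg equilibrium (HWE) test, and
sliding-window LD pruning of dosage vectors.

The cascade order used by the pipeline driver is: bi-allelic/min-depth at
read time -> distance thinning -> missingness -> depth percentile -> HWE ->
MAF.  Each step can log its survivor counts into a :class:`FilterReport`.

Every filter is idempotent: applying it twice with the same parameters
equals applying it once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, allele_frequencies, minor_allele_frequencies

log = logging.getLogger(__name__)


@dataclass
class FilterStep:
    name: str
    loci_before: int
    loci_after: int
    samples_before: int
    samples_after: int


@dataclass
class FilterReport:
    """Ordered log of survivor counts, one row per filter step."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, before: GenotypeMatrix, after: GenotypeMatrix) -> None:
        step = FilterStep(
            name, before.n_loci, after.n_loci, before.n_samples, after.n_samples
        )
        self.steps.append(step)
        log.info(
            "filter %-18s loci %d -> %d, samples %d -> %d",
            name, step.loci_before, step.loci_after,
            step.samples_before, step.samples_after,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(s) for s in self.steps],
            columns=["name", "loci_before", "loci_after", "samples_before", "samples_after"],
        )


def _report(report: FilterReport | None, name: str, before: GenotypeMatrix, after: GenotypeMatrix) -> None:
    if report is not None:
        report.add(name, before, after)


# ----------------------------------------------------------------------


def thin_by_distance(
    g: GenotypeMatrix, min_bp: int, report: FilterReport | None = None
) -> GenotypeMatrix:
    """Greedy left-to-right distance thinning, per chromosome.

    Keep a locus iff its position is at least ``min_bp`` away from the last
    kept locus on the same chromosome; the retained loci are then pairwise
    >= ``min_bp`` apart within each chromosome.
    """
    keep: list[int] = []
    last_chrom: str | None = None
    last_pos = -(10**12)
    for j, locus in enumerate(g.loci):
        if locus.chrom != last_chrom or locus.pos - last_pos >= min_bp:
            keep.append(j)
            last_chrom, last_pos = locus.chrom, locus.pos
    out = g.take_loci(keep)
    _report(report, f"thin>={min_bp}bp", g, out)
    return out


def filter_missingness(
    g: GenotypeMatrix, max_missing_rate: float, report: FilterReport | None = None
) -> GenotypeMatrix:
    """Cap the missing fraction per locus, then per sample.

    Loci whose missing fraction exceeds ``max_missing_rate`` are dropped
    first; sample missingness is then computed on the surviving loci and
    samples above the cap are dropped too.
    """
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    miss = g.missing_mask()
    locus_keep = np.flatnonzero(miss.mean(axis=0) <= max_missing_rate)
    out = g.take_loci(locus_keep)
    if out.n_loci:
        sample_keep = np.flatnonzero(out.missing_mask().mean(axis=1) <= max_missing_rate)
    else:
        sample_keep = np.arange(out.n_samples)
    out = out.take_samples(sample_keep)
    _report(report, f"missing<={max_missing_rate:g}", g, out)
    return out


def filter_maf(
    g: GenotypeMatrix, min_maf: float, report: FilterReport | None = None
) -> GenotypeMatrix:
    """Retain loci with minor allele frequency strictly above ``min_maf``.

    Loci whose frequency is undefined (no non-missing calls) are dropped
    with a warning.
    """
    maf = minor_allele_frequencies(g)
    undef = np.isnan(maf)
    if undef.any():
        log.warning("%d loci with undefined frequency dropped by MAF filter", int(undef.sum()))
    out = g.take_loci(np.flatnonzero(~undef & (maf > min_maf)))
    _report(report, f"maf>{min_maf:g}", g, out)
    return out


def locus_mean_depths(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus mean read depth over non-missing calls.

    Computed from the depth table when present, else taken from the stored
    ``Locus.mean_depth`` attributes; NaN where no depth exists.
    """
    depths = np.array([l.mean_depth for l in g.loci], dtype=float)
    if g.depth is not None:
        called = g.calls != MISSING
        with np.errstate(invalid="ignore"):
            depths = np.where(
                called.any(axis=0),
                (g.depth * called).sum(axis=0) / np.maximum(called.sum(axis=0), 1),
                np.nan,
            )
    return depths


def filter_depth_cap(
    g: GenotypeMatrix, max_mean_depth: float, report: FilterReport | None = None
) -> GenotypeMatrix:
    """Drop loci with mean read depth strictly above an absolute cap."""
    depths = locus_mean_depths(g)
    keep = np.flatnonzero(~(depths > max_mean_depth))  # NaN-depth loci retained
    out = g.take_loci(keep)
    _report(report, f"depth<={max_mean_depth:g}", g, out)
    return out


def filter_depth_percentile(
    g: GenotypeMatrix, percentile: float = 90.0, report: FilterReport | None = None
) -> GenotypeMatrix:
    """Drop loci whose mean read depth exceeds the stated empirical
    percentile of the per-locus mean-depth distribution.

    Unusually deep loci are the signature of collapsed paralogous regions.
    The percentile uses numpy's linear-interpolation convention; survivor
    counts depend on that choice, so it is fixed here.  Note the cutoff is
    re-estimated from whatever matrix the filter receives: the percentile
    form is a one-shot step, while :func:`filter_depth_cap` (absolute
    cutoff) is idempotent.  Without depth data the step is skipped with a
    warning.
    """
    depths = locus_mean_depths(g)
    if np.isnan(depths).all():
        log.warning("no depth information; depth-percentile filter skipped")
        _report(report, f"depth<=p{percentile:g} (skipped)", g, g)
        return g
    cutoff = float(np.nanpercentile(depths, percentile))
    return filter_depth_cap(g, cutoff, report)


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int, mode: str = "two-sided") -> float:
    """Exact conditional HWE test on one locus's genotype counts.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of matching parity; the two-sided p-value sums the
    probabilities of all configurations no more likely than the observed
    one.  ``mode="excess-het"`` gives the one-sided tail toward
    heterozygote excess.  A monomorphic locus returns p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    if mode not in ("two-sided", "excess-het"):
        raise ValueError(f"unknown mode {mode!r}")
    n_A = 2 * n_AA + n_Aa
    if n_A == 0 or n_A == 2 * n:
        return 1.0

    rare = min(n_A, 2 * n - n_A)
    # possible het counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    lg = math.lgamma
    logw = np.array(
        [
            h * math.log(2.0)
            - lg((rare - h) // 2 + 1)
            - lg(h + 1)
            - lg(n - (rare + h) // 2 + 1)
            for h in hets
        ]
    )
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    if mode == "excess-het":
        p = probs[hets >= n_Aa].sum()
    else:
        p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def genotype_counts(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus (n_hom_ref, n_het, n_hom_alt) counts, shape (n_loci, 3)."""
    return np.stack([(g.calls == d).sum(axis=0) for d in (0, 1, 2)], axis=1)


def filter_hwe(
    g: GenotypeMatrix,
    alpha: float = 1e-4,
    mode: str = "two-sided",
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Drop loci with exact HWE p-value below ``alpha``."""
    counts = genotype_counts(g)
    keep = [
        j
        for j in range(g.n_loci)
        if counts[j].sum() == 0
        or hwe_exact_test(*(int(c) for c in counts[j]), mode=mode) >= alpha
    ]
    out = g.take_loci(keep)
    _report(report, f"hwe p>={alpha:g}", g, out)
    return out


# ----------------------------------------------------------------------
# LD pruning


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete calls; 0 when either is constant or < 2 calls."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0.0 or yv.std() == 0.0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    g: GenotypeMatrix,
    window: int = 10,
    step: int = 3,
    r2_max: float = 0.5,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Sliding-window LD pruning of dosage vectors.

    Windows of ``window`` surviving SNPs advance by ``step`` within each
    chromosome.  Within a window, while any retained pair has squared
    Pearson correlation above ``r2_max``, the member with the lower MAF is
    removed (tie: the later position goes).  Sweeps repeat until a full pass
    removes nothing, so on termination no retained pair inside any window
    violates the threshold.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 1 <= step <= window:
        raise ValueError("step must satisfy 1 <= step <= window")
    maf = minor_allele_frequencies(g)
    chroms = np.array([l.chrom for l in g.loci])
    keep = np.ones(g.n_loci, dtype=bool)

    def prune_window(idx: list[int]) -> bool:
        removed = False
        while True:
            live = [j for j in idx if keep[j]]
            violating: tuple[int, int] | None = None
            for a in range(len(live)):
                for b in range(a + 1, len(live)):
                    if _pairwise_r2(g.calls[:, live[a]], g.calls[:, live[b]]) > r2_max:
                        violating = (live[a], live[b])
                        break
                if violating:
                    break
            if violating is None:
                return removed
            ja, jb = violating
            # drop lower MAF; tie -> later position
            if (maf[ja], -g.loci[ja].pos) < (maf[jb], -g.loci[jb].pos):
                keep[ja] = False
            else:
                keep[jb] = False
            removed = True

    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        changed = True
        while changed:
            changed = False
            live = [int(j) for j in cols if keep[j]]
            start = 0
            while start < len(live):
                if prune_window(live[start : start + window]):
                    changed = True
                start += step
    out = g.take_loci(np.flatnonzero(keep))
    _report(report, f"ld-prune {window}/{step}/{r2_max:g}", g, out)
    return out
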