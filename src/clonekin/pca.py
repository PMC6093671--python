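"""Population structure: imputation, PCA and group-difference tests.

The genotype table (samples x loci dosage) is completed by mean imputation,
centered and scaled per locus (population standard deviation, divide-by-n),
and decomposed by SVD.  Scores on the leading components summarize
structure; group separation along a component is tested with a
Mann-Whitney U test and Bonferroni correction, and two score sets for the
same samples (e.g. from two marker systems) are compared by Pearson
correlation of their leading five components with the same correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Scores, explained-variance fractions and loadings of a PCA."""

    scores: pd.DataFrame  # samples x k, columns PC1..PCk
    explained_variance_fraction: np.ndarray
    k: int
    loadings: np.ndarray | None = None


@dataclass
class GroupTest:
    """One Mann-Whitney comparison of two groups along one component."""

    grouping: str
    component: int
    u_statistic: float
    p_raw: float
    p_adjusted: float
    n_a: int
    n_b: int


def mean_impute(g: GenotypeMatrix) -> np.ndarray:
    """Complete the dosage table by replacing MISSING with the locus mean.

    Raises on a locus with no non-missing call (its mean is undefined).
    """
    calls = g.calls.astype(float)
    obs = g.calls != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.flatnonzero(n_obs == 0)[0])
        locus = g.loci[j]
        raise ValueError(f"locus {locus.chrom}:{locus.pos} has no non-missing calls")
    means = np.where(obs, calls, 0.0).sum(axis=0) / n_obs
    return np.where(obs, calls, means[None, :])


def center_scale(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize columns: subtract the mean, divide by the population
    (divide-by-n) standard deviation.

    Zero-variance columns carry no information and would divide by zero;
    they are dropped with a warning.  Returns the standardized table and a
    boolean mask of retained columns.
    """
    table = np.asarray(table, dtype=float)
    if table.shape[0] < 2:
        raise ValueError("center_scale needs at least 2 samples")
    mu = table.mean(axis=0)
    sd = table.std(axis=0)  # ddof=0
    keep = sd > 0
    if (~keep).any():
        log.warning("%d zero-variance columns dropped before scaling", int((~keep).sum()))
    return (table[:, keep] - mu[keep]) / sd[keep], keep


def pca(table: np.ndarray, k: int, sample_ids: list[str] | None = None) -> PcaResult:
    """PCA of a standardized table by singular value decomposition.

    Scores are the projections onto the top-``k`` right singular directions;
    the explained fraction of component i is its eigenvalue over the total
    variance.  Component signs are normalized so each component's
    largest-magnitude loading is positive, making outputs reproducible.
    """
    table = np.asarray(table, dtype=float)
    n, m = table.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n_samples - 1, n_loci) = {min(n - 1, m)}")
    u, s, vt = np.linalg.svd(table - table.mean(axis=0), full_matrices=False)
    # sign convention: largest-magnitude loading positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    eig = s**2
    frac = eig / eig.sum() if eig.sum() > 0 else np.zeros_like(eig)
    scores = u[:, :k] * s[:k]
    idx = sample_ids if sample_ids is not None else list(range(n))
    return PcaResult(
        scores=pd.DataFrame(scores, index=idx, columns=[f"PC{i+1}" for i in range(k)]),
        explained_variance_fraction=frac[:k],
        k=k,
        loadings=vt[:k].T,
    )


def mann_whitney_u(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U of the first group, p-value).

    Exact enumeration when the combined sample is <= 12 with no ties,
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    exact = combined.size <= 12 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def group_difference_tests(
    scores: pd.DataFrame,
    labels: pd.Series,
    grouping: str,
    components: tuple[int, ...] = (1, 2),
    m: int = 25,
) -> list[GroupTest]:
    """Mann-Whitney tests between the two label groups along components.

    ``labels`` must take exactly two values over the score index; p-values
    are Bonferroni-adjusted by the experiment-wide comparison count ``m``.
    """
    labels = labels.loc[scores.index]
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, got {groups}")
    out = []
    for comp in components:
        col = scores[f"PC{comp}"]
        va = col[labels == groups[0]].values
        vb = col[labels == groups[1]].values
        u, p = mann_whitney_u(va, vb)
        out.append(GroupTest(grouping, comp, u, p, bonferroni(p, m), va.size, vb.size))
    return out


def correlate_pc_sets(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, m: int = 25
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlation between two 5-component score sets.

    Returns (r, raw p, adjusted p) as k_a x k_b DataFrames; p-values come
    from the t-distribution of r and are Bonferroni-adjusted by ``m``
    (default 25 = 5 x 5 comparisons).
    """
    if list(scores_a.index) != list(scores_b.index):
        raise ValueError("score sets must cover the same samples in the same order")
    r = pd.DataFrame(index=scores_a.columns, columns=scores_b.columns, dtype=float)
    p_raw = r.copy()
    for ca in scores_a.columns:
        for cb in scores_b.columns:
            rr, pp = stats.pearsonr(scores_a[ca].values, scores_b[cb].values)
            r.loc[ca, cb] = rr
            p_raw.loc[ca, cb] = pp
    p_adj = p_raw.map(lambda p: bonferroni(float(p), m))
    return r, p_raw, p_adj
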