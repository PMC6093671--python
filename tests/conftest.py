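import numpy as np
import pytest

from clonekin.matrix import GenotypeMatrix, Locus


def make_matrix(calls, positions=None, chrom="1", depth=None, sample_ids=None,
                mean_depths=None):
    """Build a GenotypeMatrix from a nested list of dosages (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(m)]
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    if mean_depths is None:
        mean_depths = [float("nan")] * m
    loci = [Locus(chrom, positions[j], "A", "C", mean_depths[j]) for j in range(m)]
    return GenotypeMatrix(sample_ids=sample_ids, loci=loci, calls=calls,
                          depth=None if depth is None else np.asarray(depth))


@pytest.fixture
def small_noisy_matrix():
    """60 samples x 300 loci with missing calls, for idempotence checks."""
    from clonekin.simulate import SimulationConfig, simulate_collection

    cfg = SimulationConfig(
        n_loci=300, n_founders=40, clone_group_sizes=[3, 2, 2],
        n_parent_offspring_pairs=5, n_triploids=10,
        error_rate=0.01, missing_rate=0.1, seed=42,
    )
    g, _ = simulate_collection(cfg)
    return g
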