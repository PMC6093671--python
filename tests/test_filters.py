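"""Filter cascade: thinning, missingness, MAF, depth cap, HWE, LD pruning."""

import itertools

import numpy as np
import pytest
from scipy.stats import multinomial

from clonekin.filters import (
    FilterReport,
    filter_depth_cap,
    filter_depth_percentile,
    filter_hwe,
    filter_maf,
    filter_missingness,
    hwe_exact_test,
    ld_prune,
    thin_by_distance,
)
from clonekin.matrix import MISSING, GenotypeMatrix, Locus

from conftest import make_matrix


class TestThinByDistance:
    def test_greedy_scan(self):
        g = make_matrix([[0, 1, 2]], positions=[100, 105, 115])
        out = thin_by_distance(g, 10)
        assert [l.pos for l in out.loci] == [100, 115]

    def test_identity_when_already_spaced(self):
        g = make_matrix([[0, 1, 2]], positions=[100, 110, 125])
        assert thin_by_distance(g, 10).n_loci == 3

    def test_per_chromosome_rule(self):
        loci = [Locus("1", 100, "A", "C"), Locus("2", 100, "A", "C")]
        g = GenotypeMatrix(["s"], loci, np.array([[0, 1]], dtype=np.int8))
        assert thin_by_distance(g, 10).n_loci == 2

    def test_retained_loci_pairwise_spaced(self, small_noisy_matrix):
        out = thin_by_distance(small_noisy_matrix, 1500)
        pos = [l.pos for l in out.loci]
        assert all(b - a >= 1500 for a, b in zip(pos, pos[1:]))


class TestFilterMissingness:
    def test_locus_above_cap_dropped(self):
        col = [[MISSING]] * 3 + [[0]] * 7
        g = make_matrix(np.array(col))
        assert filter_missingness(g, 0.2).n_loci == 0

    def test_complete_matrix_untouched(self):
        g = make_matrix([[0, 1], [2, 1]])
        out = filter_missingness(g, 0.2)
        assert out.n_loci == 2 and out.n_samples == 2

    def test_sample_pass_runs_on_surviving_loci(self):
        # locus 0 is missing everywhere and is dropped first; sample S01 is
        # then missing at 1/4 (25%) of the surviving loci and is dropped too
        calls = np.array(
            [
                [MISSING, MISSING, 0, 1, 2],
                [MISSING, 0, 0, 1, 2],
                [MISSING, 1, 1, 1, 0],
                [MISSING, 2, 0, 0, 0],
                [MISSING, 0, 1, 2, 1],
            ]
        )
        out = filter_missingness(make_matrix(calls), 0.2)
        assert out.n_loci == 4
        assert out.sample_ids == ["S02", "S03", "S04", "S05"]


class TestFilterMaf:
    @pytest.mark.parametrize(
        "freq, kept",
        [(0.04, False), (0.5, True), (0.95, False)],  # 0.95 folds to MAF 0.05, strict
    )
    def test_strict_threshold(self, freq, kept):
        n = 100
        n_alt = int(round(2 * n * freq))
        column = [1] * (n_alt % 2) + [2] * (n_alt // 2)
        column += [0] * (n - len(column))
        g = make_matrix([[c] for c in column])
        from clonekin.matrix import allele_frequencies

        assert allele_frequencies(g)[0] == pytest.approx(freq)
        assert filter_maf(g, 0.05).n_loci == (1 if kept else 0)

    def test_undefined_frequency_dropped(self):
        g = make_matrix([[MISSING], [MISSING]])
        assert filter_maf(g, 0.05).n_loci == 0


class TestFilterDepthPercentile:
    def test_empirical_percentile_cap(self):
        # mean depths 1..10: the 90th percentile (linear interpolation) is
        # 9.1, so only the depth-10 locus is dropped
        depth = np.tile(np.arange(1, 11), (4, 1))
        g = make_matrix(np.zeros((4, 10), dtype=np.int8) + np.array([0, 1] * 5),
                        depth=depth)
        out = filter_depth_percentile(g, 90.0)
        assert out.n_loci == 9
        assert all(l.pos != 10_000 for l in out.loci)

    def test_uniform_depths_identity(self):
        g = make_matrix([[0, 1], [1, 2]], depth=[[7, 7], [7, 7]])
        assert filter_depth_percentile(g, 90.0).n_loci == 2

    def test_percentile_100_identity(self):
        g = make_matrix([[0, 1], [1, 2]], depth=[[3, 9], [5, 30]])
        assert filter_depth_percentile(g, 100.0).n_loci == 2

    def test_no_depth_information_skips(self):
        g = make_matrix([[0, 1], [1, 2]])
        out = filter_depth_percentile(g, 90.0)
        assert out.n_loci == 2


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent HWE exact-test oracle: full multinomial enumeration.

    Draws the conditional law of the het count given allele counts from the
    multinomial sampling distribution under HWE at an arbitrary frequency
    (the conditional law is frequency-free), then sums configurations no
    more probable than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    if n_A == 0 or n_A == 2 * n:
        return 1.0
    p = 0.37  # arbitrary; cancels in the conditional
    probs = [p * p, 2 * p * (1 - p), (1 - p) ** 2]
    weights = {}
    for a in range(n + 1):
        for h in range(n - a + 1):
            if 2 * a + h == n_A:
                weights[h] = multinomial.pmf([a, h, n - a - h], n, probs)
    total = sum(weights.values())
    p_obs = weights[n_Aa] / total
    return sum(w for w in weights.values() if w / total <= p_obs * (1 + 1e-12)) / total


class TestHweExactTest:
    def test_balanced_counts_not_extreme(self):
        p = hwe_exact_test(25, 50, 25)
        assert p >= 0.5
        assert p == pytest.approx(hwe_oracle(25, 50, 25), abs=1e-12)

    def test_all_heterozygote_excess_flagged(self):
        assert hwe_exact_test(0, 50, 0) < 1e-4

    def test_monomorphic_convention(self):
        assert hwe_exact_test(30, 0, 0) == 1.0

    def test_agrees_with_multinomial_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        cases = [(25, 50, 25), (0, 50, 0), (1, 0, 20), (5, 5, 5), (0, 1, 0)]
        for _ in range(40):
            n = int(rng.integers(1, 51))
            a = int(rng.integers(0, n + 1))
            h = int(rng.integers(0, n - a + 1))
            cases.append((a, h, n - a - h))
        for n_AA, n_Aa, n_aa in cases:
            got = hwe_exact_test(n_AA, n_Aa, n_aa)
            want = hwe_oracle(n_AA, n_Aa, n_aa)
            assert got == pytest.approx(want, abs=1e-12), (n_AA, n_Aa, n_aa)

    def test_excess_het_mode_is_one_sided(self):
        # heterozygote deficit is extreme two-sided but not in the excess tail
        assert hwe_exact_test(25, 0, 25) < 1e-4
        assert hwe_exact_test(25, 0, 25, mode="excess-het") == pytest.approx(1.0)


class TestFilterHwe:
    def test_extreme_locus_dropped(self):
        calls = np.array([[1] * 30, [0] * 15 + [1] * 15]).T  # locus 0: all-het
        g = make_matrix(calls)
        out = filter_hwe(g, 1e-4)
        assert out.n_loci == 1

    def test_alpha_zero_identity(self, small_noisy_matrix):
        assert filter_hwe(small_noisy_matrix, 0.0).n_loci == small_noisy_matrix.n_loci

    def test_hwe_proportioned_locus_kept(self):
        column = [0] * 25 + [1] * 50 + [2] * 25
        g = make_matrix([[c] for c in column])
        assert filter_hwe(g, 1e-4).n_loci == 1


class TestLdPrune:
    def test_duplicated_column_pruned(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=20)
        calls = np.stack([base, base, rng.integers(0, 3, size=20)], axis=1)
        out = ld_prune(make_matrix(calls), window=10, step=3, r2_max=0.5)
        assert out.n_loci == 2

    def test_orthogonal_columns_untouched(self):
        calls = np.array([[0, 0], [1, 0], [2, 0], [0, 1], [1, 1], [2, 1],
                          [0, 2], [1, 2], [2, 2]])
        assert ld_prune(make_matrix(calls), 10, 3, 0.5).n_loci == 2

    def test_three_identical_columns_leave_one(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, size=30)
        calls = np.stack([base] * 3, axis=1)
        out = ld_prune(make_matrix(calls), window=10, step=3, r2_max=0.5)
        assert out.n_loci == 1

    def test_postcondition_no_window_pair_above_threshold(self):
        # correlated blocks: every surviving within-window pair must satisfy
        # the r^2 cap (machine-checked audit of the pruner's contract)
        rng = np.random.default_rng(3)
        n, m = 60, 40
        base = rng.integers(0, 3, size=(n, 8))
        cols = [base[:, rng.integers(0, 8)].copy() for _ in range(m)]
        for c in cols[::3]:
            flip = rng.random(n) < 0.1
            c[flip] = rng.integers(0, 3, size=int(flip.sum()))
        g = make_matrix(np.stack(cols, axis=1))
        window, step, r2_max = 10, 3, 0.5
        out = ld_prune(g, window, step, r2_max)
        from clonekin.filters import _pairwise_r2

        survivors = out.calls
        start = 0
        while start < out.n_loci:
            idx = range(start, min(start + window, out.n_loci))
            for a, b in itertools.combinations(idx, 2):
                assert _pairwise_r2(survivors[:, a], survivors[:, b]) <= r2_max
            start += step

    def test_zero_variance_column_treated_as_uncorrelated(self):
        calls = np.array([[0, 0], [0, 1], [0, 2], [0, 1]])
        assert ld_prune(make_matrix(calls), 10, 3, 0.5).n_loci == 2


class TestIdempotence:
    @pytest.mark.parametrize(
        "apply",
        [
            lambda g: thin_by_distance(g, 2000),
            lambda g: filter_missingness(g, 0.15),
            lambda g: filter_maf(g, 0.05),
            lambda g: filter_depth_cap(g, 31.0),
            lambda g: filter_hwe(g, 1e-3),
            lambda g: ld_prune(g, 10, 3, 0.5),
        ],
        ids=["thin", "missingness", "maf", "depth", "hwe", "ld_prune"],
    )
    def test_filter_applied_twice_equals_once(self, small_noisy_matrix, apply):
        once = apply(small_noisy_matrix)
        twice = apply(once)
        assert twice.sample_ids == once.sample_ids
        assert [(l.chrom, l.pos) for l in twice.loci] == [
            (l.chrom, l.pos) for l in once.loci
        ]
        np.testing.assert_array_equal(twice.calls, once.calls)


class TestFilterReport:
    def test_counts_recorded_per_step(self, small_noisy_matrix):
        report = FilterReport()
        g = thin_by_distance(small_noisy_matrix, 1000, report)
        g = filter_missingness(g, 0.15, report)
        g = filter_maf(g, 0.05, report)
        frame = report.to_frame()
        assert list(frame["name"])[0].startswith("thin")
        assert (frame["loci_after"] <= frame["loci_before"]).all()
        assert (frame["samples_after"] <= frame["samples_before"]).all()
        # chained: each step starts where the previous ended
        assert list(frame["loci_before"][1:]) == list(frame["loci_after"][:-1])
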