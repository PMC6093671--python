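"""Imputation, scaling, PCA and group-difference statistics."""

import numpy as np
import pandas as pd
import pytest

from clonekin.matrix import MISSING
from clonekin.pca import (
    bonferroni,
    center_scale,
    correlate_pc_sets,
    group_difference_tests,
    mann_whitney_u,
    mean_impute,
    pca,
)
from clonekin.simulate import SimulationConfig, simulate_collection

from conftest import make_matrix


class TestMeanImpute:
    def test_missing_replaced_by_column_mean(self):
        g = make_matrix([[0], [2], [MISSING]])
        np.testing.assert_allclose(mean_impute(g)[:, 0], [0.0, 2.0, 1.0])

    def test_complete_matrix_identity(self):
        g = make_matrix([[0, 1], [2, 1]])
        np.testing.assert_array_equal(mean_impute(g), g.calls.astype(float))

    def test_singleton_mean(self):
        g = make_matrix([[1], [MISSING], [MISSING]])
        np.testing.assert_allclose(mean_impute(g)[:, 0], [1.0, 1.0, 1.0])

    def test_all_missing_locus_is_an_error(self):
        g = make_matrix([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="1:1000"):
            mean_impute(g)


class TestCenterScale:
    def test_population_sd_convention(self):
        scaled, keep = center_scale(np.array([[0.0], [1.0], [2.0]]))
        np.testing.assert_allclose(scaled[:, 0], [-1.224744871, 0.0, 1.224744871])
        assert keep.all()

    def test_constant_column_dropped(self):
        scaled, keep = center_scale(np.array([[1.0, 0.0], [1.0, 2.0]]))
        np.testing.assert_array_equal(keep, [False, True])
        assert scaled.shape == (2, 1)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 5))
        once, _ = center_scale(x)
        twice, _ = center_scale(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)


class TestPca:
    def test_rank_one_table(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.5, -1.0, 2.0])
        result = pca(np.outer(u, v), k=2)
        assert result.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_duplicated_sample_rows_get_identical_scores(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 8))
        x[1] = x[0]
        result = pca(x, k=3)
        np.testing.assert_allclose(result.scores.iloc[0], result.scores.iloc[1], atol=1e-10)

    def test_eigenvalues_match_direct_eigendecomposition(self):
        # independent route: eigenvalues of X'X for a small known table
        x = np.array([[2.0, 0.0, 1.0], [0.0, 1.0, -1.0], [-2.0, -1.0, 0.0]])
        xc = x - x.mean(axis=0)
        want = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        result = pca(x, k=2)
        got = result.explained_variance_fraction * want.sum()
        np.testing.assert_allclose(got, want[:2], atol=1e-10)

    def test_scores_orthogonal_and_fractions_normalized(self):
        rng = np.random.default_rng(3)
        x, _ = center_scale(rng.normal(size=(30, 12)))
        result = pca(x, k=12)
        gram = result.scores.values.T @ result.scores.values
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert result.explained_variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(result.explained_variance_fraction) <= 1e-12).all()
        assert np.abs(result.scores.values.mean(axis=0)).max() < 1e-10

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(15, 6))
        a = pca(x, k=3)
        b = pca(x.copy(), k=3)
        np.testing.assert_array_equal(a.scores.values, b.scores.values)
        for i in range(3):
            j = int(np.argmax(np.abs(a.loadings[:, i])))
            assert a.loadings[j, i] > 0

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            pca(np.zeros((3, 5)), k=3)


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_three_vs_three(self):
        # 2 of the C(6,3)=20 labelings are at least as extreme: p = 0.1
        u, p = mann_whitney_u([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert u == 9.0
        assert p == pytest.approx(0.1)

    def test_group_swap_symmetry(self):
        a, b = [4.0, 5.0, 6.0], [1.0, 2.0, 3.0]
        ua, pa = mann_whitney_u(a, b)
        ub, pb = mann_whitney_u(b, a)
        assert ua == len(a) * len(b) - ub
        assert pa == pytest.approx(pb)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, want", [(0.001, 25, 0.025), (0.2, 25, 1.0), (0.37, 1, 0.37)]
    )
    def test_adjustment(self, p, m, want):
        assert bonferroni(p, m) == pytest.approx(want)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 25)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestCorrelatePcSets:
    def test_self_correlation(self):
        rng = np.random.default_rng(5)
        scores = pd.DataFrame(rng.normal(size=(40, 5)),
                              columns=[f"PC{i+1}" for i in range(5)])
        r, p_raw, p_adj = correlate_pc_sets(scores, scores)
        np.testing.assert_allclose(np.diag(r.values.astype(float)), 1.0)
        assert (np.diag(p_adj.values.astype(float)) < 0.05).all()

    def test_negated_scores(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(rng.normal(size=(40, 5)),
                              columns=[f"PC{i+1}" for i in range(5)])
        r, _, _ = correlate_pc_sets(scores, -scores)
        np.testing.assert_allclose(np.diag(r.values.astype(float)), -1.0)

    def test_independent_sets_mostly_non_significant(self):
        rng = np.random.default_rng(7)
        a = pd.DataFrame(rng.normal(size=(100, 5)), columns=[f"PC{i+1}" for i in range(5)])
        b = pd.DataFrame(rng.normal(size=(100, 5)), columns=[f"PC{i+1}" for i in range(5)])
        r, _, p_adj = correlate_pc_sets(a, b)
        assert np.abs(r.values.astype(float)).max() < 0.3
        assert (p_adj.values.astype(float) == 1.0).mean() > 0.8

    def test_mismatched_samples_rejected(self):
        a = pd.DataFrame(np.zeros((3, 2)), index=["x", "y", "z"])
        b = pd.DataFrame(np.zeros((3, 2)), index=["x", "z", "y"])
        with pytest.raises(ValueError):
            correlate_pc_sets(a, b)


def _pc1_species_test(cfg):
    from clonekin.pca import pca as run_pca

    g, truth = simulate_collection(cfg)
    table, _ = center_scale(mean_impute(g))
    result = run_pca(table, k=2, sample_ids=list(g.sample_ids))
    labels = pd.Series({s: truth.population.get(s, "P1") for s in g.sample_ids})
    (test,) = group_difference_tests(result.scores, labels, "population",
                                     components=(1,))
    return test


class TestStructureDetection:
    def test_power_grows_with_divergence(self):
        # two founder subpopulations drifted apart: PC1 separates them and
        # the Bonferroni-corrected Mann-Whitney test rejects
        cfg = SimulationConfig(
            n_loci=400, n_founders=60, clone_group_sizes=[1],
            n_parent_offspring_pairs=0, n_triploids=0,
            missing_rate=0.0, seed=8,
            n_divergent_founders=30, divergence=0.15,
        )
        rejections = 0
        for seed in range(10):
            cfg.seed = 800 + seed
            if _pc1_species_test(cfg).p_adjusted < 0.05:
                rejections += 1
        assert rejections >= 9

    def test_type_i_error_controlled_without_structure(self):
        # homogeneous founders, arbitrary 50/50 labeling: raw-p rejection
        # rate at alpha=0.05 stays within binomial noise of nominal
        n_reps, alpha = 200, 0.05
        rejections = 0
        for seed in range(n_reps):
            cfg = SimulationConfig(
                n_loci=60, n_founders=24, clone_group_sizes=[1],
                n_parent_offspring_pairs=0, n_triploids=0,
                missing_rate=0.0, seed=2000 + seed,
                n_divergent_founders=12, divergence=0.0,  # labels but no drift
            )
            g, truth = simulate_collection(cfg)
            table, _ = center_scale(mean_impute(g))
            result = pca(table, k=1, sample_ids=list(g.sample_ids))
            labels = pd.Series({s: truth.population.get(s, "P1") for s in g.sample_ids})
            (test,) = group_difference_tests(result.scores, labels, "population",
                                             components=(1,), m=1)
            if test.p_raw < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert rejections / n_reps <= alpha + 3 * se
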