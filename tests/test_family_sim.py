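"""Family simulation engine: sampling distributions, sharing structure, moments."""

import numpy as np
import pytest

from lptwin import (
    CorrelationSpec,
    LPParams,
    build_covariances,
    mendelian_offspring,
    simulate_cohort,
    simulate_parents,
    twin_correlations,
)


def sample_cov(x, y):
    return ((x - x.mean(0)).T @ (y - y.mean(0))) / (len(x) - 1)


class TestParents:
    def test_additive_covariance_matches_model(self):
        p = LPParams(k=2, h2_path=0.5, corr=CorrelationSpec("uniform", 0.2))
        cov = build_covariances(p)
        A, _ = simulate_parents(200_000, p, np.random.default_rng(1))
        np.testing.assert_allclose(sample_cov(A, A), cov.sigmaA, atol=0.01)

    def test_environment_variance_is_total(self):
        p = LPParams(k=2, h2_path=0.5, c2_path=0.4)
        _, E = simulate_parents(200_000, p, np.random.default_rng(2))
        # parents carry varC + varU = 0.5 per pathway, unsplit
        np.testing.assert_allclose(E.var(axis=0), [0.5, 0.5], atol=0.01)

    def test_pathway_mean_shift(self):
        p = LPParams(k=2, mu=(3.0, -1.0), h2_path=0.5)
        cohort = simulate_cohort(p, 100_000, 3)
        np.testing.assert_allclose(cohort.mother.P.mean(axis=0), [3.0, -1.0],
                                   atol=0.02)

    def test_random_mating_no_spousal_covariance(self):
        p = LPParams(k=2, h2_path=0.5)
        cohort = simulate_cohort(p, 200_000, 4)
        cross = sample_cov(cohort.mother.A, cohort.father.A)
        np.testing.assert_allclose(cross, 0.0, atol=0.01)


@pytest.fixture(scope="module")
def cohort():
    p = LPParams(k=2, h2_path=0.5, corr=CorrelationSpec("uniform", 0.2))
    return simulate_cohort(p, 200_000, 5), build_covariances(p)


class TestMendelianSampling:

    def test_offspring_variance_preserved(self, cohort):
        c, cov = cohort
        np.testing.assert_allclose(sample_cov(c.offspring.A, c.offspring.A),
                                   cov.sigmaA, atol=0.01)

    def test_parent_offspring_covariance_half(self, cohort):
        c, cov = cohort
        np.testing.assert_allclose(sample_cov(c.offspring.A, c.mother.A),
                                   0.5 * cov.sigmaA, atol=0.01)

    def test_dz_covariance_half_mz_exact(self, cohort):
        c, cov = cohort
        np.testing.assert_allclose(sample_cov(c.offspring.A, c.dz_twin.A),
                                   0.5 * cov.sigmaA, atol=0.01)
        np.testing.assert_array_equal(c.offspring.A, c.mz_twin.A)

    def test_mendelian_deviation_independent_of_parents(self):
        p = LPParams(k=2, h2_path=0.6)
        cov = build_covariances(p)
        rng = np.random.default_rng(6)
        A_m, _ = simulate_parents(200_000, p, rng)
        A_f, _ = simulate_parents(200_000, p, rng)
        A_off = mendelian_offspring(A_m, A_f, cov.sigmaA, rng)
        M = A_off - 0.5 * (A_m + A_f)
        np.testing.assert_allclose(sample_cov(M, M), 0.5 * cov.sigmaA, atol=0.01)
        np.testing.assert_allclose(sample_cov(M, A_m), 0.0, atol=0.01)


class TestSharingStructure:
    def test_common_environment_identical_unique_independent(self):
        p = LPParams(k=2, h2_path=0.3, c2_path=0.5)
        c = simulate_cohort(p, 50_000, 7)
        np.testing.assert_array_equal(c.offspring.C, c.mz_twin.C)
        np.testing.assert_array_equal(c.offspring.C, c.dz_twin.C)
        u_corr = np.corrcoef(c.offspring.U[:, 0], c.dz_twin.U[:, 0])[0, 1]
        assert abs(u_corr) < 0.02

    def test_same_seed_reproduces_cohort(self):
        p = LPParams(k=3, h2_path=0.5, c2_path=0.2,
                     corr=CorrelationSpec("uniform", 0.1))
        c1 = simulate_cohort(p, 5_000, 11)
        c2 = simulate_cohort(p, 5_000, 11)
        np.testing.assert_array_equal(c1.offspring.Y, c2.offspring.Y)
        np.testing.assert_array_equal(c1.dz_twin.P, c2.dz_twin.P)

    def test_flat_export_shape(self):
        p = LPParams(k=2, h2_path=0.5)
        c = simulate_cohort(p, 100, 1)
        df = c.to_frame()
        assert len(df) == 5 * 100  # five roles
        assert {"family", "role", "A1", "A2", "P1", "P2", "Y"} <= set(df.columns)


class TestPhenotypes:
    def test_k1_final_equals_pathway(self):
        p = LPParams(k=1, h2_path=0.5, c2_path=0.2)
        c = simulate_cohort(p, 1_000, 8)
        np.testing.assert_array_equal(c.offspring.Y, c.offspring.P[:, 0])

    def test_min_combine(self):
        p = LPParams(k=2, h2_path=0.5, combine="min")
        c = simulate_cohort(p, 1_000, 9)
        np.testing.assert_array_equal(c.offspring.Y, c.offspring.P.min(axis=1))

    def test_max_of_two_iid_standard_normal_moments(self):
        p = LPParams(k=2, h2_path=0.5)
        c = simulate_cohort(p, 400_000, 10)
        assert c.offspring.Y.mean() == pytest.approx(1 / np.sqrt(np.pi), abs=0.005)
        assert c.offspring.Y.var() == pytest.approx(1 - 1 / np.pi, abs=0.005)

    def test_k1_linear_twin_identities(self):
        p = LPParams(k=1, h2_path=0.5, c2_path=0.0)
        c = simulate_cohort(p, 100_000, 12)
        tw = twin_correlations(c)
        assert tw.r_mz == pytest.approx(0.5, abs=0.01)
        assert tw.r_dz == pytest.approx(0.25, abs=0.01)

    def test_pathway_permutation_leaves_y_distribution_invariant(self):
        base = LPParams(k=2, mu=(0.0, 1.0), sigma2=(1.0, 2.0), h2_path=(0.3, 0.7))
        perm = LPParams(k=2, mu=(1.0, 0.0), sigma2=(2.0, 1.0), h2_path=(0.7, 0.3))
        y1 = simulate_cohort(base, 200_000, 13).offspring.Y
        y2 = simulate_cohort(perm, 200_000, 14).offspring.Y
        assert y1.mean() == pytest.approx(y2.mean(), abs=0.01)
        assert y1.var() == pytest.approx(y2.var(), abs=0.02)

    def test_variance_scaling_leaves_correlations_unchanged(self):
        p1 = LPParams(k=2, h2_path=0.5, c2_path=0.3)
        p2 = LPParams(k=2, sigma2=4.0, h2_path=0.5, c2_path=0.3)
        c1 = simulate_cohort(p1, 50_000, 15)
        c2 = simulate_cohort(p2, 50_000, 15)
        # same seed: identical normal deviates, so scaling is exact
        np.testing.assert_allclose(c2.offspring.Y, 2.0 * c1.offspring.Y,
                                   rtol=1e-12)
        t1, t2 = twin_correlations(c1), twin_correlations(c2)
        assert t1.r_mz == pytest.approx(t2.r_mz, abs=1e-12)
        assert t2.var_p == pytest.approx(4.0 * t1.var_p, rel=1e-12)

    def test_rmz_at_least_rdz_for_nonnegative_rho(self):
        for rho in (0.0, 0.3):
            p = LPParams(k=3, h2_path=0.6, c2_path=0.2,
                         corr=CorrelationSpec("uniform", rho))
            tw = twin_correlations(simulate_cohort(p, 50_000, 16))
            assert tw.r_mz >= tw.r_dz
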