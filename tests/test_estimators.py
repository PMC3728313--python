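"""Twin correlations, ACE decomposition, heritability and phantom estimators."""

import numpy as np
import pytest

from helpers_oracles import narrow_h2_basic_k2, shared_c_cov_basic_k2

from lptwin import (
    LPParams,
    ace_estimates,
    c2_final,
    narrow_sense_h2,
    phantom_heritability,
    run_replicates,
    simulate_cohort,
    twin_correlations,
)


class TestTwinCorrelations:
    def test_mz_unity_without_unique_environment(self):
        # fully heritable trait: MZ co-twin shares the whole genome
        p = LPParams(k=2, h2_path=1.0)
        tw = twin_correlations(simulate_cohort(p, 10_000, 1))
        assert tw.r_mz == pytest.approx(1.0, abs=1e-12)

    def test_linear_identities_high_heritability(self):
        p = LPParams(k=1, h2_path=0.8, c2_path=0.0)
        tw = twin_correlations(simulate_cohort(p, 100_000, 2))
        assert tw.r_mz == pytest.approx(0.8, abs=0.01)
        assert tw.r_dz == pytest.approx(0.4, abs=0.01)

    def test_shuffled_cotwins_uncorrelated(self):
        p = LPParams(k=2, h2_path=0.5, c2_path=0.3)
        c = simulate_cohort(p, 50_000, 3)
        rng = np.random.default_rng(0)
        c.mz_twin.Y = rng.permutation(c.mz_twin.Y)
        c.dz_twin.Y = rng.permutation(c.dz_twin.Y)
        tw = twin_correlations(c)
        assert abs(tw.r_mz) < 0.02 and abs(tw.r_dz) < 0.02

    def test_degenerate_phenotype_raises(self):
        p = LPParams(k=1, h2_path=0.5)
        c = simulate_cohort(p, 1_000, 4)
        for role in ("offspring", "mz_twin", "dz_twin"):
            c.role(role).Y = np.zeros(1_000)
        with pytest.raises(ValueError, match="degenerate"):
            twin_correlations(c)


class TestACE:
    @pytest.mark.parametrize("r_mz,r_dz,h2", [
        (0.89, 0.47, 0.84),   # height
        (0.55, 0.28, 0.54),   # triglycerides
        (0.23, 0.13, 0.20),   # high-fat dairy intake
    ])
    def test_falconer_identity_reproduces_observed_h2(self, r_mz, r_dz, h2):
        est = ace_estimates(r_mz, r_dz)
        assert est.h2_ace == pytest.approx(h2, abs=1e-12)
        assert est.h2_ace + est.c2_ace + est.e2_ace == pytest.approx(1.0)

    def test_equal_correlations_pure_common_environment(self):
        est = ace_estimates(0.37, 0.37)
        assert est.h2_ace == 0.0
        assert est.c2_ace == pytest.approx(0.37)

    def test_no_truncation_of_negative_components(self):
        est = ace_estimates(0.6, 0.1)  # rMZ > 2 rDZ: epistasis signature
        assert est.c2_ace == pytest.approx(-0.4)


class TestNarrowSenseH2:
    def test_linear_case_returns_pathway_heritability(self):
        p = LPParams(k=1, h2_path=0.5)
        c = simulate_cohort(p, 100_000, 5)
        h2 = narrow_sense_h2(c.offspring.Y, c.offspring.A)
        assert h2 == pytest.approx(0.5, abs=0.01)

    def test_pure_noise_phenotype_zero(self):
        p = LPParams(k=2, h2_path=0.5)
        c = simulate_cohort(p, 50_000, 6)
        noise = np.random.default_rng(0).standard_normal(50_000)
        assert narrow_sense_h2(noise, c.offspring.A) == pytest.approx(0.0, abs=0.001)

    def test_matches_quadrature_oracle_basic_k2(self):
        p = LPParams(k=2, h2_path=0.5)
        c = simulate_cohort(p, 100_000, 7)
        h2 = narrow_sense_h2(c.offspring.Y, c.offspring.A)
        assert h2 == pytest.approx(narrow_h2_basic_k2(0.5), abs=0.01)

    def test_rank_deficient_design_warns(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(1_000)
        A = np.column_stack([a, a])  # perfectly collinear pathways
        y = a + rng.standard_normal(1_000)
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            narrow_sense_h2(y, A)

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError):
            narrow_sense_h2(np.zeros(3), np.zeros((3, 2)))


class TestC2Final:
    @pytest.mark.parametrize("method", ["mz_minus_broad", "pair", "regression"])
    def test_linear_case_all_methods(self, method):
        p = LPParams(k=1, h2_path=0.5, c2_path=0.2)
        val = c2_final(p, n=200_000, rng=9, method=method)
        assert val == pytest.approx(0.1, abs=0.01)

    def test_zero_common_environment(self):
        p = LPParams(k=2, h2_path=0.5, c2_path=0.0)
        assert c2_final(p, n=100_000, rng=10) == pytest.approx(0.0, abs=0.01)

    def test_pair_method_matches_quadrature_oracle(self):
        p = LPParams(k=2, h2_path=0.5, c2_path=0.5)
        val = c2_final(p, n=300_000, rng=11, method="pair")
        oracle = shared_c_cov_basic_k2(0.5, 0.5)
        assert 0.0 <= val <= 0.25
        assert val == pytest.approx(oracle, abs=0.01)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            c2_final(LPParams(k=1), method="bogus")


class TestPhantom:
    def test_height_k2_cell_ratio(self):
        assert phantom_heritability(0.55, 0.84) == pytest.approx(0.345, abs=0.001)

    def test_height_k10_cell_ratio(self):
        assert phantom_heritability(0.15, 0.84) == pytest.approx(0.821, abs=0.001)

    def test_no_epistasis_is_zero(self):
        assert phantom_heritability(0.4, 0.4) == 0.0

    def test_nonpositive_ace_estimate_rejected(self):
        with pytest.raises(ValueError):
            phantom_heritability(0.1, 0.0)


class TestRunReplicates:
    def test_fixed_seed_reproducible(self):
        p = LPParams(k=2, h2_path=0.5)
        o1 = run_replicates(p, n_families=5_000, n_reps=3, seed=12)
        o2 = run_replicates(p, n_families=5_000, n_reps=3, seed=12)
        assert o1.means == o2.means and o1.mc_se == o2.mc_se

    def test_epistasis_grows_with_pathway_count(self):
        kwargs = dict(n_families=50_000, n_reps=4, seed=13)
        phantom1 = run_replicates(LPParams(k=1, h2_path=0.5), **kwargs).means["phantom"]
        phantom2 = run_replicates(LPParams(k=2, h2_path=0.5), **kwargs).means["phantom"]
        # ~3 MC standard errors at this replicate budget
        assert phantom1 == pytest.approx(0.0, abs=0.04)
        assert phantom2 > phantom1 + 0.1

    def test_ace_estimate_upward_bias(self):
        # h2_ACE >= h2_narrow whenever pathway correlations are non-negative
        for k, rho in [(2, 0.0), (3, 0.2)]:
            from lptwin import CorrelationSpec
            p = LPParams(k=k, h2_path=0.6, c2_path=0.1,
                         corr=CorrelationSpec("uniform", rho))
            out = run_replicates(p, n_families=50_000, n_reps=3, seed=14)
            assert out.means["h2_ace"] >= out.means["h2_narrow"]

    def test_mc_standard_errors_small_at_scale(self):
        p = LPParams(k=1, h2_path=0.5)
        out = run_replicates(p, n_families=100_000, n_reps=8, seed=15)
        assert out.mc_se["h2_ace"] <= 0.01

    def test_json_round_trip(self):
        import json
        p = LPParams(k=2, h2_path=0.5, c2_path=0.1)
        out = run_replicates(p, n_families=5_000, n_reps=2, seed=16)
        payload = json.loads(out.to_json())
        assert payload["params"]["k"] == 2
        assert set(payload["means"]) == set(out.means)
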