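"""Coalescent-time densities against independent oracles and invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from migsci.densities import (
    density_moments,
    density_mscm,
    density_msci,
    mscm_density,
    msci_density,
    transition_matrix,
)
from migsci.params import MSCMParams, MSciParams


def _Q(w, theta_A):
    c = 2.0 / theta_A
    return np.array([[-w, w, 0.0], [0.0, -c, c], [0.0, 0.0, 0.0]])


def _random_mscm(rng, variant):
    tau_R = rng.uniform(1e-4, 0.05)
    tau_T = 0.0 if variant == "IM" else rng.uniform(0.0, tau_R * 0.95)
    return MSCMParams(
        variant, tau_R, tau_T,
        theta_A=rng.uniform(1e-4, 0.05), theta_B=rng.uniform(1e-4, 0.05),
        theta_T=rng.uniform(1e-4, 0.05), theta_R=rng.uniform(1e-4, 0.05),
        M=rng.uniform(0.0, 2.0),
    )


class TestTransitionMatrix:
    def test_identity_at_t0(self):
        assert np.allclose(transition_matrix(80.0, 0.002, 0.0), np.eye(3))

    def test_matches_matrix_exponential(self):
        P = transition_matrix(80.0, 0.002, 0.002)
        assert np.abs(P - expm(_Q(80.0, 0.002) * 0.002)).max() < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_expm_on_random_grid(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.0, 4 * 2.0 / 1e-4)
        thA = rng.uniform(1e-4, 0.05)
        t = rng.uniform(0.0, 0.05)
        P = transition_matrix(w, thA, t)
        assert np.abs(P - expm(_Q(w, thA) * t)).max() < 1e-10

    def test_near_singularity_w_equals_coalescent_rate(self):
        thA = 0.002
        for w in (2 / thA, 2 / thA * (1 + 1e-10), 2 / thA * (1 - 1e-10)):
            P = transition_matrix(w, thA, 0.001)
            assert np.abs(P - expm(_Q(w, thA) * 0.001)).max() < 1e-10

    @given(
        w=st.floats(0.0, 2000.0),
        thA=st.floats(1e-4, 0.05),
        t=st.floats(0.0, 0.1),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rows_are_stochastic(self, w, thA, t):
        P = transition_matrix(w, thA, t)
        assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-12)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-12

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            w = rng.uniform(0, 2000)
            thA = rng.uniform(1e-4, 0.05)
            s, t = rng.uniform(0, 0.02, 2)
            lhs = transition_matrix(w, thA, s + t)
            rhs = transition_matrix(w, thA, s) @ transition_matrix(w, thA, t)
            assert np.abs(lhs - rhs).max() < 1e-10

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(-1.0, 0.002, 0.001)
        with pytest.raises(ValueError):
            transition_matrix(1.0, 0.002, -0.001)


class TestMscmDensity:
    @pytest.mark.parametrize("variant", ["IM", "IIM", "SC"])
    @pytest.mark.parametrize("seed", range(4))
    def test_normalization_random_grid(self, variant, seed):
        p = _random_mscm(np.random.default_rng(100 + seed), variant)
        assert mscm_density(p).integral() == pytest.approx(1.0, abs=1e-8)

    def test_iim_with_tau_T_zero_equals_im(self, im_params):
        iim0 = dataclasses.replace(im_params, variant="IIM")
        ts = np.linspace(0, 0.03, 400)
        np.testing.assert_allclose(
            density_mscm(ts, iim0), density_mscm(ts, im_params), atol=1e-12
        )

    def test_no_gene_flow_limit(self, im_params):
        p = dataclasses.replace(im_params, M=0.0)
        d = mscm_density(p)
        assert d(p.tau_R * 0.5) == 0.0
        t = p.tau_R + 0.003
        expected = (2 / p.theta_R) * np.exp(-2 * (t - p.tau_R) / p.theta_R)
        assert d(t) == pytest.approx(expected, rel=1e-12)

    def test_density_depends_on_M_thetaB_only_through_w(self, im_params):
        alt = dataclasses.replace(im_params, M=2 * im_params.M,
                                  theta_B=2 * im_params.theta_B)
        ts = np.linspace(0, 0.02, 200)
        np.testing.assert_allclose(
            density_mscm(ts, im_params), density_mscm(ts, alt), rtol=1e-12
        )

    def test_sc_continuous_at_tau_T_discontinuous_at_tau_R(self, sc_params):
        d = mscm_density(sc_params)
        eps = 1e-10
        tT, tR = sc_params.tau_T, sc_params.tau_R
        assert d(tT - eps) == pytest.approx(d(tT + eps), rel=1e-5)
        assert abs(d(tR - eps) - d(tR + eps)) > 1e-3

    def test_iim_zero_before_tau_T(self, iim_params):
        d = mscm_density(iim_params)
        ts = np.linspace(0, iim_params.tau_T * 0.999, 50)
        assert np.all(d(ts) == 0.0)

    def test_invalid_params_raise(self, im_params):
        bad = dataclasses.replace(im_params, tau_T=0.01)
        with pytest.raises(ValueError):
            mscm_density(bad)


class TestMsciDensity:
    def test_phi_zero_is_pure_isolation(self, msci_truth):
        p = dataclasses.replace(msci_truth, phi=0.0)
        d = msci_density(p)
        assert d(0.003) == 0.0  # between tau_S and tau_R
        t = p.tau_R + 0.002
        assert d(t) == pytest.approx(
            (2 / p.theta_R) * np.exp(-2 * (t - p.tau_R) / p.theta_R), rel=1e-12
        )

    def test_phi_one_midpiece_value(self, msci_truth):
        p = dataclasses.replace(msci_truth, phi=1.0)
        t = 0.003
        expected = (2 / p.theta_S) * np.exp(-2 * (t - p.tau_S) / p.theta_S)
        assert density_msci(t, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_normalization_random_grid(self, seed):
        rng = np.random.default_rng(200 + seed)
        tau_R = rng.uniform(1e-4, 0.05)
        p = MSciParams(
            tau_R=tau_R, tau_S=rng.uniform(0, 0.95 * tau_R),
            theta_R=rng.uniform(1e-4, 0.05), theta_S=rng.uniform(1e-4, 0.05),
            phi=rng.uniform(0, 1),
        )
        assert msci_density(p).integral() == pytest.approx(1.0, abs=1e-8)

    def test_zero_below_tau_S(self, msci_truth):
        d = msci_density(msci_truth)
        assert d(msci_truth.tau_S * 0.9) == 0.0
        assert d.support_min == msci_truth.tau_S


class TestMoments:
    def test_msci_phi_zero_shifted_exponential(self, msci_truth):
        p = dataclasses.replace(msci_truth, phi=0.0)
        mean, var = density_moments(msci_density(p))
        assert mean == pytest.approx(p.tau_R + p.theta_R / 2, abs=1e-8)
        assert var == pytest.approx((p.theta_R / 2) ** 2, abs=1e-8)

    def test_im_no_migration_shifted_exponential(self, im_params):
        p = dataclasses.replace(im_params, M=0.0)
        mean, _ = density_moments(mscm_density(p))
        assert mean == pytest.approx(p.tau_R + p.theta_R / 2, abs=1e-8)

    def test_monte_carlo_mean_matches(self, im_params, rng):
        from migsci.params import two_species_network
        from migsci.simulate import CompiledNetwork

        cn = CompiledNetwork(two_species_network(im_params, samples=1))
        N = 20000
        ts = np.array(
            [cn.simulate(rng).mrca_age("A_1", "B_1") for _ in range(N)]
        )
        mean, var = density_moments(mscm_density(im_params))
        se = np.sqrt(var / N)
        assert abs(ts.mean() - mean) < 3 * se


class TestMsprimeOracle:
    def test_im_density_matches_msprime(self, im_params):
        """Independent structured-coalescent oracle for the IM closed form."""
        msprime = pytest.importorskip("msprime")
        from scipy import stats

        p = im_params
        mu = 1e-8
        # haploid msprime populations coalesce at rate 1/N per generation;
        # theta = 4*N_dip*mu corresponds to N = theta/(2 mu)
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=p.theta_A / (2 * mu))
        dem.add_population(name="B", initial_size=p.theta_B / (2 * mu))
        dem.add_population(name="R", initial_size=p.theta_R / (2 * mu))
        dem.add_population_split(time=p.tau_R / mu, derived=["A", "B"],
                                 ancestral="R")
        dem.set_migration_rate(source="B", dest="A", rate=4 * p.M * mu / p.theta_B)
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1}, demography=dem, ploidy=1,
            num_replicates=10000, random_seed=11,
        )
        times = np.array(
            [next(t.trees()).time(t.first().root) for t in reps]
        ) * mu
        ks = stats.kstest(times, mscm_density(p).cdf)
        assert ks.pvalue > 0.01
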