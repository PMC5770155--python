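import math

import numpy as np
import pytest

import ratecorr as rc
from ratecorr.covariance import (
    UnstableEquilibriumError,
    _lyapunov_blocks,
    expand_blocks,
)
from ratecorr.equilibria import equilibrium_at

from conftest import random_stable_setup, stable_equilibrium


def _blocks(cov):
    return np.array(
        [
            cov.variances[0],
            cov.variances[1],
            cov.pair_cov["EE"],
            cov.pair_cov["II"],
            cov.pair_cov["EI"],
        ]
    )


class TestLyapunov:
    def test_scalar_ou_variance(self):
        # dV = -V/tau dt + sigma dB has stationary variance sigma^2 tau / 2
        tau, sigma = 1.7, 0.3
        S = rc.lyapunov_covariance(np.array([[-1.0 / tau]]), np.array([[sigma**2]]))
        assert S[0, 0] == pytest.approx(sigma**2 * tau / 2.0, rel=1e-12)

    def test_output_symmetric_psd(self, reference_network, asynchronous_equilibrium):
        noise = rc.default_noise(c_ee=0.3, c_ii=0.2, c_ei=0.1)
        S = rc.lyapunov_covariance(
            rc.full_jacobian(asynchronous_equilibrium, reference_network),
            rc.build_noise_covariance(reference_network, noise),
        )
        np.testing.assert_array_equal(S, S.T)
        assert np.linalg.eigvalsh(S)[0] >= -1e-10 * S.max()

    def test_unstable_jacobian_rejected(self):
        with pytest.raises(UnstableEquilibriumError):
            rc.lyapunov_covariance(np.array([[0.1]]), np.array([[1.0]]))

    def test_exchangeability_three_distinct_offdiagonals(
        self, reference_network, asynchronous_equilibrium
    ):
        noise = rc.default_noise(c_ee=0.25, c_ii=0.5, c_ei=0.1)
        S = rc.lyapunov_covariance(
            rc.full_jacobian(asynchronous_equilibrium, reference_network),
            rc.build_noise_covariance(reference_network, noise),
        )
        off = S[~np.eye(10, dtype=bool)]
        distinct = np.unique(np.round(off / np.abs(off).max(), 10))
        assert len(distinct) == 3  # EE, II and EI pair covariances


class TestClosedFormVsOracle:
    def test_reference_point(self, reference_network, asynchronous_equilibrium):
        noise = rc.default_noise(c_ee=0.3, c_ii=0.6, c_ei=0.2)
        cov = rc.closed_form_covariance(asynchronous_equilibrium, reference_network, noise)
        assert cov.method == "closed_form"
        ref = _blocks(_lyapunov_blocks(asynchronous_equilibrium, reference_network, noise))
        np.testing.assert_allclose(_blocks(cov), ref, rtol=1e-8)

    def test_random_draws_with_random_noise(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            net, eq = random_stable_setup(rng)
            c = rng.uniform(0.0, 0.9)
            noise = rc.NoiseModel(
                rng.uniform(1e-5, 1e-3, 2),
                np.array([[c, c * 0.5], [c * 0.5, c]]),
            )
            cov = rc.closed_form_covariance(eq, net, noise)
            if cov.method != "closed_form":
                continue
            ref = _blocks(_lyapunov_blocks(eq, net, noise))
            np.testing.assert_allclose(_blocks(cov), ref, rtol=1e-8, atol=1e-30)

    def test_unstable_equilibrium_rejected(self, reference_network):
        eqs = rc.find_fixed_points(rc.Stimulus.ei(12.0, -35.0), reference_network, seed=0)
        unstable = next(e for e in eqs if not e.stable)
        with pytest.raises(UnstableEquilibriumError):
            rc.closed_form_covariance(unstable, reference_network, rc.default_noise())

    def test_degenerate_coupling_falls_back_to_lyapunov(self, zero_weight_network):
        eq = equilibrium_at([0.0, 0.0], rc.Stimulus.ei(0.0, 0.0), zero_weight_network)
        cov = rc.closed_form_covariance(eq, zero_weight_network, rc.default_noise())
        assert cov.method == "lyapunov"
        # decoupled neurons: exact OU variance, zero correlations
        assert cov.variances[0] == pytest.approx(1e-8 / 2.0, rel=1e-10)
        assert abs(cov.corr["EI"]) < 1e-12


class TestFiniteTime:
    def test_zero_horizon_is_zero(self):
        J = np.array([[-1.0]])
        S = rc.finite_time_covariance(J, np.array([[1.0]]), 0.0)
        np.testing.assert_array_equal(S, 0.0)

    def test_scalar_ou_closed_form(self):
        tau, sigma, t = 1.3, 0.2, 0.9
        S = rc.finite_time_covariance(
            np.array([[-1.0 / tau]]), np.array([[sigma**2]]), t
        )
        expected = sigma**2 * tau / 2.0 * (1.0 - math.exp(-2.0 * t / tau))
        assert S[0, 0] == pytest.approx(expected, rel=1e-8)

    def test_converges_to_stationary(self, reference_network, asynchronous_equilibrium):
        J = rc.full_jacobian(asynchronous_equilibrium, reference_network)
        SB = rc.build_noise_covariance(reference_network, rc.default_noise())
        S30 = rc.finite_time_covariance(J, SB, 30.0, atol=1e-22)
        Sinf = rc.lyapunov_covariance(J, SB)
        assert np.max(np.abs(S30 - Sinf)) < 1e-6 * np.max(np.abs(Sinf))

    def test_propagator_semigroup(self, reference_network, asynchronous_equilibrium):
        J = rc.full_jacobian(asynchronous_equilibrium, reference_network)
        P1 = rc.propagator(J, 0.7)
        P2 = rc.propagator(J, 0.3)
        np.testing.assert_allclose(rc.propagator(J, 1.0), P1 @ P2, atol=1e-8)
        np.testing.assert_allclose(rc.propagator(J, 0.0), np.eye(10), atol=1e-14)


class TestCorrelationFromCovariance:
    def test_diagonal_gives_identity(self):
        C = rc.correlation_from_covariance(np.diag([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(C, np.eye(3))

    def test_rank_one_gives_all_ones(self):
        s = np.array([0.5, 1.5, 2.0])
        C = rc.correlation_from_covariance(np.outer(s, s))
        np.testing.assert_allclose(C, 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rc.correlation_from_covariance(np.diag([1.0, 0.0]))

    def test_near_fold_correlations_approach_one(self, reference_network, fold_scan):
        # convergence is of square-root order in the stimulus distance, so a
        # distance of 1e-5 puts every block correlation above 0.95
        fold = next(p for p in fold_scan if p.kind == "saddle_node" and p.stable_side)
        eq = stable_equilibrium(
            rc.Stimulus.ei(fold.location + 1e-5, -35.0), reference_network
        )
        cov = rc.closed_form_covariance(eq, reference_network, rc.default_noise())
        assert all(c > 0.95 for c in cov.corr.values())


class TestAsymptoticRegimes:
    def test_asynchronous_limit_independent_noise(self, reference_network):
        # strong stimuli decorrelate the circuit and each variance tends
        # to the decoupled OU value sigma_B^2 / (2 tau)
        noise = rc.default_noise()
        for I in (100.0, -100.0):
            eq = stable_equilibrium(rc.Stimulus.ei(I, I), reference_network)
            cov = rc.closed_form_covariance(eq, reference_network, noise)
            assert max(abs(c) for c in cov.corr.values()) < 1e-3
            for a, tau in enumerate((1.0, 1.0)):
                ratio = cov.variances[a] * 2.0 * tau / 1e-8
                assert ratio == pytest.approx(1.0, abs=1e-4)

    def test_decorrelation_is_monotone_beyond_saturation(self, reference_network):
        noise = rc.default_noise()
        maxima = []
        for I in (20.0, 40.0, 60.0, 80.0, 100.0):
            eq = stable_equilibrium(rc.Stimulus.ei(I, I), reference_network)
            cov = rc.closed_form_covariance(eq, reference_network, noise)
            maxima.append(max(abs(c) for c in cov.corr.values()))
        assert all(a > b for a, b in zip(maxima, maxima[1:]))

    def test_noise_correlation_transfer_at_strong_input(self, reference_network):
        noise = rc.default_noise(c_ee=0.8, c_ii=0.8, c_ei=0.8)
        eq = stable_equilibrium(rc.Stimulus.ei(100.0, 100.0), reference_network)
        cov = rc.closed_form_covariance(eq, reference_network, noise)
        for c in cov.corr.values():
            assert c == pytest.approx(0.8, abs=1e-3)


class TestBranchingPointLaws:
    @pytest.mark.parametrize("n_i", [2, 3, 4])
    def test_anticorrelation_limit(self, n_i):
        # as lambda_I -> 0- with imperfect inhibitory noise correlation,
        # C_II -> 1 / (1 - N_I): the lower bound for N_I exchangeable units
        net = rc.default_network(n_i=n_i)
        noise = rc.default_noise()
        pts = rc.locate_on_segment("I_I", (-5.0, 8.0), 1.0, net, noise, step=0.02)
        bp = next(p for p in pts if p.kind == "branching_point" and p.stable_side)
        eq = stable_equilibrium(rc.Stimulus.ei(1.0, bp.location - 1e-4), net)
        cov = rc.closed_form_covariance(eq, net, noise)
        assert cov.corr["II"] == pytest.approx(1.0 / (1.0 - n_i), abs=0.01)

    def test_fully_correlated_inhibitory_noise_wins(self, reference_network, hopf_bp_scan):
        bp = next(p for p in hopf_bp_scan if p.kind == "branching_point")
        noise = rc.default_noise(c_ee=1.0, c_ii=1.0, c_ei=1.0)
        ref = rc.default_noise()
        sig_far = None
        for d in (1e-2, 1e-3, 1e-4):
            eq = stable_equilibrium(
                rc.Stimulus.ei(1.0, bp.location - d), reference_network
            )
            cov = rc.closed_form_covariance(eq, reference_network, noise)
            assert cov.corr["II"] == pytest.approx(1.0, abs=1e-6)
            # sigma_I stays bounded while the independent-noise value diverges
            cov0 = rc.closed_form_covariance(eq, reference_network, ref)
            if sig_far is None:
                sig_far = cov.sigma_v[1]
            assert cov.sigma_v[1] < 10 * sig_far
            assert cov0.sigma_v[1] > cov.sigma_v[1]


class TestRatesAndRegimes:
    def test_rate_correlations_equal_potential_correlations(
        self, reference_network, asynchronous_equilibrium
    ):
        cov = rc.closed_form_covariance(
            asynchronous_equilibrium, reference_network, rc.default_noise()
        )
        rs = rc.rate_statistics(asynchronous_equilibrium, cov, reference_network)
        assert rs.rate_corr == cov.corr

    def test_saturated_rates(self, reference_network):
        eq = stable_equilibrium(rc.Stimulus.ei(100.0, 100.0), reference_network)
        cov = rc.closed_form_covariance(eq, reference_network, rc.default_noise())
        rs = rc.rate_statistics(eq, cov, reference_network)
        assert rs.mean_rates[0] == pytest.approx(1.0, abs=1e-3)
        assert rs.mean_rates[1] == pytest.approx(1.0, abs=1e-3)

    def test_geometric_mean_at_threshold(self, zero_weight_network):
        eq = equilibrium_at([2.0, 2.0], rc.Stimulus.ei(2.0, 2.0), zero_weight_network)
        cov = rc.closed_form_covariance(eq, zero_weight_network, rc.default_noise())
        rs = rc.rate_statistics(eq, cov, zero_weight_network)
        assert rs.geometric_mean_rates["EI"] == pytest.approx(0.5, rel=1e-12)

    def test_regime_labels(self, reference_network, fold_scan):
        noise = rc.default_noise()
        eq = stable_equilibrium(rc.Stimulus.ei(14.0, -35.0), reference_network)
        cov = rc.closed_form_covariance(eq, reference_network, noise)
        spec = rc.spectrum_at(eq, reference_network)
        assert rc.regime_classify(cov, spec, reference_network, noise)[0] == "asynchronous"

        fold = next(p for p in fold_scan if p.kind == "saddle_node" and p.stable_side)
        eq = stable_equilibrium(
            rc.Stimulus.ei(fold.location + 1e-4, -35.0), reference_network
        )
        cov = rc.closed_form_covariance(eq, reference_network, noise)
        spec = rc.spectrum_at(eq, reference_network)
        assert rc.regime_classify(cov, spec, reference_network, noise)[0] == "synchronous"

    def test_zero_coupling_is_asynchronous_everywhere(self, zero_weight_network):
        noise = rc.default_noise()
        for stim in (rc.Stimulus.ei(0.0, 0.0), rc.Stimulus.ei(5.0, -5.0)):
            eq = stable_equilibrium(stim, zero_weight_network)
            cov = rc.closed_form_covariance(eq, zero_weight_network, noise)
            spec = rc.spectrum_at(eq, zero_weight_network)
            assert (
                rc.regime_classify(cov, spec, zero_weight_network, noise)[0]
                == "asynchronous"
            )


class TestExpandedMatrix:
    def test_expanded_blocks_symmetric_psd(self, reference_network, asynchronous_equilibrium):
        cov = rc.closed_form_covariance(
            asynchronous_equilibrium, reference_network, rc.default_noise(c_ee=0.5, c_ii=0.5, c_ei=0.5)
        )
        S = expand_blocks(cov, reference_network)
        np.testing.assert_array_equal(S, S.T)
        assert np.linalg.eigvalsh(S)[0] >= -1e-10 * S.max()
        assert np.all(np.abs(rc.correlation_from_covariance(S)) <= 1.0)
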