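import numpy as np
import pytest

import ratecorr as rc

from conftest import stable_equilibrium


class TestSaddleNodeCondition:
    def test_no_self_excitation_means_no_fold(self, reference_network):
        net = rc.default_network(j_ee=0.0)
        q, ok = rc.saddle_node_condition(net)
        assert q == 0.0 and not ok

    def test_reference_circuit_quantity(self, reference_network):
        q, ok = rc.saddle_node_condition(reference_network)
        assert q == pytest.approx(35.0 / 9.0, rel=1e-15)
        assert ok

    def test_boundary_is_strict(self):
        # J_EE chosen so the quantity is exactly 1
        net = rc.default_network(j_ee=36.0 / 14.0)
        q, ok = rc.saddle_node_condition(net)
        assert q == pytest.approx(1.0, rel=1e-12)
        assert not ok


class TestBranchingCondition:
    def test_reference_circuit_quantity(self, reference_network):
        q, ok = rc.branching_condition(reference_network)
        assert q == pytest.approx(17.0 / 9.0, rel=1e-15)
        assert ok

    def test_no_self_inhibition(self):
        net = rc.default_network(j_ii=0.0)
        q, ok = rc.branching_condition(net)
        assert q == 0.0 and not ok

    def test_vanishes_with_network_size(self):
        # symmetry breaking is a finite-size effect: the quantity decays
        # as 1/(N-1) at fixed weights
        big = rc.default_network(n_e=80, n_i=20)
        q, ok = rc.branching_condition(big)
        assert q < 0.2 and not ok


class TestHopfCondition:
    def test_reference_circuit_satisfied(self, reference_network):
        h = rc.hopf_condition(reference_network)
        assert h.c == 1.0  # 1/tau_E^2
        assert h.discriminant > 0
        assert h.satisfied
        assert reference_network.populations[0].nu_max * 2.0 / (4.0 * h.z) > 1.0

    def test_no_loop_no_oscillation(self):
        net = rc.default_network(j_ee=0.0, j_ei=0.0)
        h = rc.hopf_condition(net)
        assert h.a == 0.0
        assert not h.satisfied

    def test_zero_self_inhibition_rejected(self):
        net = rc.default_network(j_ii=0.0)
        with pytest.raises(ZeroDivisionError):
            rc.hopf_condition(net)

    def test_negative_discriminant_unsatisfied(self):
        # weak coupling: the quadratic has no real root
        net = rc.default_network(j_ee=1.0, j_ei=-1.0, j_ie=1.0, j_ii=-1.0)
        h = rc.hopf_condition(net)
        assert h.discriminant <= 0 or not h.satisfied


class TestLocateOnSegment:
    def test_fold_on_stable_branch(self, fold_scan):
        folds = [p for p in fold_scan if p.kind == "saddle_node"]
        assert folds
        stable_fold = next(p for p in folds if p.stable_side)
        assert stable_fold.location == pytest.approx(11.86, abs=0.01)
        assert abs(stable_fold.localization_residual) < 1e-6

    def test_second_fold_on_unstable_branch(self, fold_scan):
        others = [
            p for p in fold_scan if p.kind == "saddle_node" and not p.stable_side
        ]
        assert others and others[0].location == pytest.approx(12.226, abs=0.01)

    def test_hopf_location(self, hopf_bp_scan):
        hopf = next(p for p in hopf_bp_scan if p.kind == "hopf")
        assert hopf.location == pytest.approx(-13.67, abs=0.01)
        assert abs(hopf.localization_residual) < 1e-6
        assert hopf.stable_side

    def test_branching_point_location(self, hopf_bp_scan):
        bp = next(p for p in hopf_bp_scan if p.kind == "branching_point")
        assert bp.location == pytest.approx(1.165, abs=0.005)
        assert abs(bp.localization_residual) < 1e-6
        assert bp.stable_side

    def test_located_kinds_satisfy_necessary_conditions(
        self, reference_network, fold_scan, hopf_bp_scan
    ):
        kinds = {p.kind for p in fold_scan} | {p.kind for p in hopf_bp_scan}
        if "saddle_node" in kinds:
            assert rc.saddle_node_condition(reference_network)[1]
        if "branching_point" in kinds:
            assert rc.branching_condition(reference_network)[1]
        if "hopf" in kinds:
            assert rc.hopf_condition(reference_network).satisfied

    def test_zero_coupling_segment_is_empty(self, zero_weight_network):
        pts = rc.locate_on_segment(
            "I_E", (-2.0, 2.0), 0.0, zero_weight_network, step=0.1
        )
        assert pts == []

    def test_indicator_changes_sign_across_bp(self, reference_network, hopf_bp_scan):
        bp = next(p for p in hopf_bp_scan if p.kind == "branching_point")
        lam_below = rc.intra_eigenvalues(
            stable_equilibrium(rc.Stimulus.ei(1.0, bp.location - 1e-3), reference_network),
            reference_network,
        )[1]
        eqs = rc.find_fixed_points(
            rc.Stimulus.ei(1.0, bp.location + 1e-3), reference_network, seed=0
        )
        lam_above = min(rc.intra_eigenvalues(e, reference_network)[1] for e in eqs)
        # the homogeneous branch's lambda_I crosses zero
        assert lam_below < 0


class TestLimitingCorrelations:
    def test_fold_prediction(self, reference_network, fold_scan):
        fold = next(p for p in fold_scan if p.kind == "saddle_node" and p.stable_side)
        eq = stable_equilibrium(
            rc.Stimulus.ei(fold.location + 1e-5, -35.0), reference_network
        )
        pred = rc.limiting_correlations(
            "saddle_node", reference_network, rc.default_noise(), eq
        )
        assert pred["C_EE"] == pred["C_II"] == pred["C_EI"] == 1.0
        assert pred["sigma_ratio_I_over_E"] > 0
        cov = rc.closed_form_covariance(eq, reference_network, rc.default_noise())
        ratio = cov.sigma_v[1] / cov.sigma_v[0]
        assert ratio == pytest.approx(pred["sigma_ratio_I_over_E"], rel=0.02)

    @pytest.mark.parametrize("n_i, limit", [(2, -1.0), (3, -0.5)])
    def test_branching_point_prediction(self, n_i, limit):
        net = rc.default_network(n_i=n_i)
        pred = rc.limiting_correlations("branching_point", net, rc.default_noise())
        assert pred["C_II"] == pytest.approx(limit)

    def test_hopf_excludes_between_population_limit(self, reference_network):
        pred = rc.limiting_correlations("hopf", reference_network, rc.default_noise())
        assert pred["C_EE"] == pred["C_II"] == 1.0
        assert pred["C_EI"] is None

    def test_unknown_kind_rejected(self, reference_network):
        with pytest.raises(ValueError):
            rc.limiting_correlations("cusp", reference_network, rc.default_noise())


class TestConvergenceTowardLimits:
    def test_fold_correlations_converge_monotonically(self, reference_network, fold_scan):
        fold = next(p for p in fold_scan if p.kind == "saddle_node" and p.stable_side)
        noise = rc.default_noise()
        prev = -np.inf
        # the collective eigenvalue vanishes like sqrt(distance) at a fold,
        # so correlations converge to 1 with square-root order
        for d in (1e-1, 1e-2, 1e-3, 1e-4, 1e-5):
            eq = stable_equilibrium(
                rc.Stimulus.ei(fold.location + d, -35.0), reference_network
            )
            cov = rc.closed_form_covariance(eq, reference_network, noise)
            c = min(cov.corr.values())
            assert c > prev
            prev = c
        assert prev > 0.95

    def test_hopf_within_population_correlations_converge(
        self, reference_network, hopf_bp_scan
    ):
        hopf = next(p for p in hopf_bp_scan if p.kind == "hopf")
        noise = rc.default_noise()
        prev = -np.inf
        for d in (1e-1, 1e-2, 1e-3, 1e-4):
            eq = stable_equilibrium(
                rc.Stimulus.ei(1.0, hopf.location + d), reference_network
            )
            cov = rc.closed_form_covariance(eq, reference_network, noise)
            c = min(cov.corr["EE"], cov.corr["II"])
            assert c > prev
            prev = c
        assert prev > 0.99

    def test_bp_anticorrelation_converges(self, reference_network, hopf_bp_scan):
        bp = next(p for p in hopf_bp_scan if p.kind == "branching_point")
        noise = rc.default_noise()
        prev = np.inf
        for d in (1e-1, 1e-2, 1e-3, 1e-4):
            eq = stable_equilibrium(
                rc.Stimulus.ei(1.0, bp.location - d), reference_network
            )
            cov = rc.closed_form_covariance(eq, reference_network, noise)
            assert cov.corr["II"] < prev
            prev = cov.corr["II"]
        assert prev == pytest.approx(-1.0, abs=0.01)
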