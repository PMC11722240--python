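"""Circuit model: derivative algebra, pair/triplet dynamics, reporter, phase maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import POINT1, POINT2
from notchdyn.circuit import (
    PAIR_TOPOLOGY,
    TRIPLET_TOPOLOGY,
    CircuitParams,
    derivatives,
    high_notch_cell,
    phase_map,
    reporter_accumulation,
    signaling_speed,
    simulate,
    simulate_pair,
    simulate_triplet,
    steady_state_delta,
)
from notchdyn.exceptions import ParameterError, TopologyError
from oracles import rk4_circuit


class TestDerivatives:
    def test_origin_forced_by_equations(self):
        # N=D=0: no activation, uninhibited Delta production at rate v
        dn, dd = derivatives([0.0, 0.0], [0.0, 0.0], CircuitParams(kn=0.5, kd=0.25))
        assert np.allclose(dn, 0.0)
        assert np.allclose(dd, 1.0)

    def test_half_maximal_inhibition_point(self):
        # N = KD exactly halves Delta production, so D = 0.5 is stationary
        p = CircuitParams(kn=0.5, kd=0.25)
        _, dd = derivatives([p.kd, p.kd], [0.5, 0.5], p)
        assert np.allclose(dd, 0.0, atol=1e-14)

    def test_matches_hand_evaluated_hill_terms(self):
        p = CircuitParams(kn=0.5, kd=0.25)
        notch, delta = np.array([0.010, 0.011]), np.array([1.0, 1.0])
        dn, dd = derivatives(notch, delta, p)
        for i, j in ((0, 1), (1, 0)):
            expected_dn = delta[j] ** 2 / (0.5**2 + delta[j] ** 2) - notch[i]
            expected_dd = 1.0 / (1.0 + (notch[i] / 0.25) ** 2) - delta[i]
            assert dn[i] == pytest.approx(expected_dn, abs=1e-15)
            assert dd[i] == pytest.approx(expected_dd, abs=1e-15)

    def test_parameter_and_topology_errors(self):
        with pytest.raises(ParameterError):
            CircuitParams(kn=0.0, kd=1.0)
        with pytest.raises(ParameterError):
            CircuitParams(kn=1.0, kd=-1.0)
        with pytest.raises(TopologyError):
            derivatives([0.0, 0.0], [0.0, 0.0], POINT1, topology=((), (0,)))


class TestPairDynamics:
    def test_symmetric_init_gives_identical_cells(self):
        traj = simulate_pair(POINT1, init_notch=[0.01, 0.01], init_delta=[1.0, 1.0])
        assert np.allclose(traj.notch[:, 0], traj.notch[:, 1], atol=1e-9)
        assert np.allclose(traj.delta[:, 0], traj.delta[:, 1], atol=1e-9)

    @pytest.mark.parametrize("params", [POINT1, POINT2], ids=["low_kd", "high_kd"])
    def test_agrees_with_fixed_step_rk4_oracle(self, params):
        traj = simulate_pair(params)
        t_o, n_o, d_o = rk4_circuit(
            params.kn, params.kd, [0.010, 0.011], [1.0, 1.0], PAIR_TOPOLOGY,
            t_end=10.0, dt=1e-4, sample_every=2500,
        )
        n_i = np.array([np.interp(t_o, traj.times, traj.notch[:, c]) for c in range(2)]).T
        d_i = np.array([np.interp(t_o, traj.times, traj.delta[:, c]) for c in range(2)]).T
        assert np.max(np.abs(n_i - n_o)) < 1e-5
        assert np.max(np.abs(d_i - d_o)) < 1e-5

    def test_low_kd_pair_resolves_into_opposing_states(self):
        # The 0.001 Notch asymmetry is amplified to opposing high-Notch/low-Delta
        # and low-Notch/high-Delta states; growth rate ~0.3 means resolution
        # needs t ~ 40, not the t=10 window used for the phase maps.
        traj = simulate_pair(POINT1, t_end=40.0)
        hi = high_notch_cell(traj)
        lo = 1 - hi
        assert hi == 1  # cell with the initial Notch head start wins
        assert abs(traj.notch[-1, hi] - traj.notch[-1, lo]) > 0.5
        assert traj.delta[-1, hi] < 0.15
        assert traj.delta[-1, lo] > 0.9

    def test_high_kd_pair_keeps_high_delta_in_high_notch_cell(self, traj_point2):
        # Injury-like state: elevated KD leaves Delta high despite high Notch
        hi = high_notch_cell(traj_point2)
        assert traj_point2.delta[-1, hi] > 0.5
        assert traj_point2.notch[-1, hi] > 0.5

    def test_permuting_cell_labels_permutes_trajectories(self):
        a = simulate_pair(POINT1, init_notch=[0.010, 0.011])
        b = simulate_pair(POINT1, init_notch=[0.011, 0.010])
        assert np.allclose(a.notch[:, 0], b.notch[:, 1], atol=1e-10)
        assert np.allclose(a.delta[:, 1], b.delta[:, 0], atol=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n1=st.floats(0.0, 1.0), n2=st.floats(0.0, 1.0),
        d1=st.floats(0.0, 1.0), d2=st.floats(0.0, 1.0),
    )
    def test_state_stays_in_unit_box(self, n1, n2, d1, d2):
        traj = simulate_pair(POINT1, init_notch=[n1, n2], init_delta=[d1, d2])
        assert traj.notch.min() >= -1e-9 and traj.delta.min() >= -1e-9
        assert traj.notch.max() <= 1 + 1e-6 and traj.delta.max() <= 1 + 1e-6


class TestTripletDynamics:
    def test_fully_symmetric_triplet_stays_identical(self):
        traj = simulate_triplet(POINT1, init_notch=[0.01] * 3, init_delta=[1.0] * 3)
        for c in (1, 2):
            assert np.allclose(traj.notch[:, 0], traj.notch[:, c], atol=1e-9)
            assert np.allclose(traj.delta[:, 0], traj.delta[:, c], atol=1e-9)

    def test_agrees_with_rk4_oracle(self):
        traj = simulate_triplet(POINT2)
        t_o, n_o, d_o = rk4_circuit(
            POINT2.kn, POINT2.kd, [0.010, 0.010, 0.011], [1.0] * 3, TRIPLET_TOPOLOGY,
            t_end=10.0, dt=1e-4, sample_every=5000,
        )
        n_i = np.array([np.interp(t_o, traj.times, traj.notch[:, c]) for c in range(3)]).T
        assert np.max(np.abs(n_i - n_o)) < 1e-5

    def test_high_kd_triplet_high_notch_cell_keeps_delta(self):
        traj = simulate_triplet(POINT2)
        hi = high_notch_cell(traj)
        assert hi == 2
        assert traj.delta[-1, hi] > 0.5

    def test_mean_coupling_damps_triplet_resolution_at_low_kd(self):
        # With mean-neighbor input the all-mutual triplet's asymmetric mode is
        # stable at KD=0.25 (coupling eigenvalue -1/2): no winner emerges even
        # at long times and all cells sit at the symmetric state.
        traj = simulate_triplet(POINT1, t_end=60.0)
        assert np.ptp(traj.notch[-1]) < 0.05
        assert np.all(traj.delta[-1] > 0.3)


class TestReporter:
    def test_zero_and_unit_integrands(self):
        t = np.linspace(0, 5, 51)
        assert np.allclose(reporter_accumulation(t, np.zeros((51, 2))), 0.0)
        rep = reporter_accumulation(t, np.ones((51, 1)), beta=1.0)[:, 0]
        assert np.allclose(rep, t, atol=1e-12)

    def test_matches_trapezoid_oracle_and_is_monotone(self, traj_point1):
        rep = traj_point1.reporter
        # independent trapezoid accumulation on the same grid
        dt = np.diff(traj_point1.times)[:, None]
        expected = np.vstack(
            [np.zeros(2), np.cumsum(0.5 * dt * (traj_point1.notch[1:] + traj_point1.notch[:-1]), axis=0)]
        )
        assert np.max(np.abs(rep - expected)) / np.max(expected) < 1e-6
        assert np.all(np.diff(rep, axis=0) >= -1e-12)

    def test_negative_beta_rejected(self):
        with pytest.raises(ParameterError):
            reporter_accumulation(np.linspace(0, 1, 5), np.ones((5, 1)), beta=-0.1)

    def test_ode_reporter_matches_integral_in_alpha_to_zero_limit(self):
        p = CircuitParams(kn=0.5, kd=0.25, beta=1.0, alpha=1e-6)
        ode = simulate_pair(p, reporter_mode="ode")
        integral = simulate_pair(p, reporter_mode="integral")
        assert np.max(np.abs(ode.reporter - integral.reporter)) < 1e-4


class TestScalarMetrics:
    def test_steady_state_delta_reference_points(self):
        # frozen from the RK4 oracle: symmetric-state Delta at t=10
        assert steady_state_delta(POINT1) == pytest.approx(0.3533, abs=2e-3)
        assert steady_state_delta(POINT2) == pytest.approx(0.6966, abs=2e-3)

    def test_steady_state_delta_saturates_at_large_kd(self):
        assert steady_state_delta(CircuitParams(kn=0.5, kd=1e6)) == pytest.approx(1.0, abs=1e-3)

    def test_speed_of_unit_notch_is_one(self):
        # direct check of the (R(10)-R(4))/6 definition on a constant-N trace
        t = np.linspace(0, 10, 1001)
        rep = reporter_accumulation(t, np.ones((1001, 1)))[:, 0]
        speed = (np.interp(10, t, rep) - np.interp(4, t, rep)) / 6.0
        assert speed == pytest.approx(1.0, abs=1e-12)

    def test_elevated_kd_speeds_signaling(self):
        assert signaling_speed(POINT2) > signaling_speed(POINT1)

    def test_speed_agrees_with_trapezoid_oracle(self, traj_point2):
        cell = high_notch_cell(traj_point2)
        notch = traj_point2.notch[:, cell]
        t = traj_point2.times
        dt = np.diff(t)
        rep = np.concatenate([[0.0], np.cumsum(0.5 * dt * (notch[1:] + notch[:-1]))])
        expected = (np.interp(10, t, rep) - np.interp(4, t, rep)) / 6.0
        assert signaling_speed(traj_point2.params) == pytest.approx(expected, rel=1e-6)


class TestPhaseMap:
    def test_single_point_grid_equals_scalar_metric(self):
        pm = phase_map([0.5], [1.0], metric="steady_state_delta")
        assert pm.values.shape == (1, 1)
        assert pm.values[0, 0] == pytest.approx(steady_state_delta(POINT2), abs=1e-12)

    def test_speed_non_decreasing_in_kd_at_fixed_kn(self):
        pm = phase_map([0.5, 2.0], [0.1, 0.25, 1.0], metric="signaling_speed")
        assert np.all(np.diff(pm.values, axis=1) >= -1e-9)
        assert np.all(np.isfinite(pm.values))

    def test_invalid_grids_rejected(self):
        with pytest.raises(ParameterError):
            phase_map([], [1.0])
        with pytest.raises(ParameterError):
            phase_map([0.5], [-1.0])
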