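import math

import numpy as np
import pytest

import oxiline as ox
from oxiline.network import Segment


def two_segment_chain(r_term=1e7):
    geom = ox.SegmentGeometry(0.02, 0.004, 1e-3)
    wall = ox.WallProperties(elastic_modulus=1e6)
    segs = [
        Segment(id="a", geometry=geom, wall=wall),
        Segment(id="b", geometry=geom, wall=wall, parent="a", terminal_resistance=r_term),
    ]
    return ox.VesselNetwork(segs)


class TestAssembly:
    def test_state_counts_straight(self, straight_net):
        system = ox.assemble_flow_odes(straight_net)
        d = system.describe()
        # root flow prescribed by the waveform; leaf pressure algebraic
        assert d["branch_states"] == 9
        assert d["node_states"] == 9
        assert d["states"] == 18

    def test_two_segment_coefficients_match_hand_assembly(self):
        """The distal branch ODE reduces to L dQ/dt = P - (R' + R_term) Q."""
        net = two_segment_chain(r_term=3e6)
        system = ox.assemble_flow_odes(net)
        e = net.elements("b")
        iq, ipa = system.iq["b"], system.ip["a"]
        assert system.A[iq, iq] == pytest.approx(-(e.resistivity + 3e6) / e.inertance)
        assert system.A[iq, ipa] == pytest.approx(1.0 / e.inertance)
        ea = net.elements("a")
        assert system.A[ipa, iq] == pytest.approx(-1.0 / ea.compliance)
        assert system.g[ipa] == pytest.approx(1.0 / ea.compliance)

    def test_junction_couples_parent_and_both_children(self, bifurcated_net):
        system = ox.assemble_flow_odes(bifurcated_net)
        row = system.ip["cc9"]
        cols = {system.iq["ic0"], system.iq["ec0"], system.iq["cc9"]}
        nonzero = set(np.nonzero(system.A[row])[0])
        assert cols == nonzero

    def test_invalid_network_rejected_with_violations(self):
        geom = ox.SegmentGeometry(0.02, 0.004, 1e-3)
        wall = ox.WallProperties(elastic_modulus=1e6)
        net = ox.VesselNetwork([Segment(id="a", geometry=geom, wall=wall)])
        with pytest.raises(ox.InvalidNetworkError) as exc:
            ox.assemble_flow_odes(net)
        assert any("terminal" in v for v in exc.value.violations)


class TestRk4:
    def test_scalar_exponential_convergence(self):
        _, traj = ox.rk4_integrate(lambda t, y: -y, np.array([1.0]), 0.05, 20)
        assert traj[-1, 0] == pytest.approx(math.exp(-1.0), abs=1e-7)

    def test_zero_rhs_constant(self):
        _, traj = ox.rk4_integrate(lambda t, y: 0.0 * y, np.array([2.0, -1.0]), 0.05, 20)
        assert np.array_equal(traj[0], traj[-1])

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_reported_with_time(self):
        with pytest.raises(ox.IntegrationDivergedError) as exc:
            ox.rk4_integrate(lambda t, y: y**3, np.array([5.0]), 0.5, 100)
        assert exc.value.time > 0

    def test_linear_rlc_matches_closed_form(self):
        """Constant-inflow two-segment chain vs the exact modal solution."""
        net = two_segment_chain(r_term=5e7)
        system = ox.assemble_flow_odes(net)
        q0 = 1e-5
        A, g = system.A, system.g * q0
        x_ss = np.linalg.solve(A, -g)
        lam, V = np.linalg.eig(A)
        x0 = np.zeros(2)
        coef = np.linalg.solve(V, x0 - x_ss)

        def exact(t):
            return (V @ (coef * np.exp(lam * t))).real + x_ss

        dt, n = 1e-5, 2000
        _, traj = ox.rk4_integrate(lambda t, y: A @ y + g, x0, dt, n)
        xe = exact(n * dt)
        assert np.linalg.norm(traj[-1] - xe) / np.linalg.norm(xe) < 1e-6


class TestStability:
    def test_small_dt_passes_large_dt_fails(self, straight_net):
        system = ox.assemble_flow_odes(straight_net)
        assert ox.check_stability(system, 1e-7).stable
        assert not ox.check_stability(system, 1.0).stable

    def test_bound_consistent_with_analytic_eigenvalues(self):
        """2x2 chain: bound from the report vs scanning the char-poly roots."""
        net = two_segment_chain(r_term=5e7)
        system = ox.assemble_flow_odes(net)
        e = net.elements("b")
        ea = net.elements("a")
        # char poly of [[-(R+Rt)/L, 1/L], [-1/C, 0]]
        a1 = (e.resistivity + 5e7) / e.inertance
        a0 = 1.0 / (e.inertance * ea.compliance)
        lam = np.roots([1.0, a1, a0])

        def amp(z):
            return abs(1 + z + z**2 / 2 + z**3 / 6 + z**4 / 24)

        dts = np.geomspace(1e-6, 1e0, 400)
        ok = [all(amp(l * dt) <= 1 + 1e-9 for l in lam) for dt in dts]
        dt_scan = dts[np.searchsorted(np.logical_not(ok), True) - 1]
        rep = ox.check_stability(system, 1e-6)
        assert 0.5 < rep.dt_max_estimate / dt_scan < 2.0


class TestPeriodicFlow:
    def test_steady_series_resistance_closed_form(self, straight_net, steady_flow_straight):
        sol = steady_flow_straight
        q0 = 3.0e-5
        r_total = sum(straight_net.elements(s).resistivity for s in straight_net.ids)
        r_term = straight_net.segment("s9").terminal_resistance
        assert sol.inlet_pressure[-1] == pytest.approx(q0 * (r_total + r_term), rel=1e-8)
        assert np.abs(sol.dvdt[-1]).max() < 1e-8
        # every intermediate node pressure follows the series ladder
        for j, sid in enumerate(sol.order):
            downstream = q0 * (
                sum(straight_net.elements(s).resistivity for s in sol.order[j + 1:]) + r_term
            )
            assert sol.pressure[-1, j] == pytest.approx(downstream, rel=1e-7)

    def test_zero_inflow_zero_solution(self, straight_net):
        wf = ox.constant_waveform(0.0, period=1.0)
        sol = ox.solve_periodic_flow(straight_net, wf, dt=1e-4, cycle_tol=1e-8)
        assert np.abs(sol.flow).max() == 0.0
        assert np.abs(sol.pressure).max() == 0.0

    def test_sinusoidal_solution_is_periodic(self, pulsatile_flow_curved):
        sol = pulsatile_flow_curved
        ref = np.abs(sol.state_trajectory).max()
        assert np.abs(sol.state_trajectory[-1] - sol.state_trajectory[0]).max() < 1e-6 * ref

    def test_junction_flow_balance_steady(self, bifurcated_net):
        wf = ox.constant_waveform(6.0e-6, period=1.0)
        sol = ox.solve_periodic_flow(bifurcated_net, wf, dt=1e-4, cycle_tol=1e-10,
                                     max_cycles=200)
        q = sol.flow[-1]
        col = {sid: sol.seg_column(sid) for sid in ("cc9", "ic0", "ec0", "ic9", "ec9")}
        assert q[col["cc9"]] == pytest.approx(q[col["ic0"]] + q[col["ec0"]], rel=1e-10)
        for leaf in ("ic9", "ec9"):
            r = bifurcated_net.segment(leaf).terminal_resistance
            assert sol.pressure[-1, col[leaf]] == r * q[col[leaf]]  # algebraic, exact

    def test_mean_inlet_power_nonnegative(self, pulsatile_flow_curved):
        assert pulsatile_flow_curved.mean_inlet_power() >= 0.0

    def test_nonconvergence_raises_with_norm(self, straight_net):
        wf = ox.waveform_preset("abdominal")
        with pytest.raises(ox.ConvergenceError) as exc:
            ox.solve_periodic_flow(straight_net, wf, dt=1e-4, cycle_tol=1e-14, max_cycles=3)
        assert exc.value.last_norm > 0

    def test_unstable_dt_raises(self, straight_net):
        wf = ox.constant_waveform(3e-5, period=1.0)
        with pytest.raises(ox.StabilityError):
            ox.solve_periodic_flow(straight_net, wf, dt=5e-3)


class TestVelocity:
    def test_round_trip_and_signs(self):
        geom = ox.SegmentGeometry(0.02, 0.005, 1e-3)
        q = math.pi * 0.005**2 * 0.3
        assert ox.segment_velocity(q, geom) == pytest.approx(0.3, rel=1e-12)
        assert ox.segment_velocity(0.0, geom) == 0.0
        assert ox.segment_velocity(-q, geom) < 0

    def test_dataframe_layout(self, steady_flow_straight):
        df = steady_flow_straight.to_dataframe()
        assert list(df.columns) == ["time_s", "segment_id", "Q_m3s", "P_Pa", "v_ms", "dvdt_ms2"]
        assert len(df) == steady_flow_straight.flow.size
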