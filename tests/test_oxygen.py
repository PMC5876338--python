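import logging
import math
from dataclasses import replace

import numpy as np
import pytest

import oxiline as ox
from oxiline.errors import ConfigError


class TestCoefficients:
    def test_inertance_values(self):
        assert ox.convective_inertance(1.0) == -1.0
        assert ox.convective_inertance(0.5) == -2.0
        assert ox.convective_inertance(-0.25) == 4.0

    def test_inertance_clamps_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="oxiline.oxygen"):
            out = ox.convective_inertance(0.0, v_floor=1e-6)
        assert out == pytest.approx(-1e6)
        assert any("clamp" in rec.message for rec in caplog.records)

    def test_resistance_values(self):
        assert ox.convective_resistance(0.7, 0.0) == 0.0
        assert ox.convective_resistance(0.5, 0.1) == pytest.approx(0.4)

    def test_resistance_is_time_derivative_of_inverse_velocity(self):
        t = np.linspace(0, 2 * np.pi, 20001)
        dt = t[1] - t[0]
        v = 1.0 + 0.5 * np.sin(t)
        dvdt = 0.5 * np.cos(t)
        r0 = ox.convective_resistance(v, dvdt)
        cd = (-1.0 / v[2:] + 1.0 / v[:-2]) / (2 * dt)
        assert np.abs(r0[1:-1] - cd).max() < 1e-6


class TestAlgebra:
    def test_po2_to_content(self):
        geom = ox.SegmentGeometry(0.02, 1.0 / math.sqrt(math.pi), 1e-3)
        assert ox.po2_to_content(0.0, 3e-5, geom) == 0.0
        assert ox.po2_to_content(85.0, 1.0, geom) == pytest.approx(85.0, rel=1e-12)
        m1 = ox.po2_to_content(40.0, 3e-5, geom)
        assert ox.po2_to_content(80.0, 3e-5, geom) == pytest.approx(2 * m1, rel=1e-12)
        with pytest.raises(ValueError):
            ox.po2_to_content(-1.0, 3e-5, geom)

    def test_convective_flux(self):
        assert ox.convective_flux(1050.0, 0.2, 1e-6) == pytest.approx(2.1e-4)
        assert ox.convective_flux(1050.0, 0.0, 1e-6) == 0.0
        assert ox.convective_flux(1050.0, -0.2, 1e-6) < 0

    def test_diffusive_flux(self):
        gamma = 1050.0 * 1.2e-9
        assert ox.diffusive_flux(gamma, 1.0, 1.0, 0.02) == 0.0
        assert ox.diffusive_flux(gamma, 1.0, 0.0, 0.02) == pytest.approx(-6.3e-5)
        a = ox.diffusive_flux(gamma, 0.3, 0.8, 0.01)
        b = ox.diffusive_flux(gamma, 0.8, 0.3, 0.01)
        assert a == -b
        with pytest.raises(ValueError):
            ox.diffusive_flux(gamma, 1.0, 0.0, 0.0)


class TestClosures:
    geom = ox.SegmentGeometry(0.02, 0.005, 1e-3)
    fluid = ox.FluidProperties()

    def test_zero_at_equal_concentrations(self):
        for closure in (ox.SherwoodClosure(), ox.FixedCoefficientClosure(1e-4)):
            assert ox.wall_flux(1e-3, 1e-3, self.geom, closure, self.fluid) == 0.0

    def test_sherwood_linear_in_difference(self):
        cl = ox.SherwoodClosure()
        q1 = ox.wall_flux(2e-3, 1e-3, self.geom, cl, self.fluid)
        q2 = ox.wall_flux(3e-3, 1e-3, self.geom, cl, self.fluid)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)
        assert q1 == pytest.approx(math.pi * self.fluid.gamma * 3.66 * 1e-3, rel=1e-12)
        assert q1 > 0  # flux out of blood when bulk exceeds wall

    def test_prescribed_ignores_concentrations(self):
        cl = ox.PrescribedFluxClosure(4.2e-7)
        assert ox.wall_flux(9e-3, 0.0, self.geom, cl, self.fluid) == pytest.approx(4.2e-7)
        assert ox.wall_flux(0.0, 9e-3, self.geom, cl, self.fluid) == pytest.approx(4.2e-7)

    def test_make_closure_names(self):
        assert isinstance(ox.make_closure("sherwood"), ox.SherwoodClosure)
        assert isinstance(
            ox.make_closure("fixed-coefficient", coefficient=1e-4),
            ox.FixedCoefficientClosure,
        )
        with pytest.raises(ConfigError):
            ox.make_closure("nusselt")
        with pytest.raises(ConfigError):
            ox.make_closure("fixed-coefficient")


class TestAssembly:
    def test_state_and_interface_counts(self, straight_net, steady_flow_straight):
        bc = ox.OxygenBoundary()
        system = ox.assemble_oxygen_odes(straight_net, steady_flow_straight, bc)
        assert system.n_states == 10
        assert system.n_interfaces == 11

    def test_low_velocity_warning_attached(self, straight_net):
        wf = ox.constant_waveform(1e-11, period=1.0)  # v ~ 1e-7 m/s, below floor
        flow = ox.solve_periodic_flow(straight_net, wf, dt=5e-4, cycle_tol=1e-6)
        system = ox.assemble_oxygen_odes(straight_net, flow, ox.OxygenBoundary())
        assert system.warnings
        assert system.clamp_fraction > 0.10


class TestSolveSteady:
    def test_no_sink_outlet_equals_inlet(self, straight_net, steady_flow_straight):
        bc = ox.OxygenBoundary(inlet_po2_mmhg=85.0, wall_po2_mmhg=85.0)
        sol = ox.solve_oxygen(straight_net, steady_flow_straight, bc, cycle_tol=1e-10)
        assert sol.po2_mmhg[-1, -1] == pytest.approx(85.0, rel=1e-8)
        # spatially constant convective flux under conservation with no sink
        assert np.ptp(sol.jcon[-1]) < 1e-8 * abs(sol.jcon[-1, 0])

    def test_integrated_mass_balance_with_sink(self, steady_sink_solution):
        sol = steady_sink_solution
        dx = np.array([sol.net.segment(s).geometry.length for s in sol.order])
        expected_outlet = sol.inlet_flux[-1] - np.sum(sol.wall_flux[-1] * dx)
        assert sol.jcon[-1, -1] == pytest.approx(expected_outlet, rel=1e-6)

    def test_residual_small_and_doubling_sink_doubles_drop(self, straight_net,
                                                           steady_flow_straight):
        sol1 = ox.solve_oxygen(
            straight_net, steady_flow_straight,
            ox.OxygenBoundary(wall_po2_mmhg=0.0, closure=ox.PrescribedFluxClosure(1e-9)),
            cycle_tol=1e-12, max_cycles=300,
        )
        sol2 = ox.solve_oxygen(
            straight_net, steady_flow_straight,
            ox.OxygenBoundary(wall_po2_mmhg=0.0, closure=ox.PrescribedFluxClosure(2e-9)),
            cycle_tol=1e-12, max_cycles=300,
        )
        assert np.abs(ox.mass_balance_residual(sol1)[-1]).max() < 1e-6
        drop1 = sol1.upstream_flux[-1] - sol1.jcon[-1]
        drop2 = sol2.upstream_flux[-1] - sol2.jcon[-1]
        assert np.allclose(drop2, 2 * drop1, rtol=1e-6)

    def test_exponential_decay_closed_form(self, straight_net, steady_flow_straight):
        from conftest import strong_sink_closure

        cl = strong_sink_closure(straight_net, flow=steady_flow_straight)
        bc = ox.OxygenBoundary(inlet_po2_mmhg=85.0, wall_po2_mmhg=60.0, closure=cl)
        sol = ox.solve_oxygen(straight_net, steady_flow_straight, bc,
                              cycle_tol=1e-12, max_cycles=300)
        v = steady_flow_straight.velocity[-1, 0]
        k = cl.decay_rate(straight_net.segment("s0").geometry, straight_net.fluid)
        x = np.cumsum([straight_net.segment(s).geometry.length for s in sol.order])
        analytic = 60.0 + 25.0 * np.exp(-k * x / v)
        err = np.abs(sol.po2_mmhg[-1] - analytic) / 25.0
        assert err.max() < 0.05  # first-order spatial error at 10 segments

    def test_spatial_error_halves_with_segment_count(self, straight_net):
        from oxiline.network import rediscretize_chain
        from conftest import strong_sink_closure

        wf = ox.constant_waveform(3.0e-5, period=1.0)
        errors = {}
        for n_seg in (10, 20):
            chain = rediscretize_chain(straight_net, n_seg)
            flow = ox.solve_periodic_flow(chain, wf, dt=1e-4, cycle_tol=1e-10,
                                          max_cycles=100)
            cl = strong_sink_closure(chain, flow=flow)
            bc = ox.OxygenBoundary(inlet_po2_mmhg=85.0, wall_po2_mmhg=60.0, closure=cl)
            sol = ox.solve_oxygen(chain, flow, bc, cycle_tol=1e-12, max_cycles=300)
            v = flow.velocity[-1, 0]
            k = cl.decay_rate(chain.segment("n0").geometry, chain.fluid)
            x = np.cumsum([chain.segment(s).geometry.length for s in sol.order])
            analytic = 60.0 + 25.0 * np.exp(-k * x / v)
            errors[n_seg] = np.abs(sol.po2_mmhg[-1] - analytic).max()
        ratio = errors[20] / errors[10]
        assert 0.3 < ratio < 0.7  # first-order: halving dx ~ halves the error

    def test_linearity_superposition(self, straight_net, steady_flow_straight):
        def solve(inlet, wall):
            bc = ox.OxygenBoundary(inlet_po2_mmhg=inlet, wall_po2_mmhg=wall)
            return ox.solve_oxygen(straight_net, steady_flow_straight, bc,
                                   cycle_tol=1e-12, max_cycles=300)

        s1 = solve(85.0, 60.0)
        s2 = solve(40.0, 10.0)
        s3 = solve(85.0 + 40.0, 60.0 + 10.0)
        combo = s1.jcon[-1] + s2.jcon[-1]
        assert np.allclose(s3.jcon[-1], combo, rtol=1e-8)


class TestJunctions:
    def test_concentration_continuity_and_flux_split(self, bifurcated_net):
        wf = ox.constant_waveform(6.0e-6, period=1.0)
        flow = ox.solve_periodic_flow(bifurcated_net, wf, dt=1e-4, cycle_tol=1e-10,
                                      max_cycles=200)
        bc = ox.OxygenBoundary(inlet_po2_mmhg=85.3, wall_po2_mmhg=55.5)
        sol = ox.solve_oxygen(bifurcated_net, flow, bc, cycle_tol=1e-12, max_cycles=300)
        c = {s: sol.seg_column(s) for s in ("cc9", "ic0", "ec0")}
        j_par = sol.jcon[-1, c["cc9"]]
        j_ic = sol.upstream_flux[-1, c["ic0"]]
        j_ec = sol.upstream_flux[-1, c["ec0"]]
        assert j_ic + j_ec == pytest.approx(j_par, rel=1e-9)  # conserved split
        q_ic = flow.flow[-1, c["ic0"]]
        q_ec = flow.flow[-1, c["ec0"]]
        assert j_ic / j_ec == pytest.approx(q_ic / q_ec, rel=1e-9)  # proportional to flow

    def test_outlet_po2_below_inlet_with_sink(self, bifurcated_net):
        wf = ox.constant_waveform(6.0e-6, period=1.0)
        flow = ox.solve_periodic_flow(bifurcated_net, wf, dt=1e-4, cycle_tol=1e-10,
                                      max_cycles=200)
        bc = ox.OxygenBoundary(inlet_po2_mmhg=85.3, wall_po2_mmhg=55.5)
        sol = ox.solve_oxygen(bifurcated_net, flow, bc, cycle_tol=1e-12, max_cycles=300)
        for leaf in sol.net.leaves:
            assert sol.po2_mmhg[-1, sol.seg_column(leaf)] < 85.3


class TestDiagnostics:
    def test_impedance_identity_on_unmasked_samples(self, steady_sink_solution):
        sol = steady_sink_solution
        z_con, _ = ox.impedance_diagnostics(sol)
        dx = np.array([sol.net.segment(s).geometry.length for s in sol.order])
        div_diff = (sol.jdiff_out - sol.jdiff_in) / dx[None, :]
        lhs = np.ma.filled(z_con * sol.jcon + div_diff, 0.0)
        assert np.abs(lhs).max() < 1e-12 * np.abs(div_diff).max()

    def test_zcon_vanishes_without_flux_gradient(self, straight_net, steady_flow_straight):
        bc = ox.OxygenBoundary(inlet_po2_mmhg=85.0, wall_po2_mmhg=85.0)
        sol = ox.solve_oxygen(straight_net, steady_flow_straight, bc, cycle_tol=1e-10)
        z_con, _ = ox.impedance_diagnostics(sol)
        assert np.abs(np.ma.filled(z_con[-1], 0.0)).max() < 1e-10

    def test_zero_flux_samples_masked(self, steady_sink_solution):
        sol = steady_sink_solution
        jcon = sol.jcon.copy()
        jcon[0, 0] = 0.0
        sol2 = replace(sol, jcon=jcon)
        z_con, _ = ox.impedance_diagnostics(sol2)
        assert bool(z_con.mask[0, 0])
        assert np.isfinite(np.ma.filled(z_con, 0.0)).all()

    def test_vfloor_insensitive_when_flow_fast(self, straight_net, steady_flow_straight):
        sols = [
            ox.solve_oxygen(
                straight_net, steady_flow_straight,
                ox.OxygenBoundary(v_floor=vf), cycle_tol=1e-10,
            )
            for vf in (1e-6, 1e-4)
        ]
        assert np.array_equal(sols[0].jcon, sols[1].jcon)
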