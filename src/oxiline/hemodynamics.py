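"""Lumped-parameter (transmission-line) blood flow on a vessel network.

Each segment is an inverted-L circuit cell: a series resistance--inertance
branch carrying the segment flow Q_i, then a shunt compliance to ground at the
downstream node holding the pressure P_i.  The governing relations are the
fluid transmission-line pair: the axial momentum law

    -dP/dx = R' Q + L' dQ/dt        (per segment, integrated over dx)

and node continuity C' dP/dt = sum(Q_in) - sum(Q_out).  The inlet flow is
prescribed by a periodic waveform; each leaf closes on an algebraic terminal
resistance P_leaf = R_term * Q_leaf which is substituted into the leaf branch
equation (so leaf pressures are not states).  The resulting system is linear,

    dx/dt = A x + g * Q_in(t),

and is integrated with the classical fixed-step fourth-order Runge-Kutta
scheme to a periodic steady state detected by the cycle-to-cycle L2 norm.

Naming note: the literature conventionally calls the series impedance of a
transmission line "longitudinal" and the shunt impedance "transverse"; the
source formulation this package follows writes the pressure-gradient law with
the symbol Z_x labelled "transverse impedance".  The equations used here are
the ones as written; only the label differs from convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, IntegrationDivergedError, InvalidNetworkError, StabilityError
from .network import SegmentGeometry, VesselNetwork, validate_network
from .waveforms import FlowWaveform


def segment_velocity(q, geom: SegmentGeometry):
    """Mean axial velocity v = Q / (pi R^2) under the uniform-profile assumption.

    Works elementwise on arrays; negative Q yields negative v (retrograde
    flow is representable).
    """
    return np.asarray(q, dtype=float) / geom.area


class FlowSystem:
    """Assembled linear flow ODE system ``dx/dt = A x + g Q_in(t)`` for a network.

    State layout: one flow state per non-root segment (the root flow is
    prescribed by the inlet waveform) followed by one pressure state per
    non-leaf segment (leaf pressures are algebraic through the terminal
    resistance).
    """

    def __init__(self, net: VesselNetwork):
        violations = validate_network(net)
        if violations:
            raise InvalidNetworkError(violations)
        self.net = net
        self.order = net.topological_order()
        self.root = self.order[0]
        leaves = set(net.leaves)

        self.q_ids = [sid for sid in self.order if sid != self.root]
        self.p_ids = [sid for sid in self.order if sid not in leaves]
        self.iq = {sid: i for i, sid in enumerate(self.q_ids)}
        self.ip = {sid: len(self.q_ids) + i for i, sid in enumerate(self.p_ids)}
        self.n_states = len(self.q_ids) + len(self.p_ids)
        self.n_branch_states = len(self.q_ids)
        self.n_node_states = len(self.p_ids)

        elems = {sid: net.elements(sid) for sid in self.order}
        self.elements = elems
        A = np.zeros((self.n_states, self.n_states))
        g = np.zeros(self.n_states)

        for sid in self.q_ids:
            seg = net.segment(sid)
            e = elems[sid]
            row = self.iq[sid]
            # upstream pressure: parent's downstream node (parent is never a leaf)
            A[row, self.ip[seg.parent]] += 1.0 / e.inertance
            A[row, row] -= e.resistivity / e.inertance
            if sid in leaves:
                A[row, row] -= seg.terminal_resistance / e.inertance
            else:
                A[row, self.ip[sid]] -= 1.0 / e.inertance

        for sid in self.p_ids:
            e = elems[sid]
            row = self.ip[sid]
            if sid == self.root:
                g[row] = 1.0 / e.compliance  # prescribed inlet flow enters here
            else:
                A[row, self.iq[sid]] += 1.0 / e.compliance
            for child in net.children(sid):
                A[row, self.iq[child]] -= 1.0 / e.compliance

        self.A = A
        self.g = g

    def rhs(self, t, x, q_in):
        """Right-hand side with prescribed inlet flow value ``q_in`` at time t."""
        return self.A @ x + self.g * q_in

    def eigenvalues(self):
        if self.n_states == 0:
            return np.zeros(0, dtype=complex)
        return np.linalg.eigvals(self.A)

    def describe(self) -> dict:
        return {
            "segments": len(self.net),
            "branch_states": self.n_branch_states,
            "node_states": self.n_node_states,
            "states": self.n_states,
            "root": self.root,
            "leaves": sorted(self.net.leaves),
        }


def assemble_flow_odes(net: VesselNetwork) -> FlowSystem:
    """Assemble the lumped flow ODE system for a validated network."""
    return FlowSystem(net)


def _rk4_amplification(z):
    return 1.0 + z + z**2 / 2.0 + z**3 / 6.0 + z**4 / 24.0


@dataclass
class StabilityReport:
    dt: float
    max_abs_eig: float
    max_amplification: float
    dt_max_estimate: float
    stable: bool


def check_stability(system: FlowSystem, dt: float) -> StabilityReport:
    """Estimate whether fixed-step RK4 at ``dt`` is stable for the linear system.

    Evaluates the RK4 amplification factor at every eigenvalue of A; the step
    is flagged unstable when any |R(lambda dt)| exceeds one.  ``dt_max_estimate``
    is found by bisection on the same criterion.
    """
    eigs = system.eigenvalues()
    if eigs.size == 0:
        return StabilityReport(dt, 0.0, 0.0, np.inf, True)
    amp = float(np.max(np.abs(_rk4_amplification(eigs * dt))))
    stable = amp <= 1.0 + 1e-9

    def ok(step):
        return float(np.max(np.abs(_rk4_amplification(eigs * step)))) <= 1.0 + 1e-9

    hi = dt
    while not ok(hi):
        hi *= 0.5
    while ok(hi * 2.0) and hi < 1e6:
        hi *= 2.0
    lo = hi
    hi = hi * 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return StabilityReport(dt, float(np.max(np.abs(eigs))), amp, lo, stable)


def rk4_integrate(f, y0, dt: float, n_steps: int, t0: float = 0.0):
    """Classical fixed-step RK4 for ``dy/dt = f(t, y)``.

    Returns (times, trajectory) with trajectory[k] = y(t0 + k dt), shape
    (n_steps + 1, dim).  Raises :class:`IntegrationDivergedError` naming the
    first time at which a non-finite state appears.
    """
    y = np.array(y0, dtype=float)
    out = np.empty((n_steps + 1,) + y.shape)
    out[0] = y
    t = t0
    for k in range(n_steps):
        k1 = np.asarray(f(t, y))
        k2 = np.asarray(f(t + 0.5 * dt, y + 0.5 * dt * k1))
        k3 = np.asarray(f(t + 0.5 * dt, y + 0.5 * dt * k2))
        k4 = np.asarray(f(t + dt, y + dt * k3))
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = t0 + (k + 1) * dt
        if not np.all(np.isfinite(y)):
            raise IntegrationDivergedError(t)
        out[k + 1] = y
    times = t0 + dt * np.arange(n_steps + 1)
    return times, out


@dataclass
class FlowSolution:
    """Converged periodic flow solution on a uniform time grid over one cycle.

    Arrays are shaped (n_times, n_segments) in the network's topological
    order; ``times`` spans one period inclusive of both endpoints.
    """

    net: VesselNetwork
    order: list
    times: np.ndarray
    dt: float
    flow: np.ndarray  # Q (m^3/s)
    pressure: np.ndarray  # downstream node pressure per segment (Pa)
    velocity: np.ndarray  # v (m/s)
    dvdt: np.ndarray  # from the ODE right-hand side (m/s^2)
    inlet_pressure: np.ndarray  # (n_times,) Pa
    cycles_run: int = 0
    cycle_norm: float = np.nan
    waveform: FlowWaveform | None = None
    state_trajectory: np.ndarray | None = field(default=None, repr=False)

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def seg_column(self, sid: str) -> int:
        return self.order.index(sid)

    def mean_inlet_power(self) -> float:
        """Period-averaged hydraulic power delivered at the inlet (W)."""
        q_in = self.flow[:, self.seg_column(self.order[0])]
        return float(np.trapezoid(self.inlet_pressure * q_in, self.times) / self.period)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format table: time_s, segment_id, Q_m3s, P_Pa, v_ms, dvdt_ms2."""
        nt, ns = self.flow.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, ns),
                "segment_id": np.tile(np.asarray(self.order, dtype=object), nt),
                "Q_m3s": self.flow.ravel(),
                "P_Pa": self.pressure.ravel(),
                "v_ms": self.velocity.ravel(),
                "dvdt_ms2": self.dvdt.ravel(),
            }
        )


def _integrate_cycle(system: FlowSystem, x0, dt, steps, w_half):
    """One cycle of RK4 on the linear system with precomputed forcing samples.

    ``w_half`` holds the inlet flow on the half-step grid (2*steps + 1 points).
    """
    A, g = system.A, system.g
    x = x0
    traj = np.empty((steps + 1, x0.size))
    traj[0] = x
    for k in range(steps):
        w0, wm, w1 = w_half[2 * k], w_half[2 * k + 1], w_half[2 * k + 2]
        k1 = A @ x + g * w0
        k2 = A @ (x + 0.5 * dt * k1) + g * wm
        k3 = A @ (x + 0.5 * dt * k2) + g * wm
        k4 = A @ (x + dt * k3) + g * w1
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        traj[k + 1] = x
    if not np.all(np.isfinite(x)):
        raise IntegrationDivergedError(steps * dt)
    return traj


def solve_periodic_flow(
    net: VesselNetwork,
    waveform: FlowWaveform,
    dt: float = 1e-4,
    cycle_tol: float = 1e-4,
    max_cycles: int = 50,
    check: bool = True,
) -> FlowSolution:
    """Integrate the lumped flow system to its periodic steady state.

    Cycles of length ``waveform.period`` are integrated with fixed-step RK4
    until the relative L2 cycle-to-cycle difference of the full state
    trajectory drops below ``cycle_tol``; the final cycle is returned.
    ``dt`` is snapped to an integer divisor of the period.  With ``check``
    the RK4 stability estimate is consulted first.
    """
    if cycle_tol <= 0:
        raise ValueError("cycle_tol must be positive")
    system = assemble_flow_odes(net)
    T = waveform.period
    steps = max(1, round(T / dt))
    dt = T / steps
    if check:
        rep = check_stability(system, dt)
        if not rep.stable:
            raise StabilityError(dt, rep.dt_max_estimate)

    t_half = np.arange(2 * steps + 1) * (dt / 2.0)
    w_half = np.asarray(waveform.evaluate(t_half), dtype=float)

    x = np.zeros(system.n_states)
    prev = None
    norm = np.nan
    cycles = 0
    traj = np.zeros((steps + 1, max(system.n_states, 1)))[:, : system.n_states]
    if system.n_states == 0:
        cycles, norm = 1, 0.0
    else:
        for cycles in range(1, max_cycles + 1):
            traj = _integrate_cycle(system, x, dt, steps, w_half)
            x = traj[-1]
            if prev is not None:
                ref = np.linalg.norm(prev)
                norm = np.linalg.norm(traj - prev) / max(ref, 1e-300)
                if norm < cycle_tol:
                    break
            prev = traj
        else:
            raise ConvergenceError(max_cycles, norm, cycle_tol)

    return _build_solution(system, waveform, traj, dt, steps, cycles, norm)


def _build_solution(system, waveform, traj, dt, steps, cycles, norm) -> FlowSolution:
    net = system.net
    order = system.order
    times = np.arange(steps + 1) * dt
    w = np.asarray(waveform.evaluate(times), dtype=float)
    dw = np.asarray(waveform.derivative(times), dtype=float)

    nseg = len(order)
    flow = np.empty((steps + 1, nseg))
    pressure = np.empty((steps + 1, nseg))
    velocity = np.empty((steps + 1, nseg))
    dvdt = np.empty((steps + 1, nseg))

    # dx/dt recomputed from the RHS at the stored samples (not finite-differenced)
    if system.n_states:
        dX = traj @ system.A.T + np.outer(w, system.g)
    else:
        dX = np.zeros((steps + 1, 0))

    leaves = set(net.leaves)
    for j, sid in enumerate(order):
        seg = net.segment(sid)
        area = seg.geometry.area
        if sid == system.root:
            q = w
            dq = dw
        else:
            q = traj[:, system.iq[sid]]
            dq = dX[:, system.iq[sid]]
        flow[:, j] = q
        velocity[:, j] = q / area
        dvdt[:, j] = dq / area
        if sid in leaves:
            pressure[:, j] = seg.terminal_resistance * q
        else:
            pressure[:, j] = traj[:, system.ip[sid]]

    e_root = system.elements[system.root]
    if system.root in system.ip:
        p_root_node = traj[:, system.ip[system.root]]
    else:  # single-segment network: fully algebraic
        p_root_node = net.segment(system.root).terminal_resistance * w
    inlet_pressure = p_root_node + e_root.resistivity * w + e_root.inertance * dw

    return FlowSolution(
        net=net,
        order=list(order),
        times=times,
        dt=dt,
        flow=flow,
        pressure=pressure,
        velocity=velocity,
        dvdt=dvdt,
        inlet_pressure=inlet_pressure,
        cycles_run=cycles,
        cycle_norm=float(norm) if norm == norm else np.nan,
        waveform=waveform,
        state_trajectory=traj,
    )
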