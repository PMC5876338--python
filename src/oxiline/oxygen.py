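"""Lumped transmission-line model of oxygen transport in a vessel network.

The transported quantities are the cross-section oxygen content
M = integral of 2 pi r C dr (uniform profile: M = pi R^2 C), the convective
flux J_con = rho v M carried by bulk motion, and the axial diffusive flux
J_diff = Gamma dM/dx.  The transmission-line pair for oxygen reads

    -dJ_diff/dx = R0 J_con + L0 dJ_con/dt
    -dJ_con/dx  = -q_wall = 2 pi R (Gamma dC/dr)|_{r=R}

with the convective coefficients

    R0 = (1/v^2) dv/dt = d/dt(-1/v)     [1/m]
    L0 = -1/v                           [s/m]

R0 is the fraction of the remaining oxygen convection per unit distance and
|L0| the transit time of oxygen per unit distance (L0 itself is negative by
construction; the sign is kept as derived and |L0| is what is reported as a
transit time).  In circuit terms each segment is a series R0--L0 branch
carrying J_con with the oxygen lost to the wall entering as a current sink.

The two lines above combine (equivalently, the cross-section-integrated
transport equation in flux variables) into the explicit per-segment update
integrated here,

    dJ_i/dt = v_i [ R0_i J_i - (J_i - J_up,i)/dx_i + dJ_diff/dx|_i - q_w,i ],

with upwind (flow-directed) spatial coupling for the convective divergence and
centred two-point interface differences for J_diff.  Both transmission-line
lines are recovered afterwards as residual/impedance diagnostics.

The radial wall gradient is not resolvable in a lumped model; three selectable
closures surrogate it: a Sherwood-number mass-transfer law (default, Sh = 3.66,
fully developed laminar), a fixed mass-transfer coefficient, and a prescribed
per-length flux ("oxygen consumption" mode).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ConvergenceError, IntegrationDivergedError
from .hemodynamics import FlowSolution
from .network import FluidProperties, SegmentGeometry, VesselNetwork

logger = logging.getLogger(__name__)

DEFAULT_V_FLOOR = 1e-6  # m/s; regularization floor at flow reversal
#: Default oxygen solubility: dissolved mass-fraction concentration per mmHg.
#: Any positive value yields identical PO2 fields (the model is linear in C).
DEFAULT_SOLUBILITY = 3.0e-5


def _clamp_velocity(v, v_floor, warn_context=None):
    """Clamp |v| to >= v_floor keeping the sign; log when clamping occurs."""
    v = np.asarray(v, dtype=float)
    small = np.abs(v) < v_floor
    n_small = int(np.count_nonzero(small))
    if n_small and warn_context is not None:
        logger.warning(
            "%s: clamped %d velocity sample(s) below the %g m/s floor",
            warn_context, n_small, v_floor,
        )
    sign = np.where(v >= 0.0, 1.0, -1.0)
    clamped = np.where(small, sign * v_floor, v)
    return clamped, n_small


def convective_inertance(v, v_floor: float = DEFAULT_V_FLOOR):
    """Convective inertance L0 = -1/v (s/m), the negated transit time per metre.

    Velocities below ``v_floor`` in magnitude are clamped (sign-preserving)
    with a logged warning, never silently.
    """
    vc, _ = _clamp_velocity(v, v_floor, warn_context="convective_inertance")
    out = -1.0 / vc
    return float(out) if np.ndim(v) == 0 else out


def convective_resistance(v, dvdt, v_floor: float = DEFAULT_V_FLOOR):
    """Convective resistance R0 = (1/v^2) dv/dt (1/m).

    Equals d/dt(-1/v) for smooth v; zero for steady flow.
    """
    vc, _ = _clamp_velocity(v, v_floor, warn_context="convective_resistance")
    out = np.asarray(dvdt, dtype=float) / vc**2
    return float(out) if np.ndim(v) == 0 and np.ndim(dvdt) == 0 else out


def po2_to_content(po2_mmhg, solubility: float, geom: SegmentGeometry):
    """Cross-section oxygen content M = pi R^2 * alpha * PO2 (Henry's law)."""
    if np.any(np.asarray(po2_mmhg) < 0):
        raise ValueError("oxygen tension must be non-negative")
    if not solubility > 0:
        raise ValueError("solubility must be positive")
    return geom.area * solubility * np.asarray(po2_mmhg, dtype=float)


def convective_flux(rho, v, m):
    """Convective oxygen flux J_con = rho v M; sign follows the flow."""
    return rho * np.asarray(v, dtype=float) * np.asarray(m, dtype=float)


def diffusive_flux(gamma, m_upstream, m_downstream, dx):
    """Interface diffusive flux J_diff = Gamma (M_down - M_up)/dx (two-point)."""
    if np.any(np.asarray(dx) <= 0):
        raise ValueError("dx must be positive")
    return gamma * (np.asarray(m_downstream, float) - np.asarray(m_upstream, float)) / dx


# -- wall-flux closures ----------------------------------------------------


@dataclass(frozen=True)
class SherwoodClosure:
    """Sherwood-number closure for the radial wall gradient.

    Approximates (dC/dr)|_R ~= -Sh (C_bulk - C_wall)/(2R), giving a
    per-length wall flux q_w = pi Gamma Sh (C_bulk - C_wall).  Sh = 3.66 is
    the fully developed laminar mass-transfer value.
    """

    sherwood_number: float = 3.66

    def per_length_flux(self, c_bulk, c_wall, geom, fluid):
        return math.pi * fluid.gamma * self.sherwood_number * (
            np.asarray(c_bulk, float) - c_wall
        )

    def decay_rate(self, geom, fluid):
        """k such that steady uniform advection obeys dC/dx = -(k/v)(C - C_wall)."""
        return fluid.o2_diffusivity * self.sherwood_number / geom.radius**2


@dataclass(frozen=True)
class FixedCoefficientClosure:
    """Fixed mass-transfer coefficient h_m (m/s): q_w = 2 pi R rho h_m (C - C_wall)."""

    coefficient: float

    def per_length_flux(self, c_bulk, c_wall, geom, fluid):
        return 2.0 * math.pi * geom.radius * fluid.density * self.coefficient * (
            np.asarray(c_bulk, float) - c_wall
        )

    def decay_rate(self, geom, fluid):
        return 2.0 * self.coefficient / geom.radius


@dataclass(frozen=True)
class PrescribedFluxClosure:
    """Prescribed constant per-length wall flux (oxygen-consumption mode)."""

    flux_per_length: float = 0.0

    def per_length_flux(self, c_bulk, c_wall, geom, fluid):
        return np.full_like(np.asarray(c_bulk, float), self.flux_per_length)

    def decay_rate(self, geom, fluid):
        return 0.0


def make_closure(name: str, **params):
    """Build a wall-flux closure by config name.

    Names: 'sherwood' (param sherwood_number), 'fixed-coefficient'
    (param coefficient, m/s), 'prescribed-flux' (param flux_per_length).
    """
    if name == "sherwood":
        return SherwoodClosure(params.get("sherwood_number", 3.66))
    if name == "fixed-coefficient":
        if "coefficient" not in params:
            raise ConfigError("fixed-coefficient closure requires 'coefficient' (m/s)")
        return FixedCoefficientClosure(params["coefficient"])
    if name == "prescribed-flux":
        return PrescribedFluxClosure(params.get("flux_per_length", 0.0))
    raise ConfigError(f"unknown wall-flux closure {name!r}")


def wall_flux(c_bulk, c_wall, geom: SegmentGeometry, closure, fluid: FluidProperties):
    """Per-length oxygen flux out of the blood, q_w >= 0 when C_bulk >= C_wall."""
    return closure.per_length_flux(c_bulk, c_wall, geom, fluid)


# -- boundary conditions ---------------------------------------------------


@dataclass
class OxygenBoundary:
    """Oxygen boundary data for a network.

    ``inlet_po2_mmhg`` may be a number or a callable of absolute time
    (for step/transient studies).  ``wall_po2_mmhg`` may be a number or a
    mapping segment-id -> mmHg.  ``solubility`` converts tension to
    concentration (Henry's law); the model is linear in it.
    """

    inlet_po2_mmhg: object = 85.0
    wall_po2_mmhg: object = 60.0
    solubility: float = DEFAULT_SOLUBILITY
    closure: object = field(default_factory=SherwoodClosure)
    v_floor: float = DEFAULT_V_FLOOR

    def __post_init__(self):
        if not self.solubility > 0:
            raise ConfigError("solubility must be positive")
        if not self.v_floor > 0:
            raise ConfigError("v_floor must be positive")
        if not callable(self.inlet_po2_mmhg) and self.inlet_po2_mmhg < 0:
            raise ConfigError("inlet oxygen tension must be >= 0")

    def inlet_concentration(self, t):
        po2 = self.inlet_po2_mmhg(t) if callable(self.inlet_po2_mmhg) else self.inlet_po2_mmhg
        return self.solubility * po2

    def wall_concentration(self, seg_id: str):
        if isinstance(self.wall_po2_mmhg, dict):
            po2 = self.wall_po2_mmhg[seg_id]
        else:
            po2 = self.wall_po2_mmhg
        if po2 < 0:
            raise ConfigError(f"wall oxygen tension for '{seg_id}' must be >= 0")
        return self.solubility * po2


# -- ODE system ------------------------------------------------------------


class OxygenSystem:
    """Assembled oxygen ODE system on top of a converged flow solution.

    One convective-flux state J_i per segment (its value at the segment's
    downstream face, upwind convention); interface diffusive fluxes are
    derived quantities.  The driving velocity/acceleration fields are read
    from the flow trajectory; oxygen RK4 stages are aligned with flow samples
    when the oxygen step is an even multiple of the flow step and otherwise
    obtained by linear interpolation.
    """

    def __init__(self, net: VesselNetwork, flow: FlowSolution, bc: OxygenBoundary,
                 h: float | None = None):
        net.require_valid()
        if flow.order != net.topological_order():
            raise ConfigError("flow solution does not match the network's segment order")
        self.net = net
        self.flow = flow
        self.bc = bc
        self.order = list(flow.order)
        nseg = len(self.order)
        self.nseg = nseg

        steps_f = flow.times.size - 1
        h = 2.0 * flow.dt if h is None else h
        ratio = h / flow.dt
        r = round(ratio)
        if abs(ratio - r) > 1e-9 * max(1.0, ratio) or r < 1 or steps_f % r != 0:
            raise ConfigError(
                "oxygen step must be an integer multiple of the flow step that "
                "divides the cycle"
            )
        self.h = r * flow.dt
        self.steps = steps_f // r

        idx = {sid: i for i, sid in enumerate(self.order)}
        self.parent = np.array(
            [idx[net.segment(sid).parent] if net.segment(sid).parent else -1
             for sid in self.order]
        )
        self.is_root = self.parent < 0
        self.leaf_mask = np.array([sid in set(net.leaves) for sid in self.order])
        self.dx = np.array([net.segment(sid).geometry.length for sid in self.order])
        self.area = np.array([net.segment(sid).geometry.area for sid in self.order])
        par_dx = np.where(self.is_root, self.dx, self.dx[self.parent])
        self.dx_face = np.where(self.is_root, self.dx, 0.5 * (self.dx + par_dx))
        self.rho = net.fluid.density
        self.gamma = net.fluid.gamma
        self.geoms = [net.segment(sid).geometry for sid in self.order]
        self.c_wall = np.array([bc.wall_concentration(sid) for sid in self.order])
        # closures act per segment with identical parameters; vectorized via
        # per-segment coefficient arrays for the linear closures
        q10 = np.array(
            [float(bc.closure.per_length_flux(1.0, 0.0, g, net.fluid)) for g in self.geoms]
        )
        q00 = np.array(
            [float(bc.closure.per_length_flux(0.0, 0.0, g, net.fluid)) for g in self.geoms]
        )
        self._qw_coeff = q10 - q00  # slope in (C_bulk - C_wall); 0 for prescribed flux
        self._qw_const = q00

        # per-stage flow fields on the oxygen half-step grid over one cycle
        n_half = 2 * self.steps + 1
        pos = np.linspace(0.0, steps_f, n_half)  # flow-grid fractional index
        self.v_half = self._sample(flow.velocity, pos)
        self.dvdt_half = self._sample(flow.dvdt, pos)
        self.t_half = pos * flow.dt
        vc, n_clamped = _clamp_velocity(self.v_half, bc.v_floor, warn_context=None)
        self.vc_half = vc
        self.q_half = vc * self.area[None, :]
        self.clamp_fraction = n_clamped / self.v_half.size
        self.warnings: list[str] = []
        frac_per_seg = (np.abs(self.v_half) < bc.v_floor).mean(axis=0)
        for j, frac in enumerate(frac_per_seg):
            if frac > 0.10:
                self.warnings.append(
                    f"segment '{self.order[j]}' velocity below the {bc.v_floor:g} m/s "
                    f"floor for {100 * frac:.1f}% of the cycle"
                )
        if n_clamped:
            logger.warning(
                "oxygen system: clamped %d of %d velocity samples; %s",
                n_clamped, self.v_half.size,
                "; ".join(self.warnings) or "scattered clamping",
            )

    @staticmethod
    def _sample(arr, pos):
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, arr.shape[0] - 1)
        w = (pos - lo)[:, None]
        return (1.0 - w) * arr[lo] + w * arr[hi]

    @property
    def n_states(self) -> int:
        return self.nseg

    @property
    def n_interfaces(self) -> int:
        """Diffusive-flux interfaces: one upstream face per segment + leaf outlets."""
        return self.nseg + int(np.count_nonzero(self.leaf_mask))

    def initial_state(self, po2_mmhg: float | None = None):
        """Uniform-tension initial state consistent with the t=0 flow field."""
        if po2_mmhg is None:
            c0 = self.bc.inlet_concentration(0.0)
        else:
            c0 = self.bc.solubility * po2_mmhg
        return self.rho * self.q_half[0] * c0

    # core right-hand side -------------------------------------------------

    def _rhs(self, j, vc, q, dvdt, t):
        c = j / (self.rho * q)
        m = self.area * c
        r0 = dvdt / vc**2

        c_in = self.bc.inlet_concentration(t)
        c_up = c[self.parent]
        c_up[self.is_root] = c_in
        j_up = self.rho * q * c_up

        m_up = m[self.parent]
        m_up[self.is_root] = (self.area * c_in)[self.is_root]
        fd_up = self.gamma * (m - m_up) / self.dx_face
        fd_dn = np.zeros_like(fd_up)
        np.add.at(fd_dn, self.parent[~self.is_root], fd_up[~self.is_root])
        fd_dn[self.leaf_mask] = 0.0  # zero-gradient outflow

        qw = self._qw_coeff * c + self._qw_const - self._qw_coeff * self.c_wall
        return vc * (r0 * j - (j - j_up) / self.dx + (fd_dn - fd_up) / self.dx - qw)

    def integrate_cycle(self, j0, cycle_start_time=0.0):
        """One cycle of RK4; returns the (steps+1, nseg) trajectory."""
        h = self.h
        j = np.array(j0, dtype=float)
        traj = np.empty((self.steps + 1, self.nseg))
        traj[0] = j
        for k in range(self.steps):
            i0, im, i1 = 2 * k, 2 * k + 1, 2 * k + 2
            t0 = cycle_start_time + self.t_half[i0]
            tm = cycle_start_time + self.t_half[im]
            t1 = cycle_start_time + self.t_half[i1]
            k1 = self._rhs(j, self.vc_half[i0], self.q_half[i0], self.dvdt_half[i0], t0)
            k2 = self._rhs(j + 0.5 * h * k1, self.vc_half[im], self.q_half[im],
                           self.dvdt_half[im], tm)
            k3 = self._rhs(j + 0.5 * h * k2, self.vc_half[im], self.q_half[im],
                           self.dvdt_half[im], tm)
            k4 = self._rhs(j + h * k3, self.vc_half[i1], self.q_half[i1],
                           self.dvdt_half[i1], t1)
            j = j + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.all(np.isfinite(j)):
                bad = int(np.argmax(~np.isfinite(j)))
                raise IntegrationDivergedError(
                    cycle_start_time + (k + 1) * h,
                    detail=f"first failing segment '{self.order[bad]}'",
                )
            traj[k + 1] = j
        return traj


def assemble_oxygen_odes(net: VesselNetwork, flow: FlowSolution, bc: OxygenBoundary,
                         h: float | None = None) -> OxygenSystem:
    """Assemble the oxygen ODE system driven by a converged flow solution."""
    return OxygenSystem(net, flow, bc, h=h)


@dataclass
class OxygenSolution:
    """Oxygen transport solution on the oxygen time grid.

    Arrays are (n_times, n_segments) in topological order.  ``wall_flux`` is
    the per-length flux out of the blood (kg m^-1 s^-1); ``residual`` is the
    per-segment convective mass-balance residual normalized by the mean inlet
    convective flux magnitude.
    """

    net: VesselNetwork
    order: list
    times: np.ndarray
    dt: float
    jcon: np.ndarray
    m: np.ndarray
    c: np.ndarray
    po2_mmhg: np.ndarray
    jdiff_in: np.ndarray
    jdiff_out: np.ndarray
    upstream_flux: np.ndarray
    inlet_flux: np.ndarray
    wall_flux: np.ndarray
    residual: np.ndarray
    cycles_run: int
    cycle_norm: float
    clamp_fraction: float
    warnings: list
    bc: OxygenBoundary = field(repr=False, default=None)
    flow: FlowSolution = field(repr=False, default=None)

    def seg_column(self, sid: str) -> int:
        return self.order.index(sid)

    @property
    def leaf_columns(self) -> list:
        leaves = set(self.net.leaves)
        return [j for j, sid in enumerate(self.order) if sid in leaves]

    def outlet_flux(self) -> dict:
        """Leaf-exit convective flux series keyed by segment id."""
        leaves = set(self.net.leaves)
        return {sid: self.jcon[:, self.seg_column(sid)] for sid in self.order if sid in leaves}

    def conservation_summary(self) -> dict:
        """Period-averaged convective oxygen balance: inlet - outlets - wall sink."""
        T = self.times[-1] - self.times[0]
        mean = lambda y: float(np.trapezoid(y, self.times) / T)
        inlet = mean(self.inlet_flux)
        outlets = sum(mean(self.jcon[:, j]) for j in self.leaf_columns)
        dx = np.array([self.net.segment(sid).geometry.length for sid in self.order])
        wall = float(sum(mean(self.wall_flux[:, j]) * dx[j] for j in range(len(self.order))))
        scale = max(abs(inlet), 1e-300)
        return {
            "inlet_flux_mean": inlet,
            "outlet_flux_mean_total": outlets,
            "wall_flux_mean_total": wall,
            "imbalance_relative": (inlet - outlets - wall) / scale,
        }

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format oxygen results table."""
        nt, ns = self.jcon.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, ns),
                "segment_id": np.tile(np.asarray(self.order, dtype=object), nt),
                "Jcon": self.jcon.ravel(),
                "Jdiff_in": self.jdiff_in.ravel(),
                "Jdiff_out": self.jdiff_out.ravel(),
                "M": self.m.ravel(),
                "C": self.c.ravel(),
                "PO2_mmHg": self.po2_mmhg.ravel(),
                "wall_flux": self.wall_flux.ravel(),
                "residual": self.residual.ravel(),
            }
        )


def solve_oxygen(
    net: VesselNetwork,
    flow: FlowSolution,
    bc: OxygenBoundary,
    dt: float | None = None,
    cycle_tol: float = 1e-6,
    max_cycles: int = 200,
    initial_po2_mmhg: float | None = None,
    keep_all_cycles: bool = False,
    require_convergence: bool = True,
) -> OxygenSolution:
    """Integrate the oxygen system to its periodic steady state.

    Same convergence contract as the flow solver: cycles are repeated until
    the relative L2 cycle-to-cycle trajectory difference drops below
    ``cycle_tol``.  With ``keep_all_cycles`` the concatenated multi-cycle
    trajectory is returned (useful for step-response/transit studies, where
    ``require_convergence=False`` with a fixed ``max_cycles`` gives a plain
    transient run).
    """
    system = assemble_oxygen_odes(net, flow, bc, h=dt)
    j = system.initial_state(initial_po2_mmhg)
    T = system.steps * system.h

    all_traj = []
    prev = None
    norm = np.nan
    converged = False
    for cycle in range(1, max_cycles + 1):
        traj = system.integrate_cycle(j, cycle_start_time=(cycle - 1) * T)
        j = traj[-1]
        if keep_all_cycles:
            all_traj.append(traj[:-1] if cycle < max_cycles else traj)
        if prev is not None:
            ref = np.linalg.norm(prev)
            norm = np.linalg.norm(traj - prev) / max(ref, 1e-300)
            if norm < cycle_tol:
                converged = True
                if keep_all_cycles and all_traj and all_traj[-1].shape[0] == system.steps:
                    all_traj[-1] = traj  # keep the closing sample of the last cycle
                break
        prev = traj
    cycles = cycle
    if require_convergence and not converged and max_cycles > 1:
        raise ConvergenceError(cycles, norm, cycle_tol)

    if keep_all_cycles:
        jtraj = np.concatenate(all_traj, axis=0)
        times = np.arange(jtraj.shape[0]) * system.h
    else:
        jtraj = traj
        times = np.arange(system.steps + 1) * system.h

    return _derive_solution(system, jtraj, times, cycles, norm)


def _derive_solution(system: OxygenSystem, jtraj, times, cycles, norm) -> OxygenSolution:
    """Recompute the derived per-sample fields from the J trajectory."""
    nt = jtraj.shape[0]
    steps = system.steps
    # flow half-grid index for each stored sample (periodic extension)
    k = np.arange(nt) % steps
    if nt > 1 and k[-1] == 0:
        k[-1] = steps  # cycle-closing sample uses the end-of-cycle flow row
    half_idx = 2 * k
    vc = system.vc_half[half_idx]
    q = system.q_half[half_idx]

    c = jtraj / (system.rho * q)
    m = system.area[None, :] * c
    po2 = c / system.bc.solubility

    c_in = np.array([system.bc.inlet_concentration(t) for t in times])
    c_up = c[:, system.parent]
    c_up[:, system.is_root] = c_in[:, None]
    j_up = system.rho * q * c_up
    inlet_flux = (system.rho * q[:, system.is_root] * c_in[:, None]).ravel()

    m_up = m[:, system.parent]
    m_up[:, system.is_root] = (c_in[:, None] * system.area[system.is_root][None, :])
    fd_up = system.gamma * (m - m_up) / system.dx_face[None, :]
    fd_dn = np.zeros_like(fd_up)
    nonroot = ~system.is_root
    np.add.at(fd_dn.T, system.parent[nonroot], fd_up.T[nonroot])
    fd_dn[:, system.leaf_mask] = 0.0

    qw = (system._qw_coeff[None, :] * (c - system.c_wall[None, :])
          + system._qw_const[None, :])

    T = max(times[-1] - times[0], system.h)
    inlet_scale = max(float(np.mean(np.abs(inlet_flux))), 1e-300)
    residual = ((j_up - jtraj) - qw * system.dx[None, :]) / inlet_scale

    return OxygenSolution(
        net=system.net,
        order=system.order,
        times=times,
        dt=system.h,
        jcon=jtraj,
        m=m,
        c=c,
        po2_mmhg=po2,
        jdiff_in=fd_up,
        jdiff_out=fd_dn,
        upstream_flux=j_up,
        inlet_flux=inlet_flux,
        wall_flux=qw,
        residual=residual,
        cycles_run=cycles,
        cycle_norm=float(norm) if norm == norm else np.nan,
        clamp_fraction=system.clamp_fraction,
        warnings=list(system.warnings),
        bc=system.bc,
        flow=system.flow,
    )


def mass_balance_residual(solution: OxygenSolution, net: VesselNetwork | None = None):
    """Per-segment convective mass-balance residual series.

    residual_i(t) = (J_up,i - J_i - q_w,i dx_i) / mean |inlet J_con|; at a
    steady converged state this is the constraint the scheme enforces and
    vanishes to solver tolerance.
    """
    return solution.residual


def impedance_diagnostics(solution: OxygenSolution, floor_fraction: float = 1e-9):
    """Convective and diffusive impedance series with masked denominators.

    Z_con = -(dJ_diff/dx)/J_con and Z_diff = -(dJ_con/dx)/J_diff; samples
    whose denominator magnitude falls below ``floor_fraction`` times its
    cycle maximum are masked rather than reported as huge/infinite.
    """
    dx = np.array([solution.net.segment(sid).geometry.length for sid in solution.order])
    div_diff = (solution.jdiff_out - solution.jdiff_in) / dx[None, :]
    div_con = (solution.jcon - solution.upstream_flux) / dx[None, :]
    jd_mid = 0.5 * (solution.jdiff_in + solution.jdiff_out)

    jcon_floor = floor_fraction * np.max(np.abs(solution.jcon), initial=1e-300)
    jd_floor = floor_fraction * np.max(np.abs(jd_mid), initial=1e-300)
    z_con = np.ma.masked_array(
        -div_diff / np.where(np.abs(solution.jcon) < jcon_floor, np.nan, solution.jcon),
        mask=np.abs(solution.jcon) < jcon_floor,
    )
    z_diff = np.ma.masked_array(
        -div_con / np.where(np.abs(jd_mid) < jd_floor, np.nan, jd_mid),
        mask=np.abs(jd_mid) < jd_floor,
    )
    return z_con, z_diff
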