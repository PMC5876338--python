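"""Dense 1D advection--diffusion--wall-sink reference solver.

The lumped oxygen model discretizes the cross-section-integrated transport
equation

    rho dM/dt + rho v dM/dx = 2 pi R (Gamma dC/dr)|_R + Gamma d^2M/dx^2

on a handful of segments.  This module solves the same equation densely
(hundreds of nodes) by the method of lines -- first-order upwind advection,
centred diffusion, classical RK4 in time -- using the *identical* wall-flux
closure object, so the two models share the same sink physics and the dense
solution is the correct convergence target for the lumped scheme.

The solver works in concentration C(x, t) on a uniform grid with a Dirichlet
inlet and a zero-gradient outlet, and tracks cumulative inlet/outlet/sink
fluxes with the same RK4 stages so that discrete mass conservation holds to
rounding error by construction (and is checkable per run).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CflError, ConfigError
from .network import FluidProperties, SegmentGeometry, VesselNetwork
from .oxygen import OxygenBoundary, solve_oxygen
from .hemodynamics import solve_periodic_flow
from .waveforms import FlowWaveform


@dataclass
class PdeGrid:
    """Uniform centerline grid metadata for the 1D reference solver."""

    x: np.ndarray
    dx: float
    dt: float
    cfl: float


@dataclass
class PdeSolution:
    """Dense 1D solution C(x, t) with derived flux fields.

    ``c`` is (n_stored_times, n_nodes); conservation trackers hold the
    cumulative inlet/outlet/sink mass transported up to each stored time.
    """

    grid: PdeGrid
    times: np.ndarray
    c: np.ndarray
    radius: float
    fluid: FluidProperties
    velocity: np.ndarray  # v(t) at stored times
    cumulative_in: np.ndarray
    cumulative_out: np.ndarray
    cumulative_sink: np.ndarray

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    def content(self):
        """Total oxygen mass rho A integral C dx (interior nodes) per stored time."""
        return self.fluid.density * self.area * self.grid.dx * self.c[:, 1:].sum(axis=1)

    def outlet_convective_flux(self):
        """J_con at the outlet node: rho v A C(L, t)."""
        return self.fluid.density * self.velocity * self.area * self.c[:, -1]

    def jcon_field(self):
        return self.fluid.density * self.velocity[:, None] * self.area * self.c

    def jdiff_field(self):
        m = self.area * self.c
        return self.fluid.gamma * np.gradient(m, self.grid.dx, axis=1)

    def conservation_residual(self):
        """(mass change) - (in - out - sink), relative to transported mass.

        Zero to rounding by construction; a nonzero value flags an
        implementation defect, not a modelling error.
        """
        mass = self.content()
        transported = self.cumulative_in - self.cumulative_out - self.cumulative_sink
        scale = max(np.max(np.abs(self.cumulative_in)), np.max(np.abs(mass)), 1e-300)
        return ((mass - mass[0]) - transported) / scale

    def segment_mean_concentration(self, n_segments: int):
        """Average C over n equal segment spans (for lumped comparison)."""
        nx = self.c.shape[1]
        edges = np.linspace(0, nx, n_segments + 1).astype(int)
        return np.stack(
            [self.c[:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])], axis=1
        )


def solve_advection_diffusion_1d(
    length: float,
    radius: float,
    velocity,
    c_inlet,
    closure,
    c_wall: float,
    fluid: FluidProperties | None = None,
    n_nodes: int = 500,
    dt: float | None = None,
    t_end: float = 1.0,
    c_init=None,
    store_every: int = 1,
) -> PdeSolution:
    """Method-of-lines solve of the 1D cross-section-integrated equation.

    ``velocity`` and ``c_inlet`` may be numbers or callables of time; the
    wall sink uses the same closure object as the lumped model.  Raises
    :class:`CflError` with a suggested dt when v_max dt/dx > 0.9.
    """
    fluid = fluid or FluidProperties()
    if n_nodes < 50:
        raise ConfigError("reference solver needs >= 50 nodes")
    geom = SegmentGeometry(length=length, radius=radius, wall_thickness=1e-3)
    area = geom.area
    x = np.linspace(0.0, length, n_nodes)
    dx = x[1] - x[0]

    v_fn = velocity if callable(velocity) else (lambda t, _v=float(velocity): _v)
    cin_fn = c_inlet if callable(c_inlet) else (lambda t, _c=float(c_inlet): _c)

    v_probe = np.abs([v_fn(t) for t in np.linspace(0.0, t_end, 101)])
    v_max = float(np.max(v_probe))
    d = fluid.o2_diffusivity
    if dt is None:
        dt_adv = 0.45 * dx / max(v_max, 1e-12)
        dt_dif = 0.2 * dx**2 / max(d, 1e-30)
        dt = min(dt_adv, dt_dif, t_end)
    cfl = v_max * dt / dx
    if cfl > 0.9:
        raise CflError(cfl, 0.9 * dx / max(v_max, 1e-12))
    if d * dt / dx**2 > 0.35:
        raise CflError(d * dt / dx**2, 0.35 * dx**2 / d)

    n_steps = max(1, int(round(t_end / dt)))
    dt = t_end / n_steps

    q10 = float(closure.per_length_flux(1.0, 0.0, geom, fluid))
    q00 = float(closure.per_length_flux(0.0, 0.0, geom, fluid))
    qw_coeff, qw_const = q10 - q00, q00
    rho_a = fluid.density * area

    if c_init is None:
        c = np.full(n_nodes, cin_fn(0.0), dtype=float)
    else:
        c = np.array(c_init, dtype=float)
        if c.size != n_nodes:
            raise ConfigError("c_init length must match n_nodes")

    def rhs(t, state):
        cc, _in, _out, _sink = state
        v = v_fn(t)
        cc = cc.copy()
        cc[0] = cin_fn(t)
        dcdt = np.zeros_like(cc)
        adv = np.empty_like(cc)
        if v >= 0:
            adv[1:] = -v * (cc[1:] - cc[:-1]) / dx
        else:
            adv[1:-1] = -v * (cc[2:] - cc[1:-1]) / dx
            adv[-1] = 0.0
        dif = np.zeros_like(cc)
        dif[1:-1] = d * (cc[2:] - 2.0 * cc[1:-1] + cc[:-2]) / dx**2
        dif[-1] = d * (cc[-2] - cc[-1]) / dx**2  # ghost: zero gradient
        qw = qw_coeff * (cc - c_wall) + qw_const  # per length, kg/(m s)
        dcdt[1:] = adv[1:] + dif[1:] - qw[1:] / rho_a
        # conservation trackers (mass per time, consistent with the telescoped
        # spatial operator over interior nodes)
        flux_in = rho_a * (v * cc[0] - d * (cc[1] - cc[0]) / dx)
        flux_out = rho_a * v * cc[-1]
        sink = float(qw[1:].sum() * dx)
        return dcdt, flux_in, flux_out, sink

    store_idx = list(range(0, n_steps + 1, store_every))
    if store_idx[-1] != n_steps:
        store_idx.append(n_steps)
    stored_c = np.empty((len(store_idx), n_nodes))
    stored_t = np.empty(len(store_idx))
    stored_v = np.empty(len(store_idx))
    cum = np.zeros((len(store_idx), 3))

    c[0] = cin_fn(0.0)
    acc = np.zeros(3)
    si = 0

    def maybe_store(k, t):
        nonlocal si
        if si < len(store_idx) and k == store_idx[si]:
            stored_c[si] = c
            stored_t[si] = t
            stored_v[si] = v_fn(t)
            cum[si] = acc
            si += 1

    maybe_store(0, 0.0)
    for k in range(n_steps):
        t = k * dt
        s1 = rhs(t, (c, *acc))
        s2 = rhs(t + 0.5 * dt, (c + 0.5 * dt * s1[0], *acc))
        s3 = rhs(t + 0.5 * dt, (c + 0.5 * dt * s2[0], *acc))
        s4 = rhs(t + dt, (c + dt * s3[0], *acc))
        c = c + (dt / 6.0) * (s1[0] + 2.0 * s2[0] + 2.0 * s3[0] + s4[0])
        for j in range(3):
            acc[j] += (dt / 6.0) * (s1[j + 1] + 2.0 * s2[j + 1] + 2.0 * s3[j + 1] + s4[j + 1])
        c[0] = cin_fn((k + 1) * dt)
        maybe_store(k + 1, (k + 1) * dt)

    grid = PdeGrid(x=x, dx=dx, dt=dt, cfl=cfl)
    return PdeSolution(
        grid=grid,
        times=stored_t,
        c=stored_c,
        radius=radius,
        fluid=fluid,
        velocity=stored_v,
        cumulative_in=cum[:, 0],
        cumulative_out=cum[:, 1],
        cumulative_sink=cum[:, 2],
    )


# -- lumped vs PDE comparison ---------------------------------------------


@dataclass
class ComparisonReport:
    """Quantified lumped-vs-dense comparison on a single tube."""

    n_pde_nodes: int
    segment_counts: list
    outlet_flux_error_mean: dict  # n_segments -> relative period-mean error
    outlet_flux_error_peak: dict
    outlet_flux_error_max_instant: dict
    concentration_error_rms: dict  # n_segments -> RMS relative C error
    monotone_convergence: bool
    details: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        payload = {
            "n_pde_nodes": self.n_pde_nodes,
            "segment_counts": list(self.segment_counts),
            "outlet_flux_error_mean": {str(k): v for k, v in self.outlet_flux_error_mean.items()},
            "outlet_flux_error_peak": {str(k): v for k, v in self.outlet_flux_error_peak.items()},
            "outlet_flux_error_max_instant": {
                str(k): v for k, v in self.outlet_flux_error_max_instant.items()
            },
            "concentration_error_rms": {
                str(k): v for k, v in self.concentration_error_rms.items()
            },
            "monotone_convergence": self.monotone_convergence,
            "details": self.details,
        }
        return json.dumps(payload, indent=2, **kwargs)


def compare_lumped_vs_pde(
    net: VesselNetwork,
    waveform: FlowWaveform,
    bc: OxygenBoundary,
    segment_counts=(5, 10, 20, 40),
    n_pde_nodes: int = 500,
    flow_dt: float = 1e-4,
    flow_cycle_tol: float = 1e-8,
    oxygen_cycle_tol: float = 1e-8,
    n_transit_periods: float = 4.0,
) -> ComparisonReport:
    """Run the lumped model at several segment counts against the dense solver.

    Restricted to unbranched single tubes (the oracle is 1D along one
    centerline).  The dense solver is driven by the length-weighted mean
    lumped velocity and the identical closure and boundary data.
    """
    from .network import rediscretize_chain

    order = net.topological_order()
    if any(len(net.children(sid)) > 1 for sid in order):
        raise ConfigError("the reference comparison supports single unbranched tubes only")

    length = net.total_length
    radius = net.segment(order[0]).geometry.radius
    c_in = bc.inlet_concentration(0.0)
    if callable(bc.inlet_po2_mmhg):
        raise ConfigError("comparison requires a constant inlet oxygen tension")
    c_wall = bc.wall_concentration(order[0])

    flux_mean_err: dict = {}
    flux_peak_err: dict = {}
    flux_inst_err: dict = {}
    conc_err: dict = {}
    details: dict = {}

    lumped = {}
    ref_flow = None
    for n_seg in segment_counts:
        chain = rediscretize_chain(net, n_seg)
        flow = solve_periodic_flow(chain, waveform, dt=flow_dt,
                                   cycle_tol=flow_cycle_tol, max_cycles=200)
        sol = solve_oxygen(chain, flow, bc, cycle_tol=oxygen_cycle_tol, max_cycles=500)
        lumped[n_seg] = sol
        if ref_flow is None:
            ref_flow = flow

    # dense reference driven by the length-weighted mean lumped velocity
    dx_w = np.array([ref_flow.net.segment(s).geometry.length for s in ref_flow.order])
    v_mean_t = (ref_flow.velocity * dx_w[None, :]).sum(axis=1) / dx_w.sum()
    period = ref_flow.period
    times_f = ref_flow.times

    def v_fn(t):
        return float(np.interp(np.mod(t, period), times_f, v_mean_t))

    t_transit = length / max(float(np.mean(v_mean_t)), 1e-12)
    t_end = n_transit_periods * max(t_transit, period)
    t_end = math.ceil(t_end / period) * period  # whole periods
    pde = solve_advection_diffusion_1d(
        length, radius, v_fn, c_in, bc.closure, c_wall,
        fluid=net.fluid, n_nodes=n_pde_nodes, t_end=t_end,
        store_every=5,
    )
    # final-period window of the dense run
    last = pde.times >= (t_end - period - 1e-12)
    t_pde = pde.times[last]
    jout_pde = pde.outlet_convective_flux()[last]
    jmean_pde = float(np.trapezoid(jout_pde, t_pde) / (t_pde[-1] - t_pde[0]))
    jpeak_pde = float(np.max(np.abs(jout_pde)))

    for n_seg, sol in lumped.items():
        jout = list(sol.outlet_flux().values())[0]
        jmean = float(np.trapezoid(jout, sol.times) / (sol.times[-1] - sol.times[0]))
        jpeak = float(np.max(np.abs(jout)))
        # instantaneous comparison on the common final-period phase grid
        jout_interp = np.interp(np.mod(t_pde, period), sol.times, jout)
        scale = max(abs(jmean_pde), 1e-300)
        flux_mean_err[n_seg] = abs(jmean - jmean_pde) / scale
        flux_peak_err[n_seg] = abs(jpeak - jpeak_pde) / max(jpeak_pde, 1e-300)
        flux_inst_err[n_seg] = float(np.max(np.abs(jout_interp - jout_pde)) / scale)

        c_seg_pde = pde.segment_mean_concentration(n_seg)[last]
        c_lumped_mean = np.array(
            [np.trapezoid(sol.c[:, j], sol.times) / (sol.times[-1] - sol.times[0])
             for j in range(n_seg)]
        )
        c_pde_mean = c_seg_pde.mean(axis=0)
        conc_err[n_seg] = float(
            np.sqrt(np.mean((c_lumped_mean - c_pde_mean) ** 2)) / max(c_in, 1e-300)
        )
        details[str(n_seg)] = {
            "outlet_flux_mean_lumped": jmean,
            "outlet_flux_mean_pde": jmean_pde,
        }

    counts = sorted(segment_counts)
    errs = [flux_mean_err[n] for n in counts]
    monotone = all(errs[i + 1] < errs[i] for i in range(len(errs) - 1))
    return ComparisonReport(
        n_pde_nodes=n_pde_nodes,
        segment_counts=list(segment_counts),
        outlet_flux_error_mean=flux_mean_err,
        outlet_flux_error_peak=flux_peak_err,
        outlet_flux_error_max_instant=flux_inst_err,
        concentration_error_rms=conc_err,
        monotone_convergence=monotone,
        details=details,
    )
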