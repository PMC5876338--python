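# Methods

## Scope and model

`oxiline` simulates dissolved-oxygen transport in arterial segment networks
with a lumped-parameter (zero-dimensional) model built on the electrical
transmission-line analogy, coupled one-way to a lumped pulsatile blood-flow
model. The intended use is desk-scale prediction of oxygen concentration
distributions in vessel trees where a 3D CFD/FSI computation would be
disproportionate, and verification of the lumped oxygen scheme against a
dense 1D solver of the same cross-section-integrated equation.

### Hemodynamics

Each vessel segment of length Δx, lumen radius R, wall thickness h and
elastic modulus E is an inverted-L circuit cell — a series
resistance–inertance branch carrying the flow Q, then a shunt compliance to
ground holding the downstream pressure P:

    R' = 8 μ Δx / (π R⁴)        Poiseuille resistivity
    L' = ρ Δx / (π R²)          plug-flow inertance
    C' = 3 π R³ Δx / (2 E h)    thin-wall compliance

These are the classical closures consistent with the model's uniform-velocity
assumption. The governing relations are the fluid transmission-line pair
(−∂P/∂x = R'Q + L'∂Q/∂t per branch; C'∂P/∂t = ΣQ_in − ΣQ_out per node).
The inlet flow is a prescribed periodic waveform; each leaf closes on an
algebraic terminal resistance draining to zero reference pressure (a venous
offset is configurable). Leaf pressures are eliminated algebraically,
P_leaf = R_term·Q_leaf, substituted into the leaf branch equation. Besides
being exact, this elimination removes the fast 1/(R_term·C') relaxation mode
that would otherwise dominate the stiffness of networks with small terminal
resistances, and it is what makes the default time step feasible on all
three built-in vessels. The root inlet flow is taken from the waveform
directly rather than integrated as a state, so it carries no drift.

The resulting system is linear, `dx/dt = A x + g·Q_in(t)`, integrated with
the classical fixed-step fourth-order Runge–Kutta scheme (fixed step rather
than adaptive: the fixed-step RK4 behaviour is itself part of what the
package verifies). `check_stability` evaluates the RK4 amplification factor
at the eigenvalues of `A` and estimates the largest stable step by
bisection; the default dt = 1e-4 s is stable for all built-in vessels
(estimated bounds ≈ 8e-4, 1.2e-4, 4e-4 s for the straight/curved/bifurcated
fixtures). Periodic steady state is declared when the relative L2
cycle-to-cycle difference of the full state trajectory falls below
`cycle_tol` (default 1e-4, max 50 cycles; the verification suite uses
1e-8–1e-12 where tighter statements are made). dv/dt is recomputed from the
ODE right-hand side at the stored samples, never finite-differenced, because
it enters the oxygen coefficient R₀ = (1/v²)∂v/∂t where differencing noise
would be amplified at low velocity.

A naming caveat: the formulation this package follows labels the series
(pressure-gradient) impedance "transverse" and the shunt impedance
"longitudinal", which is the reverse of common transmission-line usage. The
equations implemented are the ones as written; only the label differs.

### Oxygen transport

The transported variables are the cross-section oxygen content
M = ∫2πrC dr (= πR²C for a flat profile), the convective flux J_con = ρvM
and the axial diffusive flux J_diff = Γ∂M/∂x, with Γ = ρD. The diffusion
coefficient is exposed as D (m²/s) and the Γ = ρD conversion is internal;
C is then a mass-fraction-like concentration and every reported tension is
invariant to the solubility scale. Oxygen tensions (mmHg) convert to
concentration through a Henry solubility α (default 3e-5 per mmHg; any
positive value gives identical PO₂ fields because the model is linear).

The oxygen transmission-line pair is

    −∂J_diff/∂x = R₀ J_con + L₀ ∂J_con/∂t
    −∂J_con/∂x  = −q_w,            q_w = −2πR(Γ ∂C/∂r)|_{r=R}

with the convective coefficients R₀ = (1/v²)∂v/∂t = ∂/∂t(−1/v) (fraction of
remaining oxygen convection per unit distance, 1/m) and L₀ = −1/v (s/m).
L₀ is negative by construction while its magnitude is the transit time per
unit distance; the implementation keeps the sign as derived and reports
|L₀| as the transit time. These two lines combine into the explicit update
integrated per segment,

    dJ_i/dt = v_i [ R₀,i J_i − (J_i − J_up,i)/Δx_i + ∂J_diff/∂x|_i − q_w,i ],

which is the cross-section-integrated transport equation written in flux
variables; both transmission-line lines are recovered afterwards as
diagnostics (`mass_balance_residual`, `impedance_diagnostics`). Spatial
differencing is upwind (flow-directed) for the convective divergence —
stability for advection-dominated transport — and centred two-point at
segment interfaces for J_diff. The outlet boundary is zero axial content
gradient; the inlet is a prescribed tension (number or callable of time for
step studies).

Junction rule (the lumped formulation needs one and none is standard):
concentration continuity across the junction with the convective flux split
in proportion to the instantaneous child flows, J_up,child = ρQ_child·C_parent,
and interface diffusive flux conserved (the parent's downstream diffusive
flux is the sum of the children's upstream-face fluxes). The split then sums
exactly to the parent's outflow whenever the junction node stores no volume;
the small compliance storage of a pulsatile junction appears in the
instantaneous balance but averages to zero over a cycle, which is what the
conservation checks measure.

Velocity-zero regularization: L₀ and R₀ diverge at flow reversal, so |v| is
clamped at a floor (default 1e-6 m/s), sign-preserving, never silently — a
warning is logged, the clamped fraction is reported on the solution, and a
per-segment warning is attached when more than 10% of a cycle is clamped.
The built-in inlet waveforms are strictly forward, so clamping does not
occur in the shipped configurations; a sensitivity check (floor 1e-6 vs
1e-4) is part of the test suite.

### Wall-flux closures

The radial gradient at the wall cannot be resolved by a lumped model, and
estimating the flux into the wall is acknowledged to be the hard part of
this model class. Three closures are selectable:

* `sherwood` (default): (∂C/∂r)|_R ≈ −Sh·(C − C_wall)/(2R) with Sh = 3.66
  (fully developed laminar mass transfer), giving q_w = πΓSh(C − C_wall);
* `fixed-coefficient`: q_w = 2πR ρ h_m (C − C_wall) with a user mass-transfer
  coefficient h_m (m/s);
* `prescribed-flux`: a constant per-length extraction (oxygen-consumption
  mode), independent of concentrations.

The lumped solver and the 1D reference solver consume the *same closure
object*, so solver comparisons isolate discretization error from closure
uncertainty.

### Oxygen time stepping

The oxygen system is linear time-varying (coefficients from the flow
solution). It is advanced with the same fixed-step RK4; by default the
oxygen step is 2× the flow step so the RK4 stage times land exactly on flow
samples (odd multiples fall back to linear interpolation of the flow
fields). Periodic convergence uses the same cycle-to-cycle criterion as the
flow solver. For transient studies (e.g. a step in inlet tension) the solver
can run a fixed number of cycles without the convergence requirement and
return the concatenated multi-cycle trajectory.

## Reference solver

`solve_advection_diffusion_1d` solves the same cross-section-integrated
equation densely: first-order upwind advection, centred diffusion, RK4 in
time, Dirichlet inlet, zero-gradient outlet, ≥ 50 nodes (500 in the shipped
comparisons), CFL ≤ 0.9 enforced with a suggested dt on violation.
Cumulative inlet/outlet/sink fluxes are integrated with the same RK4 stages
as the state, so discrete mass conservation holds to rounding error by
construction and is asserted per run. The dense solver is deliberately 1D:
it discretizes exactly the equation the lumped model lumps, so it is the
correct convergence target for the lumped scheme. Agreement with a 3D
fluid–structure computation is *not* claimed or tested by this package.

In `compare_lumped_vs_pde` the dense solver is driven by the length-weighted
mean lumped velocity (the comparisons shipped are steady, where this is
exact); the lumped model is re-run at 5/10/20/40 segments of the same tube
and the outlet convective-flux and per-segment concentration errors are
tabulated.

## Built-in vessels and study conditions

Three verification vessels are shipped, with printed material parameters:

| | straight | curved | bifurcated (CC / IC / EC) |
|---|---|---|---|
| segments × length | 10 × 20 mm | 9 × 3.84 mm | 10 × 6.45 / 10 × 6.23 / 10 × 6.2 mm |
| wall thickness | 2 mm | 0.18 mm | 0.7 mm |
| elastic modulus | 5.11 MPa | 0.7 MPa | 0.5 MPa |
| terminal resistance (mmHg·s/cm³) | 0.0865 | 55.6 | 21.7 (IC), 35.3 (EC) |
| inlet / wall PO₂ (mmHg) | 85 / 60 | 85 / 48 | 85.3 / 55.5 |

Blood: ρ = 1050 kg/m³, μ = 3.5e-3 kg/(m·s), D = 1.2e-9 m²/s; wall density
1060 kg/m³, Poisson ratio 0.49 (retained for completeness; only E and h
enter the compliance). Lumen calibers are not part of the printed parameter
set; the fixtures use representative arterial values (diameters 10 mm
straight/abdominal, 4 mm curved/coronary, 6.3/4.5/3.6 mm CC/IC/EC), all
overridable in configuration. Curvature radius and bifurcation angle are
stored as metadata only — the model is one-dimensional along the centerline
and carries no secondary-flow correction.

### Inlet waveforms

Measured inlet traces are not available as numbers, so `waveforms` ships
surrogate presets chosen once: half-sine systole on a diastolic baseline,
abdominal-like (T = 1.0 s, mean 3.0e-5 m³/s), coronary-like (T = 0.8 s,
mean 1.5e-6 m³/s), carotid-like (T = 0.9 s, mean 6.0e-6 m³/s), each with
amplitude keeping the flow strictly forward. Every quantitative statement in
the test suite uses either constant flow or a fully specified pulse — never
the presets' physiological realism. Synthetic pulses are evaluated by
trigonometric interpolation of their uniform samples (smooth forcing), which
is what allows the RK4 order measurement to reach fourth order; tabulated
user waveforms use periodic linear interpolation as documented.

### What the surrogates do and do not show

The synthetic conditions exercise the full advertised mechanics — pulsatile
wave propagation in a compliant tree, junction splitting, wall extraction,
flow-driven R₀/L₀ coefficients — but they are not patient data: flow-reversal
episodes (where the v-floor would matter), non-Newtonian effects,
hemoglobin carriage, and measured geometry are all outside what a passing
suite demonstrates. Hemoglobin in particular is excluded by the model's own
scope; dissolved-oxygen results are expected to relate approximately
linearly to oxyhemoglobin-carrying computations, and a post-hoc rescaling
hook is deliberately *not* enabled by default.

## Verification quantities (what `scripts/acceptance.py` recomputes)

* **Coefficient identities** — L₀·v = −1 at every sample (to rounding);
  R₀ vs the central difference of −1/v on a pulsatile solution (O(dt²)).
* **Steady closed form** — constant inflow: inlet pressure = Q(ΣR' + R_term)
  to 1e-8 relative; dv/dt ≡ 0 hence R₀ ≡ 0.
* **Oxygen conservation** — periodic steady state on each fixture: the
  period-averaged inlet convective flux balances outlets + wall extraction
  to < 1e-4 relative; mean per-segment residual < 1e-4.
* **Oracle equivalence** — steady flow with a strengthened fixed-coefficient
  sink (decay exponent kL/v ≈ 0.8, set a priori so discretization error is
  visible above the ~1e-4 physical extraction of these short tubes):
  10-segment outlet flux within 5% of the 500-node dense solution, error
  strictly decreasing over 5→10→20→40 segments.
* **Closed-form limit** — steady advection with linear sink tracks
  C(x) = C_wall + (C_in − C_wall)e^(−kx/v); halving the segment length about
  halves the error (first-order spatial scheme).
* **Transit time** — with the sink off and D→0, the first temporal moment of
  the outlet step response equals Σ|L₀,i|Δx_i = L/v to well within one time
  step. The moment (area) reading is used deliberately: the mid-rise crossing
  of a cascade of N first-order upwind cells is biased early by ≈ Δx/(3v),
  one-third of a segment transit, so a half-height reading cannot meet a
  one-time-step tolerance at any N; the first moment is exact for this
  scheme class.
* **No-sink identity** — wall tension = inlet tension: outlet PO₂ = inlet
  PO₂ to 1e-6 relative on all fixtures.
* **RK4 order** — the converged periodic flow solution changes as O(dt⁴)
  under step halving (measured log–log slope ≥ 3.5 across 2e-4 → 2.5e-5 s).

Problem sizes were selected so the full recomputation completes in a few
minutes on one core: dt = 1e-4 s flow steps, 500-node dense reference,
segment counts 5–40.

## Numerical choices and degenerate inputs

* Tolerances: flow cycle_tol default 1e-4 (tighter in verification), oxygen
  1e-6; convergence failures raise with the last norm attached.
* Non-finite states abort integration naming the time (and segment, for
  oxygen) of first failure.
* Zero inflow is exactly representable (all-zero solution); retrograde flow
  is representable (signed velocities); velocities inside the floor band are
  clamped with warnings as described.
* Impedance diagnostics mask samples whose denominator (J_con or the
  interface mean of J_diff) is below 1e-9 of its cycle maximum rather than
  reporting unbounded ratios.
* Single-segment networks degenerate to a fully algebraic flow solution and
  are handled without states.
* Unit conversions use 1 mmHg = 133.322 Pa exactly once at the boundary;
  terminal resistances round-trip mmHg·s/cm³ ↔ SI to 1e-12 relative.

## Known limitations

* One-way coupling only: oxygen does not feed back on flow (true of the
  model class, not just the code).
* First-order spatial accuracy of the upwind convective coupling — the price
  of robustness at segment scale; the convergence study quantifies it.
* No radial concentration structure beyond the closure; no oxyhemoglobin
  dissociation kinetics; no tissue-side consumption model beyond the wall
  sink; no venous or cardiac chamber models; terminal resistances drain to a
  configurable constant reference pressure.
* The dense reference is rigid-tube and 1D; it validates the lumped
  discretization, not the compliant-wall 3D physics.
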