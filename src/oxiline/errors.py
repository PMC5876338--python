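"""Exception types shared across the package."""


class OxilineError(Exception):
    """Base class for all package-specific errors."""


class InvalidNetworkError(OxilineError):
    """A vessel network violates its structural invariants.

    Carries the list of human-readable violations in ``violations``.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid vessel network: " + "; ".join(self.violations))


class IntegrationDivergedError(OxilineError):
    """NaN/Inf appeared in the state during time integration."""

    def __init__(self, time, detail=""):
        self.time = time
        msg = f"integration diverged at t = {time:.6g} s"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ConvergenceError(OxilineError):
    """Periodic steady state was not reached within the cycle budget."""

    def __init__(self, cycles, last_norm, tol):
        self.cycles = cycles
        self.last_norm = last_norm
        self.tol = tol
        super().__init__(
            f"no periodic convergence after {cycles} cycles: "
            f"cycle-to-cycle norm {last_norm:.3e} > tol {tol:.3e}"
        )


class StabilityError(OxilineError):
    """Requested time step exceeds the RK4 stability bound."""

    def __init__(self, dt, dt_max, detail=""):
        self.dt = dt
        self.dt_max = dt_max
        msg = f"dt = {dt:.3g} s exceeds the RK4 stability estimate {dt_max:.3g} s"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ConfigError(OxilineError):
    """Invalid run/network/closure configuration."""


class CflError(OxilineError):
    """The 1D reference solver's CFL limit is violated."""

    def __init__(self, cfl, dt_suggested):
        self.cfl = cfl
        self.dt_suggested = dt_suggested
        super().__init__(
            f"CFL number {cfl:.3f} > 0.9; reduce dt to <= {dt_suggested:.3g} s"
        )
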