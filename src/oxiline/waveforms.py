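"""Pulsatile inlet flow waveforms.

Measured inlet traces for the three verification vessels are not available as
numbers, so this module generates physiologically plausible surrogates: a
half-sine systolic pulse over a configurable fraction of the cycle riding on a
diastolic baseline, or a small harmonic series.  Users with digitized in-vivo
traces load them through :func:`waveform_from_table`.

Two periodic evaluation modes are supported:

``linear``
    piecewise-linear periodic interpolation of the samples (tables);
``fourier``
    trigonometric interpolation of uniformly spaced samples.  This is smooth
    (C-infinity), which matters when measuring the order of accuracy of the
    fixed-step RK4 integrator: a forcing with derivative kinks would cap the
    observable convergence order at two regardless of the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class PulseSpec:
    """Parameters of a synthetic periodic inlet pulse.

    Parameters
    ----------
    period : float
        Cardiac period T (s).
    mean_flow : float
        Cycle-averaged volumetric flow (m^3/s); the generated waveform's
        numerical mean matches this to 1e-10 relative.
    amplitude : float
        Peak systolic excursion above the diastolic baseline (m^3/s).
    systolic_fraction : float
        Fraction of the cycle occupied by the systolic pulse, in (0, 1).
    shape : str
        'half-sine' (default) or 'harmonic'.
    harmonics : tuple
        For 'harmonic': (relative amplitude, phase rad) per harmonic k=1,2,...
    """

    period: float
    mean_flow: float
    amplitude: float
    systolic_fraction: float = 0.35
    shape: str = "half-sine"
    harmonics: tuple = ((1.0, 0.0), (0.4, 1.2), (0.15, 2.1))

    def __post_init__(self):
        if not self.period > 0:
            raise ConfigError(f"period must be positive, got {self.period}")
        if self.mean_flow < 0:
            raise ConfigError(f"mean flow must be >= 0, got {self.mean_flow}")
        if not (0.0 < self.systolic_fraction < 1.0):
            raise ConfigError(
                f"systolic fraction must lie in (0, 1), got {self.systolic_fraction}"
            )
        if self.shape not in ("half-sine", "harmonic"):
            raise ConfigError(f"unknown pulse shape {self.shape!r}")


@dataclass
class FlowWaveform:
    """Periodic inlet flow waveform Q(t).

    ``times`` are strictly increasing sample instants in [0, T); ``values``
    the flows at those instants (m^3/s).  Evaluation wraps periodically.
    """

    period: float
    times: np.ndarray
    values: np.ndarray
    interpolation: str = "linear"
    _fourier: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not self.period > 0:
            raise ConfigError("waveform period must be positive")
        if self.times.size < 4:
            raise ConfigError("waveform needs at least 4 samples")
        if self.times.size != self.values.size:
            raise ConfigError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigError("waveform sample times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] >= self.period:
            raise ConfigError("waveform sample times must lie in [0, period)")
        if self.interpolation not in ("linear", "fourier"):
            raise ConfigError(f"unknown interpolation {self.interpolation!r}")
        if self.interpolation == "fourier":
            dt = np.diff(self.times)
            if not np.allclose(dt, self.period / self.times.size, rtol=1e-9, atol=0.0):
                raise ConfigError("fourier interpolation requires uniform sampling")
            self._fourier = self._fourier_coefficients()

    def _fourier_coefficients(self):
        n = self.values.size
        coeffs = np.fft.rfft(self.values) / n
        k = np.arange(coeffs.size)
        # drop the unmatched Nyquist sine ambiguity for even n: treat the
        # Nyquist term as a pure cosine (standard trigonometric interpolant)
        omega = 2.0 * np.pi * k / self.period
        return coeffs, omega, n

    def _eval_fourier(self, t, derivative=False):
        coeffs, omega, n = self._fourier
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        phase = np.exp(1j * np.outer(np.atleast_1d(t) - self.times[0], omega))
        c = coeffs.copy()
        scale = np.full(c.size, 2.0)
        scale[0] = 1.0
        if n % 2 == 0:
            scale[-1] = 1.0
        if derivative:
            c = c * 1j * omega
        out = (phase * (scale * c)).sum(axis=1).real
        return float(out[0]) if scalar else out

    def evaluate(self, t):
        """Flow at (array of) times t, periodic extension (m^3/s)."""
        t = np.asarray(t, dtype=float)
        if self.interpolation == "fourier":
            return self._eval_fourier(t)
        tau = np.mod(t - self.times[0], self.period) + self.times[0]
        tp = np.concatenate([self.times, [self.times[0] + self.period]])
        vp = np.concatenate([self.values, [self.values[0]]])
        return np.interp(tau, tp, vp)

    __call__ = evaluate

    def derivative(self, t):
        """dQ/dt at times t (piecewise constant for linear interpolation)."""
        t = np.asarray(t, dtype=float)
        if self.interpolation == "fourier":
            return self._eval_fourier(t, derivative=True)
        tau = np.mod(t - self.times[0], self.period) + self.times[0]
        tp = np.concatenate([self.times, [self.times[0] + self.period]])
        vp = np.concatenate([self.values, [self.values[0]]])
        idx = np.clip(np.searchsorted(tp, tau, side="right") - 1, 0, tp.size - 2)
        return (vp[idx + 1] - vp[idx]) / (tp[idx + 1] - tp[idx])

    @property
    def mean(self) -> float:
        """Period-average of the interpolated waveform (exact for each mode)."""
        if self.interpolation == "fourier":
            return float(np.mean(self.values))
        tp = np.concatenate([self.times, [self.times[0] + self.period]])
        vp = np.concatenate([self.values, [self.values[0]]])
        return float(np.trapezoid(vp, tp) / self.period)

    def to_table(self):
        """(times, values) arrays suitable for CSV export; round-trips exactly."""
        return self.times.copy(), self.values.copy()


def waveform_from_table(times, flows, period: float) -> FlowWaveform:
    """Build a periodic linearly interpolated waveform from tabulated samples."""
    return FlowWaveform(period=period, times=np.asarray(times, float),
                        values=np.asarray(flows, float), interpolation="linear")


def constant_waveform(flow: float, period: float = 1.0, n_samples: int = 8) -> FlowWaveform:
    """Constant inflow expressed as a (trivially periodic) waveform."""
    t = np.arange(n_samples) * (period / n_samples)
    return FlowWaveform(period=period, times=t, values=np.full(n_samples, float(flow)),
                        interpolation="fourier")


def synthetic_pulse(spec: PulseSpec, n_samples: int = 64) -> FlowWaveform:
    """Generate a periodic pulse waveform from a :class:`PulseSpec`.

    The samples are uniformly spaced and evaluated by trigonometric
    interpolation.  After shaping, the baseline is shifted so the waveform's
    period-average equals ``spec.mean_flow`` exactly (amplitude preserved).
    """
    if n_samples < 16:
        raise ConfigError("synthetic_pulse requires n_samples >= 16")
    t = np.arange(n_samples) * (spec.period / n_samples)
    if spec.shape == "half-sine":
        t_sys = spec.systolic_fraction * spec.period
        q = np.where(t < t_sys, spec.amplitude * np.sin(np.pi * t / max(t_sys, 1e-300)), 0.0)
    else:  # harmonic
        q = np.zeros_like(t)
        for k, (amp, phase) in enumerate(spec.harmonics, start=1):
            q += spec.amplitude * amp * np.sin(2.0 * np.pi * k * t / spec.period + phase)
    q = q + (spec.mean_flow - q.mean())  # exact mean under fourier evaluation
    return FlowWaveform(period=spec.period, times=t, values=q, interpolation="fourier")


#: Named fixture presets.  These are plausible surrogates for the in-vivo
#: inlet traces of an abdominal, coronary and carotid artery; no numerical
#: fidelity to any particular measurement is claimed.
PRESETS = {
    "abdominal": PulseSpec(period=1.0, mean_flow=3.0e-5, amplitude=6.0e-5,
                           systolic_fraction=0.35),
    "coronary": PulseSpec(period=0.8, mean_flow=1.5e-6, amplitude=1.5e-6,
                          systolic_fraction=0.4),
    "carotid": PulseSpec(period=0.9, mean_flow=6.0e-6, amplitude=1.2e-5,
                         systolic_fraction=0.35),
}

#: Preset conventionally paired with each built-in network fixture.
FIXTURE_PRESET = {"straight": "abdominal", "curved": "coronary", "bifurcated": "carotid"}


def waveform_preset(name: str, n_samples: int = 64) -> FlowWaveform:
    """Return a named preset waveform ('abdominal', 'coronary', 'carotid')."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown waveform preset {name!r}; have {sorted(PRESETS)}")
    return synthetic_pulse(spec, n_samples=n_samples)
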