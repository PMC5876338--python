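"""Run configuration: schema, validation, loading, provenance.

Configurations are YAML files validated with pydantic before any computation.
All physical quantities carry explicit units in their field names; clinical
units (mmHg, mmHg·s/cm³) are converted exactly once at this boundary and the
whole pipeline is SI internally.  Runs are fully deterministic; the ``seed``
field is reserved for forward compatibility and recorded in provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import __version__ as _pkg_version
from .errors import ConfigError
from .network import (
    FIXTURE_OXYGEN_TENSIONS_MMHG,
    VesselNetwork,
    build_bifurcated_fixture,
    build_curved_fixture,
    build_straight_fixture,
)
from .oxygen import OxygenBoundary, make_closure
from .waveforms import (
    FIXTURE_PRESET,
    PulseSpec,
    constant_waveform,
    synthetic_pulse,
    waveform_from_table,
    waveform_preset,
)

_FIXTURES = {
    "straight": build_straight_fixture,
    "curved": build_curved_fixture,
    "bifurcated": build_bifurcated_fixture,
}


class NetworkRef(BaseModel):
    fixture: Optional[Literal["straight", "curved", "bifurcated"]] = None
    file: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.fixture is None) == (self.file is None):
            raise ValueError("network requires exactly one of 'fixture' or 'file'")
        return self


class PulseBlock(BaseModel):
    period_s: float
    mean_flow_m3s: float
    amplitude_m3s: float
    systolic_fraction: float = 0.35
    shape: Literal["half-sine", "harmonic"] = "half-sine"
    n_samples: int = 64


class TableBlock(BaseModel):
    period_s: float
    times_s: list[float]
    flows_m3s: list[float]


class WaveformRef(BaseModel):
    preset: Optional[Literal["abdominal", "coronary", "carotid"]] = None
    constant_m3s: Optional[float] = None
    pulse: Optional[PulseBlock] = None
    table: Optional[TableBlock] = None
    period_s: float = 1.0  # used with constant_m3s

    @model_validator(mode="after")
    def _one_source(self):
        n = sum(x is not None for x in (self.preset, self.constant_m3s, self.pulse, self.table))
        if n != 1:
            raise ValueError(
                "waveform requires exactly one of 'preset', 'constant_m3s', 'pulse', 'table'"
            )
        return self


class SolverSettings(BaseModel):
    dt_s: float = Field(1e-4, gt=0)
    cycle_tol: float = Field(1e-4, gt=0)
    max_cycles: int = Field(50, ge=1)


class ClosureSettings(BaseModel):
    type: Literal["sherwood", "fixed-coefficient", "prescribed-flux"] = "sherwood"
    sherwood_number: float = 3.66
    coefficient_m_s: Optional[float] = None
    flux_per_length_kg_m_s: float = 0.0


class OxygenSettings(BaseModel):
    inlet_po2_mmhg: Optional[float] = None  # default: fixture value
    wall_po2_mmhg: Optional[Union[float, dict[str, float]]] = None
    solubility_per_mmhg: float = Field(3.0e-5, gt=0)
    closure: ClosureSettings = Field(default_factory=ClosureSettings)
    v_floor_m_s: float = Field(1e-6, gt=0)
    cycle_tol: float = Field(1e-6, gt=0)
    max_cycles: int = Field(200, ge=1)


class RunConfig(BaseModel):
    """Top-level validated run configuration."""

    schema_version: Literal["1"] = "1"
    network: NetworkRef
    waveform: Optional[WaveformRef] = None
    solver: SolverSettings = Field(default_factory=SolverSettings)
    oxygen: OxygenSettings = Field(default_factory=OxygenSettings)
    output_dir: str = "results"
    seed: int = 0  # reserved: the pipeline is deterministic

    # -- builders ---------------------------------------------------------

    def build_network(self) -> VesselNetwork:
        if self.network.fixture:
            return _FIXTURES[self.network.fixture]()
        data = yaml.safe_load(Path(self.network.file).read_text())
        net = VesselNetwork.from_dict(data)
        from .network import validate_network

        violations = validate_network(net)
        if violations:
            raise ConfigError("network file invalid: " + "; ".join(violations))
        return net

    def build_waveform(self):
        wf = self.waveform
        if wf is None:
            preset = FIXTURE_PRESET.get(self.network.fixture or "", "abdominal")
            return waveform_preset(preset)
        if wf.preset:
            return waveform_preset(wf.preset)
        if wf.constant_m3s is not None:
            return constant_waveform(wf.constant_m3s, period=wf.period_s)
        if wf.pulse:
            spec = PulseSpec(
                period=wf.pulse.period_s,
                mean_flow=wf.pulse.mean_flow_m3s,
                amplitude=wf.pulse.amplitude_m3s,
                systolic_fraction=wf.pulse.systolic_fraction,
                shape=wf.pulse.shape,
            )
            return synthetic_pulse(spec, n_samples=wf.pulse.n_samples)
        return waveform_from_table(wf.table.times_s, wf.table.flows_m3s, wf.table.period_s)

    def build_oxygen_boundary(self) -> OxygenBoundary:
        ox = self.oxygen
        defaults = FIXTURE_OXYGEN_TENSIONS_MMHG.get(self.network.fixture or "", {})
        inlet = ox.inlet_po2_mmhg if ox.inlet_po2_mmhg is not None else defaults.get("inlet", 85.0)
        wall = ox.wall_po2_mmhg if ox.wall_po2_mmhg is not None else defaults.get("wall", 60.0)
        cs = ox.closure
        params = {"sherwood_number": cs.sherwood_number}
        if cs.type == "fixed-coefficient":
            if cs.coefficient_m_s is None:
                raise ConfigError("oxygen.closure.coefficient_m_s required for fixed-coefficient")
            params = {"coefficient": cs.coefficient_m_s}
        elif cs.type == "prescribed-flux":
            params = {"flux_per_length": cs.flux_per_length_kg_m_s}
        closure = make_closure(cs.type, **params)
        return OxygenBoundary(
            inlet_po2_mmhg=inlet,
            wall_po2_mmhg=wall,
            solubility=ox.solubility_per_mmhg,
            closure=closure,
            v_floor=ox.v_floor_m_s,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; errors name field paths."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of the configuration."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def provenance_block(config: RunConfig) -> dict:
    """Provenance metadata written alongside every run's outputs."""
    return {
        "config_sha256": config_hash(config),
        "software": {"name": "oxiline", "version": _pkg_version},
        "units": "SI internally; mmHg and mmHg·s/cm³ converted at the boundary "
                 "(1 mmHg = 133.322 Pa)",
        "seed": config.seed,
    }
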