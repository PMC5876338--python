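"""Vessel network data model, electrical-analog element values, and fixtures.

A :class:`VesselNetwork` is a rooted directed tree of short uniform segments.
Each segment maps onto a transmission-line circuit cell (inverted-L topology):
a series resistance--inertance branch carrying the segment flow, followed by a
shunt compliance to ground at its downstream node.  Leaves close on an
algebraic terminal resistance standing in for the distal vasculature.

The element closures are the classical ones for a uniform-velocity profile
(the same assumption the lumped oxygen model rests on):

* Poiseuille resistivity      R' = 8 mu dx / (pi R^4)
* plug-flow inertance         L' = rho dx / (pi R^2)
* thin-wall compliance        C' = 3 pi R^3 dx / (2 E h)

Three ready-made verification fixtures are provided: a straight tube with
abdominal-artery-like properties, a curved tube with coronary-artery-like
properties, and a carotid-like bifurcation.  Segment counts, lengths, wall
thicknesses, elastic moduli, terminal resistances and oxygen boundary tensions
follow the printed verification parameters; lumen calibers are representative
defaults (the geometry sketches label diameters without printing values) and
are overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from . import units
from .errors import InvalidNetworkError


def _require_positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a strictly positive finite number, got {value!r}")


@dataclass(frozen=True)
class SegmentGeometry:
    """Geometry of one lumped segment.

    Parameters
    ----------
    length : float
        Segment length dx along the centerline (m).  Assumed much larger
        than the radial wall deformation (not enforced).
    radius : float
        Lumen radius R (m).
    wall_thickness : float
        Wall thickness h (m).
    """

    length: float
    radius: float
    wall_thickness: float

    def __post_init__(self):
        _require_positive("length", self.length)
        _require_positive("radius", self.radius)
        _require_positive("wall_thickness", self.wall_thickness)

    @property
    def area(self) -> float:
        """Lumen cross-sectional area pi R^2 (m^2)."""
        return math.pi * self.radius**2


@dataclass(frozen=True)
class WallProperties:
    """Vessel wall material properties.

    Only the elastic modulus (with the wall thickness) enters the lumped
    compliance; density and Poisson ratio are retained for completeness.
    """

    elastic_modulus: float
    density: float = 1060.0
    poisson_ratio: float = 0.49

    def __post_init__(self):
        _require_positive("elastic_modulus", self.elastic_modulus)
        _require_positive("density", self.density)
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError(
                f"poisson_ratio must lie in [0, 0.5), got {self.poisson_ratio!r}"
            )


@dataclass(frozen=True)
class FluidProperties:
    """Blood and dissolved-oxygen transport properties.

    ``o2_diffusivity`` is the molecular diffusivity D of oxygen in blood
    (m^2/s).  The transport equations are written with a diffusion
    conductance Gamma = rho * D acting on the mass-fraction concentration;
    only D is exposed here and Gamma is derived.
    """

    density: float = 1050.0
    viscosity: float = 3.5e-3
    o2_diffusivity: float = 1.2e-9

    def __post_init__(self):
        _require_positive("density", self.density)
        _require_positive("viscosity", self.viscosity)
        _require_positive("o2_diffusivity", self.o2_diffusivity)

    @property
    def gamma(self) -> float:
        """Diffusion conductance Gamma = rho * D (kg/(m s))."""
        return self.density * self.o2_diffusivity


@dataclass(frozen=True)
class SegmentElements:
    """Per-segment circuit element values (all SI, per whole segment)."""

    resistivity: float  # Pa s / m^3
    inertance: float  # Pa s^2 / m^3
    compliance: float  # m^3 / Pa


def segment_elements(
    geom: SegmentGeometry, wall: WallProperties, fluid: FluidProperties
) -> SegmentElements:
    """Compute R', L', C' for one segment from the standard closures.

    R' = 8 mu dx / (pi R^4); L' = rho dx / (pi R^2); C' = 3 pi R^3 dx / (2 E h).
    All three scale linearly with segment length, so series composition of two
    half-length segments reproduces the full-length resistance exactly.
    """
    dx, r = geom.length, geom.radius
    resistivity = 8.0 * fluid.viscosity * dx / (math.pi * r**4)
    inertance = fluid.density * dx / (math.pi * r**2)
    compliance = 3.0 * math.pi * r**3 * dx / (2.0 * wall.elastic_modulus * geom.wall_thickness)
    return SegmentElements(resistivity, inertance, compliance)


@dataclass
class Segment:
    """One lumped vessel segment.

    ``parent`` is the identifier of the upstream segment (None for the inlet
    root).  ``terminal_resistance`` (Pa s/m^3, SI) must be set on leaves and
    only on leaves.  ``metadata`` stores descriptive geometry (curvature,
    branch angles) that does not enter the 1D centerline model.
    """

    id: str
    geometry: SegmentGeometry
    wall: WallProperties
    parent: str | None = None
    terminal_resistance: float | None = None
    metadata: dict = field(default_factory=dict)


class VesselNetwork:
    """Rooted directed tree of lumped vessel segments sharing one fluid.

    Invariants (reported, not raised, by :func:`validate_network`):
    exactly one root (the inlet); connected and acyclic parent links;
    every leaf carries a terminal resistance and no internal segment does;
    junction segments have >= 2 children.
    """

    def __init__(self, segments: list[Segment], fluid: FluidProperties | None = None):
        self.segments = list(segments)
        self.fluid = fluid if fluid is not None else FluidProperties()
        self._index = {s.id: i for i, s in enumerate(self.segments)}

    # -- structure ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.segments)

    def index_of(self, seg_id: str) -> int:
        return self._index[seg_id]

    def segment(self, seg_id: str) -> Segment:
        return self.segments[self._index[seg_id]]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.segments]

    def children(self, seg_id: str) -> list[str]:
        return [s.id for s in self.segments if s.parent == seg_id]

    @property
    def roots(self) -> list[str]:
        return [s.id for s in self.segments if s.parent is None]

    @property
    def root(self) -> str:
        roots = self.roots
        if len(roots) != 1:
            raise InvalidNetworkError([f"expected exactly one inlet root, found {len(roots)}"])
        return roots[0]

    @property
    def leaves(self) -> list[str]:
        child_count = {s.id: 0 for s in self.segments}
        for s in self.segments:
            if s.parent in child_count:
                child_count[s.parent] += 1
        return [sid for sid, n in child_count.items() if n == 0]

    @property
    def junctions(self) -> list[str]:
        """Segments whose downstream node feeds more than one child."""
        counts: dict[str, int] = {}
        for s in self.segments:
            if s.parent is not None:
                counts[s.parent] = counts.get(s.parent, 0) + 1
        return [sid for sid, n in counts.items() if n >= 2]

    def topological_order(self) -> list[str]:
        """Segment ids root-first; raises if the parent links contain a cycle."""
        order: list[str] = []
        children: dict[str | None, list[str]] = {}
        for s in self.segments:
            children.setdefault(s.parent, []).append(s.id)
        stack = list(children.get(None, []))
        seen: set[str] = set()
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise InvalidNetworkError([f"segment '{sid}' visited twice (cycle?)"])
            seen.add(sid)
            order.append(sid)
            stack.extend(children.get(sid, []))
        if len(order) != len(self.segments):
            raise InvalidNetworkError(["network is not connected/acyclic from its root"])
        return order

    def elements(self, seg_id: str) -> SegmentElements:
        s = self.segment(seg_id)
        return segment_elements(s.geometry, s.wall, self.fluid)

    @property
    def total_length(self) -> float:
        return sum(s.geometry.length for s in self.segments)

    def require_valid(self) -> None:
        violations = validate_network(self)
        if violations:
            raise InvalidNetworkError(violations)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Serialize to the documented config schema (exact float round-trip)."""
        seg_block = []
        terminals = []
        for s in self.segments:
            seg_block.append(
                {
                    "id": s.id,
                    "parent": s.parent,
                    "length_m": s.geometry.length,
                    "radius_m": s.geometry.radius,
                    "wall_thickness_m": s.geometry.wall_thickness,
                    "elastic_modulus_pa": s.wall.elastic_modulus,
                    "wall_density_kg_m3": s.wall.density,
                    "poisson_ratio": s.wall.poisson_ratio,
                    **({"metadata": dict(s.metadata)} if s.metadata else {}),
                }
            )
            if s.terminal_resistance is not None:
                terminals.append(
                    {
                        "segment": s.id,
                        "resistance_mmhg_s_cm3": units.terminal_resistance_from_si(
                            s.terminal_resistance
                        ),
                    }
                )
        return {
            "fluid": {
                "density_kg_m3": self.fluid.density,
                "viscosity_pa_s": self.fluid.viscosity,
                "o2_diffusivity_m2_s": self.fluid.o2_diffusivity,
            },
            "segments": seg_block,
            "terminals": terminals,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "VesselNetwork":
        fluid_block = data.get("fluid", {})
        fluid = FluidProperties(
            density=fluid_block.get("density_kg_m3", 1050.0),
            viscosity=fluid_block.get("viscosity_pa_s", 3.5e-3),
            o2_diffusivity=fluid_block.get("o2_diffusivity_m2_s", 1.2e-9),
        )
        terminals = {
            t["segment"]: units.terminal_resistance_to_si(t["resistance_mmhg_s_cm3"])
            for t in data.get("terminals", [])
        }
        segments = []
        for block in data.get("segments", []):
            segments.append(
                Segment(
                    id=str(block["id"]),
                    geometry=SegmentGeometry(
                        length=block["length_m"],
                        radius=block["radius_m"],
                        wall_thickness=block["wall_thickness_m"],
                    ),
                    wall=WallProperties(
                        elastic_modulus=block["elastic_modulus_pa"],
                        density=block.get("wall_density_kg_m3", 1060.0),
                        poisson_ratio=block.get("poisson_ratio", 0.49),
                    ),
                    parent=block.get("parent"),
                    terminal_resistance=terminals.get(str(block["id"])),
                    metadata=dict(block.get("metadata", {})),
                )
            )
        return cls(segments, fluid)


def validate_network(net: VesselNetwork) -> list[str]:
    """Check all VesselNetwork invariants; return human-readable violations.

    An empty list means the network is well formed.  Violations name the
    offending segment or junction.
    """
    violations: list[str] = []
    ids = [s.id for s in net.segments]
    if len(set(ids)) != len(ids):
        violations.append("duplicate segment identifiers")
        return violations

    roots = net.roots
    if len(roots) != 1:
        violations.append(f"exactly one inlet root required, found {len(roots)}: {roots}")

    id_set = set(ids)
    for s in net.segments:
        if s.parent is not None and s.parent not in id_set:
            violations.append(f"segment '{s.id}' references unknown parent '{s.parent}'")

    # acyclicity / connectivity by walking parent chains
    for s in net.segments:
        seen = set()
        cur: str | None = s.id
        while cur is not None:
            if cur in seen:
                violations.append(f"acyclicity violated on the parent chain of '{s.id}'")
                break
            seen.add(cur)
            parent = net.segment(cur).parent if cur in id_set else None
            cur = parent
        else:
            continue
        break  # one cycle report is enough

    leaves = set(net.leaves)
    for s in net.segments:
        if s.id in leaves and s.terminal_resistance is None:
            violations.append(f"leaf '{s.id}' lacks a terminal resistance")
        if s.id not in leaves and s.terminal_resistance is not None:
            violations.append(f"internal segment '{s.id}' carries a terminal resistance")
        if s.terminal_resistance is not None and not s.terminal_resistance > 0:
            violations.append(f"terminal resistance on '{s.id}' must be positive")
    return violations


# -- verification fixtures -------------------------------------------------
#
# Boundary oxygen tensions that accompany each fixture in the verification
# set-up; importing code (config/CLI) uses these as defaults.
FIXTURE_OXYGEN_TENSIONS_MMHG = {
    "straight": {"inlet": 85.0, "wall": 60.0},
    "curved": {"inlet": 85.0, "wall": 48.0},
    "bifurcated": {"inlet": 85.3, "wall": 55.5},
}


def build_straight_fixture(n_segments: int = 10, radius: float = 5.0e-3) -> VesselNetwork:
    """Straight abdominal-artery-like tube: n segments x 20 mm.

    Wall 2 mm thick, E = 5.11 MPa; terminal resistance 0.0865 mmHg s/cm^3.
    The default caliber (10 mm diameter) is a representative abdominal value.
    """
    geom = SegmentGeometry(length=20.0e-3, radius=radius, wall_thickness=2.0e-3)
    wall = WallProperties(elastic_modulus=5.11e6)
    r_term = units.terminal_resistance_to_si(0.0865)
    segments = [
        Segment(
            id=f"s{i}",
            geometry=geom,
            wall=wall,
            parent=None if i == 0 else f"s{i - 1}",
            terminal_resistance=r_term if i == n_segments - 1 else None,
        )
        for i in range(n_segments)
    ]
    return VesselNetwork(segments, FluidProperties())


def build_curved_fixture(n_segments: int = 9, radius: float = 2.0e-3) -> VesselNetwork:
    """Curved coronary-artery-like tube: n segments x 3.84 mm of arc.

    Wall 0.18 mm, E = 0.7 MPa; terminal resistance 55.6 mmHg s/cm^3.
    Curvature is metadata only: the lumped model is one-dimensional along the
    centerline, so a 90 deg arc of 22 mm curvature radius is recorded but does
    not change any element value.
    """
    geom = SegmentGeometry(length=3.84e-3, radius=radius, wall_thickness=0.18e-3)
    wall = WallProperties(elastic_modulus=0.7e6)
    r_term = units.terminal_resistance_to_si(55.6)
    meta = {"curvature_radius_m": 0.022, "curvature_angle_deg": 90.0}
    segments = [
        Segment(
            id=f"c{i}",
            geometry=geom,
            wall=wall,
            parent=None if i == 0 else f"c{i - 1}",
            terminal_resistance=r_term if i == n_segments - 1 else None,
            metadata=dict(meta),
        )
        for i in range(n_segments)
    ]
    return VesselNetwork(segments, FluidProperties())


def build_bifurcated_fixture(
    cc_radius: float = 3.15e-3,
    ic_radius: float = 2.25e-3,
    ec_radius: float = 1.8e-3,
) -> VesselNetwork:
    """Carotid-like bifurcation: CC trunk feeding IC and EC branches.

    10 segments each: CC 6.45 mm, IC 6.23 mm (terminal 21.7 mmHg s/cm^3),
    EC 6.2 mm (terminal 35.3 mmHg s/cm^3).  Wall 0.7 mm, E = 0.5 MPa.
    The bifurcation angle is metadata only.
    """
    wall = WallProperties(elastic_modulus=0.5e6)
    meta = {"bifurcation_angle_deg": 50.0}
    segments: list[Segment] = []
    for i in range(10):
        segments.append(
            Segment(
                id=f"cc{i}",
                geometry=SegmentGeometry(6.45e-3, cc_radius, 0.7e-3),
                wall=wall,
                parent=None if i == 0 else f"cc{i - 1}",
            )
        )
    for name, length, radius, r_term in (
        ("ic", 6.23e-3, ic_radius, 21.7),
        ("ec", 6.2e-3, ec_radius, 35.3),
    ):
        for i in range(10):
            segments.append(
                Segment(
                    id=f"{name}{i}",
                    geometry=SegmentGeometry(length, radius, 0.7e-3),
                    wall=wall,
                    parent="cc9" if i == 0 else f"{name}{i - 1}",
                    terminal_resistance=(
                        units.terminal_resistance_to_si(r_term) if i == 9 else None
                    ),
                    metadata=dict(meta) if i == 0 else {},
                )
            )
    return VesselNetwork(segments, FluidProperties())


def rediscretize_chain(net: VesselNetwork, n_segments: int) -> VesselNetwork:
    """Rebuild an unbranched single-tube network with ``n_segments`` segments.

    Preserves total length, caliber, wall and terminal resistance; used by
    convergence studies against the 1D reference solver.
    """
    order = net.topological_order()
    if any(len(net.children(sid)) > 1 for sid in order):
        raise InvalidNetworkError(["rediscretize_chain requires an unbranched tube"])
    first = net.segment(order[0])
    last = net.segment(order[-1])
    dx = net.total_length / n_segments
    geom = replace(first.geometry, length=dx)
    segments = [
        Segment(
            id=f"n{i}",
            geometry=geom,
            wall=first.wall,
            parent=None if i == 0 else f"n{i - 1}",
            terminal_resistance=last.terminal_resistance if i == n_segments - 1 else None,
        )
        for i in range(n_segments)
    ]
    return VesselNetwork(segments, net.fluid)
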