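"""Reduced-order aortic-arch geometries.

The arch is represented as a centerline network: vessel segments with
piecewise-linear radius profiles, joined at junctions into a tree with one
inlet and four outlets (the three supra-aortic branches and the descending
aorta).  Exactly one segment carries the coarctation, marked by its start
and end planes.  From the geometry alone we derive three quantities the
rest of the pipeline consumes:

* the Poiseuille (viscous) resistance of any segment or sub-interval,
* the ground-truth stenosis coefficients (f, s) of the lesion — a viscous
  friction term plus a Borda–Carnot expansion loss, and
* the ESC narrowing rate, 1 - d_min / d_diaphragm.

Units throughout: lengths and radii in cm, pressures in mmHg, flows in
cm^3/s, so resistances are mmHg·s/cm^3 and the quadratic loss coefficient
is mmHg·s^2/cm^6.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

GEOMETRY_SCHEMA_VERSION = "1.0"

__all__ = [
    "InvalidGeometryError",
    "FluidProperties",
    "VesselSegment",
    "Junction",
    "Outlet",
    "AortaNetwork",
    "StenosisCoefficients",
    "poiseuille_resistance_interval",
    "segment_viscous_coefficient",
    "narrowing_rate",
    "stenosis_true_coefficients",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
]


class InvalidGeometryError(ValueError):
    """A network or segment violates a geometric invariant."""


@dataclass(frozen=True)
class FluidProperties:
    """Blood properties in mmHg-cm-s units.

    Defaults correspond to the standard values mu = 0.004 Pa·s and
    rho = 1060 kg/m^3 (1 mmHg = 1333.22 dyn/cm^2).
    """

    viscosity: float = 3.0e-5  # mmHg·s
    density: float = 7.95e-4   # mmHg·s^2/cm^2

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be strictly positive")


@dataclass(frozen=True)
class StenosisCoefficients:
    """Coefficients of the stenosis pressure-flow law dp = f*Q + s*Q^2."""

    f: float  # mmHg·s/cm^3
    s: float  # mmHg·s^2/cm^6

    def __post_init__(self) -> None:
        if self.f < 0 or self.s < 0:
            raise ValueError("stenosis coefficients must be non-negative")

    def pressure_drop(self, flow: float) -> float:
        return self.f * flow + self.s * flow * flow


@dataclass
class VesselSegment:
    """A centerline vessel segment with a piecewise-linear radius profile.

    ``radius_profile`` is an ordered list of (axial position, radius) pairs;
    positions must increase strictly from 0 to ``length``.  When
    ``is_lesion`` the coarctation occupies [lesion_start, lesion_end] within
    the segment.
    """

    id: str
    length: float
    radius_profile: list[tuple[float, float]]
    is_lesion: bool = False
    lesion_start: float | None = None
    lesion_end: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidGeometryError(f"segment {self.id}: non-positive length")
        prof = [(float(x), float(r)) for x, r in self.radius_profile]
        if len(prof) < 2:
            raise InvalidGeometryError(f"segment {self.id}: need >= 2 profile points")
        xs = [x for x, _ in prof]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise InvalidGeometryError(
                f"segment {self.id}: profile positions must strictly increase")
        if abs(xs[0]) > 1e-12 or abs(xs[-1] - self.length) > 1e-9:
            raise InvalidGeometryError(
                f"segment {self.id}: profile must span [0, length]")
        if any(r <= 0 for _, r in prof):
            raise InvalidGeometryError(f"segment {self.id}: non-positive radius")
        self.radius_profile = prof
        if self.is_lesion:
            if self.lesion_start is None or self.lesion_end is None:
                raise InvalidGeometryError(
                    f"segment {self.id}: lesion planes required when is_lesion")
            if not (0 <= self.lesion_start < self.lesion_end <= self.length):
                raise InvalidGeometryError(
                    f"segment {self.id}: lesion planes must satisfy "
                    "0 <= start < end <= length")

    def radius_at(self, x: float) -> float:
        """Linear interpolation of the radius at axial position x."""
        if not 0 <= x <= self.length + 1e-12:
            raise InvalidGeometryError(f"segment {self.id}: position {x} outside segment")
        prof = self.radius_profile
        x = min(x, self.length)
        for (x0, r0), (x1, r1) in zip(prof, prof[1:]):
            if x <= x1:
                t = (x - x0) / (x1 - x0)
                return r0 + t * (r1 - r0)
        return prof[-1][1]

    def min_radius(self, start: float | None = None, end: float | None = None) -> float:
        """Minimum radius over [start, end] (default: the whole segment).

        The profile is piecewise linear, so the minimum is attained at an
        interval endpoint or a profile knot inside the interval.
        """
        a = 0.0 if start is None else start
        b = self.length if end is None else end
        candidates = [self.radius_at(a), self.radius_at(b)]
        candidates += [r for x, r in self.radius_profile if a < x < b]
        return min(candidates)


@dataclass(frozen=True)
class Junction:
    """Joins an upstream segment to an optional downstream segment and an
    optional outlet branch.  A terminal junction has no downstream segment
    and must carry an outlet."""

    upstream: str
    downstream: str | None = None
    outlet: str | None = None

    def __post_init__(self) -> None:
        if self.downstream is None and self.outlet is None:
            raise InvalidGeometryError(
                f"junction after {self.upstream}: needs a downstream segment "
                "or an outlet")


@dataclass(frozen=True)
class Outlet:
    id: str
    diameter: float  # cm, reference diameter used for resistance allocation

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidGeometryError(f"outlet {self.id}: non-positive diameter")


@dataclass
class AortaNetwork:
    """Tree-structured arch network: one inlet, four outlets, one lesion."""

    segments: list[VesselSegment]
    junctions: list[Junction]
    outlets: list[Outlet]
    inlet_segment: str
    diaphragm_diameter: float

    def __post_init__(self) -> None:
        self._validate()

    # -- lookups -----------------------------------------------------------
    def segment(self, seg_id: str) -> VesselSegment:
        return self._seg_by_id[seg_id]

    @property
    def lesion_segment(self) -> VesselSegment:
        return self._lesion

    def junction_after(self, seg_id: str) -> Junction:
        return self._junction_by_upstream[seg_id]

    def _validate(self) -> None:
        self._seg_by_id = {s.id: s for s in self.segments}
        if len(self._seg_by_id) != len(self.segments):
            raise InvalidGeometryError("duplicate segment ids")
        if self.inlet_segment not in self._seg_by_id:
            raise InvalidGeometryError("inlet segment not found")
        if self.diaphragm_diameter <= 0:
            raise InvalidGeometryError("non-positive diaphragm diameter")
        if len(self.outlets) != 4:
            raise InvalidGeometryError("exactly four outlets required")
        outlet_ids = {o.id for o in self.outlets}
        if len(outlet_ids) != 4:
            raise InvalidGeometryError("duplicate outlet ids")

        self._junction_by_upstream = {}
        for j in self.junctions:
            if j.upstream not in self._seg_by_id:
                raise InvalidGeometryError(f"junction upstream {j.upstream} unknown")
            if j.upstream in self._junction_by_upstream:
                raise InvalidGeometryError(f"segment {j.upstream} has two junctions")
            if j.downstream is not None and j.downstream not in self._seg_by_id:
                raise InvalidGeometryError(f"junction downstream {j.downstream} unknown")
            if j.outlet is not None and j.outlet not in outlet_ids:
                raise InvalidGeometryError(f"junction outlet {j.outlet} unknown")
            self._junction_by_upstream[j.upstream] = j

        # connectivity: walk from the inlet; every segment reached once
        seen: list[str] = []
        used_outlets: set[str] = set()
        seg = self.inlet_segment
        while seg is not None:
            if seg in seen:
                raise InvalidGeometryError("cycle detected in network")
            seen.append(seg)
            j = self._junction_by_upstream.get(seg)
            if j is None:
                raise InvalidGeometryError(f"segment {seg} has no downstream junction")
            if j.outlet is not None:
                if j.outlet in used_outlets:
                    raise InvalidGeometryError(f"outlet {j.outlet} used twice")
                used_outlets.add(j.outlet)
            seg = j.downstream
        if set(seen) != set(self._seg_by_id):
            raise InvalidGeometryError("network is not connected from the inlet")
        if used_outlets != outlet_ids:
            raise InvalidGeometryError("all four outlets must be attached")

        lesions = [s for s in self.segments if s.is_lesion]
        if len(lesions) != 1:
            raise InvalidGeometryError("exactly one lesion segment required")
        self._lesion = lesions[0]

    def path_from_inlet(self) -> list[str]:
        """Segment ids in order from the inlet to the terminal junction."""
        out, seg = [], self.inlet_segment
        while seg is not None:
            out.append(seg)
            seg = self._junction_by_upstream[seg].downstream
        return out


# ---------------------------------------------------------------------------
# Geometry-derived quantities
# ---------------------------------------------------------------------------

def _inv_r4_integral(x0: float, r0: float, x1: float, r1: float) -> float:
    # closed form of ∫ dx / r(x)^4 over a linear piece
    h = x1 - x0
    if abs(r1 - r0) < 1e-14 * max(r0, r1):
        return h / r0**4
    return h / (3.0 * (r1 - r0)) * (1.0 / r0**3 - 1.0 / r1**3)


def poiseuille_resistance_interval(
    segment: VesselSegment, start: float, end: float, fluid: FluidProperties
) -> float:
    """Poiseuille resistance 8*mu/pi * ∫ dx/r^4 over [start, end] of a segment.

    Exact (closed form per linear profile piece); additive over sub-intervals.
    """
    if not (0 <= start < end <= segment.length + 1e-12):
        raise InvalidGeometryError(
            f"segment {segment.id}: interval [{start}, {end}] invalid")
    total = 0.0
    prof = segment.radius_profile
    for (x0, r0), (x1, r1) in zip(prof, prof[1:]):
        a, b = max(x0, start), min(x1, end)
        if b <= a:
            continue
        ra = r0 + (a - x0) / (x1 - x0) * (r1 - r0)
        rb = r0 + (b - x0) / (x1 - x0) * (r1 - r0)
        total += _inv_r4_integral(a, ra, b, rb)
    return 8.0 * fluid.viscosity / math.pi * total


def segment_viscous_coefficient(segment: VesselSegment, fluid: FluidProperties) -> float:
    """Linear (viscous) resistance of a whole segment, mmHg·s/cm^3."""
    return poiseuille_resistance_interval(segment, 0.0, segment.length, fluid)


def narrowing_rate(network: AortaNetwork) -> float:
    """ESC narrowing rate: 1 - (minimum lesion diameter / diaphragm diameter).

    Clipped below at zero (a lesion no narrower than the diaphragm-level
    aorta scores 0).  Scale invariant by construction.
    """
    les = network.lesion_segment
    d_min = 2.0 * les.min_radius(les.lesion_start, les.lesion_end)
    return max(0.0, 1.0 - d_min / network.diaphragm_diameter)


def stenosis_true_coefficients(
    network: AortaNetwork,
    fluid: FluidProperties,
    expansion_factor: float = 1.0,
) -> StenosisCoefficients:
    """Ground-truth (f, s) of the lesion between its start and end planes.

    f is the Poiseuille integral over the lesion interval.  s is a
    Borda–Carnot sudden-expansion loss,
    ``K_e * rho/2 * (1/A_min - 1/A_ref)^2``, with A_min the minimal lesion
    lumen area, A_ref the lumen area at the lesion start plane and K_e the
    expansion-loss factor (1.0 = classical Borda–Carnot; other values inject
    deliberate model mismatch).  Both are pure functions of geometry and
    fluid — independent of any flow or pressure.
    """
    les = network.lesion_segment
    f_true = poiseuille_resistance_interval(
        les, les.lesion_start, les.lesion_end, fluid)
    r_min = les.min_radius(les.lesion_start, les.lesion_end)
    r_ref = les.radius_at(les.lesion_start)
    a_min = math.pi * r_min**2
    a_ref = math.pi * r_ref**2
    s_true = expansion_factor * 0.5 * fluid.density * (1.0 / a_min - 1.0 / a_ref) ** 2
    return StenosisCoefficients(f=f_true, s=s_true)


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------

def network_to_dict(network: AortaNetwork) -> dict:
    return {
        "schema_version": GEOMETRY_SCHEMA_VERSION,
        "units": {"length": "cm", "diameter": "cm"},
        "inlet_segment": network.inlet_segment,
        "diaphragm_diameter": network.diaphragm_diameter,
        "segments": [
            {
                "id": s.id,
                "length": s.length,
                "radius_profile": [[x, r] for x, r in s.radius_profile],
                "is_lesion": s.is_lesion,
                "lesion_start": s.lesion_start,
                "lesion_end": s.lesion_end,
            }
            for s in network.segments
        ],
        "junctions": [
            {"upstream": j.upstream, "downstream": j.downstream, "outlet": j.outlet}
            for j in network.junctions
        ],
        "outlets": [{"id": o.id, "diameter": o.diameter} for o in network.outlets],
    }


def network_from_dict(data: dict) -> AortaNetwork:
    version = data.get("schema_version")
    if version != GEOMETRY_SCHEMA_VERSION:
        raise InvalidGeometryError(f"unsupported geometry schema {version!r}")
    return AortaNetwork(
        segments=[
            VesselSegment(
                id=s["id"],
                length=s["length"],
                radius_profile=[tuple(p) for p in s["radius_profile"]],
                is_lesion=s.get("is_lesion", False),
                lesion_start=s.get("lesion_start"),
                lesion_end=s.get("lesion_end"),
            )
            for s in data["segments"]
        ],
        junctions=[
            Junction(j["upstream"], j.get("downstream"), j.get("outlet"))
            for j in data["junctions"]
        ],
        outlets=[Outlet(o["id"], o["diameter"]) for o in data["outlets"]],
        inlet_segment=data["inlet_segment"],
        diaphragm_diameter=data["diaphragm_diameter"],
    )


def save_network(network: AortaNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(network), indent=1))


def load_network(path: str | Path) -> AortaNetwork:
    return network_from_dict(json.loads(Path(path).read_text()))
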