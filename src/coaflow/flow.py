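"""Steady flow solution of an arch network with single-resistance outlets.

Each outlet is a lumped-parameter model (LPM) with one resistance draining
to a common reference (venous) pressure; a fixed static pressure is applied
at the inlet.  Every segment obeys the algebraic law

    dp = f*Q + s*Q^2 (+ m*Q^1.75)

with s = 0 for non-lesion segments; the lesion segment additionally carries
the expansion loss s (and, in mismatch experiments, a turbulent-friction
term m*Q^1.75).  The nonlinear system in the junction pressures is solved
by damped Newton with an analytic Jacobian, seeded by the linearized
(Poiseuille-only) circuit solution; a bisection-based shooting fallback
covers the rare Newton failure.

The six-level resistance sweep reproduces the study protocol: total outlet
resistance 9.6 mmHg·s/cm^3 scaled by 1, 1/2, ..., 1/6, the steady state
solved at each level, and the lesion (Q, dp) pair recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    AortaNetwork,
    FluidProperties,
    StenosisCoefficients,
    segment_viscous_coefficient,
    stenosis_true_coefficients,
)

DEFAULT_INLET_PRESSURE = 80.0       # mmHg, normal physiological static pressure
DEFAULT_TOTAL_RESISTANCE = 9.6      # mmHg·s/cm^3
DEFAULT_SWEEP_SCALES = (1.0, 1 / 2, 1 / 3, 1 / 4, 1 / 5, 1 / 6)
_RE_EXPONENT = 1.75                 # exponent of the optional mismatch term

__all__ = [
    "InvalidParameterError",
    "SolverError",
    "DegenerateSegmentError",
    "OutletResistanceSet",
    "FlowSolution",
    "SweepPoint",
    "SweepResult",
    "allocate_outlet_resistances",
    "segment_flow_from_dp",
    "solve_steady_network",
    "solve_steady_network_bruteforce",
    "run_resistance_sweep",
    "sweep_to_frame",
    "write_sweep_csv",
    "read_sweep_csv",
]


class InvalidParameterError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


class DegenerateSegmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Outlet resistances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutletResistanceSet:
    """Per-outlet LPM resistances whose parallel combination is the total."""

    resistances: dict[str, float]          # outlet id -> mmHg·s/cm^3
    total_resistance: float
    reference_pressure: float = 0.0        # mmHg (venous side of the LPM)

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.resistances.values()):
            raise InvalidParameterError("outlet resistances must be positive")
        if self.total_resistance <= 0:
            raise InvalidParameterError("total resistance must be positive")
        parallel = 1.0 / sum(1.0 / r for r in self.resistances.values())
        if abs(parallel - self.total_resistance) > 1e-10 * self.total_resistance:
            raise InvalidParameterError(
                "parallel combination of outlet resistances "
                f"({parallel}) does not equal the stated total "
                f"({self.total_resistance})")

    def scaled(self, scale: float) -> "OutletResistanceSet":
        """Multiply every resistance by ``scale`` (preserves allocation ratios)."""
        if scale <= 0:
            raise InvalidParameterError("scale must be positive")
        return OutletResistanceSet(
            resistances={k: r * scale for k, r in self.resistances.items()},
            total_resistance=self.total_resistance * scale,
            reference_pressure=self.reference_pressure,
        )


def allocate_outlet_resistances(
    outlet_diameters: Mapping[str, float] | Sequence[float],
    total_resistance: float,
    exponent: float = 1.0,
    reference_pressure: float = 0.0,
) -> OutletResistanceSet:
    """Allocate a total resistance over outlets by their diameters.

    Outlet conductance is proportional to d_i**exponent and normalized so
    the parallel combination equals ``total_resistance``.  ``exponent=1``
    is the literal inverse-diameter allocation (the default); ``exponent=3``
    gives a Murray-law flow split.
    """
    if not isinstance(outlet_diameters, Mapping):
        outlet_diameters = {f"outlet_{i}": d for i, d in enumerate(outlet_diameters)}
    if total_resistance <= 0:
        raise InvalidParameterError("total resistance must be positive")
    if exponent <= 0:
        raise InvalidParameterError("exponent must be positive")
    if any(d <= 0 for d in outlet_diameters.values()):
        raise InvalidParameterError("outlet diameters must be positive")
    weights = {k: d**exponent for k, d in outlet_diameters.items()}
    wsum = sum(weights.values())
    g_total = 1.0 / total_resistance
    resistances = {k: wsum / (g_total * w) for k, w in weights.items()}
    return OutletResistanceSet(
        resistances=resistances,
        total_resistance=total_resistance,
        reference_pressure=reference_pressure,
    )


# ---------------------------------------------------------------------------
# Element pressure-flow law
# ---------------------------------------------------------------------------

def _element_dp(f: float, s: float, m: float, q: float) -> float:
    # odd extension for q < 0 keeps the law monotone through zero
    sign = 1.0 if q >= 0 else -1.0
    q = abs(q)
    return sign * (f * q + s * q * q + m * q**_RE_EXPONENT)


def _element_dpdq(f: float, s: float, m: float, q: float) -> float:
    q = abs(q)
    d = f + 2.0 * s * q
    if m > 0 and q > 0:
        d += m * _RE_EXPONENT * q ** (_RE_EXPONENT - 1.0)
    return d


def segment_flow_from_dp(f: float, s: float, dp: float, m: float = 0.0) -> float:
    """Invert dp = f*Q + s*Q^2 (+ m*Q^1.75) for the unique non-negative Q.

    Closed form for m = 0; Newton/bisection hybrid otherwise.
    """
    if f < 0 or s < 0 or m < 0:
        raise InvalidParameterError("loss coefficients must be non-negative")
    if dp < 0:
        raise InvalidParameterError("pressure drop must be non-negative")
    if dp == 0:
        return 0.0
    if f == 0 and s == 0 and m == 0:
        raise DegenerateSegmentError("zero-loss element cannot carry a pressure drop")
    if m == 0:
        if s == 0:
            return dp / f
        return (-f + math.sqrt(f * f + 4.0 * s * dp)) / (2.0 * s)
    # bracket then bisect/newton on the monotone residual
    hi = 1.0
    while _element_dp(f, s, m, hi) < dp:
        hi *= 2.0
        if hi > 1e12:
            raise SolverError("failed to bracket element flow")
    lo = 0.0
    q = hi / 2
    for _ in range(200):
        r = _element_dp(f, s, m, q) - dp
        if r > 0:
            hi = q
        else:
            lo = q
        d = _element_dpdq(f, s, m, q)
        q_newton = q - r / d if d > 0 else None
        q_next = q_newton if q_newton is not None and lo < q_newton < hi \
            else 0.5 * (lo + hi)
        if abs(q_next - q) < 1e-15 * max(q, 1e-300):
            return q_next
        q = q_next
    return q


def _signed_flow_from_dp(f: float, s: float, m: float, dp: float) -> float:
    if dp >= 0:
        return segment_flow_from_dp(f, s, dp, m)
    return -segment_flow_from_dp(f, s, -dp, m)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Element:
    """Solver view of one segment: nodes it joins and its loss law."""

    seg_id: str
    f: float
    s: float
    m: float


@dataclass
class FlowSolution:
    """Converged steady state: per-segment flows, node pressures, and the
    lesion-plane (Q, dp) pair."""

    segment_flows: dict[str, float]        # cm^3/s
    node_pressures: dict[str, float]       # mmHg, junction nodes keyed by upstream segment
    outlet_flows: dict[str, float]         # cm^3/s
    lesion_flow: float
    lesion_dp: float
    newton_iterations: int
    used_fallback: bool = False

    def mass_residuals(self) -> dict[str, float]:
        """Relative mass-conservation residual at each junction (filled by the
        solver; recomputed here from the stored flows)."""
        return dict(self._residuals)


def _network_elements(
    network: AortaNetwork,
    fluid: FluidProperties,
    lesion_expansion_factor: float,
    lesion_re_friction: float,
) -> tuple[list[_Element], StenosisCoefficients, float]:
    """Per-segment loss laws plus the lesion law restricted to its planes."""
    coeffs = stenosis_true_coefficients(network, fluid, lesion_expansion_factor)
    elements = []
    for seg in network.segments:
        f_seg = segment_viscous_coefficient(seg, fluid)
        if seg.is_lesion:
            m = lesion_re_friction
            elements.append(_Element(seg.id, f_seg, coeffs.s, m))
        else:
            elements.append(_Element(seg.id, f_seg, 0.0, 0.0))
    return elements, coeffs, lesion_re_friction


def _lesion_plane_dp(
    network: AortaNetwork,
    fluid: FluidProperties,
    coeffs: StenosisCoefficients,
    re_friction: float,
    q: float,
) -> float:
    return _element_dp(coeffs.f, coeffs.s, re_friction, q)


# ---------------------------------------------------------------------------
# Steady solver
# ---------------------------------------------------------------------------

def solve_steady_network(
    network: AortaNetwork,
    fluid: FluidProperties,
    inlet_pressure: float,
    outlets: OutletResistanceSet,
    lesion_expansion_factor: float = 1.0,
    lesion_re_friction: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-11,
) -> FlowSolution:
    """Damped-Newton steady-state solution of the network.

    Unknowns are the pressures at the junction nodes (the inlet pressure is
    prescribed).  The residual at a junction is the flow imbalance
    ``Q_upstream - Q_downstream - Q_outlet``; convergence is declared when
    the maximum imbalance falls below ``tol`` relative to the inlet flow.
    Backflow (a negative converged flow) is unsupported and raises.
    """
    pref = outlets.reference_pressure
    if inlet_pressure <= pref:
        raise InvalidParameterError("inlet pressure must exceed the reference pressure")
    elements, coeffs, re_m = _network_elements(
        network, fluid, lesion_expansion_factor, lesion_re_friction)
    elem_by_id = {e.seg_id: e for e in elements}

    path = network.path_from_inlet()
    n = len(path)  # one junction node per segment (at its downstream end)
    junctions = [network.junction_after(sid) for sid in path]
    out_g = []
    for j in junctions:
        if j.outlet is not None:
            out_g.append(1.0 / outlets.resistances[j.outlet])
        else:
            out_g.append(0.0)

    # A (near-)lossless segment forces pressure identity between its end
    # nodes, which makes the Newton system in node pressures singular or
    # hopelessly ill-conditioned; the monotone shooting formulation in the
    # inlet flow handles it directly.
    if any(e.f < 1e-9 and e.s == 0 and e.m == 0 for e in elements):
        return solve_steady_network_bruteforce(
            network, fluid, inlet_pressure, outlets,
            lesion_expansion_factor, lesion_re_friction)

    # --- linearized initial guess (Poiseuille conductances only) ----------
    g_seg = np.array([1.0 / max(elem_by_id[sid].f, 1e-12) for sid in path])
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(n):
        A[i, i] += g_seg[i] + out_g[i]
        if i == 0:
            b[i] += g_seg[i] * inlet_pressure
        else:
            A[i, i - 1] -= g_seg[i]
            A[i - 1, i] -= g_seg[i]
        b[i] += out_g[i] * pref
        # downstream segment conductance appears via the i+1 row symmetric term
        if i + 1 < n:
            A[i, i] += g_seg[i + 1]
    p = np.linalg.solve(A, b)
    p = np.clip(p, pref, inlet_pressure)

    def residual(pvec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = np.empty(n)
        for i, sid in enumerate(path):
            e = elem_by_id[sid]
            up = inlet_pressure if i == 0 else pvec[i - 1]
            q[i] = _signed_flow_from_dp(e.f, e.s, e.m, up - pvec[i])
        r = np.empty(n)
        for i in range(n):
            q_down = q[i + 1] if i + 1 < n else 0.0
            r[i] = q[i] - q_down - out_g[i] * (pvec[i] - pref)
        return r, q

    converged = False
    used_fallback = False
    it = 0
    r, q = residual(p)
    scale_ref = max(1.0, abs(q[0]))
    for it in range(1, max_iter + 1):
        if np.max(np.abs(r)) < tol * scale_ref:
            converged = True
            break
        # analytic Jacobian: dQ_i/d(dp_i) along the chain
        dq = np.empty(n)
        for i, sid in enumerate(path):
            e = elem_by_id[sid]
            dq[i] = 1.0 / max(_element_dpdq(e.f, e.s, e.m, q[i]), 1e-14)
        J = np.zeros((n, n))
        for i in range(n):
            J[i, i] = -dq[i] - out_g[i]
            if i > 0:
                J[i, i - 1] = dq[i]
            if i + 1 < n:
                J[i, i + 1] = dq[i + 1]
                J[i, i] -= dq[i + 1]  # downstream flow grows with p_i
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            break
        # damped update with residual backtracking
        lam = 1.0
        norm0 = np.linalg.norm(r)
        improved = False
        for _ in range(60):
            p_try = np.clip(p + lam * step, pref, inlet_pressure)
            r_try, q_try = residual(p_try)
            if np.linalg.norm(r_try) < norm0 * (1.0 - 1e-4 * lam) or np.linalg.norm(
                    r_try) < tol * scale_ref:
                p, r, q = p_try, r_try, q_try
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
        scale_ref = max(1.0, abs(q[0]))

    if not converged:
        r, q = residual(p)
        if np.max(np.abs(r)) < tol * max(1.0, abs(q[0])):
            converged = True
    if not converged:
        # shooting fallback: single bisection on the inlet flow, with
        # propagation-consistent residuals
        sol = solve_steady_network_bruteforce(
            network, fluid, inlet_pressure, outlets,
            lesion_expansion_factor, lesion_re_friction)
        if sol._residuals and max(sol._residuals.values()) > 1e-8:
            raise SolverError(
                "steady solver failed to converge "
                f"(max residual {max(sol._residuals.values()):.3e})")
        return sol

    if np.min(q) < -1e-9 * max(1.0, abs(q[0])):
        raise SolverError("backflow detected; negative segment flow unsupported")

    lesion_id = network.lesion_segment.id
    q_les = q[path.index(lesion_id)]
    dp_les = _element_dp(coeffs.f, coeffs.s, re_m, q_les)

    node_pressures = {sid: float(p[i]) for i, sid in enumerate(path)}
    outlet_flows = {}
    for i, j in enumerate(junctions):
        if j.outlet is not None:
            outlet_flows[j.outlet] = float(out_g[i] * (p[i] - pref))
    sol = FlowSolution(
        segment_flows={sid: float(q[i]) for i, sid in enumerate(path)},
        node_pressures=node_pressures,
        outlet_flows=outlet_flows,
        lesion_flow=float(q_les),
        lesion_dp=float(dp_les),
        newton_iterations=it,
        used_fallback=used_fallback,
    )
    sol._residuals = {
        path[i]: float(abs(r[i]) / max(1.0, abs(q[0]))) for i in range(n)}
    return sol


def _propagate(path, elem_by_id, out_g, inlet_pressure, pref, q0):
    """Forward propagation of pressures/flows along the chain for inlet flow q0.

    Returns (pressures, flows, terminal imbalance).  The imbalance is the
    flow left over after the terminal outlet, a strictly increasing function
    of q0, which makes single-variable bisection exact.
    """
    n = len(path)
    p = np.empty(n)
    q = np.empty(n)
    flow = q0
    pressure = inlet_pressure
    for i, sid in enumerate(path):
        e = elem_by_id[sid]
        q[i] = flow
        pressure = pressure - _element_dp(e.f, e.s, e.m, flow)
        p[i] = pressure
        flow = flow - out_g[i] * (pressure - pref)
    return p, q, flow


def _solve_by_shooting(path, elem_by_id, out_g, inlet_pressure, pref):
    # leftover terminal flow is strictly increasing in the trial inlet flow:
    # negative when the trial is too small, positive when too large
    lo, hi = 0.0, 1.0
    while _propagate(path, elem_by_id, out_g, inlet_pressure, pref, hi)[2] < 0:
        hi *= 2.0
        if hi > 1e12:
            raise SolverError("shooting fallback failed to bracket the inlet flow")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _propagate(path, elem_by_id, out_g, inlet_pressure, pref, mid)[2] < 0:
            lo = mid
        else:
            hi = mid
    q0 = 0.5 * (lo + hi)
    p, q, _ = _propagate(path, elem_by_id, out_g, inlet_pressure, pref, q0)
    return p, q


def solve_steady_network_bruteforce(
    network: AortaNetwork,
    fluid: FluidProperties,
    inlet_pressure: float,
    outlets: OutletResistanceSet,
    lesion_expansion_factor: float = 1.0,
    lesion_re_friction: float = 0.0,
) -> FlowSolution:
    """Independent brute-force oracle: bisection on the total inlet flow.

    Pressures are propagated forward along the arch from a trial inlet flow;
    the terminal flow imbalance is strictly monotone in the trial, so plain
    bisection converges to machine precision.  Shares no code path with the
    Newton iteration (used for cross-validation in tests).
    """
    pref = outlets.reference_pressure
    elements, coeffs, re_m = _network_elements(
        network, fluid, lesion_expansion_factor, lesion_re_friction)
    elem_by_id = {e.seg_id: e for e in elements}
    path = network.path_from_inlet()
    junctions = [network.junction_after(sid) for sid in path]
    out_g = [1.0 / outlets.resistances[j.outlet] if j.outlet else 0.0
             for j in junctions]
    p, q = _solve_by_shooting(path, elem_by_id, out_g, inlet_pressure, pref)
    if np.min(q) < -1e-9 * max(1.0, abs(q[0])):
        raise SolverError("backflow detected; negative segment flow unsupported")
    lesion_id = network.lesion_segment.id
    q_les = q[path.index(lesion_id)]
    sol = FlowSolution(
        segment_flows={sid: float(q[i]) for i, sid in enumerate(path)},
        node_pressures={sid: float(p[i]) for i, sid in enumerate(path)},
        outlet_flows={
            j.outlet: float(out_g[i] * (p[i] - pref))
            for i, j in enumerate(junctions) if j.outlet is not None},
        lesion_flow=float(q_les),
        lesion_dp=float(_element_dp(coeffs.f, coeffs.s, re_m, q_les)),
        newton_iterations=0,
        used_fallback=True,
    )
    n = len(path)
    sol._residuals = {}
    for i in range(n):
        q_down = q[i + 1] if i + 1 < n else 0.0
        imbalance = q[i] - q_down - out_g[i] * (p[i] - pref)
        sol._residuals[path[i]] = float(abs(imbalance) / max(1.0, abs(q[0])))
    return sol


# ---------------------------------------------------------------------------
# Resistance sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepPoint:
    scale: float
    total_resistance: float
    flow: float           # lesion Q, cm^3/s
    pressure_drop: float  # lesion dp, mmHg


@dataclass
class SweepResult:
    points: list[SweepPoint]

    def __post_init__(self) -> None:
        flows = [p.flow for p in self.points]
        if any(b <= a for a, b in zip(flows, flows[1:])):
            raise SolverError("sweep flows must strictly increase as the "
                              "total resistance is lowered")

    @property
    def flows(self) -> np.ndarray:
        return np.array([p.flow for p in self.points])

    @property
    def pressure_drops(self) -> np.ndarray:
        return np.array([p.pressure_drop for p in self.points])


def run_resistance_sweep(
    network: AortaNetwork,
    fluid: FluidProperties,
    inlet_pressure: float = DEFAULT_INLET_PRESSURE,
    base_total_resistance: float = DEFAULT_TOTAL_RESISTANCE,
    scales: Sequence[float] = DEFAULT_SWEEP_SCALES,
    exponent: float = 1.0,
    reference_pressure: float = 0.0,
    lesion_expansion_factor: float = 1.0,
    lesion_re_friction: float = 0.0,
) -> SweepResult:
    """Solve the steady state at each total-resistance level.

    Scales are sorted descending (largest resistance first) so flows come
    out in increasing order.  Scaling multiplies every outlet resistance,
    preserving the inverse-diameter allocation ratios.
    """
    if len(scales) < 1 or any(not 0 < s <= 1 for s in scales):
        raise InvalidParameterError("scales must lie in (0, 1]")
    if len(set(scales)) != len(scales):
        raise InvalidParameterError("scales must be distinct")
    diameters = {o.id: o.diameter for o in network.outlets}
    base = allocate_outlet_resistances(
        diameters, base_total_resistance, exponent, reference_pressure)
    points = []
    for scale in sorted(scales, reverse=True):
        try:
            sol = solve_steady_network(
                network, fluid, inlet_pressure, base.scaled(scale),
                lesion_expansion_factor=lesion_expansion_factor,
                lesion_re_friction=lesion_re_friction)
        except SolverError as exc:
            raise SolverError(f"sweep failed at scale {scale}: {exc}") from exc
        points.append(SweepPoint(
            scale=scale,
            total_resistance=base_total_resistance * scale,
            flow=sol.lesion_flow,
            pressure_drop=sol.lesion_dp,
        ))
    return SweepResult(points=points)


def sweep_to_frame(sweep: SweepResult, patient_id: str = "") -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": patient_id,
        "scale": [p.scale for p in sweep.points],
        "total_resistance": [p.total_resistance for p in sweep.points],
        "Q_bar_cm3_s": [p.flow for p in sweep.points],
        "dp_bar_mmHg": [p.pressure_drop for p in sweep.points],
    })


def write_sweep_csv(sweeps: Mapping[str, SweepResult], path: str | Path) -> None:
    frames = [sweep_to_frame(s, pid) for pid, s in sweeps.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_sweep_csv(path: str | Path) -> dict[str, SweepResult]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, SweepResult] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("scale", ascending=False)
        out[str(pid)] = SweepResult(points=[
            SweepPoint(row.scale, row.total_resistance, row.Q_bar_cm3_s,
                       row.dp_bar_mmHg)
            for row in grp.itertuples()])
    return out
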