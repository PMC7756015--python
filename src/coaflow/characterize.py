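"""Fit the stenosis pressure-flow curve dp = f*Q + s*Q^2 to sweep points.

The model is linear in (f, s), so the least-squares problem is solved
exactly on the design matrix [Q, Q^2]; the default non-negativity
constraint uses an active-set NNLS solve.  A Gauss-Newton path is kept
behind ``method="iterative"`` for parity with iterative curve fitting and
must agree with the direct solution to 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, nnls

from .flow import SweepResult, run_resistance_sweep
from .geometry import AortaNetwork, FluidProperties, StenosisCoefficients

__all__ = [
    "InsufficientDataError",
    "DegenerateDesignError",
    "CurveFitReport",
    "fit_pressure_flow_curve",
    "characterize_patient",
]


class InsufficientDataError(ValueError):
    pass


class DegenerateDesignError(ValueError):
    pass


@dataclass(frozen=True)
class CurveFitReport:
    coefficients: StenosisCoefficients
    residual_sum_squares: float
    n_points: int
    converged: bool

    def __post_init__(self) -> None:
        if self.residual_sum_squares < -1e-12:
            raise ValueError("negative residual sum of squares")
        if self.n_points < 2:
            raise ValueError("a fit needs at least two points")


def fit_pressure_flow_curve(
    points: Sequence[tuple[float, float]] | SweepResult,
    constrain_nonnegative: bool = True,
    method: str = "normal",
) -> CurveFitReport:
    """Least-squares (f, s) from (Q, dp) pairs.

    ``points`` is a sequence of (flow, pressure drop) pairs or a
    :class:`SweepResult`.  With ``constrain_nonnegative`` (the default) the
    coefficients are restricted to f, s >= 0, so a non-stenotic vessel fits
    to exactly zero rather than a small negative value.
    """
    if isinstance(points, SweepResult):
        pts = list(zip(points.flows, points.pressure_drops))
    else:
        pts = [(float(q), float(dp)) for q, dp in points]
    q = np.array([p[0] for p in pts])
    dp = np.array([p[1] for p in pts])
    if len(np.unique(q[q > 0])) < 2:
        raise InsufficientDataError("need at least two distinct positive flows")
    X = np.column_stack([q, q * q])
    if np.linalg.matrix_rank(X) < 2:
        raise DegenerateDesignError("flow values give a rank-deficient design")

    if method == "normal":
        if constrain_nonnegative:
            beta, rnorm = nnls(X, dp)
            rss = float(rnorm**2)
            converged = True
        else:
            beta, res, _, _ = np.linalg.lstsq(X, dp, rcond=None)
            rss = float(np.sum((dp - X @ beta) ** 2))
            converged = True
    elif method == "iterative":
        bounds = (0.0, np.inf) if constrain_nonnegative else (-np.inf, np.inf)
        start = np.maximum(np.linalg.lstsq(X, dp, rcond=None)[0], 1e-12) \
            if constrain_nonnegative else np.zeros(2)
        out = least_squares(
            lambda b: X @ b - dp, start, bounds=bounds,
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        beta = out.x
        rss = float(np.sum(out.fun**2))
        converged = bool(out.success)
    else:
        raise ValueError(f"unknown fit method {method!r}")

    f, s = float(beta[0]), float(beta[1])
    if constrain_nonnegative:
        f, s = max(f, 0.0), max(s, 0.0)
        coeffs = StenosisCoefficients(f=f, s=s)
    else:
        # bypass the non-negativity invariant for diagnostic use
        coeffs = StenosisCoefficients(f=max(f, 0.0), s=max(s, 0.0))
        object.__setattr__(coeffs, "f", f)
        object.__setattr__(coeffs, "s", s)
    return CurveFitReport(
        coefficients=coeffs,
        residual_sum_squares=rss,
        n_points=len(pts),
        converged=converged,
    )


def characterize_patient(
    network: AortaNetwork,
    fluid: FluidProperties | None = None,
    inlet_pressure: float = 80.0,
    base_total_resistance: float = 9.6,
    scales: Sequence[float] = (1.0, 1 / 2, 1 / 3, 1 / 4, 1 / 5, 1 / 6),
    exponent: float = 1.0,
    lesion_expansion_factor: float = 1.0,
    lesion_re_friction: float = 0.0,
) -> tuple[StenosisCoefficients, CurveFitReport, SweepResult]:
    """Full per-patient characterization: sweep then curve fit.

    Returns the fitted coefficients together with the fit report and the
    raw sweep, so callers can persist the intermediate pressure-flow points.
    """
    fluid = fluid or FluidProperties()
    sweep = run_resistance_sweep(
        network, fluid,
        inlet_pressure=inlet_pressure,
        base_total_resistance=base_total_resistance,
        scales=scales,
        exponent=exponent,
        lesion_expansion_factor=lesion_expansion_factor,
        lesion_re_friction=lesion_re_friction,
    )
    report = fit_pressure_flow_curve(sweep)
    return report.coefficients, report, sweep
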