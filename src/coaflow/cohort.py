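"""Virtual pediatric cohort generator.

Stands in for the study population: pediatric patients with a
variable-severity isthmus coarctation, a catheterization-style peak
systolic pressure gradient (PSPG) reference measurement, and the 20 mmHg
diagnostic label.  Each patient carries a full arch network (ascending
aorta, three supra-aortic branch outlets, isthmus lesion, descending
aorta), BSA-scaled dimensions, and a peak-systolic flow that is distinct
from the resting flows used by the diagnostic resistance sweep — that
deliberate asymmetry (labels from peak flow, features from resting
hemodynamics) is what makes classification imperfect.

The stenosis-severity prior is calibrated per cohort: all patient-level
random draws are made first, then the severity location parameter is found
by bisection so the realized number of PSPG-positive patients matches the
target prevalence.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    AortaNetwork,
    FluidProperties,
    InvalidGeometryError,
    Junction,
    Outlet,
    StenosisCoefficients,
    VesselSegment,
    narrowing_rate,
    network_from_dict,
    network_to_dict,
    stenosis_true_coefficients,
)
from .flow import _element_dp

COHORT_SCHEMA_VERSION = "1.0"
PSPG_CUTOFF_MMHG = 20.0

__all__ = [
    "CalibrationError",
    "CohortConfig",
    "VirtualPatient",
    "Cohort",
    "sample_patient_geometry",
    "reference_pspg",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Priors and noise levels of the virtual cohort.

    Defaults emulate the target study composition: n = 65 with a 38/65
    CoA prevalence, ages 1 month to 14 years (log-normal, median one year),
    ~54% male, and BSA growing with age around 0.5 m^2.  Stenosis severity
    (fractional diameter narrowing at the isthmus) is normal with sd
    ``severity_sd`` around a location calibrated to the prevalence; peak
    isthmus flow scales with BSA (150 cm^3/s per m^2) with log-normal
    patient variability; the measured PSPG adds truncated-Gaussian noise
    of ``pspg_noise_sd`` mmHg to the reference value.
    """

    n: int = 65
    target_prevalence: float = 38.0 / 65.0
    seed: int = 42

    # covariates
    age_log_median_months: float = 12.0
    age_log_sd: float = 1.0
    age_range_months: tuple[float, float] = (1.0, 168.0)
    male_fraction: float = 0.54
    bsa_noise_sd: float = 0.08

    # geometry priors
    isthmus_radius_cm_at_bsa_05: float = 0.40   # reference (pre-lesion) radius
    severity_sd: float = 0.15
    severity_range: tuple[float, float] = (0.02, 0.85)
    severity_location_bounds: tuple[float, float] = (0.01, 0.84)
    lesion_length_cm_at_bsa_05: float = 0.8
    lesion_length_log_sd: float = 0.45
    lesion_length_range_cm: tuple[float, float] = (0.2, 3.0)
    throat_fraction_range: tuple[float, float] = (0.2, 0.8)
    lesion_plane_jitter_cm: float = 0.0

    # hemodynamic priors
    peak_flow_scale: float = 150.0              # cm^3/s per m^2 BSA
    peak_flow_log_sd: float = 0.25
    pspg_noise_sd: float = 2.0                  # mmHg

    # model-mismatch knobs (defaults: matched physics)
    expansion_factor_range: tuple[float, float] = (1.0, 1.0)
    re_friction_coefficient: float = 0.0        # lesion m = coeff * f_true

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.pspg_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class VirtualPatient:
    id: str
    age_months: float
    sex: int                      # 1 = male
    bsa: float                    # m^2
    network: AortaNetwork
    peak_flow: float              # cm^3/s
    pspg_reference: float         # mmHg, noiseless
    pspg_measured: float          # mmHg, with catheterization noise
    coa_label: int
    severity: float               # fractional diameter narrowing drawn
    expansion_factor: float = 1.0
    re_friction: float = 0.0      # lesion mismatch term m

    @property
    def narrowing_rate(self) -> float:
        return narrowing_rate(self.network)


@dataclass
class Cohort:
    patients: list[VirtualPatient]
    config: CohortConfig
    severity_location: float      # calibrated prior location

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append({
                "patient_id": p.id,
                "age_months": p.age_months,
                "sex": p.sex,
                "bsa": p.bsa,
                "peak_flow": p.peak_flow,
                "pspg_reference": p.pspg_reference,
                "pspg_measured": p.pspg_measured,
                "coa_label": p.coa_label,
                "narrowing_rate": p.narrowing_rate,
                "severity": p.severity,
            })
        return pd.DataFrame(rows)

    @property
    def n_positive(self) -> int:
        return sum(p.coa_label for p in self.patients)


# ---------------------------------------------------------------------------
# Geometry construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PatientDraw:
    """All patient-level randomness, drawn once; geometry is then a
    deterministic function of the draw and the severity location."""

    age_months: float
    sex: int
    bsa: float
    severity_z: float             # standard-normal severity innovation
    length_z: float
    throat_u: float
    flow_z: float
    noise_z: float
    expansion_u: float
    jitter_z: float


def _draw_patient(config: CohortConfig, rng: np.random.Generator) -> _PatientDraw:
    age = float(np.clip(
        math.exp(rng.normal(math.log(config.age_log_median_months),
                            config.age_log_sd)),
        *config.age_range_months))
    sex = int(rng.random() < config.male_fraction)
    age_y = age / 12.0
    bsa = float(np.clip(
        (0.22 + 0.25 * age_y**0.6) * (1.0 + rng.normal(0.0, config.bsa_noise_sd)),
        0.2, 1.8))
    return _PatientDraw(
        age_months=age, sex=sex, bsa=bsa,
        severity_z=float(rng.normal()),
        length_z=float(rng.normal()),
        throat_u=float(rng.random()),
        flow_z=float(rng.normal()),
        noise_z=float(rng.normal()),
        expansion_u=float(rng.random()),
        jitter_z=float(rng.normal()),
    )


def _severity(draw: _PatientDraw, location: float, config: CohortConfig) -> float:
    return float(np.clip(location + config.severity_sd * draw.severity_z,
                         *config.severity_range))


def _build_network(draw: _PatientDraw, severity: float,
                   config: CohortConfig) -> AortaNetwork:
    """Deterministic arch network from one patient draw.

    Fixed topology: ascending aorta -> brachiocephalic outlet -> arch A ->
    left carotid outlet -> arch B -> left subclavian outlet -> isthmus
    (lesion) -> descending aorta -> descending outlet.  All radii scale as
    sqrt(BSA); the aorta regains its reference caliber at the diaphragm, so
    the ESC narrowing rate equals the drawn severity (up to plane jitter).
    """
    scale = math.sqrt(draw.bsa / 0.5)
    r_ref = config.isthmus_radius_cm_at_bsa_05 * scale
    r_min = r_ref * (1.0 - severity)
    l_les = float(np.clip(
        config.lesion_length_cm_at_bsa_05 * scale * math.exp(
            config.lesion_length_log_sd * draw.length_z),
        *config.lesion_length_range_cm))
    throat = (config.throat_fraction_range[0]
              + draw.throat_u * (config.throat_fraction_range[1]
                                 - config.throat_fraction_range[0]))

    # isthmus segment: entry run, taper, throat, recovery taper, exit run
    entry = 0.4 * scale
    exit_run = 0.6 * scale
    taper = 0.5 * (1.0 - throat) * l_les
    lesion_start = entry
    lesion_end = entry + l_les
    length = entry + l_les + exit_run
    profile = [
        (0.0, r_ref),
        (lesion_start, r_ref),
        (lesion_start + taper, r_min),
        (lesion_end - taper, r_min),
        (lesion_end, r_ref),
        (length, r_ref),
    ]
    # collapse coincident knots (throat -> 1 gives taper -> 0)
    prof = [profile[0]]
    for x, r in profile[1:]:
        if x - prof[-1][0] > 1e-9:
            prof.append((x, r))
    jitter = config.lesion_plane_jitter_cm * draw.jitter_z
    ls = float(np.clip(lesion_start + jitter, 0.0, lesion_start + taper))
    le = float(np.clip(lesion_end - jitter, lesion_end - taper, length))
    if le <= ls:
        ls, le = lesion_start, lesion_end

    r_asc = 1.5 * r_ref
    d_asc = 2.0 * r_asc
    segments = [
        VesselSegment("ascending", 2.5 * scale,
                      [(0.0, r_asc), (2.5 * scale, 1.4 * r_ref)]),
        VesselSegment("arch_a", 1.2 * scale,
                      [(0.0, 1.4 * r_ref), (1.2 * scale, 1.25 * r_ref)]),
        VesselSegment("arch_b", 1.2 * scale,
                      [(0.0, 1.25 * r_ref), (1.2 * scale, r_ref)]),
        VesselSegment("isthmus", length, prof, is_lesion=True,
                      lesion_start=ls, lesion_end=le),
        VesselSegment("descending", 6.0 * scale,
                      [(0.0, r_ref), (6.0 * scale, 0.95 * r_ref)]),
    ]
    outlets = [
        Outlet("brachiocephalic", 0.50 * d_asc),
        Outlet("left_carotid", 0.30 * d_asc),
        Outlet("left_subclavian", 0.35 * d_asc),
        Outlet("descending_outlet", 2.0 * 0.95 * r_ref),
    ]
    junctions = [
        Junction("ascending", "arch_a", "brachiocephalic"),
        Junction("arch_a", "arch_b", "left_carotid"),
        Junction("arch_b", "isthmus", "left_subclavian"),
        Junction("isthmus", "descending", None),
        Junction("descending", None, "descending_outlet"),
    ]
    return AortaNetwork(
        segments=segments, junctions=junctions, outlets=outlets,
        inlet_segment="ascending", diaphragm_diameter=2.0 * r_ref,
    )


def sample_patient_geometry(
    config: CohortConfig,
    rng: np.random.Generator,
    severity_location: float = 0.45,
    max_resamples: int = 20,
) -> AortaNetwork:
    """Draw one arch network from the geometry priors.

    Invalid draws (degenerate profiles from extreme prior combinations) are
    rejected and resampled, up to ``max_resamples`` attempts.
    """
    for _ in range(max_resamples):
        draw = _draw_patient(config, rng)
        severity = _severity(draw, severity_location, config)
        try:
            return _build_network(draw, severity, config)
        except InvalidGeometryError:
            continue
    raise CalibrationError("geometry priors kept producing invalid networks")


# ---------------------------------------------------------------------------
# Reference PSPG and cohort generation
# ---------------------------------------------------------------------------

def reference_pspg(
    network: AortaNetwork,
    fluid: FluidProperties,
    peak_flow: float,
    expansion_factor: float = 1.0,
    re_friction: float = 0.0,
) -> float:
    """Noiseless catheterization ground truth: the lesion's true
    pressure-flow law evaluated at peak-systolic flow."""
    if peak_flow <= 0:
        raise ValueError("peak flow must be positive")
    coeffs = stenosis_true_coefficients(network, fluid, expansion_factor)
    return _element_dp(coeffs.f, coeffs.s, re_friction, peak_flow)


def _patient_from_draw(
    draw: _PatientDraw, severity_location: float, config: CohortConfig,
    fluid: FluidProperties, patient_id: str,
) -> VirtualPatient:
    severity = _severity(draw, severity_location, config)
    network = _build_network(draw, severity, config)
    k_lo, k_hi = config.expansion_factor_range
    k_e = k_lo + draw.expansion_u * (k_hi - k_lo)
    coeffs = stenosis_true_coefficients(network, fluid, k_e)
    m = config.re_friction_coefficient * coeffs.f
    peak_flow = config.peak_flow_scale * draw.bsa * math.exp(
        config.peak_flow_log_sd * draw.flow_z)
    ref = reference_pspg(network, fluid, peak_flow, k_e, m)
    measured = max(0.0, ref + config.pspg_noise_sd * draw.noise_z)
    return VirtualPatient(
        id=patient_id,
        age_months=draw.age_months,
        sex=draw.sex,
        bsa=draw.bsa,
        network=network,
        peak_flow=peak_flow,
        pspg_reference=ref,
        pspg_measured=measured,
        coa_label=int(measured >= PSPG_CUTOFF_MMHG),
        severity=severity,
        expansion_factor=k_e,
        re_friction=m,
    )


def generate_cohort(config: CohortConfig,
                    fluid: FluidProperties | None = None) -> Cohort:
    """Generate a cohort with the prevalence-calibrated severity prior.

    All patient-level randomness is drawn first; the severity location is
    then found by bisection so the realized positive count equals
    ``round(n * target_prevalence)``.  Each patient's label is monotone in
    the location (more severe -> higher PSPG), so the count is a monotone
    step function and the bisection is exact up to ties.
    """
    fluid = fluid or FluidProperties()
    rng = np.random.default_rng(config.seed)
    draws = [_draw_patient(config, rng) for _ in range(config.n)]

    def positives(location: float) -> int:
        total = 0
        for i, d in enumerate(draws):
            p = _patient_from_draw(d, location, config, fluid, f"p{i:03d}")
            total += p.coa_label
        return total

    target = int(round(config.n * config.target_prevalence))
    lo, hi = config.severity_location_bounds
    if positives(lo) > target or positives(hi) < target:
        raise CalibrationError(
            "target prevalence unreachable within the severity prior bounds")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if positives(mid) < target:
            lo = mid
        else:
            hi = mid
    location = hi  # smallest location reaching the target count

    patients = [
        _patient_from_draw(d, location, config, fluid, f"p{i:03d}")
        for i, d in enumerate(draws)
    ]
    realized = sum(p.coa_label for p in patients)
    if abs(realized - config.n * config.target_prevalence) > \
            0.1 * config.n * config.target_prevalence:
        raise CalibrationError(
            f"realized prevalence {realized}/{config.n} misses the target "
            f"{config.target_prevalence:.3f} by more than 10%")
    return Cohort(patients=patients, config=config, severity_location=location)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, path: str | Path) -> None:
    data = {
        "schema_version": COHORT_SCHEMA_VERSION,
        "config": asdict(cohort.config),
        "severity_location": cohort.severity_location,
        "patients": [
            {**{k: v for k, v in vars(p).items() if k != "network"},
             "network": network_to_dict(p.network)}
            for p in cohort.patients
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def load_cohort(path: str | Path) -> Cohort:
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != COHORT_SCHEMA_VERSION:
        raise ValueError("unsupported cohort schema")
    cfg_raw = dict(data["config"])
    for key, val in cfg_raw.items():
        if isinstance(val, list):
            cfg_raw[key] = tuple(val)
    config = CohortConfig(**cfg_raw)
    patients = []
    for praw in data["patients"]:
        praw = dict(praw)
        network = network_from_dict(praw.pop("network"))
        patients.append(VirtualPatient(network=network, **praw))
    return Cohort(patients=patients, config=config,
                  severity_location=data["severity_location"])
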