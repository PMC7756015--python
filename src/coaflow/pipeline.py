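"""End-to-end pipeline: cohort generation, per-patient characterization,
cross-validated diagnosis, and the ESC comparison, with file outputs.

The pipeline is a pure function of its configuration (all randomness flows
from the seed), so two runs with the same config produce identical
reports.  Outputs: a feature table CSV (per-patient f, s, narrowing rate,
PSPG, label), a sweep CSV, a fold-assignment CSV, and a report JSON with
per-fold and average metrics for the combined, single-feature and ESC
classifiers plus the Spearman correlation matrix of (PSPG, f, s).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .characterize import characterize_patient
from .cohort import Cohort, CohortConfig, generate_cohort
from .crossval import CrossValResult, cross_validate
from .diagnosis import spearman_matrix
from .flow import DEFAULT_SWEEP_SCALES, write_sweep_csv
from .geometry import FluidProperties

log = logging.getLogger("coaflow")

REPORT_SCHEMA_VERSION = "1.0"

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "build_feature_table", "load_run_config", "save_run_config"]


@dataclass(frozen=True)
class RunConfig:
    inlet_pressure: float = 80.0            # mmHg
    base_total_resistance: float = 9.6      # mmHg·s/cm^3
    sweep_scales: tuple[float, ...] = DEFAULT_SWEEP_SCALES
    resistance_exponent: float = 1.0        # 1 = inverse diameters, 3 = Murray
    fluid: FluidProperties = field(default_factory=FluidProperties)
    k_folds: int = 5
    seed: int = 42
    cohort: CohortConfig = field(default_factory=CohortConfig)
    threshold_rule: str = "youden"

    def __post_init__(self) -> None:
        if self.inlet_pressure <= 0 or self.base_total_resistance <= 0:
            raise ValueError("physical parameters must be positive")
        scales = tuple(self.sweep_scales)
        if len(set(scales)) != len(scales) or any(not 0 < s <= 1 for s in scales):
            raise ValueError("sweep scales must be distinct and in (0, 1]")


@dataclass
class PipelineResult:
    cohort: Cohort
    features: pd.DataFrame
    crossval: CrossValResult
    report: dict


def build_feature_table(cohort: Cohort, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Characterize every patient: resting sweep -> curve fit -> (f, s)."""
    rows, sweeps = [], {}
    for p in cohort.patients:
        coeffs, fit, sweep = characterize_patient(
            p.network, config.fluid,
            inlet_pressure=config.inlet_pressure,
            base_total_resistance=config.base_total_resistance,
            scales=config.sweep_scales,
            exponent=config.resistance_exponent,
            lesion_expansion_factor=p.expansion_factor,
            lesion_re_friction=p.re_friction,
        )
        sweeps[p.id] = sweep
        rows.append({
            "patient_id": p.id,
            "f": coeffs.f,
            "s": coeffs.s,
            "residual_sum_squares": fit.residual_sum_squares,
            "narrowing_rate": p.narrowing_rate,
            "pspg_measured": p.pspg_measured,
            "coa_label": p.coa_label,
            "sex": p.sex,
            "age_months": p.age_months,
            "bsa": p.bsa,
        })
    return pd.DataFrame(rows), sweeps


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Generate, characterize, cross-validate; optionally write outputs."""
    log.info("generating cohort (n=%d, seed=%d)", config.cohort.n, config.seed)
    cohort_config = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = generate_cohort(cohort_config, config.fluid)
    log.info("cohort: %d positive / %d negative",
             cohort.n_positive, len(cohort.patients) - cohort.n_positive)

    features, sweeps = build_feature_table(cohort, config)
    cv = cross_validate(features, k=config.k_folds, seed=config.seed,
                        threshold_rule=config.threshold_rule)

    corr = spearman_matrix({
        "pspg": features.pspg_measured,
        "f": features.f,
        "s": features.s,
    })

    averages = cv.averages()
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": _config_to_dict(config),
        "cohort": {
            "n": len(cohort.patients),
            "n_positive": int(cohort.n_positive),
            "n_negative": int(len(cohort.patients) - cohort.n_positive),
            "severity_location": cohort.severity_location,
        },
        "per_fold": json.loads(cv.to_frame().to_json(orient="records")),
        "averages": json.loads(averages.to_json(orient="records")),
        "spearman": {
            "rho": corr.rho.to_dict(),
            "p": corr.p.to_dict(),
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        features.to_csv(outdir / "features.csv", index=False, float_format="%.17g")
        write_sweep_csv(sweeps, outdir / "sweeps.csv")
        pd.DataFrame({
            "patient_id": features.patient_id,
            "fold": cv.folds.fold_index,
        }).to_csv(outdir / "folds.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        averages.to_csv(outdir / "summary.csv", index=False)
        log.info("wrote outputs to %s", outdir)

    return PipelineResult(cohort=cohort, features=features, crossval=cv,
                          report=report)


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def _config_to_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["sweep_scales"] = list(d["sweep_scales"])
    return d


def save_run_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = _config_to_dict(config)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=1, sort_keys=True))


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = path.read_text()
    data = yaml.safe_load(raw) if path.suffix in (".yml", ".yaml") else json.loads(raw)
    fluid = FluidProperties(**data.pop("fluid", {}))
    cohort_raw = data.pop("cohort", {})
    for key, val in cohort_raw.items():
        if isinstance(val, list):
            cohort_raw[key] = tuple(val)
    cohort = CohortConfig(**cohort_raw)
    if "sweep_scales" in data:
        data["sweep_scales"] = tuple(data["sweep_scales"])
    return RunConfig(fluid=fluid, cohort=cohort, **data)
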