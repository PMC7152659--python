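"""Structured JSON reports with schema validation.

Every pipeline artifact records the seed and a config hash so it can be
reproduced bit-for-bit.  Reports are pydantic models; the JSON schemas
shipped under ``halokin/schemas/`` are generated from these models and a
report is validated simply by constructing the model from its dict.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field

__all__ = ["FitReport", "MsmReport", "validate_report", "write_report", "export_schemas"]


class DerivedConstants(BaseModel):
    kcat: float | None = None
    kcat_se: float | None = None
    Km: float | None = None
    Km_se: float | None = None
    Ks: float | None = None
    Ks_se: float | None = None
    kcat_over_Km: float | None = None
    kcat_over_Km_se: float | None = None
    rate_limiting_step: list[str] = Field(default_factory=list)


class ContourSummary(BaseModel):
    parameter: str
    lower: float | None
    upper: float | None
    threshold: float
    lower_bounded_only: bool = False


class FitReport(BaseModel):
    kind: str = "fit"
    seed: int
    config_hash: str
    scheme: str
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    chi2_min: float
    n_points: int
    n_params: int
    converged: bool
    identifiability_flags: dict[str, str] = Field(default_factory=dict)
    derived: DerivedConstants = Field(default_factory=DerivedConstants)
    contours: list[ContourSummary] = Field(default_factory=list)


class MsmReport(BaseModel):
    kind: str = "msm"
    seed: int
    config_hash: str
    lag: int
    n_states: int
    dropped_states: list[int] = Field(default_factory=list)
    equilibrium_distribution: list[float]
    # None encodes an infinite/undefined timescale in JSON
    implied_timescales: dict[str, list[float | None]] = Field(default_factory=dict)
    ck_max_discrepancy: dict[str, float] = Field(default_factory=dict)
    channel_fractions: dict[str, float] = Field(default_factory=dict)
    nac_fraction: float | None = None


_MODELS = {"fit": FitReport, "msm": MsmReport}


def validate_report(data: dict):
    """Validate a report dict against its model; returns the typed report."""
    kind = data.get("kind")
    if kind not in _MODELS:
        raise ValueError(f"unknown report kind {kind!r}")
    return _MODELS[kind].model_validate(data)


def _sanitize(obj):
    """NaN/inf are not valid JSON; map them to null."""
    import math

    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_sanitize(v) for v in obj]
    return obj


def write_report(path, report: BaseModel) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clean = _sanitize(report.model_dump(mode="python"))
    path.write_text(json.dumps(clean, indent=2, allow_nan=False) + "\n")


def export_schemas(directory) -> None:
    """Write the JSON schema files for all report kinds."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, model in _MODELS.items():
        schema = model.model_json_schema()
        (directory / f"{kind}_report.schema.json").write_text(
            json.dumps(schema, indent=2) + "\n"
        )
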