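"""CSV/YAML input-output: traces, rate tables, trajectories, configs.

All tabular data are plain CSV.  Metadata (units, seeds, generating
parameters) travel as '#'-prefixed header lines so files stay
self-describing and round-trip losslessly.  All concentrations are uM,
times s, distances Angstrom.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mechanism import (
    SPECIES,
    ConfigurationError,
    Mechanism,
    RateParameters,
    build_mechanism,
)
from .observables import SignalCoefficients
from .synthetic import InitialRatePoint, KineticDataset, Trace

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_initial_rates_csv", "read_initial_rates_csv",
    "write_timecourse_csv", "write_trajectory_csv", "read_trajectory_csv",
    "load_config", "config_hash",
    "mechanism_from_config", "rates_from_config", "coeffs_from_config",
]


def _write_with_meta(path, df: pd.DataFrame, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {json.dumps(v) if not isinstance(v, str) else v}\n")
        df.to_csv(fh, index=False)


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            try:
                meta[key.strip()] = json.loads(val.strip())
            except (json.JSONDecodeError, ValueError):
                meta[key.strip()] = val.strip()
    return meta


def write_trace_csv(path, trace: Trace, extra_meta: dict | None = None) -> None:
    meta = {
        "units": "time_s, signal (a.u.), sigma (a.u.)",
        "E0_nominal_uM": trace.E0_nominal,
        "S0_nominal_uM": trace.S0_nominal,
        "E0_true_uM": trace.E0_true,
        "S0_true_uM": trace.S0_true,
        **(extra_meta or {}),
    }
    df = pd.DataFrame({"time_s": trace.time, "signal": trace.signal, "sigma": trace.sigma})
    _write_with_meta(path, df, meta)


def read_trace_csv(path) -> Trace:
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as e:
        raise ConfigurationError(f"unreadable trace CSV {path}: {e}") from e
    for col in ("time_s", "signal", "sigma"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing required column {col!r}")
    return Trace(
        time=df["time_s"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        sigma=df["sigma"].to_numpy(float),
        E0_nominal=float(meta.get("E0_nominal_uM", np.nan)),
        S0_nominal=float(meta.get("S0_nominal_uM", np.nan)),
        E0_true=float(meta.get("E0_true_uM", meta.get("E0_nominal_uM", np.nan))),
        S0_true=float(meta.get("S0_true_uM", meta.get("S0_nominal_uM", np.nan))),
        meta=meta,
    )


def write_initial_rates_csv(path, dataset: KineticDataset, extra_meta: dict | None = None) -> None:
    rows = dataset.initial_rates
    df = pd.DataFrame(
        {
            "S_uM": [p.S0 for p in rows],
            "E_uM": [p.E0 for p in rows],
            "v_uM_per_s": [p.v0 for p in rows],
            "sigma": [p.sigma for p in rows],
        }
    )
    meta = {"units": "S_uM, E_uM, v_uM_per_s, sigma (uM/s)", **(extra_meta or {})}
    _write_with_meta(path, df, meta)


def read_initial_rates_csv(path) -> KineticDataset:
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as e:
        raise ConfigurationError(f"unreadable initial-rate CSV {path}: {e}") from e
    pts = [
        InitialRatePoint(r.S_uM, r.E_uM, r.v_uM_per_s, r.sigma)
        for r in df.itertuples()
    ]
    return KineticDataset(initial_rates=pts, truth=meta)


def write_timecourse_csv(path, time_grid, states, meta: dict | None = None) -> None:
    df = pd.DataFrame(states, columns=list(SPECIES))
    df.insert(0, "time_s", time_grid)
    _write_with_meta(path, df, meta or {"units": "time_s; concentrations uM"})


def write_trajectory_csv(path, state_seq, features=None, meta: dict | None = None) -> None:
    df = pd.DataFrame({"frame": np.arange(len(state_seq)), "state": state_seq})
    if features is not None:
        for j in range(features.shape[1]):
            df[f"feat_{j + 1}"] = features[:, j]
    _write_with_meta(path, df, meta or {})


def read_trajectory_csv(path) -> tuple[np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path, comment="#")
    if "state" not in df.columns:
        raise ConfigurationError(f"{path}: missing required column 'state'")
    if df.empty:
        raise ConfigurationError(f"{path}: empty trajectory file")
    feats = [c for c in df.columns if c.startswith("feat_")]
    X = df[feats].to_numpy(float) if feats else None
    return df["state"].to_numpy(np.int64), X


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for provenance stamping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def mechanism_from_config(block: dict) -> Mechanism:
    if "scheme" not in block:
        raise ConfigurationError("mechanism block: missing required field 'scheme'")
    return build_mechanism(block["scheme"], bool(block.get("rapid_equilibrium", False)))


def rates_from_config(block: dict) -> RateParameters:
    rates = dict(block.get("rates", {}))
    status = rates.pop("status", block.get("status", {}))
    known = {"k1", "k_minus1", "k2", "k3", "k4", "k_minus4", "Ks"}
    bad = set(rates) - known
    if bad:
        raise ConfigurationError(f"mechanism block: unknown rate field(s) {sorted(bad)}")
    return RateParameters(status=status, **rates)


def coeffs_from_config(block: dict | None) -> SignalCoefficients | None:
    if not block:
        return None
    if "channel" not in block:
        raise ConfigurationError("observable block: missing required field 'channel'")
    return SignalCoefficients(**block)
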