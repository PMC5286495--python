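"""Observation-table and report I/O plus flat key=value config files."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimation import OBS_COLUMNS, FitResult
from .sensitivity import SensitivityReport

__all__ = ["read_observations", "write_report", "read_config", "result_to_dict"]

SCHEMA_VERSION = 1


def read_observations(path) -> pd.DataFrame:
    """Read an observations CSV (``t_days,replicate,X,N,L``; optional leading
    ``condition`` column).

    Blank N or L cells become missing values (never zeros).  Malformed numeric
    cells raise with the offending 1-based data row number; duplicate
    (replicate, t) pairs are rejected.  Rows are returned sorted by
    (replicate, t).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = list(df.columns)
    has_condition = cols and cols[0] == "condition"
    expected = (["condition"] if has_condition else []) + list(OBS_COLUMNS)
    if cols != expected:
        raise ValueError(
            f"{path.name}: header must be {','.join(OBS_COLUMNS)} "
            f"(optionally preceded by 'condition'), got {','.join(cols)}"
        )
    out = pd.DataFrame()
    if has_condition:
        out["condition"] = df["condition"].astype(str)
    for col in OBS_COLUMNS:
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path.name}: malformed numeric value {raw[bad.idxmax()]!r} "
                f"in column {col!r}, data row {row}"
            )
        if col in ("t_days", "replicate") and numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 1
            raise ValueError(f"{path.name}: missing {col} in data row {row}")
        out[col] = numeric
    keys = (["condition"] if has_condition else []) + ["replicate", "t_days"]
    dup = out.duplicated(subset=keys)
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise ValueError(f"{path.name}: duplicate (replicate, t) pair at data row {row}")
    return out.sort_values(keys, kind="mergesort").reset_index(drop=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isinf(f):
            return "Infinity" if f > 0 else "-Infinity"
        if math.isnan(f):
            return "NaN"
        return f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def result_to_dict(result) -> dict:
    """Serialize a FitResult or SensitivityReport to plain JSON-able data."""
    if isinstance(result, FitResult):
        return {
            "kind": "fit",
            "parameters": _jsonable(result.params),
            "state": _jsonable(dataclasses.asdict(result.state)),
            "r_squared": _jsonable(result.r_squared),
            "objective": result.objective,
            "converged": result.converged,
            "n_evaluations": result.n_evaluations,
            "multistart_objectives": _jsonable(result.multistart_objectives),
            "warnings": list(result.warnings),
            "frozen": _jsonable(result.frozen),
        }
    if isinstance(result, SensitivityReport):
        return {
            "kind": "sensitivity",
            "horizon_days": result.horizon,
            "delta": result.delta,
            "n_grid": result.n_grid,
            "critical_value": result.critical_value,
            "baseline_final_lipid": result.baseline_final_lipid,
            "parameters": _jsonable(result.parameters),
        }
    return _jsonable(result)


def write_report(result, path, *, seed=None, config=None) -> None:
    """Write a JSON report with schema version and a provenance block."""
    payload = result_to_dict(result)
    config_repr = json.dumps(_jsonable(config), sort_keys=True) if config is not None else ""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "tool": "algalipid",
            "version": __version__,
            "seed": seed,
            "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest() if config_repr else None,
        },
        **payload,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config(path, known_keys=None) -> dict:
    """Read a flat ``key = value`` config file ('#' starts a comment).

    Values are parsed as int, then float, then left as strings.  With
    ``known_keys`` given, an unknown key raises naming the offending key.
    """
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected 'key = value', got {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if known_keys is not None and key not in known_keys:
            raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
        for cast in (int, float):
            try:
                value = cast(value)
                break
            except ValueError:
                continue
        out[key] = value
    return out
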