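"""Schema-validated readers and writers for the package's table dialects.

All tables are plain UTF-8 CSV with a header row and "." decimals; units
are fixed by the schemas (temperatures °C, energy W, mass g, water
mg min⁻¹, flow ml min⁻¹ STP) to avoid silent unit drift.  JSON results
carry a format version and a hash of the configuration that produced them
and round-trip losslessly (NaN serialises as null).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STEADY_STATE_SCHEMA",
    "RAW_TRACE_SCHEMA",
    "MASK_SESSION_SCHEMA",
    "SchemaError",
    "read_table",
    "read_steady_state",
    "read_raw_trace",
    "read_mask_session",
    "write_results",
    "read_results",
]

FORMAT_VERSION = 1

#: column -> required dtype kind ("f" numeric, "s" string-like)
STEADY_STATE_SCHEMA = {
    "bird_id": "s",
    "group": "s",
    "acclimation": "s",
    "ta_c": "f",
    "mb_g": "f",
    "vo2_mlmin": "f",
    "vco2_mlmin": "f",
    "ewl_mgmin": "f",
    "mr_w": "f",
    "ehl_w": "f",
    "tb_c": "f",
}

RAW_TRACE_SCHEMA = {
    "time_s": "f",
    "channel": "s",
    "feo2": "f",
    "feco2": "f",
    "ph2o_kpa": "f",
    "flow_mlmin": "f",
    "ta_c": "f",
}

MASK_SESSION_SCHEMA = {
    "bird_id": "s",
    "ta_set_c": "f",
    "line": "s",
    "feo2": "f",
    "feco2": "f",
    "ph2o_kpa": "f",
    "bp_kpa": "f",
    "flow_mlmin": "f",
}


class SchemaError(ValueError):
    """A table failed schema validation; nothing was read."""


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read and validate a CSV against a column schema.

    Missing or non-numeric-where-required columns raise :class:`SchemaError`
    naming the offending column; an empty file raises explicitly.  Empty
    fields become NaN.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty: no header or rows") from None
    for col, kind in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path} is missing required column {col!r}")
        if kind == "f":
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                raise SchemaError(
                    f"{path}: column {col!r} must be numeric"
                ) from None
        else:
            df[col] = df[col].astype("string")
    return df


def read_steady_state(path) -> pd.DataFrame:
    return read_table(path, STEADY_STATE_SCHEMA)


def read_raw_trace(path):
    from .traces import RawTrace

    return RawTrace(read_table(path, RAW_TRACE_SCHEMA))


def read_mask_session(path) -> pd.DataFrame:
    return read_table(path, MASK_SESSION_SCHEMA)


def _clean(obj):
    """Make an object JSON-safe; NaN becomes null."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_clean(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def config_hash(config: dict | None) -> str:
    payload = json.dumps(_clean(config or {}), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_results(obj, path, config: dict | None = None, force: bool = False) -> Path:
    """Serialise a results object (anything with ``to_dict``, or a dict).

    Refuses to overwrite an existing file unless ``force``.  The payload is
    wrapped with a format version and a hash of the resolved configuration.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    doc = {
        "format_version": FORMAT_VERSION,
        "config_hash": config_hash(config),
        "payload": _clean(payload),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_results(path) -> dict:
    """Read a results JSON back; returns the payload dict (nulls → None)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported results format: {doc.get('format_version')!r}")
    return doc["payload"]
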