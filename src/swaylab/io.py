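"""Reading and writing stabilogram files.

Raw recordings are delimited text (CSV/TSV), one row per sample, with a
schema (YAML/JSON dict) naming the columns::

    columns:
      time_s: time        # optional if fs is declared
      cpf_x_cm: ml_cm
      cpf_y_cm: ap_cm
      mx_nm: mx           # optional
      my_nm: my           # optional
      fz: fz              # optional
    fs: 50                # optional if a time column is present
    metadata: {subject_id: S1, sex: female, age: 72, mass_kg: 68, condition: eyes_closed}

Missing optional channels yield a feature-limited recording. The sampling
rate is declared in the schema or inferred as 1/median(Δt) of the time
column. Preprocessed recordings are written back as CSV plus a JSON
provenance sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, FormatError
from .recording import StabilogramRecording, SubjectMeta

__all__ = ["load_schema", "read_recording", "write_recording"]

REQUIRED_COLUMNS = ("cpf_x_cm", "cpf_y_cm")
OPTIONAL_COLUMNS = ("mx_nm", "my_nm", "fz")


def load_schema(path) -> dict:
    """Load a YAML or JSON schema file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _meta_from_schema(schema: dict):
    md = schema.get("metadata")
    if not md:
        return None
    return SubjectMeta(
        subject_id=str(md.get("subject_id", "unknown")),
        sex=md["sex"],
        age=float(md["age"]),
        mass=float(md["mass_kg"]),
        condition=md.get("condition", "eyes_closed"),
    )


def read_recording(path, schema) -> StabilogramRecording:
    """Read one raw recording according to a column-mapping schema.

    ``schema`` is a dict (or a path loadable by :func:`load_schema`). Raises
    :class:`FormatError` for ragged columns or a non-monotone time column and
    :class:`ConfigError` when no sampling rate can be determined.
    """
    if not isinstance(schema, dict):
        schema = load_schema(schema)
    cols = schema.get("columns", {})
    for key in REQUIRED_COLUMNS:
        if key not in cols:
            raise ConfigError(f"schema is missing required column mapping {key!r}")
    sep = schema.get("delimiter")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")

    used = [v for v in cols.values() if v is not None]
    missing = [c for c in used if c not in df.columns]
    if missing:
        raise FormatError(f"file lacks mapped columns {missing}")
    if df[used].isna().any().any():
        raise FormatError("ragged input: mapped columns contain missing values")

    fs = schema.get("fs")
    if "time_s" in cols and cols["time_s"] in df.columns:
        t = df[cols["time_s"]].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError("time column is not strictly increasing")
        if fs is None:
            fs = 1.0 / float(np.median(dt))
    if fs is None:
        raise ConfigError("sampling rate undeclared and no time column to infer it")

    def get(key):
        name = cols.get(key)
        return None if name is None or name not in df.columns else df[
            name
        ].to_numpy(dtype=float)

    return StabilogramRecording(
        fs=float(fs),
        cpf_x=df[cols["cpf_x_cm"]].to_numpy(dtype=float),
        cpf_y=df[cols["cpf_y_cm"]].to_numpy(dtype=float),
        moment_x=get("mx_nm"),
        moment_y=get("my_nm"),
        weight=get("fz"),
        meta=_meta_from_schema(schema),
    )


def write_recording(recording: StabilogramRecording, path, provenance_path=None):
    """Write a recording as CSV (fixed column order) + JSON provenance block."""
    data = {"time_s": np.arange(len(recording)) / recording.fs}
    for name in ("cpf_x", "cpf_y", "moment_x", "moment_y", "weight", "weight_norm"):
        arr = getattr(recording, name)
        if arr is not None:
            data[name] = arr
    pd.DataFrame(data).to_csv(path, index=False)
    prov = {
        "fs": recording.fs,
        "preprocessed": recording.preprocessed,
        **recording.provenance,
    }
    if recording.meta is not None:
        prov["metadata"] = {
            "subject_id": recording.meta.subject_id,
            "sex": recording.meta.sex,
            "age": recording.meta.age,
            "mass_kg": recording.meta.mass,
            "condition": recording.meta.condition,
        }
    out = Path(provenance_path) if provenance_path else Path(str(path) + ".json")
    out.write_text(json.dumps(prov, indent=2))
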