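"""Schema-validated CSV I/O and the run manifest.

All tables are plain CSV: header row, UTF-8, "." decimal, empty fields
for missing values, months as the single time unit.  Floats are written
with 17 significant digits so write -> read round-trips bit-for-bit for
integers/strings and far below 1e-12 relative error for reals, and
reruns at a fixed seed are byte-identical.

Units: cTnT may arrive with an "ng/l" or "pg/ml" unit suffix in the
column header; 1 ng/l = 1 pg/ml, so both are normalized to the internal
``ctnt`` column (pg/ml) on load and results are invariant to which was
supplied.
"""
from __future__ import annotations

import hashlib
import json
import os
import re
import warnings
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .config import GROUPS

__all__ = ["ValidationError", "read_table", "read_tables", "write_results", "TABLE_SCHEMAS"]

FLOAT_FORMAT = "%.17g"


class ValidationError(ValueError):
    """A table violated its schema; the message names file, column, row."""


# required column -> permitted kind ("str" | "float" | "int")
TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "cells": {
        "cell_id": "str",
        "well_id": "str",
        "area_cell": "float",
        "area_nucleus": "float",
        "dapi_intensity": "float",
    },
    "wells": {
        "well_id": "str",
        "plate_id": "str",
        "experiment_id": "int",
        "sample_id": "str",
        "plasma_source": "str",
        "plasma_pct": "float",
        "pe": "int",
    },
    "patients": {
        "patient_id": "str",
        "group": "str",
        "age": "float",
        "sex": "str",
        "gfr": "float",
        "ctnt": "float",
        "ntprobnp": "float",
    },
    "outcomes": {
        "patient_id": "str",
        "time_htx": "float",
        "event_htx": "int",
        "time_dmp": "float",
        "event_dmp": "int",
        "time_mace": "float",
        "event_mace": "int",
    },
}

_UNIT_ALIASES = {
    re.compile(r"^ctnt[ _]*\(?(ng/l|ng_l)\)?$", re.I): "ctnt",
    re.compile(r"^ctnt[ _]*\(?(pg/ml|pg_ml)\)?$", re.I): "ctnt",
    re.compile(r"^ntprobnp[ _]*\(?(pg/ml|pg_ml)\)?$", re.I): "ntprobnp",
}


def _normalize_units(df: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        for pat, target in _UNIT_ALIASES.items():
            if pat.match(str(col).strip()):
                renames[col] = target
    return df.rename(columns=renames) if renames else df


def _first_bad_row(mask: pd.Series) -> int:
    # +2: header line plus 1-based numbering, i.e. the line in the file
    return int(np.flatnonzero(mask.to_numpy())[0]) + 2


def read_table(path: str, name: str) -> pd.DataFrame:
    """Read and validate one named table (cells/wells/patients/outcomes)."""
    if name not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table name {name!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"input table {path} does not exist")
    df = pd.read_csv(path)
    df = _normalize_units(df)
    if len(df) == 0:
        raise ValidationError(f"{path}: no rows")
    schema = TABLE_SCHEMAS[name]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in schema and c != "latent_hi"]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)

    # content checks with file line numbers
    if name == "cells":
        for col in ("area_cell", "area_nucleus"):
            bad = ~(df[col] > 0) | df[col].isna()
            if bad.any():
                raise ValidationError(
                    f"{path}: column {col!r} non-positive at row {_first_bad_row(bad)}"
                )
        bad = df["dapi_intensity"] < 0
        if bad.any():
            raise ValidationError(
                f"{path}: column 'dapi_intensity' negative at row {_first_bad_row(bad)}"
            )
    elif name == "wells":
        allowed = {"patient", "control_subject", "FCS"}
        bad = ~df["plasma_source"].isin(allowed)
        if bad.any():
            raise ValidationError(
                f"{path}: column 'plasma_source' invalid at row {_first_bad_row(bad)}"
            )
        bad = ~df["pe"].isin([0, 1])
        if bad.any():
            raise ValidationError(
                f"{path}: column 'pe' must be 0/1 at row {_first_bad_row(bad)}"
            )
    elif name == "patients":
        bad = ~df["group"].isin(GROUPS)
        if bad.any():
            raise ValidationError(
                f"{path}: column 'group' invalid at row {_first_bad_row(bad)}"
            )
        bad = ~(df["gfr"] > 0)
        if bad.any():
            raise ValidationError(
                f"{path}: column 'gfr' non-positive at row {_first_bad_row(bad)}"
            )
        for col in ("ctnt", "ntprobnp"):
            bad = df[col] < 0
            if bad.any():
                raise ValidationError(
                    f"{path}: column {col!r} negative at row {_first_bad_row(bad)}"
                )
    elif name == "outcomes":
        for col in ("time_htx", "time_dmp", "time_mace"):
            bad = ~(df[col] > 0)
            if bad.any():
                raise ValidationError(
                    f"{path}: column {col!r} non-positive at row {_first_bad_row(bad)}"
                )
        for col in ("event_htx", "event_dmp", "event_mace"):
            bad = ~df[col].isin([0, 1])
            if bad.any():
                raise ValidationError(
                    f"{path}: column {col!r} must be 0/1 at row {_first_bad_row(bad)}"
                )
    return df


def read_tables(input_dir: str) -> dict[str, pd.DataFrame]:
    """Read the four canonical tables from a directory."""
    return {
        name: read_table(os.path.join(input_dir, f"{name}.csv"), name)
        for name in TABLE_SCHEMAS
    }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    bundle: Mapping[str, pd.DataFrame],
    out_dir: str,
    summary: Mapping[str, Any] | None = None,
    manifest_extra: Mapping[str, Any] | None = None,
) -> dict[str, str]:
    """Write every table of the bundle plus summary.json and manifest.json.

    Returns {artifact name: sha256}.  The manifest records config/seed
    information passed via ``manifest_extra`` together with a checksum of
    every artifact, so a rerun can be verified byte-for-byte.
    """
    os.makedirs(out_dir, exist_ok=True)
    checksums: dict[str, str] = {}
    for name, df in bundle.items():
        path = os.path.join(out_dir, f"{name}.csv")
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        checksums[f"{name}.csv"] = _sha256(path)
    if summary is not None:
        spath = os.path.join(out_dir, "summary.json")
        with open(spath, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        checksums["summary.json"] = _sha256(spath)
    manifest = {
        "artifacts": checksums,
        **(dict(manifest_extra) if manifest_extra else {}),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return checksums


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
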