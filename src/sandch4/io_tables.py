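"""Shared tabular I/O with light schema validation.

Tables are plain CSV/TSV, spreadsheet-readable, with an optional leading
comment line declaring units (``# units: temp_C=degC, ch4_nM=nmol/L``) so
files stay self-describing. ``read_table`` validates required columns and
types and names the first offending cell on failure; writers emit a
provenance comment (tool version, seed, config hash) so outputs are
reproducible byte-for-byte for a fixed input and configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["SchemaError", "read_table", "write_table"]


class SchemaError(ValueError):
    """A table failed schema validation."""


def read_table(
    path: str | Path,
    schema: Mapping[str, type] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a CSV/TSV, skipping comment lines, and validate against a schema.

    ``schema`` maps required column names to types (float, int or str).
    Raises :class:`SchemaError` naming the missing column or the first
    unparsable cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        for col, typ in schema.items():
            if typ in (float, int):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    row = int(bad.idxmax())
                    raise SchemaError(
                        f"{path}: column {col!r}, row {row}: "
                        f"cannot parse {df[col].iloc[row]!r} as {typ.__name__}"
                    )
                df[col] = coerced.astype(float if typ is float else "Int64")
    return df


def _config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    units: Mapping[str, str] | None = None,
    config: Mapping | None = None,
    seed: int | None = None,
    float_format: str = "%.6g",
    sep: str = ",",
) -> None:
    """Write a table with a units comment line and a provenance comment."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if units:
            fh.write("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()) + "\n")
        fh.write(
            f"# provenance: sandch4 {__version__}, config {_config_hash(config)}, "
            f"seed {seed}\n"
        )
        df.to_csv(fh, index=False, float_format=float_format, sep=sep)
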