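"""CSV table dialects, schema validation, and the run manifest.

Each pipeline table has a named schema (column set, dtypes, row-level
invariants). ``load_table`` validates on read and reports offending rows
with their line numbers; ``write_table`` writes the same dialect back so
tables round-trip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable

import pandas as pd


class SchemaError(ValueError):
    """Raised when a table does not conform to its schema."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        self.row_errors = row_errors or []
        detail = "".join(f"\n  {e}" for e in self.row_errors[:20])
        super().__init__(message + detail)


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict[str, str]  # column -> pandas dtype
    datetime_columns: tuple[str, ...] = ()
    row_checks: tuple[tuple[str, Callable[[pd.Series], pd.Series]], ...] = ()


def _between(col: str, lo: float, hi: float):
    return (
        f"{col} in [{lo}, {hi}]",
        lambda df, c=col, a=lo, b=hi: (df[c] >= a) & (df[c] <= b),
    )


def _positive(col: str):
    return (f"{col} > 0", lambda df, c=col: df[c] > 0)


def _non_negative(col: str):
    return (f"{col} >= 0", lambda df, c=col: df[c] >= 0)


SCHEMAS: dict[str, TableSchema] = {
    "flux_campaign": TableSchema(
        name="flux_campaign",
        columns={
            "plot_id": "string",
            "datetime": "string",
            "chamber_id": "string",
            "conc_slope_ppm_s": "float64",
            "air_temp_c": "float64",
            "pressure_pa": "float64",
            "volume_m3": "float64",
            "area_m2": "float64",
            "soil_temp_5cm_c": "float64",
        },
        datetime_columns=("datetime",),
        row_checks=(
            _positive("volume_m3"),
            _positive("area_m2"),
            _between("pressure_pa", 50_000.0, 110_000.0),
        ),
    ),
    "temperature_log": TableSchema(
        name="temperature_log",
        columns={"plot_id": "string", "timestamp": "string", "soil_temp_5cm_c": "float64"},
        datetime_columns=("timestamp",),
    ),
    "inventory": TableSchema(
        name="inventory",
        columns={
            "plot_id": "string",
            "treatment": "string",
            "layer": "string",
            "soc_pct": "float64",
            "core_total_mass_g": "float64",
            "core_rock_mass_g": "float64",
            "core_total_vol_cm3": "float64",
            "core_rock_vol_cm3": "float64",
            "nominal_thickness_cm": "float64",
        },
        row_checks=(
            _between("soc_pct", 0.0, 60.0),
            _positive("core_total_vol_cm3"),
            _non_negative("core_rock_mass_g"),
            _non_negative("core_rock_vol_cm3"),
            _positive("nominal_thickness_cm"),
            (
                "rock mass <= total mass",
                lambda df: df["core_rock_mass_g"] <= df["core_total_mass_g"],
            ),
            (
                "rock volume < total volume",
                lambda df: df["core_rock_vol_cm3"] < df["core_total_vol_cm3"],
            ),
        ),
    ),
    "atmospheric_curve": TableSchema(
        name="atmospheric_curve",
        columns={"year": "float64", "delta14c_permil": "float64"},
    ),
    "radiocarbon_obs": TableSchema(
        name="radiocarbon_obs",
        columns={
            "year": "float64",
            "pool": "string",
            "depth": "string",
            "treatment": "string",
            "delta14c_permil": "float64",
            "sd_permil": "float64",
        },
        row_checks=(_positive("sd_permil"),),
    ),
    "annual_budgets": TableSchema(
        name="annual_budgets",
        columns={
            "plot_id": "string",
            "year": "int64",
            "method": "string",
            "cumulative_c_g_m2": "float64",
        },
    ),
    "response_records": TableSchema(
        name="response_records",
        columns={
            "block_id": "string",
            "date": "string",
            "r_control": "float64",
            "r_warming": "float64",
            "t_control": "float64",
            "t_warming": "float64",
        },
        datetime_columns=("date",),
    ),
}


def load_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Row-level violations are collected (with 1-based data line numbers,
    header = line 1) and raised together as a :class:`SchemaError`.
    """
    schema = SCHEMAS.get(schema_name)
    if schema is None:
        raise KeyError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype="string")
    if df.empty and df.columns.empty:
        raise SchemaError(f"{path}: empty file")
    missing = set(schema.columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(schema.columns)]
    errors: list[str] = []
    for col, dtype in schema.columns.items():
        if dtype == "string":
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        for i in df.index[bad]:
            errors.append(f"line {i + 2}: unparseable {col}={df.at[i, col]!r}")
        df[col] = converted.astype("float64")
    for col in schema.datetime_columns:
        converted = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
        bad = converted.isna() & df[col].notna()
        for i in df.index[bad]:
            errors.append(f"line {i + 2}: unparseable {col}={df.at[i, col]!r}")
        df[col] = converted
    if errors:
        raise SchemaError(f"{path}: {len(errors)} unparseable value(s)", errors)
    for label, check in schema.row_checks:
        ok = check(df)
        for i in df.index[~ok.fillna(False)]:
            errors.append(f"line {i + 2}: violates {label}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row value(s)", errors)
    for col, dtype in schema.columns.items():
        if dtype == "int64":
            df[col] = df[col].astype("int64")
    return df


def write_table(df: pd.DataFrame, path: str | Path, float_digits: int = 14) -> Path:
    """Write a tidy CSV preserving >= 12 significant digits for round-trips."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=f"%.{float_digits}g")
    return path


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config, seed, input digests, versions."""

    config: dict
    seed: int
    package_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "package_version": self.package_version,
                "input_digests": self.input_digests,
                "output_digests": self.output_digests,
                "created": self.created,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json() + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        doc = json.loads(Path(path).read_text())
        return cls(
            config=doc["config"],
            seed=doc["seed"],
            package_version=doc["package_version"],
            input_digests=doc.get("input_digests", {}),
            output_digests=doc.get("output_digests", {}),
            created=doc.get("created", ""),
        )
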