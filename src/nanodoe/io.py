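"""CSV/JSON/YAML readers and writers plus the validated run configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .designs import FactorSpec
from .kinetics import ReleaseCurve

__all__ = [
    "RunConfig",
    "load_config",
    "read_response_table",
    "read_release_curve",
    "write_table",
    "dump_json",
]


class SchemaError(ValueError):
    """Input table does not match the expected column schema."""


class FactorSpecModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    low: float
    high: float
    center: float | None = None
    units: str = ""

    def to_spec(self) -> FactorSpec:
        return FactorSpec(name=self.name, low=self.low, high=self.high,
                          center=self.center, units=self.units)


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (YAML-loadable).

    Unknown keys are rejected so typos fail loudly instead of being ignored.
    """

    model_config = ConfigDict(extra="forbid")

    factors: list[FactorSpecModel]
    orientations: dict[str, str]
    alpha: float = Field(default=0.05, gt=0, lt=1)
    goal: str = "maximize"
    rounding_step: float | list[float] = 0.1
    higuchi_intercept: bool = True
    seed: int = 0

    @field_validator("orientations")
    @classmethod
    def _check_orientations(cls, v):
        for key, val in v.items():
            if val not in ("maximize", "minimize"):
                raise ValueError(f"orientation for {key!r} must be maximize/minimize, got {val!r}")
        return v

    @field_validator("goal")
    @classmethod
    def _check_goal(cls, v):
        if v not in ("maximize", "minimize"):
            raise ValueError(f"goal must be maximize/minimize, got {v!r}")
        return v

    def factor_specs(self) -> list[FactorSpec]:
        return [f.to_spec() for f in self.factors]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def _read_csv_checked(path, required: list[str], aliases: dict[str, list[str]] | None = None
                      ) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    # case-insensitive header matching, plus explicit aliases
    lookup = {c.lower(): c for c in df.columns}
    rename = {}
    for want in required:
        cands = [want] + (aliases or {}).get(want, [])
        hit = next((lookup[c.lower()] for c in cands if c.lower() in lookup), None)
        if hit is None:
            raise SchemaError(f"{path}: missing column {want!r}; found {list(df.columns)}")
        rename[hit] = want
    df = df.rename(columns=rename)
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if df[col].notna().any() and coerced.isna().any() and col != "run":
            bad = df.index[coerced.isna() & df[col].notna()][0]
            raise SchemaError(f"{path}: non-numeric value in column {col!r}, row {bad}")
    return df


def read_response_table(path, response_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a run-indexed response/design table (header-keyed, any column order)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    lookup = {c.lower(): c for c in df.columns}
    if "run" not in lookup:
        raise SchemaError(f"{path}: missing 'run' column; found {list(df.columns)}")
    df = df.rename(columns={lookup["run"]: "run"}).set_index("run")
    if response_columns:
        missing = [c for c in response_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing response column(s) {missing}")
    # deterministic column ordering: design columns (X*) first, then the rest
    design_cols = sorted(c for c in df.columns if c.upper().startswith("X"))
    other = [c for c in df.columns if c not in design_cols]
    return df[design_cols + other]


def read_release_curve(path, medium: str = "") -> ReleaseCurve:
    """Read a ``time_h,Q_percent`` release-curve CSV."""
    df = _read_csv_checked(path, ["time_h", "Q_percent"],
                           aliases={"time_h": ["time", "t_h", "t"],
                                    "Q_percent": ["q", "release", "q_pct"]})
    return ReleaseCurve(times=df["time_h"].to_numpy(dtype=float),
                        q=df["Q_percent"].to_numpy(dtype=float), medium=medium)


def write_table(df: pd.DataFrame, path, float_format: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=float_format)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def dump_json(doc: dict, path=None) -> str:
    """Serialize with stable key order so identical runs give identical bytes."""
    text = json.dumps(doc, indent=2, sort_keys=True, default=_jsonify)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(text + "\n")
    return text
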