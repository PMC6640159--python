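"""Cohort and schema serialization: CSV tables with a YAML/JSON schema sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .schema import ENDPOINT_COLUMNS, VariableSchema

__all__ = ["read_cohort", "write_cohort", "read_schema", "write_schema"]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort as CSV; missing cells become empty strings."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path: str | Path, schema: VariableSchema | None = None) -> pd.DataFrame:
    """Read a cohort CSV; empty cells become NaN, categoricals stay strings."""
    dtype: dict[str, object] = {}
    if schema is not None:
        for v in schema.categorical:
            dtype[v.name] = "string"
    cohort = pd.read_csv(path, dtype=dtype or None)
    for col in ("pfs_event", "os_event"):
        if col in cohort.columns:
            cohort[col] = cohort[col].astype(bool)
    if schema is not None:
        for v in schema.categorical:
            if v.name in cohort.columns:
                cohort[v.name] = cohort[v.name].astype(object)
    return cohort


def write_schema(schema: VariableSchema, path: str | Path) -> None:
    path = Path(path)
    payload = schema.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_schema(path: str | Path) -> VariableSchema:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return VariableSchema.from_dict(payload)
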