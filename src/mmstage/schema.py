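"""Variable schema for pre-transplant multiple-myeloma cohort tables.

A cohort table carries one row per patient: an identifier, 39 pre-transplant
covariates (23 numeric, 16 categorical) and two right-censored survival
endpoints, progression-free survival (PFS) and overall survival (OS), each as
a (time in months, event flag) pair.

The default schema names the variables documented in the study population
tables (albumin, GFR, M-protein, haemoglobin, beta-2-microglobulin, relapse
status, response to induction, extramedullary disease, ISS stage,
immunoglobulin type, ...) and pads the remainder with routine pre-transplant
laboratory and history variables so that the full 39-variable shape is
exercised. The padded names are documented stand-ins, not a published list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "Variable",
    "VariableSchema",
    "default_schema",
    "ENDPOINT_COLUMNS",
    "ID_COLUMN",
    "LATENT_COLUMN",
]

ID_COLUMN = "patient_id"
LATENT_COLUMN = "latent_group"
ENDPOINT_COLUMNS = ("pfs_time_months", "pfs_event", "os_time_months", "os_event")

RESPONSE_LEVELS = ("CR", "VGPR", "PR", "NR", "SD", "PD")
GOOD_RESPONSE = ("CR", "VGPR")


@dataclass(frozen=True)
class Variable:
    """One covariate: ``kind`` is ``"numeric"`` (with units) or
    ``"categorical"`` (with an ordered level set)."""

    name: str
    kind: str  # "numeric" | "categorical"
    units: str | None = None
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise ValueError(f"categorical variable {self.name!r} needs levels")


@dataclass(frozen=True)
class VariableSchema:
    """Ordered covariate list; column order everywhere follows this order."""

    variables: tuple[Variable, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def numeric(self) -> list[Variable]:
        return [v for v in self.variables if v.kind == "numeric"]

    @property
    def categorical(self) -> list[Variable]:
        return [v for v in self.variables if v.kind == "categorical"]

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def subset(self, names: Sequence[str]) -> "VariableSchema":
        return VariableSchema(tuple(self[n] for n in names))

    def drop(self, names: Sequence[str]) -> "VariableSchema":
        dropped = set(names)
        return VariableSchema(tuple(v for v in self.variables if v.name not in dropped))

    def to_dict(self) -> dict:
        out = {}
        for v in self.variables:
            entry: dict = {"kind": v.kind}
            if v.units is not None:
                entry["units"] = v.units
            if v.levels is not None:
                entry["levels"] = list(v.levels)
            out[v.name] = entry
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        variables = []
        for name, entry in d.items():
            levels = entry.get("levels")
            variables.append(
                Variable(
                    name=name,
                    kind=entry["kind"],
                    units=entry.get("units"),
                    levels=tuple(levels) if levels is not None else None,
                )
            )
        return cls(tuple(variables))


def _num(name: str, units: str) -> Variable:
    return Variable(name, "numeric", units=units)


def _cat(name: str, *levels: str) -> Variable:
    return Variable(name, "categorical", levels=levels)


_YN = ("yes", "no")

_DEFAULT_VARIABLES: tuple[Variable, ...] = (
    # -- categorical (16) --------------------------------------------------
    _cat("relapse_after_remission", *_YN),
    _cat("response_to_induction", *RESPONSE_LEVELS),
    _cat("iss_stage", "I", "II", "III"),
    _cat("dss_stage", "I", "II", "III"),
    _cat("induction_lines", "1", "2", "3", ">3"),
    _cat(
        "immunoglobulin_type",
        "IgG-Kappa", "IgG-Lambda", "IgA-Kappa", "IgA-Lambda", "Kappa", "Lambda",
    ),
    _cat("sex", "male", "female"),
    _cat("diabetes", *_YN),
    _cat("dialysis", *_YN),
    _cat("extramedullary_disease", "present", "absent"),
    _cat("bone_lesions", *_YN),
    _cat("hypertension", *_YN),
    _cat("light_chain_type", "kappa", "lambda"),
    _cat("plasmacytoma", *_YN),
    _cat("b_symptoms", *_YN),
    _cat("ecog", "0", "1", "2", "3"),
    # -- numeric (23) ------------------------------------------------------
    _num("albumin", "g/dL"),
    _num("gfr", "mL/min/1.73m2"),
    _num("m_spike", "g/dL"),          # pre-transplant M-protein
    _num("serum_m_spike", "g/dL"),    # M-protein at diagnosis
    _num("hemoglobin", "g/dL"),
    _num("beta2_microglobulin", "mcg/mL"),
    _num("age", "years"),
    _num("creatinine", "mg/dL"),
    _num("calcium", "mg/dL"),
    _num("ldh", "U/L"),
    _num("plasma_cell_pct", "%"),
    _num("total_protein", "g/dL"),
    _num("wbc", "1e9/L"),
    _num("platelets", "1e9/L"),
    _num("anc", "1e9/L"),
    _num("esr", "mm/hr"),
    _num("uric_acid", "mg/dL"),
    _num("sgot", "U/L"),
    _num("sgpt", "U/L"),
    _num("bilirubin", "mg/dL"),
    _num("kappa_lambda_ratio", ""),
    _num("marrow_cellularity", "%"),
    _num("months_to_transplant", "months"),
)

# Variables excluded from the multivariate stack: the induction-line count,
# and the composite staging scores, which are functions of variables already
# present; 36 of the 39 covariates enter the stack.
MULTIVARIATE_EXCLUDED = ("induction_lines", "iss_stage", "dss_stage")


def default_schema() -> VariableSchema:
    """The default 39-covariate schema (23 numeric, 16 categorical)."""
    return VariableSchema(_DEFAULT_VARIABLES)
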