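"""Missing-value imputation by chained equations and cohort encoding.

Imputation follows the chained-equations (MICE) scheme: cycle over the
incomplete covariates, regress each on all others, and draw imputations —
predictive-mean matching for numeric covariates, most-probable-class
prediction for categoricals. A single completed dataset is produced (no
multiple-imputation pooling).

Encoding produces the two matrix views downstream stages need: a one-hot
``EncodedMatrix`` (categoricals expanded to indicators, numerics passed
through) and a fully binary ``BinaryMatrix`` (numerics additionally
dichotomized at supplied cutoffs, strictly-greater-than semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import BayesianRidge, LogisticRegression

from .schema import VariableSchema

__all__ = [
    "EncodedMatrix",
    "BinaryMatrix",
    "impute_missing",
    "one_hot_encode",
    "binarize",
]

PMM_DONORS = 5  # nearest predicted-value donors for predictive-mean matching


@dataclass(frozen=True)
class EncodedMatrix:
    """Numeric matrix with one-hot categoricals; ``column_map`` sends each
    column back to its (variable, level-or-None) in the schema."""

    matrix: pd.DataFrame
    column_map: dict[str, tuple[str, str | None]]


@dataclass(frozen=True)
class BinaryMatrix:
    """All-binary view: numerics dichotomized at their cutoffs (1 iff value
    strictly exceeds the cutoff), categoricals one-hot."""

    matrix: pd.DataFrame
    column_map: dict[str, tuple[str, str | float | None]]


# ---------------------------------------------------------------------------
# chained-equations imputation


def _predictor_frame(
    cohort: pd.DataFrame, schema: VariableSchema, exclude: str
) -> np.ndarray:
    """Design matrix from all covariates except ``exclude`` (one-hot cats)."""
    blocks = []
    for var in schema.variables:
        if var.name == exclude:
            continue
        col = cohort[var.name]
        if var.kind == "numeric":
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            for level in var.levels:
                blocks.append((col.to_numpy(dtype=object) == level).astype(float)[:, None])
    X = np.hstack(blocks)
    # standardize so the ridge/logistic penalties treat covariates evenly
    # regardless of measurement scale
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _pmm_draw(
    rng: np.random.Generator,
    observed_values: np.ndarray,
    pred_observed: np.ndarray,
    pred_missing: np.ndarray,
    donors: int,
) -> np.ndarray:
    """Predictive-mean matching: for each missing case pick one of the
    ``donors`` observed cases with closest predicted mean and copy its value."""
    k = min(donors, len(observed_values))
    out = np.empty(len(pred_missing))
    for i, p in enumerate(pred_missing):
        idx = np.argsort(np.abs(pred_observed - p), kind="stable")[:k]
        out[i] = observed_values[idx[rng.integers(k)]]
    return out


def impute_missing(
    cohort: pd.DataFrame,
    schema: VariableSchema,
    n_iterations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Impute missing covariate cells by chained equations.

    Endpoints must be complete. Observed cells are returned unchanged; a
    complete cohort is returned as-is (copy). A covariate with no observed
    value at all is an error.
    """
    covariates = [v.name for v in schema.variables if v.name in cohort.columns]
    missing_mask = cohort[covariates].isna()
    if not missing_mask.to_numpy().any():
        return cohort.copy()

    for name in covariates:
        if missing_mask[name].all():
            raise ValueError(f"covariate {name!r} has no observed values to impute from")

    rng = np.random.default_rng(seed)
    out = cohort.copy()

    # initial fill: column mean / modal level
    for var in schema.variables:
        if var.name not in covariates or not missing_mask[var.name].any():
            continue
        col = out[var.name]
        if var.kind == "numeric":
            out[var.name] = col.fillna(float(col.mean()))
        else:
            out[var.name] = col.fillna(col.mode().iloc[0])

    incomplete = [n for n in covariates if missing_mask[n].any()]
    for _ in range(n_iterations):
        for name in incomplete:
            var = schema[name]
            mis = missing_mask[name].to_numpy()
            obs = ~mis
            X = _predictor_frame(out, schema, exclude=name)
            if var.kind == "numeric":
                y = cohort[name].to_numpy(dtype=float)
                model = BayesianRidge()
                model.fit(X[obs], y[obs])
                pred_obs = model.predict(X[obs])
                pred_mis = model.predict(X[mis])
                draws = _pmm_draw(rng, y[obs], pred_obs, pred_mis, PMM_DONORS)
                col = out[name].to_numpy(dtype=float)
                col[mis] = draws
                out[name] = col
            else:
                y = cohort[name].to_numpy(dtype=object)
                classes = pd.unique(y[obs])
                if len(classes) == 1:
                    out.loc[mis, name] = classes[0]
                    continue
                model = LogisticRegression(max_iter=200)
                model.fit(X[obs], y[obs].astype(str))
                pred = model.predict(X[mis])
                col = out[name].to_numpy(dtype=object)
                col[mis] = pred
                out[name] = col
    return out


# ---------------------------------------------------------------------------
# encodings


def _check_levels(cohort: pd.DataFrame, schema: VariableSchema) -> None:
    for var in schema.categorical:
        values = cohort[var.name].astype(object)
        unseen = set(values) - set(var.levels)
        if unseen:
            raise ValueError(
                f"variable {var.name!r} has levels outside the schema: {sorted(map(str, unseen))}"
            )


def _require_complete(cohort: pd.DataFrame, schema: VariableSchema) -> None:
    na_cols = [v.name for v in schema.variables if cohort[v.name].isna().any()]
    if na_cols:
        raise ValueError(f"cohort has missing values in {na_cols}; impute first")


def one_hot_encode(cohort: pd.DataFrame, schema: VariableSchema) -> EncodedMatrix:
    """Expand categoricals to indicator columns (schema order, then level
    order); numerics pass through unchanged."""
    _require_complete(cohort, schema)
    _check_levels(cohort, schema)
    columns: dict[str, np.ndarray] = {}
    column_map: dict[str, tuple[str, str | None]] = {}
    for var in schema.variables:
        if var.kind == "numeric":
            columns[var.name] = cohort[var.name].to_numpy(dtype=float)
            column_map[var.name] = (var.name, None)
        else:
            values = cohort[var.name].to_numpy(dtype=object)
            for level in var.levels:
                col = f"{var.name}={level}"
                columns[col] = (values == level).astype(int)
                column_map[col] = (var.name, level)
    matrix = pd.DataFrame(columns, index=cohort.index)
    return EncodedMatrix(matrix=matrix, column_map=column_map)


def binarize(
    cohort: pd.DataFrame,
    schema: VariableSchema,
    cutoffs: dict[str, float],
) -> BinaryMatrix:
    """All-binary encoding: numeric cell -> 1 iff value > cutoff; categoricals
    one-hot. Every numeric covariate needs a cutoff."""
    _require_complete(cohort, schema)
    _check_levels(cohort, schema)
    missing = [v.name for v in schema.numeric if v.name not in cutoffs]
    if missing:
        raise ValueError(f"no cutoff supplied for numeric covariates {missing}")
    columns: dict[str, np.ndarray] = {}
    column_map: dict[str, tuple[str, str | float | None]] = {}
    for var in schema.variables:
        if var.kind == "numeric":
            c = float(cutoffs[var.name])
            col = f"{var.name}>{c:g}"
            columns[col] = (cohort[var.name].to_numpy(dtype=float) > c).astype(int)
            column_map[col] = (var.name, c)
        else:
            values = cohort[var.name].to_numpy(dtype=object)
            for level in var.levels:
                col = f"{var.name}={level}"
                columns[col] = (values == level).astype(int)
                column_map[col] = (var.name, level)
    matrix = pd.DataFrame(columns, index=cohort.index)
    return BinaryMatrix(matrix=matrix, column_map=column_map)
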