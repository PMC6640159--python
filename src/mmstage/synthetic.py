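"""Synthetic pre-transplant myeloma cohorts with a two-group latent risk
structure.

The generator emulates the statistical structure the downstream analysis
assumes: a latent high-/low-risk split (default 34%/66%), group-dependent
covariate distributions for a set of prognostic signal variables (relapse
after remission, response to induction, serum albumin and several further
laboratory markers) against a background of group-independent distractors,
Weibull survival for PFS and OS with distinct
per-group medians, administrative censoring at a fixed horizon, and MCAR
missingness.

Defaults reproduce the study conditions: n of a few hundred patients,
34% high risk, median PFS 91 vs 24 months and median OS 135 vs 51 months,
censoring horizon 150 months.

OS is PFS plus an independent Weibull tail whose scale is solved numerically
so that the *marginal* OS median of each latent group equals the configured
value; a naive tail with median ``os_median - pfs_median`` would inflate the
OS median of the sum well beyond the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .schema import (
    ENDPOINT_COLUMNS,
    GOOD_RESPONSE,
    ID_COLUMN,
    LATENT_COLUMN,
    RESPONSE_LEVELS,
    VariableSchema,
    default_schema,
)

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "inject_missingness",
    "weibull_scale_from_median",
    "validate_cohort",
]


def weibull_scale_from_median(median: float, shape: float) -> float:
    """Scale lambda of a Weibull(shape k, scale lambda) with the given median:
    lambda = median / ln(2)^(1/k)."""
    if median <= 0 or shape <= 0:
        raise ValueError("median and shape must be positive")
    return median / math.log(2.0) ** (1.0 / shape)


# ---------------------------------------------------------------------------
# group-conditional covariate model


@dataclass(frozen=True)
class NumericEffect:
    """Gaussian covariate with group-shifted means (high, low) and shared sd."""

    mean_high: float
    mean_low: float
    sd: float


@dataclass(frozen=True)
class CategoricalEffect:
    """Per-group level probabilities (ordered as the schema's level set)."""

    probs_high: tuple[float, ...]
    probs_low: tuple[float, ...]


def _response_probs(p_good: float) -> tuple[float, ...]:
    # split CR/VGPR 60/40 within good responders, PR/NR/SD/PD within the rest
    good = (0.6 * p_good, 0.4 * p_good)
    rest = 1.0 - p_good
    others = (0.55 * rest, 0.15 * rest, 0.20 * rest, 0.10 * rest)
    return good + others


def default_covariate_effects() -> dict[str, NumericEffect | CategoricalEffect]:
    """Associations between the latent group and the covariates.

    The three staging-signal variables carry the strongest effects: relapse
    after remission is much likelier in the high-risk group, a good response
    to induction (CR/VGPR) much likelier in the low-risk group, and serum
    albumin is shifted down in the high-risk group. A further handful of
    prognostic laboratory variables carry moderate group shifts in their
    clinically expected directions (residual M-protein, haemoglobin,
    beta-2-microglobulin, GFR, extramedullary disease), mirroring the broad
    univariate prognostic landscape of real transplant cohorts, where risk
    groups differ across many correlated markers rather than a single one.
    The remaining ~30 covariates are group-independent distractors.
    """
    return {
        "relapse_after_remission": CategoricalEffect(
            probs_high=(0.55, 0.45), probs_low=(0.12, 0.88)
        ),
        "response_to_induction": CategoricalEffect(
            probs_high=_response_probs(0.35), probs_low=_response_probs(0.70)
        ),
        "albumin": NumericEffect(mean_high=3.2, mean_low=3.9, sd=0.5),
        "m_spike": NumericEffect(mean_high=1.1, mean_low=0.35, sd=0.6),
        "serum_m_spike": NumericEffect(mean_high=3.0, mean_low=1.5, sd=1.2),
        "hemoglobin": NumericEffect(mean_high=9.2, mean_low=11.2, sd=1.8),
        "beta2_microglobulin": NumericEffect(mean_high=6.2, mean_low=3.6, sd=2.2),
        "gfr": NumericEffect(mean_high=71.0, mean_low=93.0, sd=22.0),
        "extramedullary_disease": CategoricalEffect(
            probs_high=(0.42, 0.58), probs_low=(0.13, 0.87)
        ),
    }


# Baseline marginals for the group-independent covariates. Numeric entries
# are (mean, sd); categorical entries are level probabilities in schema
# order. Frequencies for ISS, induction lines, immunoglobulin type, sex,
# diabetes, dialysis and extramedullary disease follow the study's cohort
# characteristics; the remainder are plausible pre-transplant laboratory
# ranges.
_NUMERIC_BASELINE: dict[str, tuple[float, float]] = {
    "albumin": (3.7, 0.5),
    "gfr": (85.0, 25.0),
    "m_spike": (0.6, 0.6),
    "serum_m_spike": (2.0, 1.5),
    "hemoglobin": (10.5, 2.0),
    "beta2_microglobulin": (4.5, 2.5),
    "age": (52.0, 8.0),
    "creatinine": (1.2, 0.6),
    "calcium": (9.5, 1.0),
    "ldh": (220.0, 80.0),
    "plasma_cell_pct": (30.0, 15.0),
    "total_protein": (8.0, 1.5),
    "wbc": (6.0, 2.0),
    "platelets": (220.0, 70.0),
    "anc": (3.5, 1.3),
    "esr": (40.0, 20.0),
    "uric_acid": (6.0, 1.5),
    "sgot": (30.0, 12.0),
    "sgpt": (32.0, 14.0),
    "bilirubin": (0.8, 0.3),
    "kappa_lambda_ratio": (5.0, 6.0),
    "marrow_cellularity": (50.0, 15.0),
    "months_to_transplant": (8.0, 4.0),
}

_CATEGORICAL_BASELINE: dict[str, tuple[float, ...]] = {
    "relapse_after_remission": (69 / 253, 184 / 253),
    "response_to_induction": _response_probs(0.56),
    "iss_stage": (67 / 253, 94 / 253, 92 / 253),
    "dss_stage": (0.22, 0.37, 0.41),
    "induction_lines": (174 / 253, 54 / 253, 19 / 253, 6 / 253),
    "immunoglobulin_type": (
        101 / 253, 43 / 253, 26 / 253, 15 / 253, 45 / 253, 23 / 253,
    ),
    "sex": (166 / 253, 87 / 253),
    "diabetes": (107 / 253, 146 / 253),
    "dialysis": (8 / 253, 245 / 253),
    "extramedullary_disease": (57 / 253, 196 / 253),
    "bone_lesions": (0.65, 0.35),
    "hypertension": (0.30, 0.70),
    "light_chain_type": (0.68, 0.32),
    "plasmacytoma": (0.12, 0.88),
    "b_symptoms": (0.25, 0.75),
    "ecog": (0.30, 0.45, 0.20, 0.05),
}


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Medians are (low-risk, high-risk) pairs in months. ``survival_shape``
    is the Weibull shape shared by both endpoints (1.0 = exponential).
    ``censor_horizon_months`` is the administrative censoring time; ``None``
    disables censoring. ``covariate_effects`` maps variable names to
    group-conditional distributions; unnamed covariates are group-independent.
    """

    n_patients: int = 253
    high_risk_fraction: float = 0.34
    median_pfs_months: tuple[float, float] = (91.0, 24.0)
    median_os_months: tuple[float, float] = (135.0, 51.0)
    survival_shape: float = 1.0
    censor_horizon_months: float | None = 150.0
    covariate_effects: dict[str, NumericEffect | CategoricalEffect] = field(
        default_factory=default_covariate_effects
    )
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if not 0.0 < self.high_risk_fraction < 1.0:
            raise ValueError(
                f"high_risk_fraction must be in (0, 1), got {self.high_risk_fraction}"
            )
        for name, (low, high) in (
            ("PFS", self.median_pfs_months),
            ("OS", self.median_os_months),
        ):
            if low <= 0 or high <= 0:
                raise ValueError(f"{name} medians must be positive")
            if not high < low:
                raise ValueError(
                    f"high-risk {name} median ({high}) must be below the "
                    f"low-risk median ({low})"
                )
        for pfs, os_ in zip(self.median_pfs_months, self.median_os_months):
            if os_ <= pfs:
                raise ValueError(
                    "per-group OS median must exceed the PFS median "
                    f"(got PFS {pfs}, OS {os_})"
                )
        if self.survival_shape <= 0:
            raise ValueError("survival_shape must be positive")
        if self.censor_horizon_months is not None and self.censor_horizon_months < 0:
            raise ValueError("censor_horizon_months must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")


# ---------------------------------------------------------------------------
# OS-tail calibration


def _sum_survival(t: float, shape: float, scale_x: float, scale_y: float) -> float:
    """P(X + Y > t) for independent Weibulls X, Y with common shape."""
    if t <= 0:
        return 1.0
    fx = stats.weibull_min(shape, scale=scale_x)
    sy = stats.weibull_min(shape, scale=scale_y).sf

    def integrand(x: float) -> float:
        return fx.pdf(x) * sy(t - x)

    tail, _ = integrate.quad(integrand, 0.0, t, limit=200)
    return fx.sf(t) + tail


def _median_of_sum(shape: float, scale_x: float, scale_y: float) -> float:
    lo = max(scale_x, scale_y) * math.log(2.0) ** (1.0 / shape)  # >= each median
    hi = lo
    while _sum_survival(hi, shape, scale_x, scale_y) > 0.5:
        hi *= 2.0
    return optimize.brentq(
        lambda t: _sum_survival(t, shape, scale_x, scale_y) - 0.5, 1e-9, hi
    )


@lru_cache(maxsize=64)
def _os_tail_scale(shape: float, pfs_median: float, os_median: float) -> float:
    """Weibull scale of the independent OS-minus-PFS tail such that the
    marginal median of PFS + tail equals ``os_median``."""
    scale_x = weibull_scale_from_median(pfs_median, shape)

    def gap(scale_y: float) -> float:
        return _median_of_sum(shape, scale_x, scale_y) - os_median

    hi = weibull_scale_from_median(3.0 * os_median, shape)
    while gap(hi) < 0:
        hi *= 2.0
    return optimize.brentq(gap, 1e-9, hi, xtol=1e-6)


# ---------------------------------------------------------------------------
# generation


def _draw_covariate(
    rng: np.random.Generator,
    var,
    high: np.ndarray,
    effects: dict,
) -> np.ndarray:
    n = high.size
    effect = effects.get(var.name)
    if var.kind == "numeric":
        base_mean, base_sd = _NUMERIC_BASELINE.get(var.name, (0.0, 1.0))
        if isinstance(effect, NumericEffect):
            means = np.where(high, effect.mean_high, effect.mean_low)
            sd = effect.sd
        else:
            means, sd = np.full(n, base_mean), base_sd
        values = rng.normal(means, sd)
        return np.maximum(values, 0.01)  # labs and rates are positive
    levels = np.asarray(var.levels, dtype=object)
    if isinstance(effect, CategoricalEffect):
        ph = np.asarray(effect.probs_high, dtype=float)
        pl = np.asarray(effect.probs_low, dtype=float)
    else:
        ph = pl = np.asarray(
            _CATEGORICAL_BASELINE.get(var.name, [1.0 / len(levels)] * len(levels)),
            dtype=float,
        )
    for p in (ph, pl):
        if len(p) != len(levels) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"invalid level probabilities for {var.name!r}")
    u = rng.random(n)
    cum_h, cum_l = np.cumsum(ph), np.cumsum(pl)
    idx = np.where(
        high,
        np.searchsorted(cum_h, u, side="right"),
        np.searchsorted(cum_l, u, side="right"),
    )
    return levels[np.minimum(idx, len(levels) - 1)]


def generate_cohort(
    config: SyntheticConfig, schema: VariableSchema | None = None
) -> pd.DataFrame:
    """Generate a cohort table under the configured study conditions.

    Returns a DataFrame with ``patient_id``, one column per schema covariate,
    the four endpoint columns, and a ``latent_group`` column recording the
    true risk group ("high"/"low"). Identical config and seed give identical
    output.
    """
    config.validate()
    if schema is None:
        schema = default_schema()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    shape = config.survival_shape

    high = rng.random(n) < config.high_risk_fraction

    data: dict[str, np.ndarray] = {ID_COLUMN: np.array([f"P{i:05d}" for i in range(n)])}
    for var in schema.variables:
        data[var.name] = _draw_covariate(rng, var, high, config.covariate_effects)

    med_pfs = np.where(high, config.median_pfs_months[1], config.median_pfs_months[0])
    pfs_scale = med_pfs / math.log(2.0) ** (1.0 / shape)
    pfs = rng.weibull(shape, size=n) * pfs_scale

    tail_scale = np.empty(n)
    for grp, flag in (("low", False), ("high", True)):
        i = 0 if grp == "low" else 1
        tail_scale[high == flag] = _os_tail_scale(
            shape, config.median_pfs_months[i], config.median_os_months[i]
        )
    os_time = pfs + rng.weibull(shape, size=n) * tail_scale

    horizon = config.censor_horizon_months
    if horizon is None:
        pfs_event = np.ones(n, dtype=bool)
        os_event = np.ones(n, dtype=bool)
    else:
        pfs_event = pfs <= horizon
        os_event = os_time <= horizon
        pfs = np.minimum(pfs, horizon)
        os_time = np.minimum(os_time, horizon)

    data["pfs_time_months"] = pfs
    data["pfs_event"] = pfs_event
    data["os_time_months"] = os_time
    data["os_event"] = os_event
    data[LATENT_COLUMN] = np.where(high, "high", "low")

    cohort = pd.DataFrame(data)
    if config.missing_rate > 0:
        cohort = inject_missingness(
            cohort, config.missing_rate, seed=int(rng.integers(2**31 - 1)),
            schema=schema,
        )
    return cohort


def inject_missingness(
    cohort: pd.DataFrame,
    rate: float,
    seed: int,
    schema: VariableSchema | None = None,
) -> pd.DataFrame:
    """Mask covariate cells independently with probability ``rate`` (MCAR).

    Endpoints, the identifier and the latent-group column are never masked.
    Returns a new table; the input is untouched.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    out = cohort.copy()
    if rate == 0.0:
        return out
    protected = {ID_COLUMN, LATENT_COLUMN, *ENDPOINT_COLUMNS}
    if schema is not None:
        columns = [v.name for v in schema.variables if v.name in out.columns]
    else:
        columns = [c for c in out.columns if c not in protected]
    rng = np.random.default_rng(seed)
    for col in columns:
        mask = rng.random(len(out)) < rate
        if mask.any():
            if out[col].dtype.kind in "iub":  # keep NaN representable
                out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


def validate_cohort(cohort: pd.DataFrame, schema: VariableSchema) -> None:
    """Check structural invariants: endpoint ordering, nonnegative times,
    categorical values inside their level sets."""
    for col in (ID_COLUMN, *ENDPOINT_COLUMNS):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    times = cohort[["pfs_time_months", "os_time_months"]].to_numpy(dtype=float)
    if (times < 0).any():
        raise ValueError("survival times must be nonnegative")
    if (times[:, 0] > times[:, 1] + 1e-9).any():
        raise ValueError("pfs_time_months must not exceed os_time_months")
    for var in schema.categorical:
        if var.name not in cohort.columns:
            continue
        observed = cohort[var.name].dropna()
        bad = set(observed.astype(str)) - set(var.levels)
        if bad:
            raise ValueError(f"{var.name!r} has values outside its level set: {bad}")
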