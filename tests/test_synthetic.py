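import math

import numpy as np
import pandas as pd
import pytest

from mmstage.schema import ENDPOINT_COLUMNS, LATENT_COLUMN
from mmstage.survival import km_estimate, median_survival
from mmstage.synthetic import (
    SyntheticConfig,
    generate_cohort,
    inject_missingness,
    validate_cohort,
    weibull_scale_from_median,
)


def test_reproducibility(schema):
    cfg = SyntheticConfig(seed=42)
    a = generate_cohort(cfg, schema)
    b = generate_cohort(cfg, schema)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(SyntheticConfig(seed=43), schema)
    assert not a.equals(c)


def test_structural_invariants(complete_cohort, schema):
    validate_cohort(complete_cohort, schema)
    assert len(complete_cohort) == 253
    t = complete_cohort[["pfs_time_months", "os_time_months"]].to_numpy()
    assert (t >= 0).all()
    assert (t[:, 0] <= t[:, 1] + 1e-12).all()


def test_high_risk_count_binomial(schema):
    # Binomial(253, 0.34): mean 86, sd ~7.5; allow 4 sd
    cohort = generate_cohort(SyntheticConfig(seed=7, missing_rate=0.0), schema)
    count = int((cohort[LATENT_COLUMN] == "high").sum())
    assert abs(count - 253 * 0.34) < 4 * math.sqrt(253 * 0.34 * 0.66)


def test_survival_calibration_at_scale(schema):
    small = schema.subset(("albumin", "sex"))  # covariates irrelevant here
    cfg = SyntheticConfig(
        n_patients=10_000, seed=1, missing_rate=0.0, censor_horizon_months=None
    )
    cohort = generate_cohort(cfg, small)
    for group, pfs_target, os_target in (("low", 91.0, 135.0), ("high", 24.0, 51.0)):
        sub = cohort[cohort[LATENT_COLUMN] == group]
        for col, ev, target in (
            ("pfs_time_months", "pfs_event", pfs_target),
            ("os_time_months", "os_event", os_target),
        ):
            med = median_survival(
                km_estimate(sub[col].to_numpy(), sub[ev].to_numpy())
            ).months
            assert med == pytest.approx(target, rel=0.10)


def test_exponential_rate_mle(schema):
    small = schema.subset(("albumin",))
    cfg = SyntheticConfig(
        n_patients=5_000,
        seed=2,
        missing_rate=0.0,
        censor_horizon_months=None,
        high_risk_fraction=0.999999,  # essentially all high-risk: median 24
    )
    cohort = generate_cohort(cfg, small)
    sub = cohort[cohort[LATENT_COLUMN] == "high"]
    rate = len(sub) / sub["pfs_time_months"].sum()  # exponential MLE
    assert rate == pytest.approx(math.log(2.0) / 24.0, rel=0.05)


def test_zero_censor_horizon(schema):
    cohort = generate_cohort(
        SyntheticConfig(n_patients=50, seed=0, missing_rate=0.0,
                        censor_horizon_months=0.0),
        schema,
    )
    assert not cohort["pfs_event"].any()
    assert not cohort["os_event"].any()
    assert (cohort["pfs_time_months"] == 0).all()
    assert (cohort["os_time_months"] == 0).all()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_patients": 0},
        {"high_risk_fraction": 0.0},
        {"high_risk_fraction": 1.0},
        {"median_pfs_months": (24.0, 91.0)},  # high must be below low
        {"median_os_months": (135.0, -1.0)},
        {"median_pfs_months": (140.0, 60.0)},  # OS median must exceed PFS
        {"missing_rate": 1.0},
        {"survival_shape": 0.0},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        SyntheticConfig(**kwargs).validate()


def test_weibull_scale_median_relation():
    assert weibull_scale_from_median(24.0, 1.0) == pytest.approx(24.0 / math.log(2.0))
    with pytest.raises(ValueError):
        weibull_scale_from_median(-1.0, 1.0)


def test_latent_count_monotone_in_fraction(schema):
    small = schema.subset(("albumin",))
    counts = []
    for frac in (0.1, 0.34, 0.7):
        cohort = generate_cohort(
            SyntheticConfig(n_patients=500, seed=9, missing_rate=0.0,
                            high_risk_fraction=frac),
            small,
        )
        counts.append(int((cohort[LATENT_COLUMN] == "high").sum()))
    assert counts == sorted(counts)


# -- missingness -----------------------------------------------------------


def test_inject_rate_zero_identity(complete_cohort, schema):
    out = inject_missingness(complete_cohort, 0.0, seed=1, schema=schema)
    pd.testing.assert_frame_equal(out, complete_cohort)


def test_inject_masked_fraction(complete_cohort, schema):
    out = inject_missingness(complete_cohort, 0.05, seed=1, schema=schema)
    cells = len(out) * len(schema)
    frac = out[schema.names].isna().to_numpy().sum() / cells
    se = math.sqrt(0.05 * 0.95 / cells)
    assert abs(frac - 0.05) < 3 * se


def test_inject_never_touches_endpoints(complete_cohort, schema):
    out = inject_missingness(complete_cohort, 0.30, seed=2, schema=schema)
    for col in ENDPOINT_COLUMNS + (LATENT_COLUMN,):
        assert not out[col].isna().any()


def test_inject_input_untouched(complete_cohort, schema):
    before = complete_cohort.copy()
    inject_missingness(complete_cohort, 0.20, seed=3, schema=schema)
    pd.testing.assert_frame_equal(complete_cohort, before)


def test_inject_invalid_rate(complete_cohort, schema):
    with pytest.raises(ValueError):
        inject_missingness(complete_cohort, 1.0, seed=0, schema=schema)
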