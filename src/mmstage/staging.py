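"""The published 3-factor staging rule as a deterministic classifier.

The rule asks three questions in fixed order:

1. Did the patient relapse after remission?  yes -> HIGH risk (exit).
2. Response to induction therapy: outside {CR, VGPR} -> HIGH risk (exit).
3. Pre-transplant GFR against a threshold of 85.6 mL/min/1.73 m^2 (final
   cue, both exits).

Only the first exit is unambiguous in the source material (relapse always
means high risk). The published figure does not state textually which side
of the response and GFR cues exits high; the defaults here follow the
survival trends (poor responders do worse; renal insufficiency is adverse,
so GFR below the threshold exits high) and the GFR direction is
configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import GOOD_RESPONSE, RESPONSE_LEVELS
from .stacked import FFTCue, FFTModel, RiskAssignment

__all__ = ["StagingRule", "published_rule", "stage_patient", "stage_cohort"]

GFR_CUTOFF = 85.6  # mL/min/1.73 m^2


@dataclass(frozen=True)
class StagingRule:
    """Fixed cue order: relapse, response to induction, GFR.

    ``gfr_high_risk_below``: if True (default) a GFR at or below the
    threshold routes to high risk; if False the direction is inverted.
    """

    gfr_threshold: float = GFR_CUTOFF
    gfr_high_risk_below: bool = True
    relapse_column: str = "relapse_after_remission"
    response_column: str = "response_to_induction"
    gfr_column: str = "gfr"

    def __post_init__(self) -> None:
        if self.gfr_threshold <= 0:
            raise ValueError("GFR threshold must be positive")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "gfr_threshold": self.gfr_threshold,
                "gfr_high_risk_below": self.gfr_high_risk_below,
                "relapse_column": self.relapse_column,
                "response_column": self.response_column,
                "gfr_column": self.gfr_column,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StagingRule":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path: str | Path) -> "StagingRule":
        return cls.from_json(Path(path).read_text())

    # -- FFT view ---------------------------------------------------------
    def as_fft_model(self) -> FFTModel:
        """Express the rule as a fast-and-frugal tree (for cross-checks and
        for applying it through the generic tree machinery)."""
        gfr_direction = "<=" if self.gfr_high_risk_below else ">"
        cues = (
            FFTCue(variable=self.relapse_column, kind="categorical",
                   exit="high", levels=("yes",)),
            FFTCue(variable=self.response_column, kind="categorical",
                   exit="high",
                   levels=tuple(l for l in RESPONSE_LEVELS if l not in GOOD_RESPONSE)),
            FFTCue(variable=self.gfr_column, kind="numeric", exit="both",
                   direction=gfr_direction, threshold=self.gfr_threshold),
        )
        return FFTModel(cues=cues, balanced_accuracy=float("nan"),
                        accuracy=float("nan"), n_train=0)


def published_rule() -> StagingRule:
    """The default published rule: relapse -> high; non-CR/VGPR response ->
    high; final cue GFR vs 85.6 (below -> high by default)."""
    return StagingRule()


def stage_patient(
    relapse: str, response: str, gfr: float, rule: StagingRule | None = None
) -> str:
    """Stage a single patient; returns 'high' or 'low'."""
    if rule is None:
        rule = published_rule()
    if relapse not in ("yes", "no"):
        raise ValueError(f"relapse must be 'yes' or 'no', got {relapse!r}")
    if response not in RESPONSE_LEVELS:
        raise ValueError(
            f"unknown response level {response!r}; expected one of {RESPONSE_LEVELS}"
        )
    if not gfr > 0:
        raise ValueError(f"GFR must be positive, got {gfr}")
    if relapse == "yes":
        return "high"
    if response not in GOOD_RESPONSE:
        return "high"
    below = gfr <= rule.gfr_threshold
    return "high" if below == rule.gfr_high_risk_below else "low"


def stage_cohort(cohort: pd.DataFrame, rule: StagingRule | None = None) -> RiskAssignment:
    """Apply the rule row-wise; all three cue columns must be complete."""
    if rule is None:
        rule = published_rule()
    for col in (rule.relapse_column, rule.response_column, rule.gfr_column):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing cue column {col!r}")
        if cohort[col].isna().any():
            raise ValueError(f"cue column {col!r} has missing values")
    risk = np.array(
        [
            stage_patient(r, resp, g, rule)
            for r, resp, g in zip(
                cohort[rule.relapse_column].astype(object),
                cohort[rule.response_column].astype(object),
                cohort[rule.gfr_column].astype(float),
            )
        ],
        dtype=object,
    ).astype(str)
    return RiskAssignment(risk=risk, provenance="staging-rule")
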