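"""Model/results interface over the stacked risk-stratification procedure.

``RiskStratification`` holds a cohort and the analysis settings; ``fit``
runs the full stack (impute if needed -> dichotomize -> Hamming distances ->
PCA at the energy threshold -> spectral clustering -> survival-based risk
labels -> FFT induction -> one-pass re-calibration) and returns a
``RiskStratificationResults`` with the cluster and final labels, the induced
tree, training accuracies, per-group Kaplan–Meier medians and log-rank
tests, and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess, stacked, survival
from .schema import (
    ID_COLUMN,
    MULTIVARIATE_EXCLUDED,
    VariableSchema,
    default_schema,
)
from .stacked import FFTModel, RiskAssignment
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RiskStratification", "RiskStratificationResults"]


class RiskStratification:
    """Stacked risk-stratification model for a pre-transplant cohort.

    Parameters
    ----------
    cohort : DataFrame
        Patient table with the schema's covariates and both endpoints.
    schema : VariableSchema, optional
        Defaults to the 39-covariate schema.
    exclude : sequence of str
        Covariates kept out of the multivariate stack (default: the
        induction-line count and the composite ISS/DSS stages, leaving 36).
    energy : float
        Cumulative eigenvalue fraction retained by the PCA step.
    max_levels, n_candidates : int
        FFT search depth and marginal-ranking pool size.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        schema: VariableSchema | None = None,
        exclude=MULTIVARIATE_EXCLUDED,
        energy: float = 0.95,
        max_levels: int = 4,
        n_candidates: int = 6,
        affinity: str = "rbf",
        impute_iterations: int = 10,
    ):
        self.cohort = cohort.reset_index(drop=True)
        self.schema = schema if schema is not None else default_schema()
        self.exclude = tuple(exclude)
        self.energy = energy
        self.max_levels = max_levels
        self.n_candidates = n_candidates
        self.affinity = affinity
        self.impute_iterations = impute_iterations

    @classmethod
    def from_synthetic(
        cls, config: SyntheticConfig, schema: VariableSchema | None = None, **kwargs
    ) -> "RiskStratification":
        schema = schema if schema is not None else default_schema()
        return cls(generate_cohort(config, schema), schema=schema, **kwargs)

    @property
    def stack_schema(self) -> VariableSchema:
        return self.schema.drop(self.exclude)

    def fit(self, seed: int = 0) -> "RiskStratificationResults":
        covariate_names = [v.name for v in self.schema.variables]
        cohort = self.cohort
        if cohort[covariate_names].isna().to_numpy().any():
            cohort = preprocess.impute_missing(
                cohort, self.schema, n_iterations=self.impute_iterations, seed=seed
            )
        stack = self.stack_schema

        cutoffs = {
            v.name: survival.kmeans_1d_cutoff(
                cohort[v.name].to_numpy(dtype=float), variable=v.name
            ).cutoff
            for v in stack.numeric
        }
        binary = preprocess.binarize(cohort, stack, cutoffs)
        distances = stacked.hamming_matrix(binary)
        embedding = stacked.pca_energy(distances, energy=self.energy)
        clusters = stacked.spectral_cluster(
            embedding, k=2, seed=seed, affinity=self.affinity
        )
        cluster_risk = stacked.assign_risk(clusters, cohort)
        fft = stacked.fit_fft(
            cohort[[v.name for v in stack.variables]],
            cluster_risk,
            stack,
            max_levels=self.max_levels,
            n_candidates=self.n_candidates,
        )
        final_risk, training_accuracy = stacked.recalibrate(cluster_risk, fft, cohort)
        return RiskStratificationResults(
            model=self,
            imputed_cohort=cohort,
            cutoffs=cutoffs,
            embedding=embedding,
            clusters=clusters,
            cluster_risk=cluster_risk,
            fft=fft,
            risk=final_risk,
            training_accuracy=training_accuracy,
            seed=seed,
        )


@dataclass
class RiskStratificationResults:
    """Fitted stratification: labels, tree, accuracies and survival contrasts."""

    model: RiskStratification
    imputed_cohort: pd.DataFrame
    cutoffs: dict[str, float]
    embedding: stacked.PCEmbedding
    clusters: stacked.ClusterLabels
    cluster_risk: RiskAssignment
    fft: FFTModel
    risk: RiskAssignment
    training_accuracy: float
    seed: int
    _group_cache: dict = field(default_factory=dict, repr=False)

    # -- survival contrasts -----------------------------------------------
    def group_survival(
        self, endpoint: str = "pfs", labels: str = "recalibrated"
    ) -> dict[str, dict]:
        """Per-risk-group KM curve, median and the two-group log-rank test."""
        key = (endpoint, labels)
        if key in self._group_cache:
            return self._group_cache[key]
        tcol, ecol = survival.ENDPOINTS[endpoint]
        assignment = self.risk if labels == "recalibrated" else self.cluster_risk
        times = self.imputed_cohort[tcol].to_numpy(dtype=float)
        events = self.imputed_cohort[ecol].to_numpy(dtype=bool)
        out: dict[str, dict] = {}
        groups = []
        for grp in ("high", "low"):
            mask = assignment.risk == grp
            curve = survival.km_estimate(times[mask], events[mask])
            out[grp] = {
                "n": int(mask.sum()),
                "events": int(events[mask].sum()),
                "curve": curve,
                "median": survival.median_survival(curve),
            }
            groups.append((times[mask], events[mask]))
        out["logrank"] = survival.logrank_test(groups)
        self._group_cache[key] = out
        return out

    def median_months(self, endpoint: str = "pfs", labels: str = "recalibrated"):
        gs = self.group_survival(endpoint, labels)
        return {g: gs[g]["median"] for g in ("high", "low")}

    def logrank_p(self, endpoint: str = "pfs", labels: str = "recalibrated") -> float:
        return self.group_survival(endpoint, labels)["logrank"].p_value

    def risk_frame(self) -> pd.DataFrame:
        ids = (
            self.imputed_cohort[ID_COLUMN]
            if ID_COLUMN in self.imputed_cohort.columns
            else None
        )
        return self.risk.to_frame(patient_id=ids)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Stacked risk stratification",
            "=" * 60,
            f"patients: {len(self.imputed_cohort)}    seed: {self.seed}",
            f"PCA components retained: {self.embedding.n_components} "
            f"(energy {self.model.energy:.0%})",
            f"high-risk fraction (recalibrated): "
            f"{float(self.risk.is_high.mean()):.1%}",
            f"FFT training accuracy vs clusters: {self.training_accuracy:.1%} "
            f"(balanced {self.fft.balanced_accuracy:.1%})",
            "",
            "Fast-and-frugal tree:",
            self.fft.describe(),
            "",
        ]
        for endpoint in ("pfs", "os"):
            gs = self.group_survival(endpoint)
            lr = gs["logrank"]
            lines.append(
                f"{endpoint.upper()}: median high {gs['high']['median']} vs "
                f"low {gs['low']['median']} months; "
                f"log-rank chi2 {lr.statistic:.2f}, p {lr.p_value:.2g}"
            )
        return "\n".join(lines)

    def plot_km(self, endpoint: str = "pfs", ax=None):
        """Kaplan–Meier curves of the two risk groups (requires matplotlib)."""
        import matplotlib.pyplot as plt
        from lifelines import KaplanMeierFitter

        if ax is None:
            _, ax = plt.subplots()
        tcol, ecol = survival.ENDPOINTS[endpoint]
        for grp, color in (("low", "tab:orange"), ("high", "black")):
            mask = self.risk.risk == grp
            kmf = KaplanMeierFitter(label=f"{grp} risk")
            kmf.fit(
                self.imputed_cohort.loc[mask, tcol],
                self.imputed_cohort.loc[mask, ecol],
            )
            kmf.plot_survival_function(ax=ax, color=color)
        ax.set_xlabel("months")
        ax.set_ylabel(f"{endpoint.upper()} survival probability")
        return ax
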