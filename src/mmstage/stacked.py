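"""The stacked multivariate risk model.

Pipeline: binarized covariates -> pairwise Hamming distance matrix -> PCA of
that matrix keeping the components that carry 95% of the eigenvalue mass ->
spectral clustering into two groups -> survival-based high/low-risk
labelling -> fast-and-frugal tree (FFT) induction on the cluster labels ->
one-pass label re-calibration by the trained tree.

Running PCA on the distance matrix itself (rather than on the feature
matrix) is deliberate: the distance matrix is the object the procedure
defines, and its leading components embed patients by their dissimilarity
profiles.

An FFT is a lexicographic decision tree: cues are asked in a fixed order and
every non-final cue sends one answer straight to an exit (high or low risk)
while the other answer falls through to the next cue; the final cue exits on
both sides. Induction here ranks cues by marginal balanced accuracy against
the labels, then searches ordered subsets of the top-ranked cues over both
cue directions and all exit structures, returning the tree with the best
training balanced accuracy. On small all-binary cue sets the searched space
coincides with full enumeration, so the result is exactly optimal there.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .preprocess import BinaryMatrix
from .schema import VariableSchema

__all__ = [
    "DegenerateAffinityWarning",
    "PCEmbedding",
    "ClusterLabels",
    "RiskAssignment",
    "FFTCue",
    "FFTModel",
    "hamming_matrix",
    "pca_energy",
    "spectral_cluster",
    "assign_risk",
    "fit_fft",
    "apply_fft",
    "recalibrate",
]

_EIG_TOL = 1e-12


class DegenerateAffinityWarning(UserWarning):
    """The patient affinity graph is degenerate (identical profiles or more
    connected components than clusters); results may be arbitrary."""


# ---------------------------------------------------------------------------
# distance + embedding


def hamming_matrix(binary: BinaryMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances (count of differing coordinates)."""
    if isinstance(binary, BinaryMatrix):
        X = binary.matrix.to_numpy(dtype=float)
    elif isinstance(binary, pd.DataFrame):
        X = binary.to_numpy(dtype=float)
    else:
        X = np.asarray(binary, dtype=float)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("Hamming distance requires a strictly binary matrix")
    n_cols = X.shape[1]
    return squareform(pdist(X, metric="hamming") * n_cols)


@dataclass(frozen=True)
class PCEmbedding:
    """Scores on the leading principal components of the distance matrix."""

    scores: np.ndarray          # n x m component scores
    eigenvalues: np.ndarray     # all eigenvalues, descending
    cumulative_energy: np.ndarray  # cumulative eigenvalue fraction
    n_components: int


def pca_energy(matrix: np.ndarray, energy: float = 0.95) -> PCEmbedding:
    """Project onto the smallest set of principal components whose
    cumulative eigenvalue fraction reaches ``energy``."""
    if not 0.0 < energy <= 1.0:
        raise ValueError(f"energy must be in (0, 1], got {energy}")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(matrix)
    ratios = pca.explained_variance_ratio_.copy()
    ratios[ratios < _EIG_TOL] = 0.0
    cum = np.cumsum(ratios)
    m = int(np.searchsorted(cum, energy - 1e-9) + 1)
    m = min(m, int((ratios > 0).sum()) or 1)
    return PCEmbedding(
        scores=scores[:, :m],
        eigenvalues=pca.explained_variance_,
        cumulative_energy=cum,
        n_components=m,
    )


# ---------------------------------------------------------------------------
# spectral clustering


@dataclass(frozen=True)
class ClusterLabels:
    labels: np.ndarray  # per-patient label in {0, ..., k-1}
    k: int
    seed: int
    params: dict = field(default_factory=dict)


def _rbf_affinity(X: np.ndarray) -> np.ndarray:
    d = squareform(pdist(X))
    nonzero = d[d > 0]
    if nonzero.size == 0:
        warnings.warn(
            "all embedded profiles are identical; affinity is degenerate",
            DegenerateAffinityWarning,
        )
        sigma = 1.0
    else:
        sigma = float(np.median(nonzero))
    return np.exp(-(d**2) / (2.0 * sigma**2))


def _knn_affinity(X: np.ndarray, n_neighbors: int, k: int) -> np.ndarray:
    graph = kneighbors_graph(X, n_neighbors=min(n_neighbors, len(X) - 1))
    A = np.asarray(((graph + graph.T) > 0).todense(), dtype=float)
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(A, directed=False)
    if n_comp > k:
        warnings.warn(
            f"affinity graph splits into {n_comp} components (> k={k})",
            DegenerateAffinityWarning,
        )
    return A

def spectral_cluster(
    embedding: PCEmbedding | np.ndarray,
    k: int = 2,
    seed: int = 0,
    affinity: str = "rbf",
    n_neighbors: int = 10,
) -> ClusterLabels:
    """Normalized spectral clustering of patients in the PC embedding.

    Affinity is a Gaussian kernel with bandwidth equal to the median pairwise
    distance (or a symmetrized k-NN graph with ``affinity="knn"``). The k
    eigenvectors of the symmetric normalized Laplacian with smallest
    eigenvalues are row-normalized and clustered by seeded k-means.
    """
    if affinity not in ("rbf", "knn"):
        raise ValueError(f"unknown affinity {affinity!r}; expected 'rbf' or 'knn'")
    X = embedding.scores if isinstance(embedding, PCEmbedding) else np.asarray(embedding)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} points")
    A = _rbf_affinity(X) if affinity == "rbf" else _knn_affinity(X, n_neighbors, k)
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    M = A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]  # I - L_sym shares eigenvectors
    eigvals, eigvecs = np.linalg.eigh((M + M.T) / 2.0)
    V = eigvecs[:, -k:]  # largest of M == smallest of the Laplacian
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0] = 1.0
    V = V / norms[:, None]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(V)
    sizes = np.bincount(labels, minlength=k)
    if (sizes == 0).any():
        raise ValueError("spectral clustering produced an empty cluster")
    return ClusterLabels(
        labels=labels, k=k, seed=seed,
        params={"affinity": affinity, "n_neighbors": n_neighbors},
    )


# ---------------------------------------------------------------------------
# survival-based risk labels


@dataclass(frozen=True)
class RiskAssignment:
    """Per-patient risk label ('high'/'low') with its provenance."""

    risk: np.ndarray
    provenance: str

    @property
    def is_high(self) -> np.ndarray:
        return self.risk == "high"

    def to_frame(self, patient_id=None) -> pd.DataFrame:
        df = pd.DataFrame({"risk": self.risk, "provenance": self.provenance})
        if patient_id is not None:
            df.insert(0, "patient_id", np.asarray(patient_id))
        return df


def assign_risk(clusters: ClusterLabels, cohort: pd.DataFrame) -> RiskAssignment:
    """Label the cluster with the smaller Kaplan–Meier median PFS as high
    risk; ties go to the cluster with the lower mean observed time."""
    from .survival import km_estimate, median_survival

    times = cohort["pfs_time_months"].to_numpy(dtype=float)
    events = cohort["pfs_event"].to_numpy(dtype=bool)
    if clusters.labels.shape[0] != len(cohort):
        raise ValueError("cluster labels and cohort have different lengths")
    stats = []
    for c in range(clusters.k):
        mask = clusters.labels == c
        med = median_survival(km_estimate(times[mask], events[mask]))
        stats.append((med.value_or_inf, float(times[mask].mean()), c))
    order = sorted(stats)  # smallest median (then mean) first = highest risk
    high_cluster = order[0][2]
    risk = np.where(clusters.labels == high_cluster, "high", "low")
    return RiskAssignment(risk=risk, provenance="cluster")


# ---------------------------------------------------------------------------
# fast-and-frugal tree


@dataclass(frozen=True)
class FFTCue:
    """One tree level. Numeric cues test ``value {direction} threshold``;
    categorical cues test ``value in levels``. ``exit`` is the class assigned
    when the test is true ('high'/'low'); the final cue has exit 'both',
    meaning true -> high and false -> low."""

    variable: str
    kind: str                      # "numeric" | "categorical"
    exit: str                      # "high" | "low" | "both"
    direction: str | None = None   # ">" or "<=" for numeric cues
    threshold: float | None = None
    levels: tuple[str, ...] | None = None

    def condition(self, cohort: pd.DataFrame) -> np.ndarray:
        col = cohort[self.variable]
        if col.isna().any():
            raise ValueError(
                f"cue variable {self.variable!r} has missing values; impute first"
            )
        if self.kind == "numeric":
            v = col.to_numpy(dtype=float)
            return v > self.threshold if self.direction == ">" else v <= self.threshold
        return col.astype(object).isin(self.levels).to_numpy()

    def describe(self) -> str:
        if self.kind == "numeric":
            test = f"{self.variable} {self.direction} {self.threshold:g}"
        else:
            test = f"{self.variable} in {{{', '.join(self.levels)}}}"
        return f"{test} -> {self.exit}"


@dataclass(frozen=True)
class FFTModel:
    cues: tuple[FFTCue, ...]
    balanced_accuracy: float
    accuracy: float
    n_train: int

    def __post_init__(self) -> None:
        if not self.cues or self.cues[-1].exit != "both":
            raise ValueError("the final cue must carry both exits")
        if any(c.exit not in ("high", "low") for c in self.cues[:-1]):
            raise ValueError("non-final cues must have exactly one exit")

    def to_json(self) -> str:
        return json.dumps(
            {
                "cues": [
                    {
                        "variable": c.variable, "kind": c.kind, "exit": c.exit,
                        "direction": c.direction, "threshold": c.threshold,
                        "levels": list(c.levels) if c.levels else None,
                    }
                    for c in self.cues
                ],
                "balanced_accuracy": self.balanced_accuracy,
                "accuracy": self.accuracy,
                "n_train": self.n_train,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FFTModel":
        d = json.loads(text)
        cues = tuple(
            FFTCue(
                variable=c["variable"], kind=c["kind"], exit=c["exit"],
                direction=c.get("direction"), threshold=c.get("threshold"),
                levels=tuple(c["levels"]) if c.get("levels") else None,
            )
            for c in d["cues"]
        )
        return cls(
            cues=cues,
            balanced_accuracy=d["balanced_accuracy"],
            accuracy=d["accuracy"],
            n_train=d["n_train"],
        )

    def describe(self) -> str:
        return "\n".join(f"{i + 1}. {c.describe()}" for i, c in enumerate(self.cues))


def _balanced_accuracy(tp: int, fn: int, tn: int, fp: int) -> float:
    pos, neg = tp + fn, tn + fp
    sens = tp / pos if pos else 0.0
    spec = tn / neg if neg else 0.0
    return 0.5 * (sens + spec)


@dataclass(frozen=True)
class _Candidate:
    """A directed condition for one cue: boolean vector plus its descriptor."""

    cond: np.ndarray
    kind: str
    direction: str | None
    threshold: float | None
    levels: tuple[str, ...] | None
    bacc: float


def _numeric_candidates(v: np.ndarray, y: np.ndarray) -> list[_Candidate]:
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    distinct = np.nonzero(np.diff(vs) > 0)[0]  # split after index i
    if distinct.size == 0:
        return []
    pos, neg = int(y.sum()), int((~y).sum())
    cum_pos = np.cumsum(ys)
    # condition "v > t" at split i: positives above = pos - cum_pos[i]
    baccs = np.empty(distinct.size)
    thresholds = np.empty(distinct.size)
    for j, i in enumerate(distinct):
        thresholds[j] = 0.5 * (vs[i] + vs[i + 1])
        tp = pos - cum_pos[i]
        fp = (len(v) - (i + 1)) - tp
        fn, tn = pos - tp, neg - fp
        baccs[j] = _balanced_accuracy(tp, fn, tn, fp)
    out = []
    for direction, j in ((">", int(np.argmax(baccs))), ("<=", int(np.argmin(baccs)))):
        t = float(thresholds[j])
        cond = v > t if direction == ">" else v <= t
        out.append(
            _Candidate(
                cond=cond, kind="numeric", direction=direction, threshold=t,
                levels=None,
                bacc=baccs[j] if direction == ">" else 1.0 - baccs[j],
            )
        )
    return out


def _categorical_candidates(values: np.ndarray, levels, y: np.ndarray) -> list[_Candidate]:
    present = [lv for lv in levels if (values == lv).any()]
    if len(present) < 2:
        return []
    pos, neg = int(y.sum()), int((~y).sum())
    level_masks = {lv: values == lv for lv in present}
    best = None
    for r in range(1, len(present)):
        for subset in combinations(present, r):
            cond = np.zeros(len(values), dtype=bool)
            for lv in subset:
                cond |= level_masks[lv]
            tp = int((cond & y).sum())
            fp = int(cond.sum()) - tp
            bacc = _balanced_accuracy(tp, pos - tp, neg - fp, fp)
            if best is None or bacc > best[0]:
                best = (bacc, subset, cond)
    bacc, subset, cond = best
    complement = tuple(lv for lv in present if lv not in subset)
    return [
        _Candidate(cond=cond, kind="categorical", direction=None, threshold=None,
                   levels=tuple(subset), bacc=bacc),
        _Candidate(cond=~cond, kind="categorical", direction=None, threshold=None,
                   levels=complement, bacc=1.0 - bacc),
    ]


def fit_fft(
    features: pd.DataFrame,
    labels: RiskAssignment | np.ndarray,
    schema: VariableSchema,
    max_levels: int = 4,
    n_candidates: int = 6,
) -> FFTModel:
    """Induce a fast-and-frugal tree predicting the high/low labels.

    Cues are scored by their best marginal balanced accuracy (numeric cues
    over midpoint thresholds in both directions, categorical cues over level
    subsets); the top ``n_candidates`` cues then enter a branch-and-bound
    search over ordered cue subsets of size <= ``max_levels``, both cue
    directions, and every exit structure. The tree with the highest training
    balanced accuracy wins; ties go to shorter trees, then to the marginal
    cue ranking. When the cue pool itself has at most ``n_candidates`` cues
    this search is exhaustive.
    """
    if isinstance(labels, RiskAssignment):
        y = labels.is_high
    else:
        labels = np.asarray(labels)
        y = labels == "high" if labels.dtype.kind in "OU" else labels.astype(bool)
    n = len(y)
    pos, neg = int(y.sum()), int(n - y.sum())
    if pos < 2 or neg < 2:
        raise ValueError("need at least two patients in each class")

    cue_candidates: list[tuple[str, list[_Candidate]]] = []
    for var in schema.variables:
        if var.name not in features.columns:
            continue
        col = features[var.name]
        if col.isna().any():
            raise ValueError(f"feature {var.name!r} has missing values; impute first")
        if var.kind == "numeric":
            cands = _numeric_candidates(col.to_numpy(dtype=float), y)
        else:
            cands = _categorical_candidates(col.to_numpy(dtype=object), var.levels, y)
        if cands:
            cue_candidates.append((var.name, cands))
    if not cue_candidates:
        raise ValueError("no usable cues (all features are constant)")

    # rank by best marginal balanced accuracy; stable sort keeps schema order on ties
    cue_candidates.sort(key=lambda item: -max(c.bacc for c in item[1]))
    pool = cue_candidates[: max(n_candidates, 1)]

    best: dict = {"bacc": -1.0, "cues": None, "depth": 0}

    def consider(path: list[FFTCue], tp: int, fp: int, tn: int, fn: int) -> None:
        bacc = _balanced_accuracy(tp, fn, tn, fp)
        if bacc > best["bacc"] + 1e-12 or (
            abs(bacc - best["bacc"]) <= 1e-12 and len(path) < best["depth"]
        ):
            best.update(bacc=bacc, cues=tuple(path), depth=len(path))

    def search(used: set, undecided: np.ndarray, tp: int, fp: int, tn: int, fn: int,
               path: list[FFTCue]) -> None:
        pos_m = int((undecided & y).sum())
        neg_m = int(undecided.sum()) - pos_m
        # admissible bound: classify every undecided patient correctly
        if _balanced_accuracy(tp + pos_m, fn, tn + neg_m, fp) <= best["bacc"] + 1e-12:
            if best["cues"] is not None:
                return
        for name, cands in pool:
            if name in used:
                continue
            for cand in cands:
                cue_kwargs = dict(
                    variable=name, kind=cand.kind, direction=cand.direction,
                    threshold=cand.threshold, levels=cand.levels,
                )
                hit = undecided & cand.cond
                miss = undecided & ~cand.cond
                hit_pos = int((hit & y).sum())
                hit_neg = int(hit.sum()) - hit_pos
                miss_pos = pos_m - hit_pos
                miss_neg = neg_m - hit_neg
                # final cue: true -> high, false -> low
                consider(
                    path + [FFTCue(exit="both", **cue_kwargs)],
                    tp + hit_pos, fp + hit_neg, tn + miss_neg, fn + miss_pos,
                )
                if len(path) + 1 < max_levels and miss.any():
                    # non-final, exit high on the true side
                    search(used | {name}, miss, tp + hit_pos, fp + hit_neg, tn, fn,
                           path + [FFTCue(exit="high", **cue_kwargs)])
                    # non-final, exit low on the true side
                    search(used | {name}, miss, tp, fp, tn + hit_neg, fn + hit_pos,
                           path + [FFTCue(exit="low", **cue_kwargs)])

    all_undecided = np.ones(n, dtype=bool)
    search(set(), all_undecided, 0, 0, 0, 0, [])

    cues = best["cues"]
    model = FFTModel(cues=cues, balanced_accuracy=best["bacc"], accuracy=0.0, n_train=n)
    predicted = apply_fft(model, features).is_high
    accuracy = float((predicted == y).mean())
    return FFTModel(
        cues=cues, balanced_accuracy=float(best["bacc"]), accuracy=accuracy, n_train=n
    )


def apply_fft(model: FFTModel, cohort: pd.DataFrame) -> RiskAssignment:
    """Route each patient through the cues, exiting at the first decisive one."""
    missing = [c.variable for c in model.cues if c.variable not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks cue variables {missing}")
    n = len(cohort)
    risk = np.empty(n, dtype=object)
    undecided = np.ones(n, dtype=bool)
    for cue in model.cues:
        cond = cue.condition(cohort)
        if cue.exit == "both":
            risk[undecided & cond] = "high"
            risk[undecided & ~cond] = "low"
            undecided[:] = False
        else:
            hit = undecided & cond
            risk[hit] = cue.exit
            undecided &= ~cond
    return RiskAssignment(risk=risk.astype(str), provenance="fft-recalibrated")


def recalibrate(
    clusters: RiskAssignment, model: FFTModel, cohort: pd.DataFrame
) -> tuple[RiskAssignment, float]:
    """One pass of the trained tree over the cohort: the tree's outputs become
    the final labels, and agreement with the cluster labels is reported as the
    training accuracy."""
    final = apply_fft(model, cohort)
    accuracy = float((final.risk == clusters.risk).mean())
    return final, accuracy
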