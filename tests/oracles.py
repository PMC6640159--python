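"""Independent reference implementations used only by the tests.

Everything here is deliberately naive — brute force and textbook formulas —
so that agreement with the package is meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def brute_force_1d_split(values):
    """Exhaustively minimize two-cluster WCSS over all splits of sorted values.

    WCSS is computed in exact rational arithmetic (floats are exact
    rationals) so ties break deterministically: prefer the more balanced
    split, then the lower cutoff. Returns (best_wcss, cutoff).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    best = None
    for i in range(1, n):
        if v[i - 1] == v[i]:  # a threshold rule cannot separate equal values
            continue
        wcss = Fraction(0)
        for part in (v[:i], v[i:]):
            s1 = sum((Fraction(x) for x in part), Fraction(0))
            s2 = sum((Fraction(x) * Fraction(x) for x in part), Fraction(0))
            wcss += s2 - s1 * s1 / len(part)
        key = (wcss, abs(n - 2 * i), v[i - 1])
        if best is None or key < best[0]:
            best = (key, v[i - 1])
    return float(best[0][0]), best[1]


def km_product_limit(times, events):
    """Textbook product-limit estimator: (event_times, survival)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    uniq = np.unique(times[events])
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1.0 - d / at_risk
        surv.append(s)
    return uniq, np.array(surv)


def logrank_statistic(times, events, groups):
    """Textbook log-rank chi-square for any number of groups.

    statistic = sum over groups of (O_g - E_g)^2 / E_g is the classic
    two-group approximation; for exactness with the package (which uses the
    full variance form via lifelines) we implement the standard
    multivariate form: U' V^-1 U over the first k-1 groups.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    U = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & events).sum()
        n_g = np.array([(at_risk & (groups == g)).sum() for g in labels])
        d_g = np.array([((times == t) & events & (groups == g)).sum() for g in labels])
        e_g = d * n_g / n
        U += d_g - e_g
        if n > 1:
            frac = d * (n - d) / (n - 1)
            for a in range(k):
                for b in range(k):
                    delta = 1.0 if a == b else 0.0
                    V[a, b] += frac * (n_g[a] / n) * (delta - n_g[b] / n)
    Ur = U[:-1]
    Vr = V[:-1, :-1]
    return float(Ur @ np.linalg.pinv(Vr) @ Ur)


def hamming_loop(matrix):
    """Naive double-loop Hamming distance matrix."""
    X = np.asarray(matrix)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sum(X[i] != X[j])
    return D


def _balanced_accuracy(tp, fp, tn, fn):
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return 0.5 * (sens + spec)


def exhaustive_fft_best_bacc(X, y, max_levels=4):
    """Best training balanced accuracy over *all* fast-and-frugal trees.

    X: (n, p) binary array (each column is a cue; direction "value == 1
    sends you along the cue" or its negation); y: binary labels (1 = high).
    Enumerates every ordered cue subset up to max_levels, both directions
    per cue, and every exit structure (each non-final cue exits high or
    low; the final cue exits both ways with either polarity).
    """
    X = np.asarray(X, dtype=int)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    best = 0.0
    for depth in range(1, min(max_levels, p) + 1):
        for order in itertools.permutations(range(p), depth):
            for dirs in itertools.product((0, 1), repeat=depth):
                # cue fires when X[:, c] == dirs[level]
                for exits in itertools.product((0, 1), repeat=depth - 1):
                    for final_high_on_fire in (0, 1):
                        pred = np.full(n, -1)
                        undecided = np.ones(n, dtype=bool)
                        for level, cue in enumerate(order):
                            fire = X[:, cue] == dirs[level]
                            if level < depth - 1:
                                out = exits[level]
                                take = undecided & fire
                                pred[take] = out
                                undecided &= ~fire
                            else:
                                pred[undecided & fire] = final_high_on_fire
                                pred[undecided & ~fire] = 1 - final_high_on_fire
                        tp = np.sum((pred == 1) & (y == 1))
                        fp = np.sum((pred == 1) & (y == 0))
                        tn = np.sum((pred == 0) & (y == 0))
                        fn = np.sum((pred == 0) & (y == 1))
                        best = max(best, _balanced_accuracy(tp, fp, tn, fn))
    return best


def planted_partition(seed, n=250, p=30, divergence=0.4, flip=0.1):
    """Two-prototype binary planted partition; returns (X, labels)."""
    rng = np.random.default_rng(seed)
    proto0 = rng.random(p) < 0.5
    proto1 = proto0 ^ (rng.random(p) < divergence)
    labels = rng.random(n) < 0.5
    X = np.where(labels[:, None], proto1, proto0) ^ (rng.random((n, p)) < flip)
    return X.astype(float), labels.astype(int)
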