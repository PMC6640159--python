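import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mmstage.schema import Variable, VariableSchema
from mmstage.stacked import (
    DegenerateAffinityWarning,
    FFTCue,
    FFTModel,
    apply_fft,
    assign_risk,
    fit_fft,
    hamming_matrix,
    pca_energy,
    recalibrate,
    spectral_cluster,
)

from .oracles import exhaustive_fft_best_bacc, hamming_loop, planted_partition

# -- Hamming ---------------------------------------------------------------


def test_hamming_matches_loop_oracle(rng):
    X = (rng.random((20, 10)) < 0.5).astype(float)
    D = hamming_matrix(X)
    np.testing.assert_array_equal(D, hamming_loop(X))
    assert (D == D.T).all()
    assert (np.diag(D) == 0).all()
    assert D.max() <= X.shape[1]


def test_hamming_rejects_non_binary():
    with pytest.raises(ValueError):
        hamming_matrix(np.array([[0.0, 0.5], [1.0, 0.0]]))


# -- PCA energy ------------------------------------------------------------


def test_pca_energy_minimality(rng):
    X = (rng.random((40, 15)) < 0.5).astype(float)
    emb = pca_energy(hamming_matrix(X), energy=0.95)
    m = emb.n_components
    assert emb.cumulative_energy[m - 1] >= 0.95 - 1e-9
    if m > 1:
        assert emb.cumulative_energy[m - 2] < 0.95
    assert (np.diff(emb.eigenvalues) <= 1e-9).all()
    assert emb.scores.shape == (40, m)


def test_pca_energy_rank_one():
    base = np.array([[0.0, 2.0], [2.0, 0.0]])
    D = np.kron(np.ones((2, 2)), base)[:3, :3]  # symmetric, low rank
    emb = pca_energy((D + D.T) / 2, energy=0.95)
    assert emb.n_components >= 1


def test_pca_energy_validates():
    with pytest.raises(ValueError):
        pca_energy(np.zeros((3, 4)))
    with pytest.raises(ValueError):
        pca_energy(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        pca_energy(np.zeros((3, 3)), energy=0.0)


# -- spectral clustering ---------------------------------------------------


def _embed(X):
    return pca_energy(hamming_matrix(X))


def test_spectral_recovers_planted_partition():
    X, truth = planted_partition(seed=0)
    res = spectral_cluster(_embed(X), k=2, seed=0)
    assert adjusted_rand_score(truth, res.labels) >= 0.9


def test_spectral_permutation_invariant():
    X, _ = planted_partition(seed=1, n=100)
    emb = _embed(X)
    a = spectral_cluster(emb, k=2, seed=0).labels
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(X))
    b = spectral_cluster(_embed(X[perm]), k=2, seed=0).labels
    assert adjusted_rand_score(a[perm], b) == pytest.approx(1.0)


def test_spectral_knn_affinity_runs():
    X, truth = planted_partition(seed=2)
    res = spectral_cluster(_embed(X), k=2, seed=0, affinity="knn")
    assert set(res.labels) <= {0, 1}


def test_spectral_degenerate_affinity_warns():
    X = np.zeros((12, 6))
    with pytest.warns(DegenerateAffinityWarning):
        spectral_cluster(pca_energy(hamming_matrix(X)), k=2, seed=0)


def test_spectral_rejects_unknown_affinity():
    X, _ = planted_partition(seed=3, n=30)
    with pytest.raises(ValueError):
        spectral_cluster(_embed(X), k=2, seed=0, affinity="cosine")


# -- risk assignment -------------------------------------------------------


def test_assign_risk_smaller_median_is_high(small_cohort):
    from mmstage.preprocess import binarize
    from mmstage.schema import MULTIVARIATE_EXCLUDED, default_schema
    from mmstage.survival import km_estimate, kmeans_1d_cutoff, median_survival

    schema = default_schema().drop(MULTIVARIATE_EXCLUDED)
    cuts = {
        v.name: kmeans_1d_cutoff(small_cohort[v.name].to_numpy(dtype=float)).cutoff
        for v in schema.numeric
    }
    emb = pca_energy(hamming_matrix(binarize(small_cohort, schema, cuts)))
    clusters = spectral_cluster(emb, k=2, seed=0)
    risk = assign_risk(clusters, small_cohort)
    t = small_cohort["pfs_time_months"].to_numpy(dtype=float)
    e = small_cohort["pfs_event"].to_numpy(dtype=bool)
    med = {
        lab: median_survival(km_estimate(t[risk.risk == lab], e[risk.risk == lab]))
        for lab in ("high", "low")
    }
    assert med["high"].value_or_inf < med["low"].value_or_inf
    assert set(risk.risk) == {"high", "low"}


# -- FFT -------------------------------------------------------------------


def _binary_frame(X):
    schema = VariableSchema(
        tuple(
            Variable(f"c{j}", "categorical", levels=("0", "1"))
            for j in range(X.shape[1])
        )
    )
    frame = pd.DataFrame(
        {f"c{j}": X[:, j].astype(int).astype(str) for j in range(X.shape[1])}
    )
    return frame, schema


def test_fft_matches_exhaustive_oracle_sample(rng):
    done = 0
    while done < 10:
        n = int(rng.integers(8, 31))
        p = int(rng.integers(1, 5))
        X = (rng.random((n, p)) < 0.5).astype(int)
        y = (rng.random(n) < 0.5).astype(int)
        if y.sum() < 2 or (1 - y).sum() < 2:
            continue
        frame, schema = _binary_frame(X)
        labels = np.where(y == 1, "high", "low")
        model = fit_fft(frame, labels, schema)
        assert model.balanced_accuracy == pytest.approx(
            exhaustive_fft_best_bacc(X, y), abs=1e-9
        )
        done += 1


def test_fft_structure_invariants(small_cohort, schema):
    from mmstage.schema import MULTIVARIATE_EXCLUDED

    stack = schema.drop(MULTIVARIATE_EXCLUDED)
    labels = np.where(
        small_cohort["latent_group"].to_numpy() == "high", "high", "low"
    )
    model = fit_fft(small_cohort[stack.names], labels, stack)
    assert 1 <= len(model.cues) <= 4
    assert model.cues[-1].exit == "both"
    assert all(c.exit in ("high", "low") for c in model.cues[:-1])
    assert len({c.variable for c in model.cues}) == len(model.cues)
    assert 0.0 <= model.balanced_accuracy <= 1.0
    clone = FFTModel.from_json(model.to_json())
    assert clone == model
    # the tree applied to its own training data reproduces the stored accuracy
    final, agreement = recalibrate(
        apply_fft(model, small_cohort), model, small_cohort
    )
    assert agreement == pytest.approx(1.0)


def test_fft_needs_both_classes(small_cohort, schema):
    labels = np.array(["high"] * len(small_cohort))
    with pytest.raises(ValueError):
        fit_fft(small_cohort[["albumin"]], labels, schema.subset(("albumin",)))


def test_apply_fft_missing_column():
    cue = FFTCue(variable="albumin", kind="numeric", exit="both",
                 direction="<=", threshold=3.5)
    model = FFTModel(cues=(cue,), balanced_accuracy=1.0, accuracy=1.0, n_train=4)
    with pytest.raises(ValueError, match="albumin"):
        apply_fft(model, pd.DataFrame({"gfr": [50.0]}))


def test_fft_model_validates_structure():
    final = FFTCue(variable="a", kind="categorical", exit="both", levels=("yes",))
    bad = FFTCue(variable="b", kind="categorical", exit="both", levels=("yes",))
    with pytest.raises(ValueError):
        FFTModel(cues=(bad, final), balanced_accuracy=0.5, accuracy=0.5, n_train=4)
    with pytest.raises(ValueError):
        FFTModel(
            cues=(FFTCue(variable="a", kind="categorical", exit="high",
                         levels=("yes",)),),
            balanced_accuracy=0.5, accuracy=0.5, n_train=4,
        )
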