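"""PCA/OPLS-DA model correctness against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from nmrmetab import multivariate as mv
from nmrmetab import preprocess as pp
from nmrmetab import synth

from conftest import matrix_from_array, noiseless_design


def pls1_nipals_oracle(X, y, tol=1e-12, max_iter=500):
    """Brute-force one-component PLS1 by NIPALS iteration, written
    independently of the package implementation."""
    X = np.asarray(X, float)
    yc = np.asarray(y, float) - np.mean(y)
    w = X.T @ yc
    for _ in range(max_iter):
        w_new = X.T @ (X @ w)
        w_new = w_new / np.linalg.norm(w_new)
        # NIPALS for PLS1 converges in one step since Y has one column;
        # iterate on the deflation-free weight update to be safe
        if np.linalg.norm(w_new - w / np.linalg.norm(w)) < tol:
            break
        w = w_new
    # canonical PLS1 weight is X'y normalized
    w = X.T @ yc
    w = w / np.linalg.norm(w)
    t = X @ w
    return w, t


def _two_class_matrix(rng, n=12, p=30, shift=0.0):
    X = rng.normal(size=(n, p))
    groups = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    if shift:
        X[n // 2 :, : max(1, p // 10)] += shift
    X = X - X.mean(axis=0)
    return X, groups


# --- PCA -------------------------------------------------------------------

def test_pca_rank_one_data_explained_by_first_component():
    rng = np.random.default_rng(0)
    u = rng.normal(size=15)
    v = rng.normal(size=40)
    X = np.outer(u, v)
    m = matrix_from_array(X, ["g"] * 15)
    fit = mv.fit_pca(m, 2)
    assert fit.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_reconstruction_residual_matches_unexplained_variance():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(15, 25))
    Xc = X - X.mean(axis=0)
    m = matrix_from_array(Xc, ["g"] * 15)
    k = 4
    fit = mv.fit_pca(m, k)
    recon = fit.scores @ fit.loadings.T
    resid = np.linalg.norm(Xc - recon) ** 2
    total = np.linalg.norm(Xc) ** 2
    expected = (1.0 - fit.explained_variance_fraction.sum()) * total
    assert resid == pytest.approx(expected, rel=1e-8)
    with pytest.raises(ValueError):
        mv.fit_pca(m, 100)


def test_pca_separates_strong_synthetic_groups(library, disease_effects):
    """Amplified group effects produce group separation along PC1."""
    frame = disease_effects.frame.copy()
    frame["fold_change"] = frame["fold_change"] ** 3  # amplify each effect
    design = noiseless_design(noise_sd=0.2, biological_cv=0.05,
                              n_per_group=6, n_points=4096, seed=3)
    sset = synth.simulate_cohort(library, synth.EffectTable(frame), design)
    trimmed = [pp.exclude_region(s) for s in sset.spectra]
    binned = pp.adaptive_bin(trimmed)
    normalized, _ = pp.pqn_normalize(binned)
    scaled = pp.scale_features(normalized)
    fit = mv.fit_pca(scaled, 2)
    pc1 = fit.scores[:, 0]
    labels = scaled.groups.to_numpy()
    from sklearn.metrics import silhouette_score

    assert silhouette_score(pc1[:, None], labels) > 0


# --- OPLS-DA ---------------------------------------------------------------

def test_zero_orthogonal_fit_equals_pls1_oracle():
    """With no orthogonal filtering the predictive component is exactly a
    one-component PLS1 fit (up to sign), on 20 random matrices."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        X, groups = _two_class_matrix(rng)
        m = matrix_from_array(X, groups)
        fit = mv.fit_oplsda(m, ("A", "B"), n_orthogonal=0)
        y = np.where(np.array(groups) == "B", 1.0, -1.0)
        w_ref, t_ref = pls1_nipals_oracle(X, y)
        sign = np.sign(w_ref @ fit.predictive_weights)
        np.testing.assert_allclose(fit.predictive_weights, sign * w_ref, atol=1e-10)
        np.testing.assert_allclose(fit.predictive_scores, sign * t_ref, atol=1e-10)


def test_vip_identity_and_symmetry():
    rng = np.random.default_rng(7)
    X, groups = _two_class_matrix(rng, shift=1.0)
    fit = mv.fit_oplsda(matrix_from_array(X, groups), ("A", "B"), 1)
    assert np.mean(fit.vip**2) == pytest.approx(1.0, abs=1e-8)
    # identical columns carry identical (hence unit) importance
    col = rng.normal(size=12)
    col[6:] += 2.0
    X_same = np.tile(col[:, None], (1, 8))
    X_same = X_same - X_same.mean(axis=0)
    fit_same = mv.fit_oplsda(matrix_from_array(X_same, groups), ("A", "B"), 0)
    np.testing.assert_allclose(fit_same.vip, 1.0, atol=1e-10)


def test_vip_flags_the_informative_feature():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(16, 20)) * 0.05
    groups = ["A"] * 8 + ["B"] * 8
    X[8:, 13] += 3.0  # the only class-informative feature
    X = X - X.mean(axis=0)
    fit = mv.fit_oplsda(matrix_from_array(X, groups), ("A", "B"), 1)
    assert int(np.argmax(fit.vip)) == 13
    assert fit.vip[13] > 1.0


def test_permuted_labels_reduce_r2y(library, disease_effects):
    rng = np.random.default_rng(5)
    design = noiseless_design(noise_sd=0.3, biological_cv=0.1,
                              n_per_group=8, n_points=4096, seed=5)
    sset = synth.simulate_cohort(library, disease_effects, design)
    trimmed = [pp.exclude_region(s) for s in sset.spectra]
    normalized, _ = pp.pqn_normalize(pp.adaptive_bin(trimmed))
    scaled = pp.scale_features(normalized)
    true_fit = mv.fit_oplsda(scaled, ("WKY-N", "SHR-N"), 1)
    shuffled = scaled.sample_meta.copy()
    shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
    perm_matrix = pp.FeatureMatrix(scaled.values, scaled.feature_meta,
                                   shuffled, "scaled")
    perm_fit = mv.fit_oplsda(perm_matrix, ("WKY-N", "SHR-N"), 1)
    assert perm_fit.r2y < true_fit.r2y


def test_orthogonal_component_absorbs_confounder():
    """A class-balanced batch shift hurts the 0-orthogonal fit more than
    the 1-orthogonal fit."""
    rng = np.random.default_rng(9)
    n = 20
    X = rng.normal(size=(n, 30)) * 0.3
    groups = ["A"] * 10 + ["B"] * 10
    X[10:, :3] += 1.0  # class effect
    batch = np.zeros(n)
    batch[::2] = 1.0  # half of each class
    X += np.outer(batch, rng.normal(size=30) * 2.0)  # strong confounder
    X = X - X.mean(axis=0)
    m = matrix_from_array(X, groups)
    r2y_0 = mv.fit_oplsda(m, ("A", "B"), 0).r2y
    r2y_1 = mv.fit_oplsda(m, ("A", "B"), 1).r2y
    assert r2y_1 >= r2y_0


def test_score_orthogonality_and_r2x_partition():
    rng = np.random.default_rng(11)
    for _ in range(10):
        X, groups = _two_class_matrix(rng, n=14, p=25, shift=1.0)
        fit = mv.fit_oplsda(matrix_from_array(X, groups), ("A", "B"), 2)
        t = fit.predictive_scores
        for k in range(fit.orthogonal_scores.shape[1]):
            t_o = fit.orthogonal_scores[:, k]
            cos = abs(t @ t_o) / (np.linalg.norm(t) * np.linalg.norm(t_o))
            assert cos < 1e-8
        # explained + residual = total X variance
        Xhat = np.outer(fit.predictive_scores, fit.predictive_loadings)
        Xhat += fit.orthogonal_scores @ fit.orthogonal_loadings.T
        resid = X - Xhat
        total = (X**2).sum()
        explained = fit.r2x * total
        assert explained + (resid**2).sum() == pytest.approx(total, rel=1e-6)


def test_class_contract_errors():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(9, 5))
    with pytest.raises(ValueError, match="pairwise|2 classes"):
        mv.fit_oplsda(matrix_from_array(X, ["A"] * 3 + ["B"] * 3 + ["C"] * 3))
    with pytest.raises(ValueError, match="fewer than 3"):
        mv.fit_oplsda(matrix_from_array(X, ["A"] * 7 + ["B"] * 2), ("A", "B"))


# --- cross-validation and permutation test ---------------------------------

def test_q2_deterministic_and_strong_effects_score_high(library, disease_effects):
    frame = disease_effects.frame.copy()
    frame["fold_change"] = frame["fold_change"] ** 3
    design = noiseless_design(noise_sd=0.3, biological_cv=0.1,
                              n_per_group=10, n_points=4096, seed=6)
    sset = synth.simulate_cohort(library, synth.EffectTable(frame), design)
    trimmed = [pp.exclude_region(s) for s in sset.spectra]
    normalized, _ = pp.pqn_normalize(pp.adaptive_bin(trimmed))
    scaled = pp.scale_features(normalized)
    q2a = mv.cross_validate_q2(scaled, ("WKY-N", "SHR-N"), 1, 7, seed=1)
    q2b = mv.cross_validate_q2(scaled, ("WKY-N", "SHR-N"), 1, 7, seed=1)
    assert q2a == q2b
    assert q2a > 0.5


def test_null_q2_stays_low():
    """Pure-noise classes: Q2 near or below zero at n = 20 (50 draws)."""
    rng = np.random.default_rng(13)
    groups = ["A"] * 10 + ["B"] * 10
    vals = []
    for _ in range(50):
        X = rng.normal(size=(20, 30))
        X = X - X.mean(axis=0)
        m = matrix_from_array(X, groups)
        vals.append(mv.cross_validate_q2(m, ("A", "B"), 1, 3,
                                         seed=int(rng.integers(2**31))))
    assert np.mean(vals) <= 0.2


def test_permutation_p_floor_and_determinism():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(20, 25)) * 0.05
    # unbalanced classes: no permutation can mirror the labelling exactly
    groups = ["A"] * 9 + ["B"] * 11
    X[9:, :5] += 2.0  # overwhelming effect: observed beats every permutation
    X = X - X.mean(axis=0)
    m = matrix_from_array(X, groups)
    res = mv.permutation_test(m, ("A", "B"), 1, n_permutations=99, seed=0,
                              n_repeats=1)
    assert res.p_value == pytest.approx(1.0 / 100.0)
    assert res.permuted_q2.size == 99
    res2 = mv.permutation_test(m, ("A", "B"), 1, n_permutations=99, seed=0,
                               n_repeats=1)
    assert res2.p_value == res.p_value
    np.testing.assert_array_equal(res2.permuted_q2, res.permuted_q2)


def test_coefficient_loadings_sign_and_bounds():
    rng = np.random.default_rng(19)
    X = rng.normal(size=(16, 12)) * 0.1
    groups = ["A"] * 8 + ["B"] * 8
    X[8:, :6] += 1.0
    X[8:, 6:9] -= 1.0
    Xc = X - X.mean(axis=0)
    Xc[:, 11] = 0.0  # degenerate feature
    m = matrix_from_array(Xc, groups)
    fit = mv.fit_oplsda(m, ("A", "B"), 0)
    with pytest.warns(UserWarning, match="zero-variance"):
        lo = mv.coefficient_loadings(fit, m)
    assert (lo["correlation"].abs() <= 1.0 + 1e-12).all()
    contrast = Xc[8:].mean(axis=0) - Xc[:8].mean(axis=0)
    strong = np.abs(contrast) > 0.5
    assert np.all(np.sign(lo["covariance"][strong]) == np.sign(contrast[strong]))
    assert lo.loc[11, "covariance"] == 0.0 and lo.loc[11, "correlation"] == 0.0
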