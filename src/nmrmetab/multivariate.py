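"""PCA and OPLS-DA with cross-validated and permutation-based validation.

OPLS-DA here is the NIPALS orthogonal-signal-correction construction: for a
two-class problem with class membership coded -1/+1, components of X
variation orthogonal to the class vector are extracted and removed, after
which a single predictive PLS component is fitted on the filtered matrix.
With zero orthogonal components the predictive component coincides with a
one-component PLS1 fit. Q2 is estimated by repeated stratified two-fold
cross-validation with fold-wise re-centering (orthogonal components are
re-estimated inside each training fold, so no information leaks from held
out samples), and model significance by a permutation test on Q2 with the
add-one p-value estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .preprocess import FeatureMatrix


@dataclass
class PcaModel:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components, orthonormal columns
    explained_variance_fraction: np.ndarray
    sample_index: pd.Index
    groups: pd.Series


@dataclass
class OplsdaModel:
    classes: tuple[str, str]  # (coded -1, coded +1)
    y: np.ndarray
    predictive_scores: np.ndarray
    predictive_weights: np.ndarray
    predictive_loadings: np.ndarray
    predictive_q: float
    orthogonal_scores: np.ndarray  # samples x k
    orthogonal_weights: np.ndarray  # features x k
    orthogonal_loadings: np.ndarray  # features x k
    r2x: float
    r2y: float
    vip: np.ndarray
    q2: float | None = None
    sample_index: pd.Index | None = None
    feature_index: pd.Index | None = None


@dataclass
class PermutationResult:
    n_permutations: int
    observed_q2: float
    permuted_q2: np.ndarray
    p_value: float


def _check_scaled(matrix: FeatureMatrix) -> None:
    if matrix.stage != "scaled":
        raise ValueError("expected a scaled feature matrix")


def fit_pca(matrix: FeatureMatrix, n_components: int = 2) -> PcaModel:
    """Principal component analysis of a scaled feature matrix."""
    _check_scaled(matrix)
    X = matrix.values.to_numpy(float)
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}]")
    pca = _SKPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaModel(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance_fraction=pca.explained_variance_ratio_,
        sample_index=matrix.values.index,
        groups=matrix.groups,
    )


def _encode_classes(groups: pd.Series, classes: tuple[str, str] | None) -> tuple[np.ndarray, tuple[str, str]]:
    labels = list(pd.unique(groups))
    if classes is None:
        if len(labels) != 2:
            raise ValueError(
                f"exactly 2 classes required, got {labels}; fit pairwise contrasts"
            )
        classes = (labels[0], labels[1])
    mask = groups.isin(classes)
    if not mask.all():
        raise ValueError("all samples must belong to one of the two classes")
    y = np.where(groups.to_numpy() == classes[1], 1.0, -1.0)
    for cls in classes:
        if (groups == cls).sum() < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
    return y, classes


def _fit_opls(X: np.ndarray, y: np.ndarray, n_orthogonal: int) -> dict:
    """Core NIPALS orthogonal-filter + single predictive component fit.

    Assumes X column-centered and y centered (the public entry points and
    the CV loop take care of centering). Returns plain arrays for speed.
    """
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    Xr = X.copy()
    w_os, p_os, t_os = [], [], []
    for _ in range(n_orthogonal):
        w = Xr.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o /= n_o
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / (t_o @ t_o)
        Xr = Xr - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
    w = Xr.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("degenerate fit: X carries no covariance with the classes")
    w /= nw
    t = Xr @ w
    p = Xr.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    if q < 0:  # sign convention: second-listed class has positive mean score
        w, t, p, q = -w, -t, -p, -q
    ss_x = float((X * X).sum())
    ss_pred = float((t @ t) * (p @ p))
    ss_orth = sum(float((to @ to) * (po @ po)) for to, po in zip(t_os, p_os))
    resid = yc - q * t
    return {
        "w": w, "t": t, "p": p, "q": q,
        "w_o": np.column_stack(w_os) if w_os else np.zeros((X.shape[1], 0)),
        "p_o": np.column_stack(p_os) if p_os else np.zeros((X.shape[1], 0)),
        "t_o": np.column_stack(t_os) if t_os else np.zeros((X.shape[0], 0)),
        "r2x": (ss_pred + ss_orth) / ss_x if ss_x > 0 else 0.0,
        "r2y": 1.0 - float(resid @ resid) / ss_y if ss_y > 0 else 0.0,
    }


def _predict(fit: dict, X: np.ndarray) -> np.ndarray:
    """Predict centered responses: orthogonal filtering then t * q."""
    Xr = X.copy()
    for k in range(fit["w_o"].shape[1]):
        t_o = Xr @ fit["w_o"][:, k]
        Xr = Xr - np.outer(t_o, fit["p_o"][:, k])
    return (Xr @ fit["w"]) * fit["q"]


def fit_oplsda(
    matrix: FeatureMatrix,
    classes: tuple[str, str] | None = None,
    n_orthogonal: int = 1,
) -> OplsdaModel:
    """Fit OPLS-DA on a scaled matrix; class order fixes the score sign."""
    _check_scaled(matrix)
    y, classes = _encode_classes(matrix.groups, classes)
    X = matrix.values.to_numpy(float)
    fit = _fit_opls(X, y, n_orthogonal)
    vip = np.sqrt(X.shape[1]) * np.abs(fit["w"])
    return OplsdaModel(
        classes=classes,
        y=y,
        predictive_scores=fit["t"],
        predictive_weights=fit["w"],
        predictive_loadings=fit["p"],
        predictive_q=fit["q"],
        orthogonal_scores=fit["t_o"],
        orthogonal_weights=fit["w_o"],
        orthogonal_loadings=fit["p_o"],
        r2x=fit["r2x"],
        r2y=fit["r2y"],
        vip=vip,
        sample_index=matrix.values.index,
        feature_index=matrix.feature_meta.index,
    )


def compute_vip(model: OplsdaModel, mode: str = "predictive") -> np.ndarray:
    """Variable importance in the projection.

    ``predictive`` (default) scores features on the single discriminant
    component: VIP_j = sqrt(p) * |w_j| with unit-norm weights, so the mean
    squared VIP is exactly 1. ``total`` weights every component by its
    share of explained class variance; with one predictive component and
    near-class-orthogonal filtered components the two variants coincide up
    to the (tiny) y-variance of the orthogonal parts.
    """
    if model.predictive_weights is None:
        raise ValueError("model is not fitted")
    p = model.predictive_weights.size
    if mode == "predictive":
        return np.sqrt(p) * np.abs(model.predictive_weights)
    if mode != "total":
        raise ValueError("mode must be 'predictive' or 'total'")
    yc = model.y - model.y.mean()
    comps = [(model.predictive_weights, model.predictive_scores)]
    for k in range(model.orthogonal_scores.shape[1]):
        comps.append((model.orthogonal_weights[:, k], model.orthogonal_scores[:, k]))
    ssy = []
    for w, t in comps:
        q = yc @ t / (t @ t)
        ssy.append(float((q * t) @ (q * t)))
    ssy_arr = np.array(ssy)
    W2 = np.column_stack([w**2 for w, _ in comps])
    return np.sqrt(p * (W2 @ ssy_arr) / ssy_arr.sum())


def coefficient_loadings(
    model: OplsdaModel, matrix: FeatureMatrix
) -> pd.DataFrame:
    """Back-scaled covariance and correlation of features with the
    predictive scores, the (value, color) pair of a coefficient plot."""
    _check_scaled(matrix)
    X = matrix.values.to_numpy(float)
    t = model.predictive_scores
    if X.shape[0] != t.size:
        raise ValueError("matrix and model have mismatched sample counts")
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    corr = np.zeros_like(cov)
    ok = (sx > 0) & (st > 0)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} zero-variance feature(s): loadings set to 0",
                      stacklevel=2)
        cov = np.where(ok, cov, 0.0)
    np.divide(cov, sx * st, out=corr, where=ok)
    return pd.DataFrame({"covariance": cov, "correlation": corr})


def _stratified_two_fold(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask: True = fold A. Each class split as evenly as possible."""
    fold_a = np.zeros(y.size, bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold_a[idx[: idx.size // 2]] = True
    return fold_a


def _q2_from_arrays(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int,
    n_repeats: int,
    rng: np.random.Generator,
) -> float:
    q2s = []
    for _ in range(n_repeats):
        fold_a = _stratified_two_fold(y, rng)
        press = tss = 0.0
        for test_mask in (fold_a, ~fold_a):
            train = ~test_mask
            mu = X[train].mean(axis=0)
            ym = y[train].mean()
            fit = _fit_opls(X[train] - mu, y[train], n_orthogonal)
            pred = _predict(fit, X[test_mask] - mu) + ym
            press += float(((y[test_mask] - pred) ** 2).sum())
            tss += float(((y[test_mask] - ym) ** 2).sum())
        q2s.append(1.0 - press / tss)
    return float(np.mean(q2s))


def cross_validate_q2(
    matrix: FeatureMatrix,
    classes: tuple[str, str] | None = None,
    n_orthogonal: int = 1,
    n_repeats: int = 7,
    seed: int = 0,
) -> float:
    """Q2 = 1 - PRESS/TSS over repeated stratified two-fold splits."""
    _check_scaled(matrix)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y, _ = _encode_classes(matrix.groups, classes)
    X = matrix.values.to_numpy(float)
    rng = np.random.default_rng(seed)
    return _q2_from_arrays(X, y, n_orthogonal, n_repeats, rng)


def permutation_test(
    matrix: FeatureMatrix,
    classes: tuple[str, str] | None = None,
    n_orthogonal: int = 1,
    n_permutations: int = 2000,
    seed: int = 0,
    n_repeats: int = 7,
) -> PermutationResult:
    """Permutation test on Q2 with p = (1 + #{Q2_perm >= Q2_obs}) / (n + 1).

    The cross-validation procedure (splits derived from one seed) is applied
    identically to the observed and every permuted labelling, so under a
    label-exchangeable null the p-value is uniform on its achievable grid.
    """
    _check_scaled(matrix)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y, _ = _encode_classes(matrix.groups, classes)
    X = matrix.values.to_numpy(float)
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(0, 2**31 - 1))

    def score(labels: np.ndarray) -> float:
        return _q2_from_arrays(
            X, labels, n_orthogonal, n_repeats, np.random.default_rng(cv_seed)
        )

    observed = score(y)
    permuted = np.array([score(rng.permutation(y)) for _ in range(n_permutations)])
    p = (1.0 + float((permuted >= observed).sum())) / (n_permutations + 1.0)
    return PermutationResult(n_permutations, observed, permuted, p)
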