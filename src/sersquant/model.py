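"""Sample splitting, PLS1 regression and cross-validation.

The split reproduces the study's rank-stratified 2:1 procedure: samples are
sorted by reference concentration from high to low (ties broken by a seeded
shuffle), consecutive triplets are formed, and one member per triplet is
drawn uniformly into the prediction set.

PLS1 is the classical NIPALS algorithm with X-deflation.  For a single
response the inner iteration collapses to a closed form — the weight vector
of each latent variable is the normalised covariance ``X_d' y`` — so each
component is extracted in one pass.  Regression coefficients for every
component count up to the requested maximum are accumulated in a single
sweep, which is what makes the wavelength-selection algorithms (thousands of
cross-validated sub-model fits) affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import ConfigurationError

__all__ = [
    "SplitResult",
    "PLSModel",
    "CVResult",
    "rank_stratified_split",
    "pls_fit",
    "pls_predict",
    "cross_validate",
    "make_folds",
    "rmsecv_curve",
    "choose_components",
]

#: Parsimony window: the chosen component count is the smallest whose RMSECV
#: is within this relative margin of the global minimum.
PARSIMONY_WINDOW = 0.02


@dataclass
class SplitResult:
    """Disjoint calibration/prediction index sets covering all samples."""

    calibration: np.ndarray
    prediction: np.ndarray
    seed: int


@dataclass
class PLSModel:
    """Fitted PLS1 model: centering vectors, per-component weight/loading
    structure and the collapsed regression vector."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, k) normalised weight vectors
    x_loadings: np.ndarray  # (p, k)
    y_loadings: np.ndarray  # (k,)
    coef: np.ndarray  # (p,) regression vector on raw (uncentered) X
    intercept: float
    n_components: int
    scores: np.ndarray = field(default_factory=lambda: np.empty((0, 0)), repr=False)


@dataclass
class CVResult:
    rmsecv: np.ndarray  # RMSECV(k) for k = 1..max_components
    n_components: int
    seed: int


def rank_stratified_split(y: np.ndarray, seed: int = 0) -> SplitResult:
    """2:1 calibration/prediction split stratified over the y ranking.

    Samples are sorted by y descending (a prior seeded shuffle breaks
    ties), grouped into consecutive non-overlapping triplets, and exactly
    one member per triplet — chosen uniformly — goes to the prediction set.
    The 1-2 leftover samples of a non-multiple-of-three n stay in the
    calibration set.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ConfigurationError(f"rank-stratified split needs n >= 3, got {n}")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(n)
    order = shuffled[np.argsort(-y[shuffled], kind="stable")]
    n_triplets = n // 3
    picks = rng.integers(0, 3, size=n_triplets)
    prediction = order[3 * np.arange(n_triplets) + picks]
    mask = np.ones(n, dtype=bool)
    mask[prediction] = False
    return SplitResult(
        calibration=np.sort(np.flatnonzero(mask)),
        prediction=np.sort(prediction),
        seed=seed,
    )


def _pls1_path(
    Xc: np.ndarray, yc: np.ndarray, kmax: int, keep_scores: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, np.ndarray]:
    """Sequential NIPALS extraction returning the coefficient path.

    Returns ``(B, W, P, q, a, T)`` where column ``k`` of ``B`` holds the
    regression vector using ``k + 1`` latent variables, and ``a <= kmax`` is
    the number actually extracted before the residual covariance vanished.
    Columns of ``B`` beyond ``a`` repeat the last vector (the curve is flat
    beyond the effective rank).
    """
    n, p = Xc.shape
    Xd = np.array(Xc, dtype=float, copy=True)
    yc = np.asarray(yc, dtype=float)
    W = np.zeros((p, kmax))
    P = np.zeros((p, kmax))
    q = np.zeros(kmax)
    R = np.zeros((p, kmax))
    B = np.zeros((p, kmax))
    T = np.zeros((n, kmax)) if keep_scores else np.empty((0, 0))
    beta = np.zeros(p)
    scale = max(1.0, float(np.sqrt(yc @ yc)), float(np.abs(Xd).max(initial=0.0)))
    a = 0
    for _ in range(kmax):
        w = Xd.T @ yc
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * scale:
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (1e-12 * scale) ** 2:
            break
        pv = (Xd.T @ t) / tt
        qk = float(yc @ t) / tt
        Xd -= np.outer(t, pv)
        r = w - R[:, :a] @ (P[:, :a].T @ w) if a else w
        beta = beta + qk * r
        W[:, a] = w
        P[:, a] = pv
        q[a] = qk
        R[:, a] = r
        B[:, a] = beta
        if keep_scores:
            T[:, a] = t
        a += 1
    for k in range(a, kmax):
        B[:, k] = B[:, a - 1] if a else 0.0
    return B, W[:, :a], P[:, :a], q[:a], a, T[:, :a] if keep_scores else T


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 with the requested number of latent variables.

    X and y are centered internally.  A request beyond the rank bound
    ``min(n_samples - 1, n_variables)`` (or beyond the effective rank found
    during extraction) is truncated with a warning.  A constant y is an
    error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.size != n:
        raise ConfigurationError(f"X has {n} rows but y has {y.size} entries")
    if n_components < 1:
        raise ConfigurationError("n_components must be >= 1")
    if np.ptp(y) == 0.0:
        raise ValueError("y has zero variance; PLS1 is undefined")
    cap = min(n - 1, p)
    if n_components > cap:
        warnings.warn(
            f"requested {n_components} components exceeds rank bound {cap}; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        n_components = cap
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    B, W, P, q, a, T = _pls1_path(X - x_mean, y - y_mean, n_components, keep_scores=True)
    if a < n_components:
        warnings.warn(
            f"effective rank {a} below requested {n_components} components; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        n_components = max(a, 1)
    coef = B[:, n_components - 1]
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W[:, :n_components],
        x_loadings=P[:, :n_components],
        y_loadings=q[:n_components],
        coef=coef,
        intercept=y_mean - float(x_mean @ coef),
        n_components=n_components,
        scores=T[:, :n_components],
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Affine prediction ``X @ coef + intercept``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.size:
        raise ConfigurationError(
            f"X has {X.shape[1]} variables but the model expects {model.coef.size}"
        )
    return X @ model.coef + model.intercept


def _kernel_fold_predictions(
    K: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    val: np.ndarray,
    max_components: int,
) -> np.ndarray:
    """Validation predictions of the PLS1 path computed in sample space.

    When p > n every NIPALS quantity lives in the row space of the centered
    training block, so the whole coefficient path can be driven by the Gram
    matrix ``K = X X'`` alone: weights ``w_j = Xc' s_j`` and loadings
    ``p_j = Xc' m_j`` are tracked through their n-dimensional coordinate
    vectors, deflation acts on the Gram matrix, and validation predictions
    come from the cross-Gram block.  Algebraically identical to the primal
    path; the only dense p-sized work left is the one Gram product.
    """
    Ktt = K[np.ix_(train, train)]
    Kvt = K[np.ix_(val, train)]
    yt = y[train]
    ym = float(yt.mean())
    yc = yt - ym
    u = Ktt.mean(axis=0)
    g = float(u.mean())
    Kc = Ktt - u[None, :] - u[:, None] + g
    Kvc = Kvt - Kvt.mean(axis=1)[:, None] - u[None, :] + g

    n = train.size
    kmax = min(max_components, n - 1)
    Kd = Kc.copy()
    T = np.zeros((n, kmax))
    tts = np.zeros(kmax)
    M = np.zeros((n, kmax))
    Rho = np.zeros((n, kmax))
    preds = np.zeros((val.size, max_components))
    gamma = np.zeros(n)
    s = yc.copy()
    scale = 0.0
    a = 0
    for k in range(kmax):
        Kdy = Kd @ yc
        nw2 = float(yc @ Kdy)
        if k == 0:
            scale = max(nw2, 1e-300)
        if nw2 <= 1e-24 * scale:
            break
        nw = np.sqrt(nw2)
        t = Kdy / nw
        tt = float(t @ t)
        if tt <= 1e-24 * scale:
            break
        q = float(yc @ t) / tt
        m = t.copy()  # m_j = Phi_j' t_j / tt_j via stored projectors
        for i in range(a):
            m -= T[:, i] * (float(T[:, i] @ m) / tts[i])
        m /= tt
        w_cov = Kc @ (s / nw)
        rho = s / nw
        for i in range(a):
            rho -= float(M[:, i] @ w_cov) * Rho[:, i]
        gamma = gamma + q * rho
        preds[:, k] = Kvc @ gamma + ym
        T[:, a] = t
        tts[a] = tt
        M[:, a] = m
        Rho[:, a] = rho
        s = s - float(t @ yc) * m
        Kd -= np.outer(t, Kd.T @ t) / tt  # left-project
        Kd -= np.outer(Kd @ t, t) / tt  # right-project
        a += 1
    for k in range(a, max_components):
        preds[:, k] = preds[:, a - 1] if a else ym
    return preds


def make_folds(
    n: int, folds: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random fold assignment: list of (train, validation) indices."""
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if folds > n:
        raise ConfigurationError(f"cannot form {folds} non-empty folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    plan = []
    for val in np.array_split(perm, folds):
        mask = np.ones(n, dtype=bool)
        mask[val] = False
        plan.append((np.flatnonzero(mask), np.sort(val)))
    return plan


def rmsecv_curve(
    X: np.ndarray,
    y: np.ndarray,
    fold_plan: list[tuple[np.ndarray, np.ndarray]],
    max_components: int,
) -> np.ndarray:
    """RMSECV(k) for k = 1..max_components under a fixed fold plan.

    Dispatches to the sample-space (Gram-matrix) PLS path when the variable
    count exceeds the training-fold size; both paths compute the same
    predictions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    sq = np.zeros(max_components)
    min_train = min(train.size for train, _ in fold_plan)
    if min_train < 2:
        raise ConfigurationError("a training fold is too small to fit PLS")
    if X.shape[1] > min_train:
        K = X @ X.T
        for train, val in fold_plan:
            pred = _kernel_fold_predictions(K, y, train, val, max_components)
            sq += ((pred - y[val][:, None]) ** 2).sum(axis=0)
        return np.sqrt(sq / n)
    for train, val in fold_plan:
        Xt = X[train]
        yt = y[train]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        kmax = min(max_components, train.size - 1, X.shape[1])
        if kmax < 1:
            raise ConfigurationError("a training fold is too small to fit PLS")
        B, *_ = _pls1_path(Xt - x_mean, yt - y_mean, kmax)
        if kmax < max_components:  # flat beyond fold rank
            B = np.hstack([B, np.repeat(B[:, -1:], max_components - kmax, axis=1)])
        pred = (X[val] - x_mean) @ B + y_mean
        sq += ((pred - y[val][:, None]) ** 2).sum(axis=0)
    return np.sqrt(sq / n)


def choose_components(rmsecv: np.ndarray) -> int:
    """Smallest k whose RMSECV is within the parsimony window of the
    global minimum."""
    rmsecv = np.asarray(rmsecv, dtype=float)
    best = float(rmsecv.min())
    return int(np.flatnonzero(rmsecv <= (1.0 + PARSIMONY_WINDOW) * best)[0]) + 1


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Seeded k-fold RMSECV curve and the parsimonious component choice."""
    if max_components < 1:
        raise ConfigurationError("max_components must be >= 1")
    y = np.asarray(y, dtype=float)
    plan = make_folds(y.size, folds, seed)
    curve = rmsecv_curve(X, y, plan, max_components)
    return CVResult(rmsecv=curve, n_components=choose_components(curve), seed=seed)
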