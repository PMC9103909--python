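"""Wavelength-selection algorithms for PLS calibration.

Four selectors, each returning the variable subset it would hand to a
downstream PLS1 model together with its iteration traces:

``boss_select``
    Bootstrapping soft shrinkage: sub-models are drawn by weighted bootstrap
    sampling of variables, scored by RMSECV, and each variable's weight is
    rebuilt from the normalised |coefficients| of the best sub-models.
    Small-weight variables are down-weighted rather than eliminated, so they
    can re-enter later rounds ("soft shrinkage"); variables absent from
    every retained sub-model drop out.

``ga_select``
    A binary-chromosome genetic algorithm (tournament selection, uniform
    crossover, bit-flip mutation, elitism) with fitness −RMSECV.

``lasso_select``
    L1-penalised least squares solved by cyclic coordinate descent over a
    descending log-spaced λ path, λ chosen by cross-validation with the
    one-standard-error rule; the selected set is the support at that λ.

``ivissa_select``
    Interval variable iterative space shrinkage: a global weighted binary
    matrix sampling phase drives per-variable inclusion probabilities
    toward the informative wavelengths, then a local phase grows symmetric
    intervals around the survivors while that reduces RMSECV.

All four are pure functions of ``(X, y, config)``; every random draw comes
from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import choose_components, make_folds, pls_fit, rmsecv_curve
from .spectra import ConfigurationError

__all__ = [
    "SelectionResult",
    "BossConfig",
    "GaConfig",
    "LassoConfig",
    "IvissaConfig",
    "boss_select",
    "ga_select",
    "lasso_select",
    "ivissa_select",
    "cluster_representatives",
]


@dataclass
class SelectionResult:
    """Outcome of one selection run.

    ``selected`` indexes the wavenumber grid (unique, sorted).  The traces
    record, per iteration, the RMSECV of the working variable set and its
    size; ``weights`` holds the method's final per-variable weight vector
    where the method defines one.
    """

    method: str
    selected: np.ndarray
    rmsecv_trace: np.ndarray
    n_vars_trace: np.ndarray
    weights: np.ndarray | None
    seed: int

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        if self.selected.size == 0:
            raise ConfigurationError(f"{self.method}: empty selection")
        if np.unique(self.selected).size != self.selected.size or np.any(
            np.diff(self.selected) < 0
        ):
            raise ConfigurationError(f"{self.method}: indices must be unique and sorted")


def _score_subset(
    X: np.ndarray,
    y: np.ndarray,
    cols: np.ndarray,
    plan: list[tuple[np.ndarray, np.ndarray]],
    max_components: int,
) -> float:
    """RMSECV of a PLS sub-model on the given columns, at the parsimonious
    component count."""
    kmax = min(max_components, cols.size)
    curve = rmsecv_curve(X[:, cols], y, plan, kmax)
    return float(curve[choose_components(curve) - 1])


# ---------------------------------------------------------------------------
# BOSS
# ---------------------------------------------------------------------------


@dataclass
class BossConfig:
    n_submodels: int = 500
    best_fraction: float = 0.1
    folds: int = 5
    max_iter: int = 50
    max_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_submodels < 1:
            raise ConfigurationError("n_submodels must be >= 1")
        if not (0 < self.best_fraction <= 1):
            raise ConfigurationError("best_fraction must lie in (0, 1]")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")


def boss_select(X: np.ndarray, y: np.ndarray, config: BossConfig | None = None) -> SelectionResult:
    """Bootstrapping soft shrinkage variable selection.

    Per round: draw ``n_submodels`` variable subsets by weighted bootstrap
    sampling (p weighted draws with replacement; the unique draws form the
    sub-model), score each by RMSECV, keep the ``best_fraction`` lowest,
    and set each variable's new weight to the sum over kept sub-models of
    its |regression coefficient| normalised within the sub-model.  Rounds
    stop once the retained-variable count has stopped decreasing (two
    consecutive non-shrinking rounds) or at ``max_iter``; the returned set
    is the round's retained set with the global minimum RMSECV (ties:
    smaller set, then earlier round).
    """
    config = config or BossConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    plan = make_folds(n, config.folds, seed=rng.integers(2**31))

    retained = np.arange(p)
    weights = np.full(p, 1.0 / p)
    n_keep = max(1, int(round(config.best_fraction * config.n_submodels)))

    rmsecv_trace: list[float] = []
    nvar_trace: list[int] = []
    best_score = np.inf
    best_set = retained
    stall = 0
    shrink_started = False

    for _ in range(config.max_iter):
        score = _score_subset(X, y, retained, plan, config.max_components)
        rmsecv_trace.append(score)
        nvar_trace.append(retained.size)
        if score < best_score or (score == best_score and retained.size < best_set.size):
            best_score = score
            best_set = retained.copy()
        if retained.size == 1:
            break

        probs = weights[retained] / weights[retained].sum()
        submodels: list[tuple[float, np.ndarray]] = []
        for _ in range(config.n_submodels):
            draws = rng.choice(retained, size=retained.size, replace=True, p=probs)
            cols = np.unique(draws)
            sub_score = _score_subset(X, y, cols, plan, config.max_components)
            if np.isfinite(sub_score):
                submodels.append((sub_score, cols))
        if not submodels:
            break
        submodels.sort(key=lambda item: item[0])
        kept = submodels[:n_keep]

        new_weights = np.zeros(p)
        for _, cols in kept:
            fit = pls_fit(
                X[:, cols], y, min(config.max_components, cols.size, n - 1)
            )
            mag = np.abs(fit.coef)
            total = mag.sum()
            if total > 0:
                new_weights[cols] += mag / total
        new_retained = np.flatnonzero(new_weights)
        if new_retained.size == 0:
            break
        # Early rounds rarely shrink the union of best-submodel supports;
        # the count criterion only arms once shrinkage has begun.
        if new_retained.size < retained.size:
            shrink_started = True
            stall = 0
        elif shrink_started:
            stall += 1
        weights = new_weights
        retained = new_retained
        if stall >= 2:
            break

    return SelectionResult(
        method="boss",
        selected=np.sort(best_set),
        rmsecv_trace=np.asarray(rmsecv_trace),
        n_vars_trace=np.asarray(nvar_trace),
        weights=weights,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# GA
# ---------------------------------------------------------------------------


@dataclass
class GaConfig:
    pop_size: int = 64
    generations: int = 100
    p_crossover: float = 0.5
    #: Per-bit flip probability; None uses the 1/n_variables convention, which
    #: keeps the expected number of flips per child at one regardless of the
    #: grid size (a fixed rate over thousands of wavelengths would swamp the
    #: weak per-variable fitness signal with random insertions).
    p_mutation: float | None = None
    elitism: int = 1
    init_density: float = 0.02
    tournament_size: int = 2
    folds: int = 5
    max_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be >= 2")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        for name in ("p_crossover", "p_mutation", "init_density"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not (0 <= self.elitism < self.pop_size):
            raise ConfigurationError("elitism must lie in [0, pop_size)")


def ga_select(X: np.ndarray, y: np.ndarray, config: GaConfig | None = None) -> SelectionResult:
    """Genetic-algorithm wavelength selection over binary chromosomes.

    Fitness is −RMSECV of the PLS sub-model encoded by the chromosome
    (empty chromosomes score −inf).  Tournament selection, uniform
    crossover, per-bit mutation and elitist carry-over; the best-ever
    chromosome's support is returned.
    """
    config = config or GaConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    plan = make_folds(n, config.folds, seed=rng.integers(2**31))

    p_mut = config.p_mutation if config.p_mutation is not None else 1.0 / p
    pop = rng.random((config.pop_size, p)) < config.init_density
    for chrom in pop:  # guarantee a non-empty start
        if not chrom.any():
            chrom[rng.integers(p)] = True

    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        if not chrom.any():
            return -np.inf
        key = chrom.tobytes()
        if key not in cache:
            cols = np.flatnonzero(chrom)
            cache[key] = -_score_subset(X, y, cols, plan, config.max_components)
        return cache[key]

    best_chrom: np.ndarray | None = None
    best_fit = -np.inf
    fit_trace: list[float] = []
    nvar_trace: list[int] = []

    for _ in range(config.generations):
        fits = np.array([fitness(c) for c in pop])
        gen_best = int(fits.argmax())
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = pop[gen_best].copy()
        fit_trace.append(-best_fit)
        nvar_trace.append(int(best_chrom.sum()))

        elite_order = np.argsort(-fits)
        new_pop = [pop[i].copy() for i in elite_order[: config.elitism]]
        while len(new_pop) < config.pop_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.pop_size, size=config.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            if rng.random() < config.p_crossover:
                mask = rng.random(p) < 0.5
                child = np.where(mask, parents[0], parents[1])
            else:
                child = parents[0].copy()
            child = child ^ (rng.random(p) < p_mut)
            new_pop.append(child)
        pop = np.array(new_pop[: config.pop_size])

    assert best_chrom is not None
    return SelectionResult(
        method="ga",
        selected=np.flatnonzero(best_chrom),
        rmsecv_trace=np.asarray(fit_trace),
        n_vars_trace=np.asarray(nvar_trace),
        weights=None,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------


@dataclass
class LassoConfig:
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    lambda_grid: Sequence[float] | None = None
    folds: int = 5
    tol: float = 1e-6
    max_sweeps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
                raise ConfigurationError(
                    "lambda_grid must be positive and strictly decreasing"
                )
        if self.n_lambdas < 2:
            raise ConfigurationError("n_lambdas must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ConfigurationError("lambda_min_ratio must lie in (0, 1)")


def _soft(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def _cd_path(
    G: np.ndarray,
    c: np.ndarray,
    lambdas: np.ndarray,
    tol: float,
    max_sweeps: int,
) -> np.ndarray:
    """Cyclic coordinate descent for (1/2n)||y - Xb||^2 + lam ||b||_1 on
    standardised data, warm-started along a descending λ path.

    ``G = X'X / n`` (unit diagonal) and ``c = X'y / n``; returns the
    coefficient matrix (n_lambdas, p).  Coordinate sweeps run over the
    active set only; the full stationarity check is a single vectorised
    gradient evaluation that pulls violating variables into the active set
    (the standard KKT-screening strategy).
    """
    p = c.size
    beta = np.zeros(p)
    path = np.zeros((lambdas.size, p))

    def sweep(idx: np.ndarray, lam: float) -> float:
        delta = 0.0
        for j in idx:
            z = c[j] - G[j] @ beta + beta[j]
            new = _soft(z, lam)
            if new != beta[j]:
                delta = max(delta, abs(new - beta[j]))
                beta[j] = new
        return delta

    active = np.zeros(p, dtype=bool)
    for i, lam in enumerate(lambdas):
        for _ in range(max_sweeps):
            idx = np.flatnonzero(active)
            for _ in range(max_sweeps):
                if idx.size == 0 or sweep(idx, lam) <= tol:
                    break
            grad = c - G @ beta
            violations = (~active) & (np.abs(grad) > lam * (1 + 1e-12) + tol)
            if not violations.any():
                break
            active |= violations
        active = beta != 0
        path[i] = beta
    return path


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lasso_select(X: np.ndarray, y: np.ndarray, config: LassoConfig | None = None) -> SelectionResult:
    """LASSO variable selection with a CV-chosen penalty (1-SE rule).

    Variables are standardised internally; the λ path descends from the
    smallest all-zero penalty λ_max = max|X'y|/n.  The chosen λ is the
    largest one whose cross-validated MSE is within one standard error of
    the minimum; the selected set is its nonzero support.  An empty support
    at the chosen λ raises an informative error.
    """
    config = config or LassoConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    plan = make_folds(n, config.folds, seed=rng.integers(2**31))

    Xs, _, _ = _standardise(X)
    yc = y - y.mean()
    lam_max = float(np.abs(Xs.T @ yc).max() / n)
    if config.lambda_grid is not None:
        lambdas = np.asarray(config.lambda_grid, dtype=float)
    else:
        if lam_max <= 0:
            raise ConfigurationError("X carries no covariance with y; λ_max = 0")
        lambdas = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambdas)

    # Per-fold paths (fold-local standardisation) -> CV mse per lambda.
    fold_mse = np.zeros((len(plan), lambdas.size))
    for f, (train, val) in enumerate(plan):
        Xt, mu, sd = _standardise(X[train])
        yt = y[train]
        ym = yt.mean()
        G = (Xt.T @ Xt) / train.size
        c = Xt.T @ (yt - ym) / train.size
        path = _cd_path(G, c, lambdas, config.tol, config.max_sweeps)
        Xv = (X[val] - mu) / sd
        preds = Xv @ path.T + ym
        fold_mse[f] = ((preds - y[val][:, None]) ** 2).mean(axis=0)

    mean_mse = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(len(plan))
    i_min = int(mean_mse.argmin())
    threshold = mean_mse[i_min] + se[i_min]
    i_chosen = int(np.flatnonzero(mean_mse <= threshold)[0])  # largest λ first

    G = (Xs.T @ Xs) / n
    c = Xs.T @ yc / n
    full_path = _cd_path(G, c, lambdas[: i_chosen + 1], config.tol, config.max_sweeps)
    beta = full_path[-1]
    selected = np.flatnonzero(beta)
    if selected.size == 0:
        raise ConfigurationError(
            f"LASSO selected no variables at λ = {lambdas[i_chosen]:.4g} "
            f"(λ_max = {lam_max:.4g}); lower the penalty grid or check the data"
        )
    counts = (full_path != 0).sum(axis=1)
    return SelectionResult(
        method="lasso",
        selected=selected,
        rmsecv_trace=np.sqrt(mean_mse[: i_chosen + 1]),
        n_vars_trace=counts,
        weights=beta,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# iVISSA
# ---------------------------------------------------------------------------


@dataclass
class IvissaConfig:
    n_samplings: int = 500
    ratio: float = 0.1
    folds: int = 5
    max_iter: int = 30
    interval_halfwidth: int = 10
    max_components: int = 10
    rtol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samplings < 2:
            raise ConfigurationError("n_samplings must be >= 2")
        if not (0 < self.ratio <= 1):
            raise ConfigurationError("ratio must lie in (0, 1]")
        if self.interval_halfwidth < 0:
            raise ConfigurationError("interval_halfwidth must be >= 0")


def _clusters(indices: np.ndarray, max_gap: int = 1) -> list[np.ndarray]:
    """Split sorted indices into runs whose internal gaps are <= max_gap."""
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > max_gap)
    return np.split(indices, breaks + 1)


def ivissa_select(X: np.ndarray, y: np.ndarray, config: IvissaConfig | None = None) -> SelectionResult:
    """Interval variable iterative space shrinkage selection.

    Global phase: weighted binary matrix sampling.  Each of ``n_samplings``
    binary rows includes variable j independently with its current
    inclusion probability (all start at 0.5); rows are scored by RMSECV and
    the probabilities are updated to each variable's inclusion frequency
    among the best ``ratio`` fraction of rows, iterating until the mean
    best-row RMSECV converges.  Local phase: contiguous runs of variables
    with probability >= 0.5 are grown symmetrically, up to
    ``interval_halfwidth`` grid steps, keeping expansions that lower the
    RMSECV.  The union of accepted intervals is returned.
    """
    config = config or IvissaConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    plan = make_folds(n, config.folds, seed=rng.integers(2**31))

    probs = np.full(p, 0.5)
    n_keep = max(1, int(round(config.ratio * config.n_samplings)))
    rmsecv_trace: list[float] = []
    nvar_trace: list[int] = []
    prev_mean = np.inf
    stall = 0

    for _ in range(config.max_iter):
        rows = rng.random((config.n_samplings, p)) < probs
        for row in rows:
            if not row.any():
                row[rng.integers(p)] = True
        scores = np.array(
            [
                _score_subset(X, y, np.flatnonzero(row), plan, config.max_components)
                for row in rows
            ]
        )
        best = np.argsort(scores)[:n_keep]
        probs = rows[best].mean(axis=0)
        mean_best = float(scores[best].mean())
        rmsecv_trace.append(mean_best)
        nvar_trace.append(int((probs >= 0.5).sum()))
        if np.isfinite(prev_mean) and abs(prev_mean - mean_best) <= config.rtol * prev_mean:
            stall += 1
        else:
            stall = 0
        prev_mean = mean_best
        if stall >= 2:
            break

    seeds = np.flatnonzero(probs >= 0.5)
    if seeds.size == 0:
        raise ConfigurationError(
            "iVISSA: all inclusion probabilities collapsed to zero; use weaker "
            "noise or a larger n_samplings"
        )

    selected = set(seeds.tolist())
    base = _score_subset(X, y, np.asarray(sorted(selected)), plan, config.max_components)
    for cluster in _clusters(seeds):
        lo, hi = int(cluster[0]), int(cluster[-1])
        for h in range(1, config.interval_halfwidth + 1):
            extension = [
                j for j in (*range(lo - h, lo), *range(hi + 1, hi + h + 1)) if 0 <= j < p
            ]
            candidate = np.asarray(sorted(selected | set(extension)))
            score = _score_subset(X, y, candidate, plan, config.max_components)
            if score < base:
                selected = set(candidate.tolist())
                base = score
            else:
                break

    return SelectionResult(
        method="ivissa",
        selected=np.asarray(sorted(selected)),
        rmsecv_trace=np.asarray(rmsecv_trace),
        n_vars_trace=np.asarray(nvar_trace),
        weights=probs,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Reporting helper
# ---------------------------------------------------------------------------


def cluster_representatives(
    selected: np.ndarray,
    wavenumbers: np.ndarray,
    values: np.ndarray | None = None,
    max_gap: int = 3,
) -> np.ndarray:
    """Wavenumbers (cm^-1) of one representative per contiguous cluster.

    Contiguous selected indices (gaps <= ``max_gap`` grid steps) are merged
    and each cluster is represented by its member with the largest
    ``|values|`` (e.g. the PLS regression coefficient) — its "peak-most"
    channel — or the central member when no values are given.  This mirrors
    how long selected-variable lists are condensed to a short wavelength
    list for reporting.
    """
    selected = np.asarray(selected, dtype=int)
    reps = []
    for cluster in _clusters(np.sort(selected), max_gap=max_gap):
        if values is not None:
            local = np.abs(np.asarray(values)[cluster])
            reps.append(cluster[int(local.argmax())])
        else:
            reps.append(cluster[cluster.size // 2])
    return np.asarray(wavenumbers)[np.asarray(reps, dtype=int)]
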