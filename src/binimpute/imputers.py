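"""The five imputation algorithms, implemented from first principles.

All methods operate on a :class:`~binimpute.io.DayMatrix` with rows = days
(samples) and columns = minutes (features), so cross-day routine appears as
inter-feature correlation and binning changes the feature space a method
sees.  Methods:

``SI``
    Simple imputation: each missing cell gets its column's observed mean
    (grand mean of all observed cells if the column has none).
``EM``
    Multivariate-normal expectation–maximization: alternate conditional-mean
    fill of each incomplete row given its observed coordinates under the
    current (mu, Sigma) with re-estimation of mu and Sigma from the
    completed matrix.  Sigma carries a ridge proportional to the average
    feature variance; above a feature cap (whole-day fits, p >> n) the
    ridge is raised and the conditional solve goes through the Woodbury
    identity so the p × p covariance is never formed.
``II``
    Iterative (chained-equations style) imputation: ridge-regularized linear
    regression of each incomplete column on all others, cycling until the
    imputed values stabilize.
``KNN``
    k-nearest-neighbor imputation with the missing-aware Euclidean distance
    (squared distances over shared coordinates, rescaled by
    n_features/n_shared); each missing cell is the unweighted mean of the k
    nearest donor rows observed in that column.
``RF``
    missForest-style imputation: a bagged regression forest per incomplete
    column, cycling until the pass-to-pass change in imputed values
    increases, then returning the previous pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._forest import forest_impute_column
from .exceptions import EmptyInputError, NumericalError
from .io import DayMatrix

METHODS = ("EM", "II", "KNN", "RF", "SI")

_DEFAULT_MAX_ITER = {"EM": 100, "II": 10, "RF": 10}
_DEFAULT_TOL = {"EM": 1e-4, "II": 1e-3}


@dataclass(frozen=True)
class ImputerConfig:
    """Method selector plus hyperparameters for the five algorithms.

    ``max_iter`` and ``tol`` default per method (EM: 100 / 1e-4, II: 10 /
    1e-3, RF: 10 passes).  ``ridge`` is relative to the average feature
    variance, making it unit-free across bpm scales; the same convention
    feeds both the EM covariance and the II regression penalty.
    """

    method: str = "SI"
    k: int = 5                  # KNN neighbor count
    max_iter: int = None
    tol: float = None
    ridge: float = 1e-6
    n_trees: int = 100          # RF
    rf_min_leaf: int = 5
    seed: int = 0
    em_feature_cap: int = 256   # above this many columns, use the large ridge
    em_ridge_large: float = 0.1
    si_strategy: str = "mean"   # or "median"

    def __post_init__(self):
        object.__setattr__(self, "method", str(self.method).upper())
        if self.method not in METHODS:
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.k < 1 or self.n_trees < 1 or self.rf_min_leaf < 1:
            raise ValueError("k, n_trees and rf_min_leaf must be >= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        if self.max_iter is not None and self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol is not None and self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.si_strategy not in ("mean", "median"):
            raise ValueError("si_strategy must be 'mean' or 'median'")

    @property
    def resolved_max_iter(self) -> int:
        return self.max_iter if self.max_iter is not None else _DEFAULT_MAX_ITER.get(self.method, 1)

    @property
    def resolved_tol(self) -> float:
        return self.tol if self.tol is not None else _DEFAULT_TOL.get(self.method, 1e-4)


@dataclass
class ImputationResult:
    """A completed matrix plus convergence diagnostics.

    Invariants: every originally observed cell is bitwise unchanged and
    every originally missing cell is finite.  ``history`` records the
    per-iteration maximum absolute change of the imputed cells (EM/II) or
    the missForest relative-change statistic (RF).
    """

    imputed: DayMatrix
    config: ImputerConfig
    n_iterations: int = 0
    converged: bool = True
    history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _observed_scale(values: np.ndarray) -> float:
    obs = values[~np.isnan(values)]
    return float(np.mean(np.abs(obs))) if obs.size else 1.0


def _si_values(values: np.ndarray, strategy: str = "mean") -> np.ndarray:
    """Column means (or medians); all-missing columns fall back to the grand mean."""
    obs_mask = ~np.isnan(values)
    if not obs_mask.any():
        raise EmptyInputError("matrix is entirely missing; nothing to impute from")
    agg = np.nanmean if strategy == "mean" else np.nanmedian
    col_has_obs = obs_mask.any(axis=0)
    fill = np.empty(values.shape[1])
    fill[col_has_obs] = agg(values[:, col_has_obs], axis=0)
    fill[~col_has_obs] = agg(values[obs_mask])
    return fill


def _identity_result(matrix: DayMatrix, config: ImputerConfig) -> ImputationResult:
    return ImputationResult(matrix.copy(), config, n_iterations=0, converged=True)


# ---------------------------------------------------------------------------
# SI
# ---------------------------------------------------------------------------

def impute_simple(matrix: DayMatrix, config: ImputerConfig = None) -> ImputationResult:
    """Fill each missing cell with its column's observed mean (or median)."""
    config = config or ImputerConfig(method="SI")
    miss = matrix.missing_mask
    if not miss.any():
        return _identity_result(matrix, config)
    fill = _si_values(matrix.values, config.si_strategy)
    out = matrix.copy()
    out.values[miss] = np.broadcast_to(fill, out.values.shape)[miss]
    return ImputationResult(out, config, n_iterations=1, converged=True)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _em_fill_patterns(X, patterns, lam):
    """One E-step: conditional-mean fill for every missing pattern.

    Sigma = Xc'Xc/n + lam*I is never formed when p_obs > n; the Woodbury
    identity reduces the solve to an n × n system (exact, not approximate).
    Returns the new values for missing cells, pattern by pattern.
    """
    n, p = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    updates = []
    for miss_idx, obs_idx, rows in patterns:
        if obs_idx.size == 0:
            updates.append(np.tile(mu[miss_idx], (len(rows), 1)))
            continue
        D = X[np.ix_(rows, obs_idx)] - mu[obs_idx]  # deviations, rows × p_obs
        Co = Xc[:, obs_idx]
        if obs_idx.size > n:
            if lam <= 0:
                raise NumericalError(
                    "covariance is rank-deficient (more observed features than "
                    "rows); set ridge > 0"
                )
            G = Co @ Co.T / n
            M = G + lam * np.eye(n)
            try:
                T = np.linalg.solve(M, Co @ D.T / n)  # n × rows
            except np.linalg.LinAlgError as e:
                raise NumericalError(f"EM solve failed: {e}; increase ridge") from None
            W = (D.T - Co.T @ T) / lam               # p_obs × rows
        else:
            S = Co.T @ Co / n + lam * np.eye(obs_idx.size)
            try:
                np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                raise NumericalError(
                    "regularized covariance is not positive definite; set ridge > 0"
                ) from None
            W = np.linalg.solve(S, D.T)              # p_obs × rows
        # Sigma_mo @ W without forming Sigma: Xc_m' (Xc_o W) / n
        U = Co @ W / n                               # n × rows
        pred = mu[miss_idx][None, :] + (Xc[:, miss_idx].T @ U).T
        updates.append(pred)
    return updates


def impute_em(matrix: DayMatrix, config: ImputerConfig = None) -> ImputationResult:
    """Multivariate-normal EM imputation (conditional-mean fill + re-estimation)."""
    config = config or ImputerConfig(method="EM")
    miss = matrix.missing_mask
    if not miss.any():
        return _identity_result(matrix, config)
    n, p = matrix.values.shape
    if n < 2:
        raise ValueError("EM needs at least 2 rows")

    X = matrix.values.copy()
    X[miss] = np.broadcast_to(_si_values(matrix.values), X.shape)[miss]
    scale = _observed_scale(matrix.values)
    tol, max_iter = config.resolved_tol, config.resolved_max_iter
    ridge_rel = config.ridge if p <= config.em_feature_cap else max(config.ridge, config.em_ridge_large)

    # group incomplete rows by missing pattern so factorizations are shared
    patterns = {}
    for r in np.flatnonzero(miss.any(axis=1)):
        patterns.setdefault(miss[r].tobytes(), []).append(r)
    pattern_list = []
    for rows in patterns.values():
        row_mask = miss[rows[0]]
        pattern_list.append(
            (np.flatnonzero(row_mask), np.flatnonzero(~row_mask), np.asarray(rows))
        )

    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = ridge_rel * float(np.var(X, axis=0).mean())
        updates = _em_fill_patterns(X, pattern_list, lam)
        change = 0.0
        for (miss_idx, _obs, rows), pred in zip(pattern_list, updates):
            block = np.ix_(rows, miss_idx)
            change = max(change, float(np.max(np.abs(X[block] - pred))))
            X[block] = pred
        history.append(change)
        if change <= tol * scale:
            converged = True
            break

    out = matrix.copy()
    out.values[miss] = X[miss]
    return ImputationResult(out, config, n_iterations=it, converged=converged, history=history)


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

def impute_knn(matrix: DayMatrix, config: ImputerConfig = None) -> ImputationResult:
    """k-nearest-neighbor imputation with the missing-aware Euclidean distance.

    d(a, b) = sqrt( sum over shared coords (a_j - b_j)^2 * C / n_shared );
    rows sharing no observed coordinate get infinite distance and rank after
    all others (ties broken by lower row index).  Each missing cell is the
    unweighted mean of the min(k, available donors) nearest rows observed in
    that column; with no donor at all the SI value is used.
    """
    config = config or ImputerConfig(method="KNN")
    miss = matrix.missing_mask
    if not miss.any():
        return _identity_result(matrix, config)
    X = matrix.values
    n, C = X.shape
    if n < 2:
        raise ValueError("KNN needs at least 2 rows")
    obs = ~miss
    si_fill = _si_values(X)

    out = matrix.copy()
    for d in np.flatnonzero(miss.any(axis=1)):
        shared = obs & obs[d]
        n_shared = shared.sum(axis=1)
        diff = X - X[d]
        sq = np.where(shared, diff * diff, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.sqrt(sq * (C / n_shared))
        dist[n_shared == 0] = np.inf
        dist[d] = np.inf  # a row is never its own donor
        order = np.lexsort((np.arange(n), dist))
        order = order[order != d]
        for j in np.flatnonzero(miss[d]):
            donors = order[obs[order, j]]
            if donors.size == 0:
                out.values[d, j] = si_fill[j]
            else:
                out.values[d, j] = float(np.mean(X[donors[: config.k], j]))
    return ImputationResult(out, config, n_iterations=1, converged=True)


# ---------------------------------------------------------------------------
# II
# ---------------------------------------------------------------------------

def _ridge_fit_predict(Xtr, ytr, Xq, lam):
    """Centered ridge regression; dual (Gram) form when p > n_train.

    With lam -> 0 this recovers ordinary least squares on well-posed data.
    """
    xm = Xtr.mean(axis=0)
    ym = ytr.mean()
    Xc = Xtr - xm
    yc = ytr - ym
    n_tr, p = Xc.shape
    try:
        if p <= n_tr:
            A = Xc.T @ Xc + lam * np.eye(p)
            beta = np.linalg.solve(A, Xc.T @ yc)
        else:
            G = Xc @ Xc.T + lam * np.eye(n_tr)
            beta = Xc.T @ np.linalg.solve(G, yc)
    except np.linalg.LinAlgError as e:
        raise NumericalError(f"II normal equations singular: {e}; set ridge > 0") from None
    return ym + (Xq - xm) @ beta


def impute_iterative(matrix: DayMatrix, config: ImputerConfig = None) -> ImputationResult:
    """Chained ridge regressions of each incomplete column on all others."""
    config = config or ImputerConfig(method="II")
    miss = matrix.missing_mask
    if not miss.any():
        return _identity_result(matrix, config)
    n, p = matrix.values.shape
    if n < 2:
        raise ValueError("II needs at least 2 rows")
    if p < 2:
        res = impute_simple(matrix, replace(config, method="SI"))
        return ImputationResult(res.imputed, config, n_iterations=1, converged=True)

    X = matrix.values.copy()
    X[miss] = np.broadcast_to(_si_values(matrix.values), X.shape)[miss]
    scale = _observed_scale(matrix.values)
    tol, max_iter = config.resolved_tol, config.resolved_max_iter
    lam = config.ridge * float(np.var(X, axis=0).mean())

    counts = miss.sum(axis=0)
    cols = sorted(np.flatnonzero(counts > 0), key=lambda j: (counts[j], j))
    feat = {j: np.delete(np.arange(p), j) for j in cols}

    history = []
    converged = False
    n_pass = 0
    for n_pass in range(1, max_iter + 1):
        change = 0.0
        for j in cols:
            tr = np.flatnonzero(~miss[:, j])
            q = np.flatnonzero(miss[:, j])
            pred = _ridge_fit_predict(X[np.ix_(tr, feat[j])], X[tr, j], X[np.ix_(q, feat[j])], lam)
            change = max(change, float(np.max(np.abs(X[q, j] - pred))))
            X[q, j] = pred
        history.append(change)
        if change <= tol * scale:
            converged = True
            break

    out = matrix.copy()
    out.values[miss] = X[miss]
    return ImputationResult(out, config, n_iterations=n_pass, converged=converged, history=history)


# ---------------------------------------------------------------------------
# RF
# ---------------------------------------------------------------------------

def impute_rf(matrix: DayMatrix, config: ImputerConfig = None) -> ImputationResult:
    """missForest-style imputation with hand-built bagged regression trees.

    Column order is ascending missing count.  After each full pass the
    relative change Delta = sum((new-old)^2)/sum(new^2) over imputed cells is
    tracked; iteration stops (returning the previous pass) the first time
    Delta increases, or at max_iter.  mtry = floor(sqrt(p)) candidate
    features per split, minimum leaf size 5, seeded bootstrap.
    """
    config = config or ImputerConfig(method="RF")
    miss = matrix.missing_mask
    if not miss.any():
        return _identity_result(matrix, config)
    n, p = matrix.values.shape
    if n < 2 or p < 2:
        raise ValueError("RF needs at least 2 rows and 2 columns")

    X = matrix.values.copy()
    X[miss] = np.broadcast_to(_si_values(matrix.values), X.shape)[miss]
    mtry = max(1, int(math.isqrt(p - 1)))
    counts = miss.sum(axis=0)
    cols = sorted(np.flatnonzero(counts > 0), key=lambda j: (counts[j], j))
    col_rows = {
        j: (np.flatnonzero(~miss[:, j]).astype(np.int64),
            np.flatnonzero(miss[:, j]).astype(np.int64))
        for j in cols
    }

    history = []
    converged = False
    n_pass = 0
    prev_vals = X[miss].copy()
    prev_delta = np.inf
    for n_pass in range(1, config.resolved_max_iter + 1):
        for j in cols:
            tr, q = col_rows[j]
            fseed = (config.seed * 1_000_003 + n_pass * 7919 + int(j) * 31 + 17) % 2_147_483_647
            X[q, j] = forest_impute_column(
                X, int(j), tr, q, config.n_trees, mtry, config.rf_min_leaf, fseed
            )
        new_vals = X[miss]
        denom = float(np.sum(new_vals**2))
        delta = float(np.sum((new_vals - prev_vals) ** 2)) / denom if denom > 0 else 0.0
        history.append(delta)
        if delta > prev_delta:
            X = matrix.values.copy()
            X[miss] = prev_vals  # revert: previous pass was the better fit
            converged = True
            break
        if delta == 0.0:
            converged = True
            break
        prev_vals = new_vals.copy()
        prev_delta = delta

    out = matrix.copy()
    out.values[miss] = X[miss]
    return ImputationResult(out, config, n_iterations=n_pass, converged=converged, history=history)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

_DISPATCH = {
    "SI": impute_simple,
    "EM": impute_em,
    "KNN": impute_knn,
    "II": impute_iterative,
    "RF": impute_rf,
}


def impute(matrix: DayMatrix, config: ImputerConfig) -> ImputationResult:
    """Route to the method named in ``config`` (EM, II, KNN, RF or SI)."""
    try:
        fn = _DISPATCH[str(config.method).upper()]
    except KeyError:
        raise ValueError(f"unknown imputation method {config.method!r}") from None
    return fn(matrix, config)
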