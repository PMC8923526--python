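"""L1-penalized linear regression (LASSO) for anthesis-rate prediction.

The model is  y_i = w0 + sum_j w_j X_ij  with the penalized objective

    min_w  1/(2n) ||Xw - y||_2^2 + alpha ||w||_1 ,

the intercept unpenalized.  It is minimized by cyclic coordinate descent
with covariance updates (the inner loop is numba-compiled), warm starts
along a descending alpha grid, and k-fold cross-validation.  The predictor
panel is chosen at the elbow of the regularization path: the smallest
support whose cross-validated R^2 is within a tolerance of the best seen.

Columns of X are expected standardized (mean 0, SD 1); environmental
features are treated exactly like metabolites, tagged by ``feature_kind``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

ALPHA_MIN_DEFAULT = 5e-5   # sweep lower endpoint
ALPHA_MAX_DEFAULT = 0.5    # sweep upper endpoint
N_ALPHAS_DEFAULT = 50

__all__ = [
    "DesignMatrix", "LassoSolution", "SweepRecord",
    "soft_threshold", "fit_lasso", "predict", "r2_score", "mse",
    "kfold_cv", "alpha_sweep", "select_elbow", "refit_panel",
    "default_alpha_grid", "kkt_residual", "null_alpha",
]


class LassoError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Feature matrix and response for the sparse linear model.

    X must be free of missing values; when built from a standardized
    metabolite matrix its columns have mean 0 and SD 1.  ``feature_kind``
    labels each column 'metabolite' or 'environment' so the M/E/C model
    variants can select columns from one container.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    feature_kind: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise LassoError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise LassoError("X and y disagree on sample count")
        if self.X.shape[0] < 2:
            raise LassoError("need at least two samples")
        if len(self.feature_ids) != self.X.shape[1]:
            raise LassoError("feature_ids length mismatch")
        if not self.feature_kind:
            self.feature_kind = ["metabolite"] * self.X.shape[1]
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise LassoError("non-finite entries in design")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def select_kind(self, kinds: Sequence[str]) -> "DesignMatrix":
        mask = [k in set(kinds) for k in self.feature_kind]
        idx = np.where(mask)[0]
        return DesignMatrix(
            self.X[:, idx], self.y,
            [self.feature_ids[i] for i in idx],
            [self.feature_kind[i] for i in idx],
        )

    def select_features(self, feature_ids: Sequence[str]) -> "DesignMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise LassoError(f"features missing from design: {missing}")
        idx = [pos[f] for f in feature_ids]
        return DesignMatrix(
            self.X[:, idx], self.y, list(feature_ids),
            [self.feature_kind[i] for i in idx],
        )


@dataclass
class LassoSolution:
    """Coefficients and fit metadata for one penalty value."""

    w: np.ndarray
    w0: float
    alpha: float
    n_sweeps: int
    converged: bool
    objective_value: float
    feature_ids: list[str] = field(default_factory=list)

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.w != 0)

    @property
    def support_ids(self) -> list[str]:
        if not self.feature_ids:
            return [str(j) for j in self.support]
        return [self.feature_ids[j] for j in self.support]


@dataclass
class SweepRecord:
    """One point of the regularization path with train and CV metrics."""

    alpha: float
    train_r2: float
    cv_r2: float
    cv_mse: float
    support_size: int
    support_ids: list[str]
    solution: LassoSolution | None = None
    cv_fold_r2: list[float] = field(default_factory=list)
    cv_fold_mse: list[float] = field(default_factory=list)


def soft_threshold(z: float, gamma: float) -> float:
    """Proximal operator of the L1 norm: sign(z) * max(|z| - gamma, 0)."""
    if gamma < 0:
        raise LassoError("gamma must be nonnegative")
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


@njit(cache=True)
def _cd_kernel(XtX, Xty, yty, n, alpha, w, tol, max_sweeps, obj_trace):  # pragma: no cover
    m = w.shape[0]
    q = XtX @ w
    record = obj_trace.shape[0] > 0
    n_sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(m):
            wj = w[j]
            ajj = XtX[j, j]
            if ajj <= 0.0:
                wnew = 0.0
            else:
                rho = (Xty[j] - q[j] + ajj * wj) / n
                if rho > alpha:
                    num = rho - alpha
                elif rho < -alpha:
                    num = rho + alpha
                else:
                    num = 0.0
                wnew = num / (ajj / n)
            d = wnew - wj
            if d != 0.0:
                w[j] = wnew
                for i2 in range(m):
                    q[i2] += XtX[i2, j] * d
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        n_sweeps = sweep + 1
        if record and sweep < obj_trace.shape[0]:
            l1 = 0.0
            wq = 0.0
            wxty = 0.0
            for j in range(m):
                l1 += abs(w[j])
                wq += w[j] * q[j]
                wxty += w[j] * Xty[j]
            obj_trace[sweep] = (yty - 2.0 * wxty + wq) / (2.0 * n) + alpha * l1
        if max_delta < tol:
            converged = True
            break
    return n_sweeps, converged


def _objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, w0: float, alpha: float) -> float:
    r = y - (X @ w + w0)
    return float(r @ r / (2 * len(y)) + alpha * np.abs(w).sum())


def fit_lasso(
    design: DesignMatrix,
    alpha: float,
    *,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
    w_init: np.ndarray | None = None,
    track_objective: bool = False,
) -> LassoSolution:
    """Cyclic coordinate descent on the 1/(2n) least-squares + alpha*L1
    objective with an unpenalized intercept.

    The intercept is handled by centering X and y, which is exactly
    equivalent to refreshing w0 = mean(y - Xw) each sweep.  Convergence is
    declared when the largest coefficient change in a sweep drops below
    ``tol``; otherwise the solution is returned with ``converged=False``
    and a warning.  With ``track_objective`` the per-sweep objective trace
    is attached as ``solution.objective_trace`` (non-increasing).
    """
    if alpha < 0:
        raise LassoError("alpha must be nonnegative")
    X, y = design.X, design.y
    n = design.n
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    XtX = Xc.T @ Xc
    Xty = Xc.T @ yc
    yty = float(yc @ yc)
    w = np.zeros(design.m) if w_init is None else np.array(w_init, dtype=float)
    trace = np.empty(min(max_sweeps, 20_000) if track_objective else 0)
    n_sweeps, converged = _cd_kernel(
        XtX, Xty, yty, float(n), float(alpha), w, float(tol), int(max_sweeps), trace
    )
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_sweeps} sweeps (alpha={alpha:g})",
            RuntimeWarning,
        )
    w0 = float(y_mean - x_mean @ w)
    sol = LassoSolution(
        w=w, w0=w0, alpha=float(alpha), n_sweeps=int(n_sweeps),
        converged=bool(converged),
        objective_value=_objective(X, y, w, w0, alpha),
        feature_ids=list(design.feature_ids),
    )
    if track_objective:
        sol.objective_trace = trace[:n_sweeps]  # type: ignore[attr-defined]
    return sol


def predict(solution: LassoSolution, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != solution.w.shape[0]:
        raise LassoError(
            f"X_new has {X_new.shape[1] if X_new.ndim == 2 else '?'} columns, "
            f"expected {solution.w.shape[0]}"
        )
    return solution.w0 + X_new @ solution.w


def r2_score(y, y_hat) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise LassoError("length mismatch")
    if y.size < 2:
        raise LassoError("need at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise LassoError("R^2 undefined for zero-variance y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def mse(y, y_hat) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise LassoError("length mismatch")
    return float(np.mean((y - y_hat) ** 2))


def kkt_residual(design: DesignMatrix, solution: LassoSolution) -> float:
    """Maximum violation of the LASSO stationarity conditions:
    |(1/n) x_j' r| <= alpha for w_j = 0, and (1/n) x_j' r = alpha sign(w_j)
    for w_j != 0 (r the residual including the intercept)."""
    r = design.y - predict(solution, design.X)
    g = design.X.T @ r / design.n
    viol = np.where(
        solution.w == 0,
        np.maximum(np.abs(g) - solution.alpha, 0.0),
        np.abs(g - solution.alpha * np.sign(solution.w)),
    )
    return float(viol.max()) if viol.size else 0.0


def null_alpha(design: DesignMatrix) -> float:
    """Smallest alpha at which the all-zero coefficient vector is optimal:
    max_j |(1/n) x_j'(y - ybar)| on the centered design."""
    Xc = design.X - design.X.mean(axis=0)
    yc = design.y - design.y.mean()
    return float(np.abs(Xc.T @ yc).max() / design.n)


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def kfold_cv(
    design: DesignMatrix,
    alpha: float,
    k: int = 10,
    seed: int = 0,
    *,
    fold_safe: bool = False,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
    warm_starts: list[np.ndarray] | None = None,
) -> dict:
    """k-fold cross-validation at one alpha.

    Folds come from a seeded shuffle; metrics are computed on the pooled
    out-of-fold predictions (per-fold values are also returned).  By default
    the design is used as supplied -- i.e. any standardization was done once
    on the full data, as the study did; ``fold_safe=True`` re-standardizes
    X within each training fold instead.
    """
    n = design.n
    if not 2 <= k <= n:
        raise LassoError(f"k must be in [2, {n}]")
    folds = _fold_indices(n, k, seed)
    oof = np.empty(n)
    fold_r2, fold_mse = [], []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        X_tr, y_tr = design.X[train_mask], design.y[train_mask]
        X_te = design.X[test_idx]
        if fold_safe:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        sub = DesignMatrix(X_tr, y_tr, design.feature_ids, design.feature_kind)
        w_init = warm_starts[f] if warm_starts is not None else None
        sol = fit_lasso(sub, alpha, tol=tol, max_sweeps=max_sweeps, w_init=w_init)
        if warm_starts is not None:
            warm_starts[f] = sol.w.copy()
        pred = predict(sol, X_te)
        oof[test_idx] = pred
        fold_mse.append(mse(design.y[test_idx], pred))
        y_te = design.y[test_idx]
        fold_r2.append(r2_score(y_te, pred) if np.ptp(y_te) > 0 else np.nan)
    return {
        "cv_r2": r2_score(design.y, oof),
        "cv_mse": mse(design.y, oof),
        "fold_r2": fold_r2,
        "fold_mse": fold_mse,
        "oof_predictions": oof,
    }


def default_alpha_grid(
    alpha_min: float = ALPHA_MIN_DEFAULT,
    alpha_max: float = ALPHA_MAX_DEFAULT,
    n_alphas: int = N_ALPHAS_DEFAULT,
) -> np.ndarray:
    """Log-spaced grid whose endpoints are exactly [alpha_min, alpha_max]."""
    return np.logspace(np.log10(alpha_min), np.log10(alpha_max), n_alphas)


def alpha_sweep(
    design: DesignMatrix,
    alpha_grid: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    *,
    tol: float = 1e-7,
    max_sweeps: int = 2_000,
    fold_safe: bool = False,
    keep_solutions: bool = True,
) -> list[SweepRecord]:
    """Regularization path: one SweepRecord per alpha, descending, with
    warm starts shared along the path (for the full-data fit and each CV
    fold separately).  The same seeded folds are reused at every alpha.

    Path fits cap the sweep count at 2000 by default: near the smallest
    penalties a strongly correlated design approaches its ill-conditioned
    least-squares limit where cyclic descent converges only slowly, while
    the panel is always selected at mid-path penalties that converge well
    before the cap; per-solution ``converged`` flags record any truncation.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise LassoError("alpha grid is empty")
    if np.any(alpha_grid <= 0):
        raise LassoError("alpha grid must be positive")
    order = np.argsort(alpha_grid)[::-1]
    records: list[SweepRecord] = [None] * alpha_grid.size  # type: ignore[list-item]
    w_full = np.zeros(design.m)
    warm = [np.zeros(design.m) for _ in range(k)]
    for pos in order:
        a = float(alpha_grid[pos])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = fit_lasso(design, a, tol=tol, max_sweeps=max_sweeps, w_init=w_full.copy())
            w_full = sol.w.copy()
            cv = kfold_cv(design, a, k=k, seed=seed, fold_safe=fold_safe,
                          tol=tol, max_sweeps=max_sweeps, warm_starts=warm)
        records[pos] = SweepRecord(
            alpha=a,
            train_r2=r2_score(design.y, predict(sol, design.X)),
            cv_r2=cv["cv_r2"],
            cv_mse=cv["cv_mse"],
            support_size=int(np.count_nonzero(sol.w)),
            support_ids=sol.support_ids,
            solution=sol if keep_solutions else None,
            cv_fold_r2=cv["fold_r2"],
            cv_fold_mse=cv["fold_mse"],
        )
    return records


def sweep_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"alpha": r.alpha, "train_r2": r.train_r2, "cv_r2": r.cv_r2,
         "cv_mse": r.cv_mse, "support_size": r.support_size}
        for r in records
    ])


def select_elbow(records: list[SweepRecord], tol: float = 0.02) -> SweepRecord:
    """Elbow rule for the predictor panel: among records whose CV R^2 is
    within ``tol`` of the best CV R^2 on the sweep, return the one with the
    smallest support; ties break toward larger alpha."""
    finite = [r for r in records if np.isfinite(r.cv_r2)]
    if not finite:
        raise LassoError("no finite cross-validation metrics on the sweep")
    cv_best = max(r.cv_r2 for r in finite)
    near = [r for r in finite if r.cv_r2 >= cv_best - tol]
    return min(near, key=lambda r: (r.support_size, -r.alpha))


def select_min_cv_mse(records: list[SweepRecord]) -> SweepRecord:
    """Selection used when re-fitting the panel on combined data: the sweep
    point with minimum cross-validated MSE (ties toward larger alpha)."""
    finite = [r for r in records if np.isfinite(r.cv_mse)]
    if not finite:
        raise LassoError("no finite cross-validation metrics on the sweep")
    return min(finite, key=lambda r: (r.cv_mse, -r.alpha))


def refit_panel(
    panel_ids: Sequence[str],
    designs: Sequence[DesignMatrix],
    alpha_grid: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    *,
    per_dataset_standardize: bool = True,
    tol: float = 1e-7,
) -> tuple[LassoSolution, SweepRecord, list[SweepRecord]]:
    """Re-fit the selected predictor panel on row-concatenated data from
    several experiments.

    Each design is restricted to the panel columns and (by default)
    standardized within its own dataset before concatenation, so batch-level
    location/scale shifts do not masquerade as signal; the re-fit then runs
    a fresh alpha sweep and picks the minimum-CV-MSE point.
    """
    panel_ids = list(panel_ids)
    if not designs:
        raise LassoError("need at least one design")
    blocks_X, blocks_y = [], []
    for d in designs:
        sub = d.select_features(panel_ids)
        X = sub.X
        if per_dataset_standardize:
            sd = X.std(axis=0)
            if np.any(sd == 0):
                bad = [panel_ids[j] for j in np.where(sd == 0)[0]]
                raise LassoError(f"constant panel columns within a dataset: {bad}")
            X = (X - X.mean(axis=0)) / sd
        blocks_X.append(X)
        blocks_y.append(sub.y)
    combined = DesignMatrix(
        np.vstack(blocks_X), np.concatenate(blocks_y), panel_ids,
        ["metabolite"] * len(panel_ids),
    )
    records = alpha_sweep(combined, alpha_grid, k=k, seed=seed, tol=tol)
    chosen = select_min_cv_mse(records)
    return chosen.solution, chosen, records
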