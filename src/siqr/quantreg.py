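"""LASSO-penalised linear quantile regression on FPC scores.

Fits, for a quantile level tau in (0, 1),

    min_{alpha, b}  sum_i rho_tau(y_i - alpha - nu_i . b)  +  h * sum_m |b_m|

with the check loss ``rho_tau(u) = (tau - 1{u <= 0}) u``.  The piecewise
linear objective is solved exactly as a linear program (HiGHS).  Score
columns are standardised to unit sample variance internally before the
penalty is applied (the leading principal component would otherwise dominate
the l1 term); reported coefficients are always on the original score scale.
The intercept and any appended scalar covariates are never penalised.

The penalty is tuned by seeded K-fold cross-validation of the out-of-fold
check loss over a geometric grid descending from ``h_max`` (the smallest
penalty that yields the all-zero slope solution); ties prefer the largest
(sparsest) penalty.  An optional post-l1 step refits without penalty on the
selected support to undo shrinkage bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from sklearn.model_selection import KFold

__all__ = [
    "QuantileModel",
    "TuningResult",
    "SolverError",
    "check_loss",
    "empirical_quantile",
    "fit_quantile_lasso",
    "default_h_grid",
    "tune_h",
    "post_l1_refit",
    "predict_quantile",
]

_ZERO_TOL = 1e-9


class SolverError(RuntimeError):
    """The LP solver failed to converge."""


def _validate_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    return tau


def check_loss(u, tau: float) -> float:
    """Mean check (quantile) loss: rho_tau(u) = (tau - 1{u<=0}) u, averaged."""
    tau = _validate_tau(tau)
    u = np.asarray(u, dtype=np.float64)
    return float(np.mean((tau - (u <= 0)) * u))


def empirical_quantile(y, tau: float) -> float:
    """The order-statistic tau-quantile minimising the empirical check loss."""
    return float(np.quantile(np.asarray(y, float), tau, method="inverted_cdf"))


@dataclass(frozen=True)
class QuantileModel:
    """A fitted linear quantile regression at one level tau.

    ``b_hat`` is on the ORIGINAL score scale; ``standardization`` records the
    per-column scale used internally.  ``support`` are the indices of nonzero
    slopes.  ``gamma_hat`` holds coefficients of unpenalised scalar
    covariates, if any.
    """

    tau: float
    alpha_hat: float
    b_hat: np.ndarray
    gamma_hat: np.ndarray | None
    h_lasso: float
    support: np.ndarray
    standardization: np.ndarray
    post_l1: bool = False
    objective: float = np.nan

    @property
    def M(self) -> int:
        return int(self.b_hat.size)

    def predict(self, scores, covariates=None) -> np.ndarray:
        return predict_quantile(self, scores, covariates)


@dataclass(frozen=True)
class TuningResult:
    """Cross-validated check loss over a penalty grid."""

    h_grid: np.ndarray
    cv_loss: np.ndarray
    chosen_h: float
    seed: int
    n_folds: int


def _solve_lp(
    y: np.ndarray, X: np.ndarray, tau: float, penalties: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Exact LP solve of the penalised check-loss problem.

    Variables (all >= 0): alpha+, alpha-, b+ (M), b- (M), u+ (N), u- (N)
    with residual constraints alpha + X b + u+ - u- = y.
    Returns (alpha, b, objective).
    """
    N, M = X.shape
    cost = np.concatenate(
        [
            [0.0, 0.0],
            penalties,
            penalties,
            np.full(N, tau),
            np.full(N, 1.0 - tau),
        ]
    )
    ones = np.ones((N, 1))
    eye = sparse.identity(N, format="csc")
    A_eq = sparse.hstack(
        [sparse.csc_matrix(ones), -sparse.csc_matrix(ones),
         sparse.csc_matrix(X), -sparse.csc_matrix(X), eye, -eye],
        format="csc",
    )
    res = linprog(
        cost, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs"
    )
    if not res.success:
        raise SolverError(f"quantile LP failed: {res.message}")
    x = res.x
    alpha = x[0] - x[1]
    b = x[2 : 2 + M] - x[2 + M : 2 + 2 * M]
    return float(alpha), b, float(res.fun)


def fit_quantile_lasso(
    y,
    scores,
    tau: float,
    h_lasso: float = 0.0,
    covariates=None,
    standardize: bool = True,
    penalize_intercept: bool = False,
) -> QuantileModel:
    """Fit the l1-penalised quantile regression of y on the score columns.

    Parameters
    ----------
    y : (N,) responses (ages, in years)
    scores : (N, M) FPC scores (original scale)
    tau : quantile level in (0, 1)
    h_lasso : penalty weight applied to (standardised) score slopes
    covariates : optional (N, P) scalar covariates, never penalised
    standardize : scale score columns to unit sample variance internally
    penalize_intercept : kept for interface completeness; must be False
    """
    tau = _validate_tau(tau)
    if penalize_intercept:
        raise NotImplementedError("the intercept is never penalised")
    if h_lasso < 0:
        raise ValueError("h_lasso must be nonnegative")
    y = np.asarray(y, dtype=np.float64).ravel()
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if scores.shape[0] != y.size:
        raise ValueError("scores and y have different lengths")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(scores))):
        raise ValueError("non-finite inputs")
    N, M = scores.shape

    if standardize and M > 0:
        scales = scores.std(axis=0, ddof=1)
        scales[~(scales > 0)] = 1.0
    else:
        scales = np.ones(M)
    Xs = scores / scales

    ncov = 0
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if covariates.shape[0] != N:
            raise ValueError("covariates and y have different lengths")
        ncov = covariates.shape[1]
        Xs = np.hstack([Xs, covariates])

    penalties = np.concatenate([np.full(M, h_lasso), np.zeros(ncov)])
    alpha, coef, obj = _solve_lp(y, Xs, tau, penalties)

    b_std = coef[:M]
    b_std = np.where(np.abs(b_std) > _ZERO_TOL, b_std, 0.0)
    b = b_std / scales
    gamma = coef[M:] if ncov else None
    support = np.flatnonzero(b_std != 0.0)
    return QuantileModel(
        tau=tau,
        alpha_hat=alpha,
        b_hat=b,
        gamma_hat=gamma,
        h_lasso=float(h_lasso),
        support=support,
        standardization=scales,
        objective=obj,
    )


def default_h_grid(
    y, scores, tau: float, n_points: int = 25, ratio: float = 1e-3
) -> np.ndarray:
    """Geometric penalty grid from h_max down to h_max * ratio (ascending).

    ``h_max`` is the smallest penalty at which the null (intercept-only)
    model is optimal on the standardised problem.  The check-loss
    subgradient at the null solution is a selection ``psi_i`` equal to
    ``tau - 1{r_i < 0}`` away from the kinks and free in ``[tau-1, tau]``
    at observations with zero residual; the null model is optimal iff some
    selection with ``sum_i psi_i = 0`` (intercept stationarity) satisfies
    ``|sum_i nu_im psi_i| <= h`` for every slope.  The smallest such ``h``
    is found by a (tiny) linear program over the kink selections.
    """
    tau = _validate_tau(tau)
    y = np.asarray(y, dtype=np.float64).ravel()
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    scales = scores.std(axis=0, ddof=1)
    scales[~(scales > 0)] = 1.0
    Xs = scores / scales
    M = Xs.shape[1]
    q = empirical_quantile(y, tau)
    r = y - q
    at_kink = np.abs(r) <= 1e-12 * max(1.0, np.abs(y).max())
    psi_fixed = np.where(at_kink, 0.0, tau - (r < 0))
    s = Xs.T @ psi_fixed  # slope gradient from the fixed part
    Xk = Xs[at_kink]
    n_kink = Xk.shape[0]
    if n_kink == 0 or M == 0:
        h_max = float(np.abs(s).max()) if M else 0.0
    else:
        # min t  s.t.  +-(s + Xk' psi_k) <= t,  sum psi_k = -sum psi_fixed,
        #              psi_k in [tau - 1, tau]
        cost = np.concatenate([[1.0], np.zeros(n_kink)])
        A_ub = np.block(
            [[-np.ones((M, 1)), Xk.T], [-np.ones((M, 1)), -Xk.T]]
        )
        b_ub = np.concatenate([-s, s])
        A_eq = np.concatenate([[0.0], np.ones(n_kink)])[None, :]
        b_eq = [-psi_fixed.sum()]
        bounds = [(0, None)] + [(tau - 1.0, tau)] * n_kink
        res = linprog(
            cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
            bounds=bounds, method="highs",
        )
        h_max = float(res.fun) if res.success else float(np.abs(s).max())
    h_max = max(h_max * (1.0 + 1e-9), 1e-8)
    return np.geomspace(h_max * ratio, h_max, n_points)


def tune_h(
    y,
    scores,
    tau: float,
    h_grid=None,
    n_folds: int = 5,
    seed: int = 0,
    covariates=None,
) -> TuningResult:
    """Choose the penalty by K-fold cross-validated out-of-fold check loss.

    The same seeded fold split is used for every grid value so losses are
    comparable; ties in CV loss go to the largest (sparsest) penalty.
    """
    tau = _validate_tau(tau)
    y = np.asarray(y, dtype=np.float64).ravel()
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if y.size < 2 * n_folds:
        raise ValueError("each fold needs at least 2 observations")
    if h_grid is None:
        h_grid = default_h_grid(y, scores, tau)
    h_grid = np.asarray(h_grid, dtype=np.float64)
    if h_grid.size == 0:
        raise ValueError("empty penalty grid")

    folds = list(
        KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(y)
    )
    cv = np.empty(h_grid.size)
    for i, h in enumerate(h_grid):
        losses = []
        for train, test in folds:
            cov_tr = covariates[train] if covariates is not None else None
            cov_te = covariates[test] if covariates is not None else None
            m = fit_quantile_lasso(
                y[train], scores[train], tau, h_lasso=h, covariates=cov_tr
            )
            resid = y[test] - m.predict(scores[test], cov_te)
            losses.append(check_loss(resid, tau))
        cv[i] = np.mean(losses)
    best = cv.min()
    chosen = float(h_grid[cv <= best + 1e-12].max())
    return TuningResult(
        h_grid=h_grid, cv_loss=cv, chosen_h=chosen, seed=int(seed),
        n_folds=int(n_folds),
    )


def post_l1_refit(model: QuantileModel, y, scores, covariates=None) -> QuantileModel:
    """Unpenalised refit restricted to the LASSO-selected support.

    The penalty is used for model selection only; the refit removes the
    shrinkage bias on the retained slopes.  An empty support yields the
    intercept-only fit (the empirical tau-quantile).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    sub = scores[:, model.support]
    refit = fit_quantile_lasso(
        y, sub, model.tau, h_lasso=0.0, covariates=covariates
    )
    b = np.zeros(model.M)
    b[model.support] = refit.b_hat
    std = np.ones(model.M)
    std[model.support] = refit.standardization
    return QuantileModel(
        tau=model.tau,
        alpha_hat=refit.alpha_hat,
        b_hat=b,
        gamma_hat=refit.gamma_hat,
        h_lasso=model.h_lasso,
        support=model.support.copy(),
        standardization=std,
        post_l1=True,
        objective=refit.objective,
    )


def predict_quantile(model: QuantileModel, scores, covariates=None) -> np.ndarray:
    """Predicted conditional quantiles alpha + nu . b (+ z . gamma)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if scores.shape[1] != model.M:
        raise ValueError(
            f"scores have {scores.shape[1]} columns, model expects {model.M}"
        )
    q = model.alpha_hat + scores @ model.b_hat
    if model.gamma_hat is not None:
        if covariates is None:
            raise ValueError("model has scalar covariates; none supplied")
        covariates = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        q = q + covariates @ model.gamma_hat
    return q
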