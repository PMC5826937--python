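"""Elastic-net-penalized Poisson regression, written from first principles.

The model predicts a nonnegative integer outcome (storage days) from a
centered/autoscaled feature matrix X via a log-linear mean mu_i =
exp(beta0 + x_i' beta). The fitted coefficients minimize

    -(1/N) * sum_i [ y_i (beta0 + x_i' beta) - exp(beta0 + x_i' beta) ]
        + lambda * ( (1-alpha) * sum_j beta_j^2 / 2 + alpha * sum_j |beta_j| )

with the intercept unpenalized. alpha in [0, 1] mixes ridge (alpha = 0)
and lasso (alpha = 1); lambda >= 0 scales the penalty.

Solver: outer IRLS (quadratic approximation with weights w = mu and
working response z = eta + (y - mu)/mu) and inner cyclic coordinate
descent with soft-thresholding, warm starts down a descending lambda path,
and active-set iteration with full KKT screening passes. Inputs are
expected pre-centered (no internal standardization); this is enforced, not
silently fixed.

Cross-validation (leave-one-out or k-fold) selects lambda by held-out
Poisson deviance; lambda_min minimizes the mean CV deviance and lambda_1se
is the largest lambda within one standard error of that minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ETA_CAP = 30.0  # linear-predictor cap before exponentiation (overflow guard)
CENTER_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries iteration diagnostics."""


@dataclass
class ElasticNetModel:
    """Fitted elastic-net Poisson model at one (alpha, lambda)."""

    alpha: float
    lam: float
    intercept: float
    coef: np.ndarray
    feature_names: list[str] | None = None
    n_sweeps: int = 0
    n_irls: int = 0
    max_delta: float = 0.0

    @property
    def nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.coef)

    def to_dict(self) -> dict:
        names = self.feature_names or [f"x{j}" for j in range(len(self.coef))]
        return {
            "alpha": self.alpha,
            "lambda": self.lam,
            "intercept": self.intercept,
            "coef": {names[j]: float(self.coef[j]) for j in self.nonzero},
            "n_sweeps": self.n_sweeps,
            "n_irls": self.n_irls,
            "max_delta": self.max_delta,
        }


@dataclass
class CVResult:
    """Cross-validated deviance over a descending lambda grid."""

    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float
    n_folds: int
    fold_scheme: str
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambdas, "mean_deviance": self.mean_deviance,
             "se_deviance": self.se_deviance}
        )


@dataclass
class PredictionEval:
    """RMSE and squared Pearson correlation of predictions vs truth."""

    rmse: float
    r2: float | None
    p_value: float | None
    predictions: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# primitives


def soft_threshold(z: float | np.ndarray, gamma: float):
    """sign(z) * max(|z| - gamma, 0)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


def poisson_deviance(y, mu) -> float:
    """2 * sum[ y ln(y/mu) - (y - mu) ], with y ln(y/mu) := 0 at y = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    if np.any(y < 0):
        raise ValueError("y must be nonnegative")
    term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _linear_predictor(X: np.ndarray, beta0: float, beta: np.ndarray) -> np.ndarray:
    return np.clip(beta0 + X @ beta, -ETA_CAP, ETA_CAP)


def penalized_objective(X, y, alpha: float, lam: float, beta0: float, beta) -> float:
    """-(1/N) log-likelihood + lambda * elastic-net penalty (Poisson)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    N = len(y)
    eta = _linear_predictor(X, beta0, beta)
    ll = float(np.sum(y * eta - np.exp(eta)))
    pen = (1.0 - alpha) * 0.5 * float(beta @ beta) + alpha * float(np.abs(beta).sum())
    return -ll / N + lam * pen


def _check_centered(X: np.ndarray) -> None:
    if np.max(np.abs(X.mean(axis=0)), initial=0.0) > CENTER_TOL:
        raise ValueError(
            "X columns must be centered (|mean| < 1e-8); autoscale the input"
        )


def compute_lambda_grid(
    X,
    y,
    alpha: float,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
) -> np.ndarray:
    """Descending log-spaced lambda grid from the analytic lambda_max.

    lambda_max = max_j |<x_j, y - ybar>| / (N * alpha) is the smallest
    penalty at which the all-zero coefficient vector (with the null
    intercept ln ybar) satisfies the KKT conditions. For alpha < 0.001 the
    alpha = 0.001 surrogate is used, as pure ridge has no finite
    lambda_max.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N, p = X.shape
    if np.all(y == y[0]):
        raise ValueError("constant outcome: no lambda path exists")
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-4 if N > p else 1e-2
    a_eff = max(alpha, 0.001)
    lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / (N * a_eff))
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


# ---------------------------------------------------------------------------
# solver


def _py_cd_solve(X, Xw, w, r, beta, beta0, idx, lam_l1, denom, wx2, wsum,
                 tol, max_sweeps):
    """Cyclic CD over `idx` until max |delta| < tol (numpy fallback)."""
    sweeps = 0
    while True:
        max_delta = 0.0
        for j in idx:
            bj = beta[j]
            rho = Xw[:, j] @ r + wx2[j] * bj
            new = soft_threshold(rho, lam_l1) / denom[j]
            if new != bj:
                r += X[:, j] * (bj - new)
                beta[j] = new
                max_delta = max(max_delta, abs(new - bj))
        d0 = (w @ r) / wsum
        beta0 += d0
        r -= d0
        sweeps += 1
        if max(max_delta, abs(d0)) < tol or sweeps >= max_sweeps:
            return beta0, sweeps


try:  # JIT-compiled inner loop; the numpy fallback is semantically identical
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _nb_cd_solve(X, Xw, w, r, beta, beta0, idx, lam_l1, denom, wx2, wsum,
                     tol, max_sweeps):  # pragma: no cover - numba path
        n = X.shape[0]
        sweeps = 0
        while True:
            max_delta = 0.0
            for t in range(idx.shape[0]):
                j = idx[t]
                bj = beta[j]
                rho = wx2[j] * bj
                for i in range(n):
                    rho += Xw[i, j] * r[i]
                if rho > lam_l1:
                    new = (rho - lam_l1) / denom[j]
                elif rho < -lam_l1:
                    new = (rho + lam_l1) / denom[j]
                else:
                    new = 0.0
                if new != bj:
                    d = bj - new
                    for i in range(n):
                        r[i] += X[i, j] * d
                    beta[j] = new
                    ad = abs(new - bj)
                    if ad > max_delta:
                        max_delta = ad
            d0 = 0.0
            for i in range(n):
                d0 += w[i] * r[i]
            d0 /= wsum
            beta0 += d0
            for i in range(n):
                r[i] -= d0
            sweeps += 1
            big = max_delta if max_delta > abs(d0) else abs(d0)
            if big < tol or sweeps >= max_sweeps:
                return beta0, sweeps

    _cd_solve = _nb_cd_solve
except ImportError:  # pragma: no cover
    _cd_solve = _py_cd_solve


def _weighted_cd(X, w, z, beta0, beta, alpha, lam, tol, max_sweeps, sweeps_used):
    """Solve the penalized weighted least-squares subproblem by CD.

    Minimizes (1/2N) sum_i w_i (z_i - beta0 - x_i'beta)^2 + lambda*penalty
    using active-set iteration: converge on the current active set, then do
    a full KKT screening pass and absorb violators.
    """
    N, p = X.shape
    w_over_n = w / N
    wsum = w.sum()
    lam_l1 = lam * alpha
    lam_l2 = lam * (1.0 - alpha)
    Xw = X * w_over_n[:, None]
    wx2 = (X * Xw).sum(axis=0)  # <w, x_j^2>/N per column
    denom = np.maximum(wx2 + lam_l2, 1e-300)
    r = z - beta0 - X @ beta
    active = set(np.flatnonzero(beta).tolist())
    sweeps = sweeps_used
    while True:
        if active:
            idx = np.sort(np.fromiter(active, dtype=np.int64))
            beta0, used = _cd_solve(X, Xw, w, r, beta, float(beta0), idx,
                                    lam_l1, denom, wx2, wsum, tol,
                                    max_sweeps - sweeps)
            sweeps += used
        else:
            d0 = (w @ r) / wsum
            beta0 += d0
            r -= d0
        # KKT screening over all coordinates (vectorized)
        g = Xw.T @ r  # gradient of smooth part at current beta
        viol = np.flatnonzero(
            (beta == 0) & (np.abs(g) > lam_l1 * (1 + 1e-12) + 1e-12)
        )
        new = [j for j in viol.tolist() if j not in active]
        if not new or sweeps >= max_sweeps:
            break
        active.update(new)
    return beta0, beta, sweeps


def fit_elastic_net_poisson(
    X,
    y,
    alpha: float,
    lam: float,
    warm_start: ElasticNetModel | None = None,
    feature_names: list[str] | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
    max_irls: int = 100,
) -> ElasticNetModel:
    """Fit the penalized Poisson model at one (alpha, lambda).

    X must be column-centered (autoscaled input); no internal
    standardization is performed. Converges when the largest coefficient
    change over an IRLS step falls below `tol`; raises ConvergenceError
    with diagnostics otherwise.
    """
    X = np.asfortranarray(X, dtype=float)  # contiguous columns for the CD loop
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must be nonnegative integers (storage days)")
    _check_centered(X)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    N, p = X.shape
    ybar = y.mean()
    if ybar <= 0:
        raise ValueError("mean outcome must be positive for a Poisson model")
    if warm_start is not None:
        beta0 = float(warm_start.intercept)
        beta = warm_start.coef.astype(float).copy()
    else:
        beta0 = float(np.log(ybar))
        beta = np.zeros(p)

    sweeps = 0
    for it in range(1, max_irls + 1):
        eta = _linear_predictor(X, beta0, beta)
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        old0, old = beta0, beta.copy()
        beta0, beta, sweeps = _weighted_cd(
            X, w, z, beta0, beta, alpha, lam, tol, max_sweeps, sweeps
        )
        delta = max(abs(beta0 - old0), float(np.max(np.abs(beta - old), initial=0.0)))
        if delta < max(tol, 1e-10):
            if not np.any(beta):
                beta0 = float(np.log(ybar))  # exact null-model optimum
            return ElasticNetModel(
                alpha=alpha, lam=lam, intercept=beta0, coef=beta,
                feature_names=list(feature_names) if feature_names is not None else None,
                n_sweeps=sweeps, n_irls=it, max_delta=delta,
            )
        if sweeps >= max_sweeps:
            break
    raise ConvergenceError(
        f"no convergence: irls={it}, sweeps={sweeps}, last max|delta|={delta:.3e}"
    )


def kkt_residuals(X, y, alpha: float, lam: float, model: ElasticNetModel) -> np.ndarray:
    """Per-coefficient first-order optimality residuals (plus intercept, last).

    For beta_j = 0: max(0, |g_j| - lambda*alpha); for beta_j != 0:
    |g_j + lambda*(1-alpha)*beta_j + lambda*alpha*sign(beta_j)|, where g is
    the gradient of the smooth part -(1/N) l.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N = len(y)
    mu = np.exp(_linear_predictor(X, model.intercept, model.coef))
    g = -(X.T @ (y - mu)) / N
    beta = model.coef
    res = np.where(
        beta == 0,
        np.maximum(0.0, np.abs(g) - lam * alpha),
        np.abs(g + lam * (1 - alpha) * beta + lam * alpha * np.sign(beta)),
    )
    res0 = abs(-(y - mu).sum() / N)
    return np.append(res, res0)


def fit_lambda_path(
    X, y, alpha: float, lambdas: np.ndarray, **kwargs
) -> list[ElasticNetModel]:
    """Fit the descending lambda path with warm starts."""
    models: list[ElasticNetModel] = []
    warm = None
    for lam in lambdas:
        warm = fit_elastic_net_poisson(X, y, alpha, lam, warm_start=warm, **kwargs)
        models.append(warm)
    return models


# ---------------------------------------------------------------------------
# cross-validation and model selection


def _fold_assignments(N: int, folds, seed: int | None) -> list[np.ndarray]:
    if folds in ("loo", None) or folds == N:
        return [np.array([i]) for i in range(N)]
    k = int(folds)
    if k < 2 or k > N:
        raise ValueError("folds must be 'loo' or an int in [2, N]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    return [np.sort(perm[i::k]) for i in range(k)]


def cross_validate_lambda(
    X,
    y,
    alpha: float,
    folds="loo",
    seed: int | None = None,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    **fit_kwargs,
) -> CVResult:
    """Select lambda by cross-validated Poisson deviance.

    The lambda grid is computed once on the full data (the fold seed
    affects only assignments). Per fold, the path is fitted on the
    training portion with warm starts and the held-out per-observation
    deviance is recorded per lambda. lambda_min minimizes the mean CV
    deviance; lambda_1se is the largest lambda whose mean is within one
    standard error of that minimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N = len(y)
    if N < 3:
        raise ValueError("need N >= 3 for cross-validation")
    if lambdas is None:
        lambdas = compute_lambda_grid(X, y, alpha, n_lambda=n_lambda)
    assignments = _fold_assignments(N, folds, seed)
    per_fold = []
    for test_idx in assignments:
        train = np.setdiff1d(np.arange(N), test_idx)
        y_tr = y[train]
        if np.all(y_tr == y_tr[0]):
            warnings.warn("fold skipped: constant training outcome", stacklevel=2)
            continue
        X_tr = X[train] - X[train].mean(axis=0)
        X_te = X[test_idx] - X[train].mean(axis=0)
        models = fit_lambda_path(X_tr, y_tr, alpha, lambdas, **fit_kwargs)
        devs = [
            poisson_deviance(
                y[test_idx], np.exp(_linear_predictor(X_te, m.intercept, m.coef))
            ) / len(test_idx)
            for m in models
        ]
        per_fold.append(devs)
    if not per_fold:
        raise ValueError("all folds skipped")
    D = np.asarray(per_fold)  # folds x lambdas
    mean = D.mean(axis=0)
    se = D.std(axis=0, ddof=1) / np.sqrt(D.shape[0]) if D.shape[0] > 1 else np.zeros_like(mean)
    i_min = int(np.argmin(mean))
    lam_min = float(lambdas[i_min])
    within = np.flatnonzero(mean <= mean[i_min] + se[i_min])
    lam_1se = float(lambdas[within.min()])  # grid descending: smallest index = largest lambda
    return CVResult(
        lambdas=np.asarray(lambdas, dtype=float),
        mean_deviance=mean,
        se_deviance=se,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        n_folds=D.shape[0],
        fold_scheme="loo" if folds in ("loo", None) else f"{int(folds)}-fold",
        seed=seed,
    )


def select_alpha(
    X,
    y,
    alpha_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    folds="loo",
    seed: int | None = None,
    **cv_kwargs,
) -> tuple[float, dict[float, CVResult]]:
    """Screen a grid of alpha values; best minimizes CV deviance at its
    own lambda_min, ties broken toward alpha = 0.5."""
    results: dict[float, CVResult] = {}
    for a in alpha_grid:
        if not 0.0 <= a <= 1.0:
            raise ValueError("alpha grid values must lie in [0, 1]")
        results[a] = cross_validate_lambda(X, y, a, folds=folds, seed=seed, **cv_kwargs)
    best_scores = {a: float(r.mean_deviance.min()) for a, r in results.items()}
    lo = min(best_scores.values())
    tied = [a for a, s in best_scores.items() if s <= lo + 1e-12 * max(1.0, abs(lo))]
    best = min(tied, key=lambda a: (abs(a - 0.5), a))
    return best, results


def split_train_test(
    samples: pd.DataFrame, fraction: float = 0.75, seed: int | None = None
) -> tuple[list[str], list[str]]:
    """Stratified-by-day random split of study samples.

    Each storage day contributes ceil(fraction * n_day) samples to the
    training set; a day with a single sample goes to training with a
    warning.
    """
    study = samples[samples["role"] == "study"] if "role" in samples else samples
    rng = np.random.default_rng(seed)
    train, test = [], []
    for day in np.sort(study["storage_day"].unique()):
        ids = study.index[study["storage_day"] == day].to_numpy()
        if len(ids) == 1:
            warnings.warn(f"day {day} has a single sample; assigned to train",
                          stacklevel=2)
            train.extend(ids.tolist())
            continue
        perm = rng.permutation(len(ids))
        n_tr = int(np.ceil(fraction * len(ids)))
        train.extend(ids[perm[:n_tr]].tolist())
        test.extend(ids[perm[n_tr:]].tolist())
    return train, test


def predict_storage_days(model: ElasticNetModel, X) -> np.ndarray:
    """yhat_i = exp(beta0 + x_i' beta); columns aligned to model features."""
    if isinstance(X, pd.DataFrame):
        if model.feature_names is not None:
            missing = set(model.feature_names) - set(X.columns)
            if missing:
                raise ValueError(f"prediction input lacks features: {sorted(missing)[:5]}")
            X = X[model.feature_names]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.coef):
        raise ValueError("feature dimension mismatch")
    return np.exp(_linear_predictor(X, model.intercept, model.coef))


def evaluate_predictions(actual, predicted) -> PredictionEval:
    """RMSE plus squared Pearson correlation (with its two-sided p-value)."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if len(y) != len(yhat) or len(y) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    if y.std() == 0 or yhat.std() == 0:
        return PredictionEval(rmse=rmse, r2=None, p_value=None, predictions=yhat)
    r, p = stats.pearsonr(y, yhat)
    return PredictionEval(rmse=rmse, r2=float(r * r), p_value=float(p),
                          predictions=yhat)


def rank_selected_features(model: ElasticNetModel) -> pd.DataFrame:
    """Nonzero-coefficient features sorted by |coefficient| descending.

    Ties are broken by feature id; an all-zero model yields an empty frame.
    """
    names = model.feature_names or [f"x{j}" for j in range(len(model.coef))]
    nz = model.nonzero
    df = pd.DataFrame(
        {"feature_id": [names[j] for j in nz],
         "coefficient": model.coef[nz]}
    )
    df["abs_coef"] = df["coefficient"].abs()
    df = df.sort_values(["abs_coef", "feature_id"], ascending=[False, True],
                        kind="mergesort").drop(columns="abs_coef")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
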