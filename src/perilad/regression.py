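"""LASSO modelling of chromatin-periphery interaction signal.

Models per-window periphery-interaction signal (RE-ChIP-like) from a matrix
of epigenomic features, optionally augmented with each window's genomic
distance to the nearest pericentromeric region (PR).  The fitting protocol
follows glmnet's defaults: internal standardization, a 100-point log-spaced
lambda grid from lambda_max down to 1e-4*lambda_max, tenfold cross-validation,
and the one-standard-error rule (lambda.1se) for the reported model.  Model
comparison holds out whole chromosomes: train on some, score MSE on others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .intervals import GenomicIntervalSet

__all__ = [
    "LassoModelResult",
    "distance_to_pr",
    "spearman_vs_pr",
    "fit_lasso_cv",
    "predict",
    "kkt_violation",
    "compare_feature_sets",
]


@dataclass
class LassoModelResult:
    feature_names: list
    coefficients: np.ndarray       # at lambda_1se, original feature scale
    intercept: float
    lambda_grid: np.ndarray        # decreasing
    cv_mean_mse: np.ndarray
    cv_se_mse: np.ndarray
    lambda_min: float
    lambda_1se: float
    coefficients_min: np.ndarray   # at lambda_min, original scale
    intercept_min: float
    dropped_features: list = dc_field(default_factory=list)
    test_mse: float | None = None
    # standardized-scale artifacts kept for KKT verification
    coef_std_1se: np.ndarray | None = None
    coef_std_min: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: float | None = None


# ------------------------------------------------------------------ distance

def distance_to_pr(windows, pr: GenomicIntervalSet):
    """Per-window distance (bp) to the nearest pericentromeric region.

    ``windows`` is a DataFrame with chrom/start/end.  Windows overlapping a
    PR get 0; otherwise the distance is the gap from the window midpoint to
    the nearest PR boundary on the same chromosome.  Windows on chromosomes
    without any PR come back NaN and are reported in the flag array.
    """
    windows = windows.reset_index(drop=True)
    n = len(windows)
    out = np.full(n, np.nan)
    for chrom, sub in windows.groupby("chrom", sort=False):
        s, e = pr.arrays(chrom)
        if len(s) == 0:
            continue
        ws = sub["start"].to_numpy()
        we = sub["end"].to_numpy()
        mid = (ws + we) / 2.0
        bounds = np.concatenate([s, e]).astype(float)
        d = np.min(np.abs(mid[:, None] - bounds[None, :]), axis=1)
        overlap = np.zeros(len(ws), dtype=bool)
        for ps, pe in zip(s, e):
            overlap |= (ws < pe) & (ps < we)
        d[overlap] = 0.0
        out[sub.index.to_numpy()] = d
    flagged = ~np.isfinite(out)
    return out, flagged


def spearman_vs_pr(signal, distances):
    """Spearman rank correlation (tie-corrected) between signal and PR distance."""
    x = np.asarray(signal, dtype=float)
    y = np.asarray(distances, dtype=float)
    if len(x) != len(y):
        raise ValueError("signal and distances must have equal length")
    if len(x) < 10:
        raise ValueError("need n >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# --------------------------------------------------------------------- lasso

def _lambda_grid(Xs, yc, n_lambda=100, ratio=1e-4):
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / len(yc))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _standardize(X, mean=None, scale=None):
    if mean is None:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
    safe = np.where(scale > 0, scale, 1.0)
    return (X - mean) / safe, mean, scale


def _fit_path(Xs, yc, lambdas):
    """Coefficient matrix (K, n_lambda) at the given penalties (decreasing)."""
    _, coefs, _ = lasso_path(Xs, yc, alphas=lambdas, tol=1e-10, max_iter=100_000)
    return coefs


def fit_lasso_cv(
    X,
    y,
    feature_names=None,
    n_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    fold_scheme: str = "random",
) -> LassoModelResult:
    """Gaussian LASSO with k-fold cross-validation and the lambda.1se rule.

    Features are standardized internally (per training fold during CV, on the
    full data for the final fit); coefficients are reported back on the
    original scale.  fold_scheme="contiguous" assigns folds as contiguous
    window blocks to respect genomic autocorrelation; the default "random"
    mirrors glmnet's seeded random fold assignment.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if feature_names is None:
        feature_names = [f"x{j+1}" for j in range(k)]
    feature_names = list(feature_names)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n={n}")
    scale_all = X.std(axis=0)
    dropped = [feature_names[j] for j in range(k) if scale_all[j] == 0]
    if dropped:
        warnings.warn(f"dropping degenerate (constant) features: {dropped}")
    keep = scale_all > 0
    Xk = X[:, keep]
    names_kept = [nm for nm, kp in zip(feature_names, keep) if kp]

    Xs_all, mu, sd = _standardize(Xk)
    ybar = float(y.mean())
    yc = y - ybar
    if lambda_grid is None:
        lambda_grid = _lambda_grid(Xs_all, yc)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    if fold_scheme == "random":
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(Xk))
    elif fold_scheme == "contiguous":
        bounds = np.linspace(0, n, n_folds + 1).astype(int)
        idx = np.arange(n)
        splits = [(np.concatenate([idx[:a], idx[b:]]), idx[a:b])
                  for a, b in zip(bounds[:-1], bounds[1:])]
    else:
        raise ValueError(f"unknown fold scheme {fold_scheme!r}")

    fold_mse = np.empty((n_folds, len(lambda_grid)))
    for f, (tr, va) in enumerate(splits):
        Xs_tr, m_tr, s_tr = _standardize(Xk[tr])
        y_tr = y[tr] - y[tr].mean()
        coefs = _fit_path(Xs_tr, y_tr, lambda_grid)
        Xs_va, _, _ = _standardize(Xk[va], m_tr, s_tr)
        pred = Xs_va @ coefs + y[tr].mean()
        fold_mse[f] = np.mean((y[va][:, None] - pred) ** 2, axis=0)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)

    i_min = int(np.argmin(cv_mean))
    lambda_min = float(lambda_grid[i_min])
    within = cv_mean <= cv_mean[i_min] + cv_se[i_min]
    i_1se = int(np.argmax(within))  # grid is decreasing: first hit = largest lambda
    lambda_1se = float(lambda_grid[i_1se])

    coefs_all = _fit_path(Xs_all, yc, lambda_grid)

    def _to_original(coef_std):
        safe = np.where(sd > 0, sd, 1.0)
        beta = coef_std / safe
        b0 = ybar - float(beta @ mu)
        full = np.zeros(k)
        full[keep] = beta
        return full, b0

    beta_1se, b0_1se = _to_original(coefs_all[:, i_1se])
    beta_min, b0_min = _to_original(coefs_all[:, i_min])
    return LassoModelResult(
        feature_names=feature_names,
        coefficients=beta_1se, intercept=b0_1se,
        lambda_grid=lambda_grid, cv_mean_mse=cv_mean, cv_se_mse=cv_se,
        lambda_min=lambda_min, lambda_1se=lambda_1se,
        coefficients_min=beta_min, intercept_min=b0_min,
        dropped_features=dropped,
        coef_std_1se=coefs_all[:, i_1se], coef_std_min=coefs_all[:, i_min],
        x_mean=mu, x_scale=sd, y_mean=ybar,
    )


def predict(result: LassoModelResult, X, which: str = "1se") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if which == "1se":
        return X @ result.coefficients + result.intercept
    return X @ result.coefficients_min + result.intercept_min


def kkt_violation(X, y, result: LassoModelResult, which: str = "1se") -> float:
    """Max violation of the LASSO subgradient conditions at the returned lambda.

    On the standardized problem with objective (1/2n)||y - Xb||^2 + lam*|b|_1
    the optimum satisfies |x_j' r| / n <= lam for zero coefficients and
    x_j' r / n = lam * sign(b_j) for active ones.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    kept = [j for j, nm in enumerate(result.feature_names) if nm not in result.dropped_features]
    Xs, _, _ = _standardize(X[:, kept], result.x_mean, result.x_scale)
    coef = result.coef_std_1se if which == "1se" else result.coef_std_min
    lam = result.lambda_1se if which == "1se" else result.lambda_min
    r = (y - result.y_mean) - Xs @ coef
    g = Xs.T @ r / len(y)
    viol = np.where(coef == 0, np.maximum(np.abs(g) - lam, 0.0),
                    np.abs(g - lam * np.sign(coef)))
    return float(viol.max())


def compare_feature_sets(X_full, X_reduced, y, chroms, train_chroms, test_chroms,
                         seed: int = 0, n_folds: int = 10):
    """Chromosome-held-out MSE comparison of two feature sets.

    Both models are fitted (tenfold CV, lambda.1se) on windows of
    ``train_chroms`` only — standardization parameters included — and scored
    by MSE on ``test_chroms``.  Returns (mse_full, mse_reduced, delta) with
    delta = mse_reduced - mse_full (positive when the full model fits better).
    """
    chroms = np.asarray(chroms)
    tr = np.isin(chroms, list(train_chroms))
    te = np.isin(chroms, list(test_chroms))
    if not te.any():
        raise ValueError("empty test set")
    if not tr.any():
        raise ValueError("empty training set")
    y = np.asarray(y, dtype=float)
    out = []
    for X in (X_full, X_reduced):
        X = np.asarray(X, dtype=float)
        if np.ptp(y[tr]) == 0:
            out.append(float(np.mean((y[te] - y[tr].mean()) ** 2)))
            continue
        fit = fit_lasso_cv(X[tr], y[tr], n_folds=n_folds, seed=seed)
        out.append(float(np.mean((y[te] - predict(fit, X[te])) ** 2)))
    mse_full, mse_reduced = out
    return mse_full, mse_reduced, mse_reduced - mse_full
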