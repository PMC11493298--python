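"""Structure-corrected regression estimators.

Four estimators of the slope of ``y`` on ``x`` in the presence of a
structured genetic covariance Sigma among sampling units:

* OLS — ignores Sigma;
* OLS + eigenvectors — the top-J eigenvectors of Sigma enter as fixed
  covariates (principal components of the genotype matrix in a GWAS;
  phylogenetic eigenvector regression on a tree), which *excises* the
  leading J dimensions from the estimator;
* GLS — residual covariance proportional to Sigma (PGLS on a tree; the
  sigma_E^2 = 0 limit of the mixed model), which *downweights* every
  dimension by its eigenvalue;
* GLS/LMM + eigenvectors — both corrections at once.

All fits are computed in the eigenrotated frame of Sigma: rotating by V^T
turns GLS into weighted least squares with per-dimension weights
``sigma_G^2 lambda_j + sigma_E^2``.  The mixed model estimates the two
variance components by restricted maximum likelihood (REML), profiled down
to a 1-D search over the ratio ``phi = sigma_E^2 / sigma_G^2``.

Wald t-tests (two-sided, df = residual dimensions minus fitted columns) are
reported for every coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .covariance import CovarianceMatrix

__all__ = [
    "RegressionFit",
    "REMLResult",
    "fit_ols",
    "fit_gls",
    "augment_with_eigenvectors",
    "reml_variance_components",
    "reml_profile_loglik",
    "association_test",
]

_SINGULAR_REL_TOL = 1e-12


@dataclass
class RegressionFit:
    """Coefficients, Wald inference, and variance components of one fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    scale: float
    method: str = "ols"
    sigma_g2: float | None = None
    sigma_e2: float | None = None
    n_eigenvectors: int = 0
    reml_boundary: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def _as_design(X, default_prefix="x") -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"{default_prefix}{j}" for j in range(X.shape[1])]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # small R diagonals localize collinear columns for the error message
    _, Rm = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(Rm))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if diag.size and diag.min() <= tol:
        bad = [names[j] for j in np.flatnonzero(diag <= tol)]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns involve {bad}"
        )


def _wls_core(
    yw: np.ndarray, Xw: np.ndarray, names: list[str], method: str, **extra
) -> RegressionFit:
    """OLS on an (already whitened) system, with Wald t inference."""
    n, p = Xw.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than columns ({p})")
    _check_rank(Xw, names)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - p
    scale = float(resid @ resid) / df
    cov = scale * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return RegressionFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(t, index=names),
        pvalues=pd.Series(pvals, index=names),
        df_resid=df,
        scale=scale,
        method=method,
        **extra,
    )


def fit_ols(y, X) -> RegressionFit:
    """Ordinary least squares with Student-t Wald tests (df = n - p)."""
    Xm, names = _as_design(X)
    y = np.asarray(y, dtype=float).ravel()
    return _wls_core(y, Xm, names, "ols")


def _rotated_weights(
    sigma: CovarianceMatrix, sigma_g2: float, sigma_e2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvectors, weights, and the kept-dimension mask.

    Dimensions whose weight ``sigma_g2 lambda_j + sigma_e2`` is numerically
    zero (possible when Sigma is singular and sigma_e2 = 0, e.g. identical
    tips) are dropped: the model puts no mass there, and for data generated
    under it the corresponding projections are almost surely zero.
    """
    lam = sigma.eigenvalues
    V = sigma.eigenvectors
    w = sigma_g2 * lam + sigma_e2
    keep = w > _SINGULAR_REL_TOL * max(w.max(), 1e-300)
    return V, w, keep


def fit_gls(
    y, X, sigma: CovarianceMatrix, sigma_g2: float = 1.0, sigma_e2: float = 0.0
) -> RegressionFit:
    """Generalized least squares with residual covariance
    ``sigma_g2 * Sigma + sigma_e2 * I``, via the eigenrotation of Sigma.

    Rotate y and X by V^T and weight dimension j by the inverse of
    ``sigma_g2 lambda_j + sigma_e2``; SEs and t-tests as OLS on the
    whitened system.  With Sigma = I this reduces exactly to OLS.
    """
    if sigma_g2 < 0 or sigma_e2 < 0 or (sigma_g2 == 0 and sigma_e2 == 0):
        raise ValueError("need sigma_g2, sigma_e2 >= 0 and not both zero")
    Xm, names = _as_design(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != sigma.n or Xm.shape[0] != sigma.n:
        raise ValueError("y/X dimensions do not match Sigma")
    V, w, keep = _rotated_weights(sigma, sigma_g2, sigma_e2)
    if not keep.all() and sigma_e2 > 0:
        raise ValueError("weighted system is singular")
    sw = 1.0 / np.sqrt(w[keep])
    Vk = V[:, keep]
    yw = (Vk.T @ y) * sw
    Xw = (Vk.T @ Xm) * sw[:, None]
    return _wls_core(
        yw, Xw, names, "gls", sigma_g2=float(sigma_g2), sigma_e2=float(sigma_e2)
    )


def augment_with_eigenvectors(X, sigma: CovarianceMatrix, J: int) -> pd.DataFrame:
    """Append the top-J eigenvectors of Sigma (deterministic sign and
    descending-eigenvalue order) as covariate columns ``eig1..eigJ``."""
    Xm, names = _as_design(X)
    n = Xm.shape[0]
    if not (0 <= J < n):
        raise ValueError(f"J must satisfy 0 <= J < n (got J={J}, n={n})")
    if n != sigma.n:
        raise ValueError("X rows do not match Sigma")
    out = pd.DataFrame(Xm, columns=names)
    for j in range(J):
        out[f"eig{j + 1}"] = sigma.eigenvectors[:, j]
    return out


# -- REML ------------------------------------------------------------------


@dataclass
class REMLResult:
    sigma_g2: float
    sigma_e2: float
    phi: float
    loglik: float
    boundary: bool


_PHI_LO, _PHI_HI = 1e-6, 1e6


def reml_profile_loglik(y, X, sigma: CovarianceMatrix, phi: float) -> float:
    """Profiled restricted log-likelihood at ratio phi = sigma_E^2/sigma_G^2.

    In the rotated frame, with weights ``w_j = lambda_j + phi``, the scale
    sigma_G^2 profiles out in closed form as the weighted residual mean
    square; the criterion below is the restricted log-likelihood at that
    profiled scale, up to an additive constant.
    """
    Xm, _ = _as_design(X)
    y = np.asarray(y, dtype=float).ravel()
    lam = sigma.eigenvalues
    V = sigma.eigenvectors
    w = lam + phi
    keep = w > _SINGULAR_REL_TOL * w.max()
    wk = w[keep]
    Vk = V[:, keep]
    yr = Vk.T @ y
    Xr = Vk.T @ Xm
    sw = 1.0 / np.sqrt(wk)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    n_eff, p = Xw.shape
    if n_eff <= p:
        return -np.inf
    XtX = Xw.T @ Xw
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    if rss <= 0:
        return -np.inf
    df = n_eff - p
    s2 = rss / df
    return -0.5 * (df * np.log(s2) + np.sum(np.log(wk)) + logdet_xtx + df)


def reml_variance_components(
    y, X, sigma: CovarianceMatrix, n_grid: int = 61
) -> REMLResult:
    """REML estimates of (sigma_G^2, sigma_E^2) for y ~ N(Xb, sG2 Sigma + sE2 I).

    The restricted likelihood is profiled to a 1-D function of the ratio
    phi = sigma_E^2 / sigma_G^2, scanned on a log grid over [1e-6, 1e6] and
    refined by bounded scalar minimization within the bracketing interval;
    the scale is recovered in closed form.  Solutions pinned at either end
    of the phi range are flagged as boundary (sigma_E^2 ~ 0 at the lower
    end; sigma_G^2 ~ 0 dominance at the upper end).
    """
    lam = sigma.eigenvalues
    if lam[0] <= 0:
        raise ValueError("Sigma is zero; components not identifiable")
    if (lam[0] - lam[-1]) <= 1e-12 * lam[0]:
        raise ValueError(
            "Sigma is proportional to the identity: only sigma_G^2 + sigma_E^2 "
            "is identifiable"
        )
    grid = np.logspace(np.log10(_PHI_LO), np.log10(_PHI_HI), n_grid)
    vals = np.array([reml_profile_loglik(y, X, sigma, phi) for phi in grid])
    if not np.isfinite(vals).any():
        raise ValueError("restricted likelihood non-finite over the entire phi grid")
    k = int(np.nanargmax(vals))
    boundary = k in (0, len(grid) - 1)
    if boundary:
        phi_hat = grid[k]
        loglik = vals[k]
    else:
        lo, hi = np.log(grid[k - 1]), np.log(grid[k + 1])
        res = minimize_scalar(
            lambda u: -reml_profile_loglik(y, X, sigma, np.exp(u)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if not np.isfinite(res.fun):
            raise ValueError("REML optimizer produced a non-finite likelihood")
        phi_hat = float(np.exp(res.x))
        loglik = -float(res.fun)
    # closed-form profiled scale at phi_hat
    Xm, _ = _as_design(X)
    yv = np.asarray(y, dtype=float).ravel()
    V = sigma.eigenvectors
    w = lam + phi_hat
    keep = w > _SINGULAR_REL_TOL * w.max()
    sw = 1.0 / np.sqrt(w[keep])
    Vk = V[:, keep]
    yw = (Vk.T @ yv) * sw
    Xw = (Vk.T @ Xm) * sw[:, None]
    beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sg2 = rss / (Xw.shape[0] - Xw.shape[1])
    return REMLResult(
        sigma_g2=float(sg2),
        sigma_e2=float(sg2 * phi_hat),
        phi=float(phi_hat),
        loglik=float(loglik),
        boundary=boundary,
    )


# -- the association test --------------------------------------------------


def association_test(
    y,
    x,
    sigma: CovarianceMatrix | None = None,
    J: int = 0,
    method: str = "ols",
) -> RegressionFit:
    """Test for association of a trait y with a predictor x.

    Design = intercept + x + top-J eigenvectors of Sigma.  ``method``:

    * ``"ols"`` — no residual-covariance weighting (Sigma only supplies the
      eigenvector covariates);
    * ``"gls"`` — weighting by Sigma with sigma_G^2 = 1, sigma_E^2 = 0
      (scale-free for t-tests; the PGLS / pure-Brownian case);
    * ``"lmm"`` — REML-estimated (sigma_G^2, sigma_E^2), then GLS at the
      estimates (the mixed-model / GWAS case).

    y and x may be Series (aligned to Sigma's labels) or plain arrays
    already in Sigma's order.  The returned fit's ``pvalues["x"]`` is the
    slope test.
    """
    if method not in ("ols", "gls", "lmm"):
        raise ValueError(f"unknown method {method!r}")
    if (J > 0 or method in ("gls", "lmm")) and sigma is None:
        raise ValueError(f"method {method!r} with J={J} requires Sigma")
    if sigma is not None:
        if isinstance(y, pd.Series):
            y = y.reindex(sigma.labels)
            if y.isna().any():
                raise KeyError("y labels do not cover Sigma labels")
        if isinstance(x, pd.Series):
            x = x.reindex(sigma.labels)
            if x.isna().any():
                raise KeyError("x labels do not cover Sigma labels")
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    n = len(y)
    if len(x) != n:
        raise ValueError("y and x lengths differ")
    if J >= n - 2:
        raise ValueError(f"J={J} leaves no residual degrees of freedom at n={n}")
    X = pd.DataFrame({"intercept": np.ones(n), "x": x})
    if J > 0:
        X = augment_with_eigenvectors(X, sigma, J)
    if method == "ols":
        fit = fit_ols(y, X)
    elif method == "gls":
        fit = fit_gls(y, X, sigma, sigma_g2=1.0, sigma_e2=0.0)
    else:
        comps = reml_variance_components(y, X, sigma)
        fit = fit_gls(y, X, sigma, sigma_g2=comps.sigma_g2, sigma_e2=comps.sigma_e2)
        fit.method = "lmm"
        fit.reml_boundary = comps.boundary
    fit.n_eigenvectors = J
    return fit
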