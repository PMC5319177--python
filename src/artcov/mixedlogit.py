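"""Maximum-likelihood random-intercept logistic regression.

Fits the model

    logit P(y_ij = 1) = x_ij' beta + u_i,   u_i ~ Normal(0, sigma_u^2)

by adaptive Gauss–Hermite quadrature: for each cluster the integrand's mode
and Laplace curvature are located by Newton's method and the quadrature grid
is centered and scaled there, so a small number of nodes (default 9)
integrates accurately even for clusters contributing hundreds of Bernoulli
observations.  Identical covariate rows within a cluster are collapsed to
binomial cells first, which makes cluster-by-period designs essentially
free to fit.

Wald standard errors come from the observed information (numerically
differentiated analytic score).  sigma_u is optimized on its natural scale
with a small positive lower bound, so near-degenerate fits (sigma_u ~ 0)
reduce smoothly to ordinary logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_fprime

_SIGMA_FLOOR = 1e-6
_LOG_2PI = float(np.log(2.0 * np.pi))


class FitError(RuntimeError):
    """Raised when the model cannot be fit (constant outcome, separation,
    singular design)."""


@dataclass
class MixedLogitResult:
    """Fitted coefficients and inference for the random-intercept logit."""

    names: list
    params: np.ndarray  # fixed effects, in `names` order
    se: np.ndarray
    cov: np.ndarray
    sigma_u: float
    sigma_u_se: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    n_quad: int
    message: str = ""

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - z * self.se, self.params + z * self.se]
        )

    @property
    def random_intercept_variance(self) -> float:
        return float(self.sigma_u**2)

    def wald_p(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


@dataclass
class _AggData:
    X: np.ndarray  # (M, p) unique covariate rows
    succ: np.ndarray  # (M,) successes per cell
    trials: np.ndarray  # (M,) trials per cell
    gidx: np.ndarray  # (M,) cluster index 0..G-1
    n_groups: int
    n_obs: int
    u_cache: np.ndarray = field(default=None)


def _aggregate(y, X, groups) -> _AggData:
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or len(y) != len(X):
        raise FitError("y and X must be aligned 1-D / 2-D arrays")
    codes, gidx_all = np.unique(np.asarray(groups), return_inverse=True)
    key = np.column_stack([gidx_all.astype(float), X])
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    succ = np.bincount(inverse, weights=y)
    trials = np.bincount(inverse)
    return _AggData(
        X=uniq[:, 1:].copy(),
        succ=succ,
        trials=trials.astype(float),
        gidx=uniq[:, 0].astype(int),
        n_groups=len(codes),
        n_obs=len(y),
        u_cache=np.zeros(len(codes)),
    )


def _modes(data: _AggData, eta0: np.ndarray, s2: float):
    """Per-cluster posterior mode and Laplace curvature of the integrand."""
    u = data.u_cache.copy()
    G = data.n_groups
    g2 = None
    for _ in range(100):
        mu = expit(eta0 + u[data.gidx])
        g1 = (
            np.bincount(data.gidx, weights=data.succ - data.trials * mu, minlength=G)
            - u / s2
        )
        g2 = (
            np.bincount(
                data.gidx, weights=data.trials * mu * (1.0 - mu), minlength=G
            )
            + 1.0 / s2
        )
        step = np.clip(g1 / g2, -4.0, 4.0)
        u += step
        if np.max(np.abs(g1)) < 1e-9:
            break
    data.u_cache = u.copy()
    tau = 1.0 / np.sqrt(g2)
    return u, tau


def _loglik_grad(theta, data: _AggData, nodes, logw, want_grad=True):
    p = data.X.shape[1]
    beta = theta[:p]
    sigma = max(theta[p], _SIGMA_FLOOR)
    s2 = sigma * sigma
    G = data.n_groups
    eta0 = data.X @ beta

    u_hat, tau = _modes(data, eta0, s2)

    K = len(nodes)
    A = np.empty((K, G))
    etas = np.empty((K, len(data.succ)))
    u_nodes = np.empty((K, G))
    sqrt2tau = np.sqrt(2.0) * tau
    for k in range(K):
        uk = u_hat + sqrt2tau * nodes[k]
        u_nodes[k] = uk
        eta = eta0 + uk[data.gidx]
        etas[k] = eta
        ll_rows = data.succ * eta - data.trials * np.logaddexp(0.0, eta)
        A[k] = (
            logw[k]
            + np.bincount(data.gidx, weights=ll_rows, minlength=G)
            - uk * uk / (2.0 * s2)
        )
    Li = logsumexp(A, axis=0) + np.log(sqrt2tau) - 0.5 * (_LOG_2PI + np.log(s2))
    ll = float(np.sum(Li))
    if not want_grad:
        return ll, None

    # quadrature-weight posterior over nodes per cluster
    W = np.exp(A - logsumexp(A, axis=0, keepdims=True))  # (K, G)
    grad_beta = np.zeros(p)
    grad_sigma = -G / sigma
    for k in range(K):
        resid = data.succ - data.trials * expit(etas[k])
        grad_beta += data.X.T @ (W[k, data.gidx] * resid)
        grad_sigma += float(np.sum(W[k] * u_nodes[k] ** 2)) / sigma**3
    grad = np.append(grad_beta, grad_sigma)
    return ll, grad


def fit_mixed_logit(
    y,
    X,
    groups,
    names=None,
    n_quad: int = 9,
    start_sigma: float = 0.5,
    compute_se: bool = True,
    maxiter: int = 300,
) -> MixedLogitResult:
    """Fit the random-intercept logistic model by adaptive quadrature ML.

    Parameters
    ----------
    y : array of 0/1 outcomes.
    X : design matrix including the intercept column.
    groups : cluster labels (one random intercept per label).
    n_quad : number of Gauss–Hermite nodes (adaptive centering).
    compute_se : skip the observed-information step when only point
        estimates are needed (e.g. calibration loops).
    """
    data = _aggregate(y, X, groups)
    p = data.X.shape[1]
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise FitError("names length does not match design columns")
    total_succ = data.succ.sum()
    if total_succ == 0 or total_succ == data.trials.sum():
        raise FitError("outcome is constant; model not identifiable")
    rank = np.linalg.matrix_rank(data.X)
    if rank < p:
        raise FitError(f"design matrix is singular (rank {rank} < {p} columns)")

    # standardize non-constant columns for optimizer conditioning; centering
    # is only applied when a constant (intercept) column can absorb it.  The
    # linear map A (theta = A @ theta_std) transforms estimates/covariance back.
    w = data.trials / data.trials.sum()
    col_mean = w @ data.X
    col_sd = np.sqrt(w @ (data.X - col_mean) ** 2)
    const_cols = col_sd < 1e-12
    center = np.where(const_cols, 0.0, col_mean) if np.any(const_cols) else np.zeros(p)
    scale = np.where(const_cols, col_mean, col_sd)  # constant col scaled by its value
    X_std = (data.X - center) / scale
    A = np.zeros((p + 1, p + 1))
    for j in range(p):
        A[j, j] = 1.0 / scale[j]
    if np.any(const_cols):
        j0 = int(np.argmax(const_cols))
        A[j0, :p] = -center / (scale * scale[j0])
        A[j0, j0] = 1.0 / scale[j0]
    A[p, p] = 1.0
    data = _AggData(
        X=X_std,
        succ=data.succ,
        trials=data.trials,
        gidx=data.gidx,
        n_groups=data.n_groups,
        n_obs=data.n_obs,
        u_cache=data.u_cache,
    )

    # starting values: plain logistic fit (clusters ignored)
    try:
        glm = sm.GLM(
            np.column_stack([data.succ, data.trials - data.succ]),
            data.X,
            family=sm.families.Binomial(),
        )
        beta0 = glm.fit(maxiter=50).params
        if not np.all(np.isfinite(beta0)):
            raise ValueError
    except Exception:
        beta0 = np.zeros(p)
    theta0 = np.append(beta0, max(start_sigma, _SIGMA_FLOOR))

    nodes, weights = hermgauss(n_quad)
    logw = np.log(weights) + nodes**2

    def objective(theta):
        ll, grad = _loglik_grad(theta, data, nodes, logw)
        return -ll, -grad

    bounds = [(None, None)] * p + [(_SIGMA_FLOOR, None)]
    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6},
    )
    theta_std = res.x
    theta = A @ theta_std
    ll = -float(res.fun)
    converged = bool(res.success)
    message = str(res.message)

    se = np.full(p, np.nan)
    cov = np.full((p, p), np.nan)
    sigma_se = float("nan")
    if compute_se:
        def score(t):
            return _loglik_grad(t, data, nodes, logw)[1]

        H = approx_fprime(theta_std, score, centered=True)
        H = 0.5 * (H + H.T)
        info = -H
        try:
            full_cov = A @ np.linalg.inv(info) @ A.T
        except np.linalg.LinAlgError:
            full_cov = np.full((p + 1, p + 1), np.nan)
        diag = np.diag(full_cov)
        if np.all(np.isfinite(diag[:p])) and np.all(diag[:p] > 0):
            cov = full_cov[:p, :p]
            se = np.sqrt(diag[:p])
        else:
            converged = False
            message += "; observed information not positive definite"
        sigma_se = (
            float(np.sqrt(diag[p])) if np.isfinite(diag[p]) and diag[p] > 0 else float("nan")
        )

    return MixedLogitResult(
        names=list(names),
        params=theta[:p].copy(),
        se=se,
        cov=cov,
        sigma_u=float(max(theta[p], _SIGMA_FLOOR)),
        sigma_u_se=sigma_se,
        loglik=ll,
        converged=converged,
        n_obs=data.n_obs,
        n_groups=data.n_groups,
        n_quad=n_quad,
        message=message,
    )
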