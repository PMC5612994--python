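"""Random-intercept linear mixed model via profiled REML.

Specialized to the single-grouping-factor random-intercept design used by
the within/between-system contrast, which makes every fit a cheap 1-D
optimization: for V = sigma^2 (I + rho Z Z') the GLS estimates, the
profiled sigma^2 and the REML criterion are all closed forms in rho, so a
parametric bootstrap with thousands of refits stays fast.  Agreement with
a general-purpose mixed-model routine is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    sigma2: float  # residual variance
    tau2: float  # random-intercept variance
    rho: float  # tau2 / sigma2
    n_obs: int
    n_groups: int
    converged: bool


class _Sums:
    """Sufficient statistics for the profiled REML criterion."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X, self.groups = X, groups
        self.n, self.p = X.shape
        self.codes, counts = np.unique(groups, return_inverse=False), None
        codes, inv = np.unique(groups, return_inverse=True)
        self.inv = inv
        self.G = len(codes)
        self.m = np.bincount(inv).astype(float)  # group sizes
        self.XtX = X.T @ X
        # per-group column sums of X: (G, p)
        self.S = np.zeros((self.G, self.p))
        np.add.at(self.S, inv, X)
        self.set_y(y)

    def set_y(self, y: np.ndarray) -> None:
        self.y = y
        self.Xty = self.X.T @ y
        self.yty = float(y @ y)
        self.u = np.bincount(self.inv, weights=y)  # per-group sums of y

    def criterion_and_fit(self, rho: float):
        w = rho / (1.0 + rho * self.m)  # shrinkage weight per group
        XtWX = self.XtX - (self.S * w[:, None]).T @ self.S
        XtWy = self.Xty - self.S.T @ (w * self.u)
        yWy = self.yty - float(w @ self.u**2)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(yWy - float(beta @ XtWy), 1e-300)
        df = self.n - self.p
        crit = (
            df * np.log(rss)
            + float(np.log1p(rho * self.m).sum())
            + float(np.linalg.slogdet(XtWX)[1])
        )
        return crit, beta, XtWX, rss


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, max_rho: float = 1e6
) -> RandomInterceptFit:
    """REML fit of ``y = X beta + z_group + eps`` with a random intercept."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("random-intercept model needs at least 2 groups")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    sums = _Sums(X, y, groups)
    return _fit_from_sums(sums, max_rho)


def _fit_from_sums(sums: _Sums, max_rho: float = 1e6) -> RandomInterceptFit:
    def crit(log_rho: float) -> float:
        return sums.criterion_and_fit(np.exp(log_rho))[0]

    res = minimize_scalar(crit, bounds=(-12.0, np.log(max_rho)), method="bounded",
                          options={"xatol": 1e-6})
    rho = float(np.exp(res.x))
    c0, *_ = sums.criterion_and_fit(1e-12)
    if c0 <= res.fun:  # boundary: no between-group variance
        rho = 0.0
    _, beta, XtWX, rss = sums.criterion_and_fit(max(rho, 1e-12))
    df = sums.n - sums.p
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    return RandomInterceptFit(
        beta=beta,
        se=se,
        tvalues=beta / se,
        sigma2=float(sigma2),
        tau2=float(rho * sigma2),
        rho=rho,
        n_obs=sums.n,
        n_groups=sums.G,
        converged=bool(res.success),
    )


def parametric_bootstrap(
    fit: RandomInterceptFit,
    X: np.ndarray,
    groups: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Fixed-effect estimates from ``n_bootstrap`` simulate-and-refit draws.

    Simulates from the fitted model (new random intercepts and residuals)
    and refits; returns an (n_bootstrap, p) array of betas.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    sums = _Sums(X, X @ fit.beta, groups)  # y replaced per draw
    mu = X @ fit.beta
    tau, sig = np.sqrt(fit.tau2), np.sqrt(fit.sigma2)
    out = np.empty((n_bootstrap, X.shape[1]))
    for b in range(n_bootstrap):
        z = tau * rng.standard_normal(sums.G)
        yb = mu + z[sums.inv] + sig * rng.standard_normal(sums.n)
        sums.set_y(yb)
        out[b] = _fit_from_sums(sums).beta
    return out
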