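"""Maximum-likelihood GLMMs with a single random intercept.

Fits generalized linear mixed models of the form

    g(E[y_ij]) = x_ij' beta + u_i,   u_i ~ N(0, sigma_u^2)

for binomial (logit), Poisson (log) and Gamma (log link, estimated
shape) families.  The marginal likelihood integrates the random
intercept out per group with adaptive Gauss-Hermite quadrature: the
integrand's mode is located by a few Newton steps (the log-integrand
is concave for all three families), the quadrature grid is centred and
scaled there, and group contributions are combined on the log scale.
This is the same strategy ML mixed-model fitters use for a scalar
random effect, and it makes likelihood-ratio tests between nested
models well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special

__all__ = ["GLMMFit", "LMMFit", "fit_glmm", "fit_lmm", "likelihood_ratio_test"]

_LOG_2PI = float(np.log(2.0 * np.pi))


class _Binomial:
    n_extra = 0

    @staticmethod
    def loglik(y, eta, extra):
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def d1(y, eta, extra):
        return y - special.expit(eta)

    @staticmethod
    def d2(y, eta, extra):
        p = special.expit(eta)
        return -p * (1.0 - p)


class _Poisson:
    n_extra = 0

    @staticmethod
    def loglik(y, eta, extra):
        return y * eta - np.exp(eta) - special.gammaln(y + 1.0)

    @staticmethod
    def d1(y, eta, extra):
        return y - np.exp(eta)

    @staticmethod
    def d2(y, eta, extra):
        return -np.exp(eta)


class _Gamma:
    """Gamma with log link; extra parameter is log(shape)."""

    n_extra = 1

    @staticmethod
    def loglik(y, eta, extra):
        a = np.exp(extra[0])
        return (
            a * np.log(a)
            - special.gammaln(a)
            + (a - 1.0) * np.log(y)
            - a * eta
            - a * y * np.exp(-eta)
        )

    @staticmethod
    def d1(y, eta, extra):
        a = np.exp(extra[0])
        return a * (y * np.exp(-eta) - 1.0)

    @staticmethod
    def d2(y, eta, extra):
        a = np.exp(extra[0])
        return -a * y * np.exp(-eta)


_FAMILIES = {"binomial": _Binomial, "poisson": _Poisson, "gamma": _Gamma}


@dataclass
class GLMMFit:
    family: str
    beta: np.ndarray
    beta_names: tuple[str, ...]
    sigma_u: float
    shape: float | None
    loglik: float
    converged: bool
    singular: bool
    cov_beta: np.ndarray | None
    n_obs: int
    n_groups: int

    def wald_block_test(self, cols: list[int]) -> tuple[float, int, float]:
        """Wald chi-square test that the given coefficient block is zero."""
        if self.cov_beta is None:
            raise ValueError("fit was computed without a coefficient covariance")
        b = self.beta[cols]
        v = self.cov_beta[np.ix_(cols, cols)]
        chi2 = float(b @ np.linalg.solve(v, b))
        df = len(cols)
        from scipy.stats import chi2 as chi2_dist

        return chi2, df, float(chi2_dist.sf(chi2, df))


class _MarginalLoglik:
    """Callable negative marginal log-likelihood on the packed parameter
    vector [beta, log_sigma_u, (extra...)]."""

    def __init__(self, y, x, groups, family: str, n_quad: int = 15):
        order = np.argsort(groups, kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.x = np.asarray(x, dtype=float)[order]
        g = np.asarray(groups)[order]
        _, self.gidx = np.unique(g, return_inverse=True)
        self.n_groups = int(self.gidx.max()) + 1
        # reduceat boundaries (groups are contiguous after the sort)
        self.starts = np.searchsorted(self.gidx, np.arange(self.n_groups))
        self.fam = _FAMILIES[family]
        self.k = self.x.shape[1]
        z, w = hermgauss(n_quad)
        self.z, self.logw = z, np.log(w)

    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts, axis=0)

    def _mode(self, xb, sigma2, extra):
        """Newton search for the per-group mode of the log integrand."""
        u = np.zeros(self.n_groups)
        curv = None
        for _ in range(50):
            eta = xb + u[self.gidx]
            g1 = self._group_sum(self.fam.d1(self.y, eta, extra)) - u / sigma2
            g2 = self._group_sum(self.fam.d2(self.y, eta, extra)) - 1.0 / sigma2
            step = g1 / g2
            np.clip(step, -3.0, 3.0, out=step)
            u = u - step
            curv = g2
            if np.max(np.abs(g1)) < 1e-9:
                break
        return u, curv

    def loglik(self, params: np.ndarray) -> float:
        beta = params[: self.k]
        sigma = float(np.exp(params[self.k]))
        extra = params[self.k + 1 :]
        sigma2 = sigma * sigma
        xb = self.x @ beta
        u_hat, curv = self._mode(xb, sigma2, extra)
        tau = 1.0 / np.sqrt(-curv)  # curvature of h at the mode
        # u values per (group, node)
        u_nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]
        eta = xb[:, None] + u_nodes[self.gidx]
        ll_obs = self._group_sum(self.fam.loglik(self.y[:, None], eta, extra))
        h = ll_obs - u_nodes**2 / (2.0 * sigma2) - 0.5 * (_LOG_2PI + np.log(sigma2))
        log_terms = self.logw[None, :] + self.z[None, :] ** 2 + h
        group_ll = np.log(np.sqrt(2.0) * tau) + special.logsumexp(log_terms, axis=1)
        return float(group_ll.sum())

    def __call__(self, params: np.ndarray) -> float:
        return -self.loglik(params)


def _numeric_hessian(fn, x, h=1e-4):
    p = len(x)
    hess = np.empty((p, p))
    f0 = fn(x)
    fp = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h
        fp[i] = fn(x + e)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h
        for j in range(i, p):
            ej = np.zeros(p)
            ej[j] = h
            fij = fn(x + ei + ej)
            hess[i, j] = hess[j, i] = (fij - fp[i] - fp[j] + f0) / (h * h)
    return hess


def _glm_start(y, x, family: str):
    import statsmodels.api as sm

    fams = {
        "binomial": sm.families.Binomial(),
        "poisson": sm.families.Poisson(),
        "gamma": sm.families.Gamma(link=sm.families.links.Log()),
    }
    try:
        res = sm.GLM(y, x, family=fams[family]).fit()
        beta0 = np.asarray(res.params, dtype=float)
        extra0 = []
        if family == "gamma":
            extra0 = [float(np.log(max(1.0 / max(res.scale, 1e-8), 1e-3)))]
        return beta0, extra0
    except Exception:
        beta0 = np.zeros(x.shape[1])
        return beta0, ([0.0] if family == "gamma" else [])


def fit_glmm(
    y,
    x,
    groups,
    family: str,
    beta_names: tuple[str, ...] | None = None,
    n_quad: int = 15,
    compute_cov: bool = True,
    maxiter: int = 300,
) -> GLMMFit:
    """Fit a random-intercept GLMM by maximum likelihood.

    ``x`` must include the intercept column.  ``family`` is one of
    binomial / poisson / gamma.  A near-zero random-intercept variance
    is reported through ``singular`` rather than raised.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if family == "gamma" and (y <= 0).any():
        raise ValueError("gamma family requires strictly positive responses")
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial family requires 0/1 responses")
    if family == "poisson" and ((y < 0).any() or (y != np.round(y)).any()):
        raise ValueError("poisson family requires non-negative counts")

    nll = _MarginalLoglik(y, x, groups, family, n_quad=n_quad)
    beta0, extra0 = _glm_start(y, x, family)
    x0 = np.concatenate([beta0, [np.log(0.5)], extra0])
    k = x.shape[1]
    bounds = [(None, None)] * k + [(np.log(1e-4), np.log(1e3))]
    bounds += [(np.log(1e-3), np.log(1e4))] * nll.fam.n_extra

    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 20000},
    )
    beta = res.x[:k]
    sigma_u = float(np.exp(res.x[k]))
    shape = float(np.exp(res.x[k + 1])) if family == "gamma" else None

    cov_beta = None
    if compute_cov:
        hess = _numeric_hessian(nll, res.x)
        try:
            cov_full = np.linalg.inv(hess)
            cov_beta = cov_full[:k, :k]
        except np.linalg.LinAlgError:
            cov_beta = None

    names = beta_names or tuple(f"x{i}" for i in range(k))
    return GLMMFit(
        family=family,
        beta=beta,
        beta_names=names,
        sigma_u=sigma_u,
        shape=shape,
        loglik=-float(res.fun),
        converged=bool(res.success),
        singular=sigma_u < 1e-3,
        cov_beta=cov_beta,
        n_obs=len(y),
        n_groups=nll.n_groups,
    )


@dataclass
class LMMFit:
    """Gaussian random-intercept linear mixed model fit."""

    beta: np.ndarray
    beta_names: tuple[str, ...]
    sigma_e: float  # residual SD
    sigma_u: float  # random-intercept SD
    loglik: float   # ML log-likelihood (REML criterion if reml=True)
    reml: bool
    converged: bool
    singular: bool
    cov_beta: np.ndarray
    n_obs: int
    n_groups: int


def _lmm_profile(y, x, starts, counts, log_s2, log_t2, reml):
    """Profiled (over beta) Gaussian marginal log-likelihood."""
    s2, t2 = np.exp(log_s2), np.exp(log_t2)
    # V_g^{-1} = (I - w_g J / n_g) / s2 with w_g = n_g t2 / (s2 + n_g t2);
    # w -> 1 wipes out cluster-constant covariates, so keep it just below
    w = np.minimum(counts * t2 / (s2 + counts * t2), 1.0 - 1e-12)
    xg_sum = np.add.reduceat(x, starts, axis=0)
    yg_sum = np.add.reduceat(y, starts)
    xtvx = (x.T @ x - (xg_sum * (w / counts)[:, None]).T @ xg_sum) / s2
    xtvy = (x.T @ y - xg_sum.T @ (w / counts * yg_sum)) / s2
    beta, *_ = np.linalg.lstsq(xtvx, xtvy, rcond=None)
    r = y - x @ beta
    rg_sum = np.add.reduceat(r, starts)
    quad = (r @ r - np.sum(w / counts * rg_sum**2)) / s2
    logdet_v = np.sum((counts - 1) * np.log(s2) + np.log(s2 + counts * t2))
    n, k = len(y), x.shape[1]
    ll = -0.5 * (logdet_v + quad + n * _LOG_2PI)
    if reml:
        sign, logdet_x = np.linalg.slogdet(xtvx)
        ll += -0.5 * logdet_x + 0.5 * k * _LOG_2PI
    return ll, beta, xtvx


def fit_lmm(
    y, x, groups, beta_names: tuple[str, ...] | None = None, reml: bool = False
) -> LMMFit:
    """ML (or REML) fit of ``y = X beta + u_group + e`` by direct
    maximization of the closed-form marginal likelihood.

    The random-intercept variance may sit on the zero boundary without
    numerical trouble, in which case the fit degrades gracefully to OLS
    and is flagged ``singular``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    order = np.argsort(np.asarray(groups), kind="stable")
    ys, xs = y[order], x[order]
    g = np.asarray(groups)[order]
    _, gidx, counts = np.unique(g, return_inverse=True, return_counts=True)
    starts = np.searchsorted(gidx, np.arange(len(counts)))
    var0 = max(float(np.var(ys)), 1e-12)

    def neg(params):
        ll = _lmm_profile(ys, xs, starts, counts.astype(float),
                          params[0], params[1], reml)[0]
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.log([var0 * 0.7, var0 * 0.3])
    res = optimize.minimize(
        neg, x0, method="L-BFGS-B",
        bounds=[
            (np.log(var0) - 12.0, np.log(var0) + 5.0),   # residual variance
            (np.log(var0) - 25.0, np.log(var0) + 5.0),   # intercept variance
        ],
    )
    ll, beta, xtvx = _lmm_profile(ys, xs, starts, counts.astype(float),
                                  res.x[0], res.x[1], reml)
    s2, t2 = np.exp(res.x)
    names = beta_names or tuple(f"x{i}" for i in range(x.shape[1]))
    return LMMFit(
        beta=beta,
        beta_names=names,
        sigma_e=float(np.sqrt(s2)),
        sigma_u=float(np.sqrt(t2)),
        loglik=float(ll),
        reml=reml,
        converged=bool(res.success),
        singular=bool(t2 < 1e-6 * s2),
        cov_beta=np.linalg.inv(xtvx),
        n_obs=len(y),
        n_groups=len(counts),
    )


def likelihood_ratio_test(full_ll: float, null_ll: float, df: int) -> tuple[float, int, float]:
    """Chi-square LRT of nested models from their maximized log-likelihoods."""
    from scipy.stats import chi2 as chi2_dist

    stat = max(0.0, 2.0 * (full_ll - null_ll))
    return stat, df, float(chi2_dist.sf(stat, df))
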