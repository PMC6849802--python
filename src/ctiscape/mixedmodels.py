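"""Mixed models with crossed variance components.

Two estimators back every modelling stage of the pipeline:

* :func:`fit_gaussian_mixed` — linear mixed model, maximum likelihood with
  the residual variance profiled out, so the outer optimisation runs over
  the log *relative* standard deviation of each random term only.
* :func:`fit_poisson_mixed` — Poisson log-link GLMM via the Laplace
  approximation: for each candidate set of variance parameters the joint
  mode of (fixed effects, random effects) is found by Newton's method and
  the integrated likelihood is approximated at that mode.

Random-effects structure is restricted to independent variance components
(crossed random intercepts, plus random slopes uncorrelated with their
intercepts), which is exactly the structure the monitoring-data models
need: Site, Year and 50-km-grid intercepts and a Year slope within Site.
All linear algebra is on the q x q scale (q = total number of random
levels) via sparse indicator matrices, which keeps replicate simulation
studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln
from scipy.stats import norm

__all__ = ["RandomTerm", "FitResult", "fit_gaussian_mixed", "fit_poisson_mixed"]

_LOG_SD_MIN = -7.0
_LOG_SD_MAX = 4.0
_SINGULAR_SD = 1e-3


@dataclass
class RandomTerm:
    """One independent variance component.

    ``codes`` gives the 0-based level index of each observation; ``values``
    optionally multiplies the indicator (a random slope uses the centred
    covariate here, a random intercept leaves it ``None``).
    """

    name: str
    codes: np.ndarray
    n_levels: int
    values: np.ndarray | None = None

    @classmethod
    def from_labels(cls, name: str, labels, values=None) -> "RandomTerm":
        codes, uniques = pd.factorize(np.asarray(labels), sort=True)
        if (codes < 0).any():
            raise ValueError(f"random term {name!r} has missing levels")
        vals = None if values is None else np.asarray(values, dtype=float)
        return cls(name=name, codes=codes, n_levels=len(uniques), values=vals)

    def matrix(self) -> sparse.csr_matrix:
        n = len(self.codes)
        data = np.ones(n) if self.values is None else self.values
        return sparse.csr_matrix(
            (data, (np.arange(n), self.codes)), shape=(n, self.n_levels)
        )


@dataclass
class FitResult:
    """Coefficients, variance components and fit statistics of one model.

    The common currency of every modelling stage: trend models, interaction
    models and the spatial CTI model all return one of these.
    """

    params: pd.Series
    bse: pd.Series
    loglik: float
    vc: dict[str, float]
    family: str
    n_obs: int
    k_params: int
    converged: bool
    singular: bool = False
    scale: float = 1.0
    method: str = ""
    message: str = ""
    ranef: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * norm.sf(np.abs(self.zvalues.to_numpy())), index=self.params.index
        )

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        zcrit = norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "lower": self.params - zcrit * self.bse,
                "upper": self.params + zcrit * self.bse,
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _stack_terms(terms: list[RandomTerm]):
    mats = [t.matrix() for t in terms]
    Z = sparse.hstack(mats, format="csr") if mats else None
    col_term = np.concatenate(
        [np.full(t.n_levels, k) for k, t in enumerate(terms)]
    ) if terms else np.empty(0, dtype=int)
    return Z, col_term


def _ols(y, X, names) -> FitResult:
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    cov = sigma2 * np.linalg.inv(XtX)
    return FitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        loglik=ll,
        vc={},
        family="gaussian",
        n_obs=n,
        k_params=p + 1,
        converged=True,
        scale=sigma2,
        method="ols",
    )


def fit_gaussian_mixed(
    y,
    X,
    terms: list[RandomTerm] | None = None,
    theta0: np.ndarray | None = None,
    reml: bool = False,
) -> FitResult:
    """Fit ``y = X b + Z u + e`` with independent variance components.

    The residual variance is profiled out analytically; the optimiser works
    on the log relative standard deviation of each random term (optionally
    warm-started from ``theta0``). With no random terms this reduces
    exactly to OLS (ML scale). ``reml=True`` maximises the restricted
    likelihood instead — the right choice for interval estimation, but
    invalid for likelihood-ratio tests of fixed effects or AIC comparison
    across fixed structures.
    """
    y = np.asarray(y, dtype=float)
    X, names = _as_design(X)
    n, p = X.shape
    terms = list(terms or [])
    if not terms:
        return _ols(y, X, names)

    Z, col_term = _stack_terms(terms)
    q = Z.shape[1]
    A = (Z.T @ Z).toarray()
    B = Z.T @ X
    c = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    n_terms = len(terms)

    def components(theta):
        lam = np.exp(np.clip(theta, _LOG_SD_MIN, _LOG_SD_MAX))[col_term]
        K = lam[:, None] * A * lam[None, :]
        K[np.diag_indices_from(K)] += 1.0
        L = cho_factor(K, lower=True)
        Bl = lam[:, None] * B
        cl = lam * c
        sB = cho_solve(L, Bl)
        sc = cho_solve(L, cl)
        XtViX = XtX - Bl.T @ sB
        XtViy = Xty - Bl.T @ sc
        ytViy = yty - cl @ sc
        beta = np.linalg.solve(XtViX, XtViy)
        rss = max(ytViy - beta @ XtViy, 1e-300)
        logdetK = 2.0 * np.sum(np.log(np.diag(L[0])))
        if reml:
            dof = n - p
            sigma2 = rss / dof
            sign, logdet_xvx = np.linalg.slogdet(XtViX)
            ll = -0.5 * (
                dof * np.log(2.0 * np.pi * sigma2) + logdetK + logdet_xvx + dof
            )
        else:
            sigma2 = rss / n
            ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdetK + n)
        return ll, beta, sigma2, XtViX, L, lam, cl

    def nll(theta):
        return -components(theta)[0]

    x0 = np.full(n_terms, np.log(0.5)) if theta0 is None else np.asarray(theta0, float)
    res = optimize.minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 2e-4, "fatol": 1e-8, "maxfev": 1200},
    )
    theta = np.clip(res.x, _LOG_SD_MIN, _LOG_SD_MAX)
    ll, beta, sigma2, XtViX, L, lam, cl = components(theta)
    cov = sigma2 * np.linalg.inv(XtViX)
    rel_sd = np.exp(theta)
    vc = {t.name: sigma2 * rel_sd[k] ** 2 for k, t in enumerate(terms)}
    # BLUPs: u_hat = sigma2*rel^2 * Z' Vinv resid / sigma2 = lam*(K^-1)(lam Z'resid)...
    resid_p = c - B @ beta
    u_scaled = lam * cho_solve(L, lam * (resid_p))
    ranef = {}
    for k, t in enumerate(terms):
        ranef[t.name] = u_scaled[col_term == k]
    return FitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        loglik=float(ll),
        vc=vc,
        family="gaussian",
        n_obs=n,
        k_params=p + n_terms + 1,
        converged=bool(res.success or res.fun <= nll(x0)),
        singular=bool((rel_sd < _SINGULAR_SD).any()),
        scale=float(sigma2),
        method="reml-profiled" if reml else "ml-profiled",
        message=str(res.message),
    )


def fit_poisson_mixed(
    y,
    X,
    terms: list[RandomTerm] | None = None,
    offset=None,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Laplace-approximate ML fit of a Poisson log-link mixed model.

    For each candidate vector of log random-effect standard deviations the
    joint penalised likelihood is maximised over (fixed effects, random
    effects) by Newton's method with step halving; the marginal likelihood
    is then approximated by the Laplace correction at that mode. ``theta0``
    warm-starts the variance parameters (useful when refitting the same
    response over a grid of covariates).
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("Poisson response must be non-negative")
    X, names = _as_design(X)
    n, p = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    terms = list(terms or [])
    Z, col_term = _stack_terms(terms)
    q = 0 if Z is None else Z.shape[1]
    n_terms = len(terms)
    const = -float(np.sum(gammaln(y + 1.0)))

    state = {"beta": None, "u": np.zeros(q)}

    def inner_mode(g):
        """Maximise the joint penalised loglik for fixed variances g (per col)."""
        beta = state["beta"]
        if beta is None:
            mean_rate = max(y.mean(), 1e-3)
            beta = np.zeros(p)
            if "Intercept" in names:
                beta[names.index("Intercept")] = np.log(mean_rate)
        u = state["u"].copy()
        ginv = 1.0 / g if q else np.empty(0)

        def pen_ll(beta, u, eta):
            return float(y @ eta - np.exp(eta).sum()) - 0.5 * float((u * u) @ ginv)

        eta = np.clip(X @ beta + (Z @ u if q else 0.0) + off, -30.0, 30.0)
        f = pen_ll(beta, u, eta)
        ok = False
        for _ in range(100):
            mu = np.exp(eta)
            r = y - mu
            gb = X.T @ r
            if q:
                gu = Z.T @ r - u * ginv
                grad = np.concatenate([gb, gu])
            else:
                grad = gb
            if np.max(np.abs(grad)) < 1e-6 * max(1.0, np.sqrt(mu.sum())):
                ok = True
                break
            Xw = X * mu[:, None]
            H_bb = X.T @ Xw
            if q:
                Zw = Z.multiply(mu[:, None]).tocsr()
                H_bu = (Zw.T @ X).T
                H_uu = (Z.T @ Zw).toarray()
                H_uu[np.diag_indices_from(H_uu)] += ginv
                H = np.block([[H_bb, H_bu], [H_bu.T, H_uu]])
            else:
                H = H_bb
            try:
                Lh = cho_factor(H, lower=True)
                step = cho_solve(Lh, grad)
            except np.linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-6 * np.abs(np.diag(H)).max()
                Lh = cho_factor(H, lower=True)
                step = cho_solve(Lh, grad)
            t = 1.0
            for _ in range(30):
                beta_new = beta + t * step[:p]
                u_new = u + t * step[p:] if q else u
                eta_new = np.clip(
                    X @ beta_new + (Z @ u_new if q else 0.0) + off, -30.0, 30.0
                )
                f_new = pen_ll(beta_new, u_new, eta_new)
                if f_new >= f - 1e-10:
                    break
                t *= 0.5
            moved = float(np.max(np.abs(t * step)))
            beta, u, eta, f = beta_new, u_new, eta_new, f_new
            if moved < 1e-9:
                ok = True
                break
        state["beta"], state["u"] = beta, u
        mu = np.exp(eta)
        return beta, u, eta, mu, f, ok

    def laplace_ll(theta):
        theta = np.clip(theta, _LOG_SD_MIN, _LOG_SD_MAX)
        g = np.exp(2.0 * theta)[col_term] if q else np.empty(0)
        beta, u, eta, mu, f, ok = inner_mode(g)
        if not q:
            return f + const, beta, ok
        Zw = Z.multiply(mu[:, None]).tocsr()
        Huu = (Z.T @ Zw).toarray()
        Huu[np.diag_indices_from(Huu)] += 1.0 / g
        sign, logdet_H = np.linalg.slogdet(Huu)
        logdet_GH = float(np.sum(np.log(g))) + logdet_H
        return f + const - 0.5 * logdet_GH, beta, ok

    if not q:
        ll, beta, ok = laplace_ll(np.empty(0))
        mu = np.exp(np.clip(X @ beta + off, -30, 30))
        cov = np.linalg.inv(X.T @ (X * mu[:, None]))
        return FitResult(
            params=pd.Series(beta, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
            loglik=float(ll),
            vc={},
            family="poisson",
            n_obs=n,
            k_params=p,
            converged=ok,
            method="laplace",
        )

    def nll(theta):
        return -laplace_ll(theta)[0]

    x0 = np.full(n_terms, np.log(0.3)) if theta0 is None else np.asarray(theta0, float)
    res = optimize.minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 2e-4, "fatol": 5e-6, "maxfev": 200 * max(n_terms, 2)},
    )
    theta = np.clip(res.x, _LOG_SD_MIN, _LOG_SD_MAX)
    ll, beta, inner_ok = laplace_ll(theta)
    u = state["u"]
    eta = np.clip(X @ beta + Z @ u + off, -30.0, 30.0)
    mu = np.exp(eta)
    g = np.exp(2.0 * theta)[col_term]
    Zw = Z.multiply(mu[:, None]).tocsr()
    Huu = (Z.T @ Zw).toarray()
    Huu[np.diag_indices_from(Huu)] += 1.0 / g
    Lh = cho_factor(Huu, lower=True)
    XwZ = (Zw.T @ X).T  # p x q as X' W Z
    Hbb = X.T @ (X * mu[:, None])
    cov = np.linalg.inv(Hbb - XwZ @ cho_solve(Lh, XwZ.T))
    sd = np.exp(theta)
    vc = {t.name: float(sd[k] ** 2) for k, t in enumerate(terms)}
    ranef = {t.name: u[col_term == k] for k, t in enumerate(terms)}
    return FitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        loglik=float(ll),
        vc=vc,
        family="poisson",
        n_obs=n,
        k_params=p + n_terms,
        converged=bool(inner_ok and (res.success or res.nit > 0)),
        singular=bool((sd < _SINGULAR_SD).any()),
        method="laplace",
        message=str(res.message),
        ranef=ranef,
    )
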