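"""Logistic mixed model with crossed scalar random intercepts (Laplace ML).

Model: for observation i with fixed design row x_i and group codes
g_f(i) for each grouping factor f,

    logit P(y_i = 1) = x_i' beta + sum_f u_f[g_f(i)],   u_f ~ N(0, sigma_f^2 I)

Estimation maximizes the Laplace approximation to the marginal likelihood:
an inner penalized Newton solve for (beta, u) at fixed variance components,
and an outer optimization over log sigma_f.  Wald standard errors for beta
come from the beta block of the inverse joint Hessian (a Schur complement),
so uncertainty in the random intercepts propagates into the fixed-effect
CIs.  This mirrors the Laplace (nAGQ = 1) fit of lme4::glmer, which serves
as an independent cross-check in the test suite.

Statsmodels provides only Bayesian variational GLMMs, hence this dedicated
frequentist implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

_SIGMA_FLOOR = 1e-4


class SeparationError(RuntimeError):
    """Raised when the response carries no information (or is separable)."""


@dataclass
class GlmmFit:
    params: pd.Series               # fixed effects
    bse: pd.Series
    conf_int: pd.DataFrame          # columns lo, hi (95%)
    odds: pd.DataFrame              # exp(beta) with CI
    random_effects: dict            # factor -> pd.Series of BLUP modes
    variances: dict                 # factor -> sigma^2
    loglik: float
    aic: float
    nobs: int
    converged: bool
    message: str
    pseudo_r2: float                # adjusted McFadden

    def summary(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame({
            "coef": self.params, "se": self.bse,
            "z": z, "p": 2.0 * norm.sf(np.abs(z)),
            "ci_lo": self.conf_int["lo"], "ci_hi": self.conf_int["hi"],
            "odds": self.odds["odds"],
            "odds_lo": self.odds["lo"], "odds_hi": self.odds["hi"],
        })


def _prepare_groups(groups: dict) -> tuple[list, list, list]:
    names, codes, levels = [], [], []
    for name, raw in groups.items():
        lv, cd = np.unique(np.asarray(raw), return_inverse=True)
        names.append(name)
        codes.append(cd.astype(int))
        levels.append(lv)
    return names, codes, levels


class _LaplaceCore:
    def __init__(self, y, X, codes, q_per):
        self.y = y
        self.X = X
        self.codes = codes
        self.q_per = q_per
        self.p = X.shape[1]
        self.q = int(sum(q_per))
        self.offsets = np.concatenate([[0], np.cumsum(q_per)])[:-1]

    def eta(self, beta, u):
        e = self.X @ beta
        for f, cd in enumerate(self.codes):
            e = e + u[self.offsets[f] + cd]
        return e

    def joint_hessian(self, w, sigmas):
        """Full (p+q) Hessian of the negative penalized log-likelihood."""
        X, p, q = self.X, self.p, self.q
        H = np.zeros((p + q, p + q))
        H[:p, :p] = X.T @ (w[:, None] * X)
        for f, cd in enumerate(self.codes):
            off = self.offsets[f]
            nf = self.q_per[f]
            for j in range(p):
                H[p + off:p + off + nf, j] = np.bincount(cd, w * X[:, j], minlength=nf)
            H[:p, p + off:p + off + nf] = H[p + off:p + off + nf, :p].T
            H[p + off:p + off + nf, p + off:p + off + nf] = (
                np.diag(np.bincount(cd, w, minlength=nf) + 1.0 / sigmas[f] ** 2)
            )
            for g in range(f + 1, len(self.codes)):
                og = self.offsets[g]
                ng = self.q_per[g]
                cross = np.bincount(cd * ng + self.codes[g], w,
                                    minlength=self.q_per[f] * ng).reshape(nf, ng)
                H[p + off:p + off + nf, p + og:p + og + ng] = cross
                H[p + og:p + og + ng, p + off:p + off + nf] = cross.T
        return H

    def penalized_nll(self, beta, u, sigmas):
        e = self.eta(beta, u)
        ll = np.sum(self.y * e - np.logaddexp(0.0, e))
        pen = 0.0
        for f in range(len(self.codes)):
            uf = u[self.offsets[f]:self.offsets[f] + self.q_per[f]]
            pen += 0.5 * np.sum(uf ** 2) / sigmas[f] ** 2
        return -(ll - pen)

    def newton(self, sigmas, beta0, u0, tol=1e-10, maxiter=60):
        beta, u = beta0.copy(), u0.copy()
        f_old = self.penalized_nll(beta, u, sigmas)
        for _ in range(maxiter):
            e = self.eta(beta, u)
            mu = expit(e)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            g = np.empty(self.p + self.q)
            r = self.y - mu
            g[:self.p] = self.X.T @ r
            for f, cd in enumerate(self.codes):
                off, nf = self.offsets[f], self.q_per[f]
                g[self.p + off:self.p + off + nf] = (
                    np.bincount(cd, r, minlength=nf)
                    - u[off:off + nf] / sigmas[f] ** 2
                )
            H = self.joint_hessian(w, sigmas)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                nb = beta + t * step[:self.p]
                nu = u + t * step[self.p:]
                f_new = self.penalized_nll(nb, nu, sigmas)
                if f_new <= f_old + 1e-12:
                    break
                t *= 0.5
            beta, u, improved = nb, nu, f_old - f_new
            f_old = f_new
            if improved < tol * (abs(f_old) + 1.0):
                break
        return beta, u, -f_old

    def laplace_loglik(self, sigmas, beta, u, pen_ll):
        e = self.eta(beta, u)
        mu = expit(e)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = self.joint_hessian(w, sigmas)
        Huu = H[self.p:, self.p:]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return -np.inf
        logdet_sigma = 0.0
        for f in range(len(self.codes)):
            logdet_sigma += 2.0 * self.q_per[f] * np.log(sigmas[f])
        return pen_ll - 0.5 * logdet_sigma - 0.5 * logdet


def fit_logistic_glmm(
    y,
    X: pd.DataFrame | np.ndarray,
    groups: dict,
    maxiter: int = 200,
) -> GlmmFit:
    """Fit a random-intercept logistic model by Laplace maximum likelihood.

    Parameters
    ----------
    y : binary response (0/1).
    X : fixed-effects design, intercept column included by the caller.
    groups : mapping factor name -> per-observation labels; each factor
        contributes one scalar random intercept per level.
    """
    if isinstance(X, pd.DataFrame):
        xnames = list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, dtype=float)
        xnames = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    if set(np.unique(ya)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if ya.min() == ya.max():
        raise SeparationError("response has no variation; no estimates possible")
    names, codes, levels = _prepare_groups(groups)
    q_per = [len(lv) for lv in levels]
    core = _LaplaceCore(ya, Xa, codes, q_per)

    state = {"beta": np.zeros(core.p), "u": np.zeros(core.q)}

    def neg_laplace(theta):
        sigmas = np.exp(np.clip(theta, np.log(_SIGMA_FLOOR), 4.0))
        beta, u, pen_ll = core.newton(sigmas, state["beta"], state["u"])
        state["beta"], state["u"] = beta, u
        return -core.laplace_loglik(sigmas, beta, u, pen_ll)

    theta0 = np.full(len(codes), np.log(0.5))
    res = minimize(neg_laplace, theta0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": maxiter * len(codes)})
    sigmas = np.exp(np.clip(res.x, np.log(_SIGMA_FLOOR), 4.0))
    beta, u, pen_ll = core.newton(sigmas, state["beta"], state["u"])
    ll = core.laplace_loglik(sigmas, beta, u, pen_ll)

    # Wald covariance for beta: Schur complement of the joint Hessian
    e = core.eta(beta, u)
    mu = expit(e)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = core.joint_hessian(w, sigmas)
    try:
        cov = np.linalg.inv(H)[:core.p, :core.p]
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)[:core.p, :core.p]
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    message = res.message if isinstance(res.message, str) else str(res.message)
    converged = bool(res.success) and np.all(np.isfinite(se))
    if np.any(np.abs(beta) > 30.0) or np.any(se > 1e3):
        converged = False
        message = "possible separation: extreme coefficients or standard errors"

    z = norm.ppf(0.975)
    params = pd.Series(beta, index=xnames)
    bse = pd.Series(se, index=xnames)
    ci = pd.DataFrame({"lo": beta - z * se, "hi": beta + z * se}, index=xnames)
    odds = pd.DataFrame({
        "odds": np.exp(beta), "lo": np.exp(ci["lo"]), "hi": np.exp(ci["hi"]),
    }, index=xnames)
    rand = {
        name: pd.Series(u[core.offsets[f]:core.offsets[f] + q_per[f]],
                        index=list(levels[f]))
        for f, name in enumerate(names)
    }
    variances = {name: float(sigmas[f] ** 2) for f, name in enumerate(names)}
    k = core.p + len(codes)
    # null model: intercept-only logistic
    p0 = ya.mean()
    ll0 = float(np.sum(ya * np.log(p0) + (1 - ya) * np.log(1 - p0)))
    pseudo_r2 = 1.0 - (ll - k) / ll0
    return GlmmFit(params=params, bse=bse, conf_int=ci, odds=odds,
                   random_effects=rand, variances=variances,
                   loglik=float(ll), aic=float(2.0 * k - 2.0 * ll),
                   nobs=int(ya.size), converged=converged, message=message,
                   pseudo_r2=float(pseudo_r2))


def lr_test(loglik_full: float, loglik_reduced: float, delta_df: int) -> dict:
    """Likelihood-ratio record for a nested model pair."""
    from scipy.stats import chi2

    stat = 2.0 * (loglik_full - loglik_reduced)
    p = float(chi2.sf(max(stat, 0.0), delta_df)) if delta_df > 0 else float("nan")
    return {"lr_stat": float(stat), "delta_df": int(delta_df), "p": p}
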