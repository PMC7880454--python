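"""Weighted logistic mixed models via the Laplace approximation.

Fits Bernoulli GLMMs with independent Gaussian random effects (crossed
random intercepts and slopes) by maximum likelihood, the same scheme the
standard mixed-model machinery uses: for candidate standard deviations
sigma the joint penalized log-likelihood is maximized over fixed effects
and spherical random effects v (penalized IRLS / Newton), and the Laplace
log-likelihood

    l(sigma) = l_joint(beta_hat, v_hat) - 0.5 * log det(I + (Z L)' W (Z L))

with L = diag(sigma) is profiled over sigma by bounded quasi-Newton.
Observation weights multiply only the Bernoulli log-likelihood terms, the
device use-availability designs rely on to de-bias slope estimates (used
points weighted 1, available points weighted ~1000).

Random-effect dimensions in these designs are small (tens of levels), so
all linear algebra is dense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

SINGULAR_TOL = 1e-4  # random-effect SD below this (response scale 1) is singular


@dataclass
class RandomTerm:
    """One independent Gaussian random term: intercept or slope by group."""

    name: str
    groups: np.ndarray            # length-n group codes
    values: np.ndarray | None = None  # slope covariate; None = intercept

    def design(self) -> tuple[np.ndarray, int]:
        levels, codes = np.unique(self.groups, return_inverse=True)
        q = len(levels)
        n = len(codes)
        Z = np.zeros((n, q))
        vals = np.ones(n) if self.values is None else np.asarray(self.values, float)
        Z[np.arange(n), codes] = vals
        return Z, q


@dataclass
class GLMMResult:
    beta: np.ndarray
    se: np.ndarray
    sigma: np.ndarray            # per-term random-effect SDs
    loglik: float
    converged: bool
    singular: bool
    singular_terms: list[str]
    n_obs: int
    n_params: int                # fixed + variance parameters
    ranef_modes: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _pirls(X, y, w, ZL, c0, max_iter=100, tol=1e-10):
    """Maximize the joint penalized weighted Bernoulli log-likelihood.

    Returns (c, f, H) with c = (beta, v), f the joint objective and H the
    negative Hessian at the optimum.
    """
    n, p = X.shape
    q = ZL.shape[1]
    A = np.hstack([X, ZL]) if q else X
    pen = np.zeros(p + q)
    pen[p:] = 1.0

    def objective(c):
        eta = A @ c
        # log-lik via logaddexp for stability
        ll = -np.logaddexp(0.0, -eta) * y - np.logaddexp(0.0, eta) * (1 - y)
        return float(np.sum(w * ll) - 0.5 * np.sum(c[p:] ** 2))

    c = c0.copy()
    f = objective(c)
    converged = False
    for _ in range(max_iter):
        eta = A @ c
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        g = A.T @ (w * (y - mu)) - pen * c
        W = w * mu * (1 - mu)
        H = A.T @ (A * W[:, None])
        H[np.arange(p + q)[p:], np.arange(p + q)[p:]] += 1.0
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            f_new = objective(c + t * step)
            if f_new >= f - 1e-14:
                break
            t *= 0.5
        c = c + t * step
        gscale = 1.0 + float(np.sum(w))
        if abs(f_new - f) <= tol * (abs(f) + 1.0) and np.max(np.abs(g)) < 1e-8 * gscale:
            f = f_new
            converged = True
            break
        f = f_new
    return c, f, H, converged


def fit_glmm(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    terms: list[RandomTerm] | None = None,
    sigma0: float = 0.3,
) -> GLMMResult:
    """Laplace-ML fit of a weighted Bernoulli GLMM.

    With no random terms this is exactly Newton-fitted weighted logistic
    regression (the Laplace correction vanishes).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    n, p = X.shape
    terms = terms or []
    Zs, qs = [], []
    for t in terms:
        Z, q = t.design()
        Zs.append(Z)
        qs.append(q)
    qtot = int(np.sum(qs)) if qs else 0
    Zfull = np.hstack(Zs) if Zs else np.zeros((n, 0))
    term_slices = []
    off = 0
    for q in qs:
        term_slices.append(slice(off, off + q))
        off += q

    state = {"c": np.zeros(p + qtot)}

    def laplace_negll(sigma):
        L = np.empty(qtot)
        for s, sl in zip(sigma, term_slices):
            L[sl] = s
        ZL = Zfull * L[None, :]
        c, f, H, _ = _pirls(X, y, w, ZL, state["c"])
        state["c"] = c
        if qtot:
            # v-block of the negative Hessian is (ZL)'W(ZL) + I
            Hv = H[p:, p:]
            sign, logdet = np.linalg.slogdet(Hv)
            lap = f - 0.5 * logdet
        else:
            lap = f
        return -lap

    if qtot:
        # derivative-free profile maximization: the Laplace objective is
        # cheap here (few variance parameters, warm-started inner solves)
        res = minimize(
            laplace_negll,
            x0=np.full(len(terms), sigma0),
            method="Nelder-Mead",
            bounds=[(0.0, 50.0)] * len(terms),
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000},
        )
        sigma = np.maximum(res.x, 0.0)
        best = res.fun
        # boundary polish: a component whose removal costs (numerically)
        # nothing sits on the boundary and is reported as exactly zero
        for k in np.argsort(sigma):
            if sigma[k] == 0.0 or sigma[k] > 0.1:
                continue
            trial = sigma.copy()
            trial[k] = 0.0
            f_trial = laplace_negll(trial)
            if f_trial <= best + 1e-3:
                sigma, best = trial, min(best, f_trial)
        outer_ok = bool(res.success)
    else:
        sigma = np.zeros(0)
        outer_ok = True
    loglik = -laplace_negll(sigma)
    # final joint fit at the optimum for coefficient covariance
    L = np.empty(qtot)
    for s, sl in zip(sigma, term_slices):
        L[sl] = s
    ZL = Zfull * L[None, :]
    c, f, H, inner_ok = _pirls(X, y, w, ZL, state["c"])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    singular_terms = [t.name for t, s in zip(terms, sigma) if s < SINGULAR_TOL]
    return GLMMResult(
        beta=c[:p],
        se=se,
        sigma=sigma,
        loglik=float(loglik),
        converged=bool(outer_ok and inner_ok),
        singular=bool(singular_terms),
        singular_terms=singular_terms,
        n_obs=n,
        n_params=p + len(terms),
        ranef_modes=c[p:] * L if qtot else None,
    )
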