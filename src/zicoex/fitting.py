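"""Penalized maximum likelihood for the zero-inflated copula pair model.

The penalized log-likelihood

    l(delta, u) = sum_i log f(y_i1, y_i2; delta, u) - 1/2 sum_theta
                  u_theta' diag(lambda_theta) u_theta

is maximized over all coefficients by trust-region Newton ascent (inner
loop) nested inside smoothing-parameter selection (outer loop), which picks
each variance component's lambda to minimize an AIC with the effective
degrees of freedom edf = tr(H_pen^-1 H_unpen) in place of the parameter
count.

Derivatives: per-cell first derivatives of log f with respect to the seven
linear predictors are computed in closed form through the copula rectangle
(only the derivative of the negative binomial cdf with respect to its own
predictor is obtained by a tight central difference); per-cell second
derivatives are central differences of that score.  The contract is
agreement with central finite differences of the penalized log-likelihood
itself, which the test-suite enforces on random states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .copula import CDF_CLIP, PMF_FLOOR, _nb_cdf_raw, _nb_pmf_raw
from .data import GenePairData
from .design import (THETA, CoefState, DesignBlocks, ModelSpec, build_design,
                     clip_eta, dparam_deta, inverse_link, predict_params)
from .trustregion import trust_region_maximize

__all__ = [
    "FitControl", "FitResult", "PairLikelihood", "fit", "fit_inner",
    "grad_hess", "penalized_loglik", "starting_values",
]

_FD_ETA = 1e-5      # step for d F_NB / d eta (central)
_FD_HESS = 1e-4     # step for per-cell Hessian as FD of the score

_I_MU1, _I_MU2, _I_S1, _I_S2, _I_RHO, _I_P1, _I_P2 = range(7)


# ---------------------------------------------------------------------------
# likelihood kernel
# ---------------------------------------------------------------------------

def _bvn_masked(x1, x2, rho, m1, m2):
    from .copula import bvn_cdf
    out = bvn_cdf(x1, x2, rho)
    return np.where(m1 & m2, out, 0.0)


class PairLikelihood:
    """Vectorized log-likelihood, score and Hessian for one gene pair."""

    def __init__(self, data: GenePairData, blocks: DesignBlocks):
        self.blocks = blocks
        self.y1 = np.asarray(data.y1, dtype=float)
        self.y2 = np.asarray(data.y2, dtype=float)
        self.z1 = self.y1 == 0
        self.z2 = self.y2 == 0
        self.n = len(self.y1)
        self.W = blocks.global_designs()

    # -- predictor plumbing -------------------------------------------------
    def eta_of_beta(self, beta: np.ndarray) -> np.ndarray:
        b = self.blocks
        out = np.empty((self.n, 7))
        for j, t in enumerate(THETA):
            sl = b.delta_slices[t]
            e = b.X[t] @ beta[sl]
            su = b.u_slices[t]
            if su.stop > su.start:
                e = e + b.Z[t] @ beta[b.n_delta + su.start:b.n_delta + su.stop]
            out[:, j] = e + b.offset[t]
        return out

    # -- per-cell pieces ----------------------------------------------------
    def _margins(self, eta):
        mu1 = np.exp(clip_eta("mu1", eta[:, _I_MU1]))
        mu2 = np.exp(clip_eta("mu2", eta[:, _I_MU2]))
        s1 = np.exp(clip_eta("sigma1", eta[:, _I_S1]))
        s2 = np.exp(clip_eta("sigma2", eta[:, _I_S2]))
        return mu1, mu2, s1, s2

    def components(self, eta):
        mu1, mu2, s1, s2 = self._margins(eta)
        rho = np.tanh(clip_eta("rho", eta[:, _I_RHO]))
        from scipy.special import expit
        p1 = expit(clip_eta("p1", eta[:, _I_P1]))
        p2 = expit(clip_eta("p2", eta[:, _I_P2]))
        F1h = _nb_cdf_raw(self.y1, mu1, s1)
        F1l = _nb_cdf_raw(self.y1 - 1.0, mu1, s1)
        F2h = _nb_cdf_raw(self.y2, mu2, s2)
        F2l = _nb_cdf_raw(self.y2 - 1.0, mu2, s2)
        f1 = _nb_pmf_raw(self.y1, mu1, s1)
        f2 = _nb_pmf_raw(self.y2, mu2, s2)
        c1l = F1l > 0.0
        c2l = F2l > 0.0
        x1h = ndtri(np.clip(F1h, CDF_CLIP, 1 - CDF_CLIP))
        x1l = ndtri(np.clip(F1l, CDF_CLIP, 1 - CDF_CLIP))
        x2h = ndtri(np.clip(F2h, CDF_CLIP, 1 - CDF_CLIP))
        x2l = ndtri(np.clip(F2l, CDF_CLIP, 1 - CDF_CLIP))
        tru = np.ones(self.n, dtype=bool)
        g = (_bvn_masked(x1h, x2h, rho, tru, tru)
             - _bvn_masked(x1l, x2h, rho, c1l, tru)
             - _bvn_masked(x1h, x2l, rho, tru, c2l)
             + _bvn_masked(x1l, x2l, rho, c1l, c2l))
        g = np.maximum(g, 0.0)
        q1 = 1.0 - p1
        q2 = 1.0 - p2
        f = q1 * q2 * g \
            + np.where(self.z2, q1 * p2 * f1, 0.0) \
            + np.where(self.z1, p1 * q2 * f2, 0.0) \
            + np.where(self.z1 & self.z2, p1 * p2, 0.0)
        return dict(mu1=mu1, mu2=mu2, s1=s1, s2=s2, rho=rho, p1=p1, p2=p2,
                    q1=q1, q2=q2, F1h=F1h, F1l=F1l, F2h=F2h, F2l=F2l,
                    f1=f1, f2=f2, c1l=c1l, c2l=c2l,
                    x1h=x1h, x1l=x1l, x2h=x2h, x2l=x2l, g=g, f=f)

    def cell_loglik(self, eta) -> np.ndarray:
        return np.log(np.maximum(self.components(eta)["f"], PMF_FLOOR))

    def loglik(self, eta) -> float:
        return float(np.sum(self.cell_loglik(eta)))

    # -- analytic score -----------------------------------------------------
    @staticmethod
    def _dI_dq(y, r, q):
        """Partial of the regularized incomplete beta I_q(r, y+1) w.r.t. q."""
        from scipy.special import gammaln
        y = np.maximum(y, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = (r - 1.0) * np.log(q) + y * np.log1p(-q) \
                + gammaln(r + y + 1.0) - gammaln(r) - gammaln(y + 1.0)
        return np.exp(np.clip(lg, -745.0, 700.0))

    def _dF_margin(self, y, eta_mu, eta_sigma, wrt: str, pmf=None):
        """Derivatives of (F(y), F(y-1), pmf(y)) w.r.t. a mean or dispersion
        predictor.

        The mean derivative is the closed-form incomplete-beta partial; the
        dispersion cdf derivative is a tight central difference (the
        incomplete beta has no closed-form partial in its first parameter),
        while the dispersion pmf derivative uses digamma terms.
        """
        from scipy.special import digamma
        mu = np.exp(np.clip(eta_mu, -30, 30))
        sig = np.exp(np.clip(eta_sigma, -12, 12))
        r = 1.0 / sig
        q = 1.0 / (1.0 + sig * mu)
        one_q = np.maximum(1.0 - q, 1e-300)
        if wrt == "mu":
            inside = (eta_mu > -30) & (eta_mu < 30)
            dq = np.where(inside, -sig * q * q * mu, 0.0)  # dq/d eta_mu
            dFh = np.where(y >= 0, self._dI_dq(y, r, q) * dq, 0.0)
            dFl = np.where(y - 1 >= 0, self._dI_dq(y - 1.0, r, q) * dq, 0.0)
            if pmf is None:
                pmf = _nb_pmf_raw(y, mu, sig)
            df = pmf * dq * (r / q - np.where(y > 0, y / one_q, 0.0))
            return dFh, dFl, df
        h = _FD_ETA
        s_p = np.exp(np.clip(eta_sigma + h, -12, 12))
        s_m = np.exp(np.clip(eta_sigma - h, -12, 12))
        dFh = (_nb_cdf_raw(y, mu, s_p) - _nb_cdf_raw(y, mu, s_m)) / (2 * h)
        dFl = (_nb_cdf_raw(y - 1.0, mu, s_p)
               - _nb_cdf_raw(y - 1.0, mu, s_m)) / (2 * h)
        if pmf is None:
            pmf = _nb_pmf_raw(y, mu, sig)
        # d log pmf / d eta_sigma = dr * [psi(y+r) - psi(r) + log q] + dq * (...)
        inside = (eta_sigma > -12) & (eta_sigma < 12)
        dr = np.where(inside, -r, 0.0)       # dr/d eta_sigma
        dq = np.where(inside, -mu * q * q * sig, 0.0)
        dlog = dr * (digamma(y + r) - digamma(r) + np.log(q)) \
            + dq * (r / q - np.where(y > 0, y / one_q, 0.0))
        return dFh, dFl, np.where(y >= 0, pmf * dlog, 0.0)

    def score_cells(self, eta) -> np.ndarray:
        """(n, 7) matrix d log f / d eta_theta (0 where the pmf is floored)."""
        c = self.components(eta)
        rho, g, f = c["rho"], c["g"], c["f"]
        q1, q2, p1, p2 = c["q1"], c["q2"], c["p1"], c["p2"]
        f1, f2 = c["f1"], c["f2"]
        z1, z2 = self.z1, self.z2
        s = np.sqrt(np.maximum(1.0 - rho * rho, 1e-12))
        inv_f = np.where(f > PMF_FLOOR, 1.0 / np.maximum(f, PMF_FLOOR), 0.0)

        def inside(F):
            return (F > CDF_CLIP) & (F < 1.0 - CDF_CLIP)

        # d(rect)/dF factors: Phi differences over the opposite margin
        def dG_dF(x_own, xo_h, xo_l, co_l):
            return ndtr((xo_h - rho * x_own) / s) \
                - np.where(co_l, ndtr((xo_l - rho * x_own) / s), 0.0)

        D_F1h = np.where(inside(c["F1h"]),
                         dG_dF(c["x1h"], c["x2h"], c["x2l"], c["c2l"]), 0.0)
        D_F1l = np.where(c["c1l"] & inside(c["F1l"]),
                         -dG_dF(c["x1l"], c["x2h"], c["x2l"], c["c2l"]), 0.0)
        D_F2h = np.where(inside(c["F2h"]),
                         dG_dF(c["x2h"], c["x1h"], c["x1l"], c["c1l"]), 0.0)
        D_F2l = np.where(c["c2l"] & inside(c["F2l"]),
                         -dG_dF(c["x2l"], c["x1h"], c["x1l"], c["c1l"]), 0.0)

        out = np.zeros((self.n, 7))
        case1 = np.where(z2, q1 * p2, 0.0)   # weight on f1 terms
        case2 = np.where(z1, p1 * q2, 0.0)
        for wrt, col in (("mu", _I_MU1), ("sigma", _I_S1)):
            dFh, dFl, df = self._dF_margin(
                self.y1, eta[:, _I_MU1], eta[:, _I_S1], wrt, pmf=f1)
            dfdeta = q1 * q2 * (D_F1h * dFh + D_F1l * dFl) + case1 * df
            out[:, col] = dfdeta * inv_f
        for wrt, col in (("mu", _I_MU2), ("sigma", _I_S2)):
            dFh, dFl, df = self._dF_margin(
                self.y2, eta[:, _I_MU2], eta[:, _I_S2], wrt, pmf=f2)
            dfdeta = q1 * q2 * (D_F2h * dFh + D_F2l * dFl) + case2 * df
            out[:, col] = dfdeta * inv_f

        # d(rect)/d rho: the bivariate normal density at the four corners
        def phi2(xa, xb):
            return np.exp(-(xa * xa - 2 * rho * xa * xb + xb * xb)
                          / (2 * s * s)) / (2 * np.pi * s)

        dg_drho = phi2(c["x1h"], c["x2h"]) \
            - np.where(c["c1l"], phi2(c["x1l"], c["x2h"]), 0.0) \
            - np.where(c["c2l"], phi2(c["x1h"], c["x2l"]), 0.0) \
            + np.where(c["c1l"] & c["c2l"], phi2(c["x1l"], c["x2l"]), 0.0)
        out[:, _I_RHO] = q1 * q2 * dg_drho \
            * dparam_deta("rho", eta[:, _I_RHO]) * inv_f

        df_dp1 = -q2 * g - np.where(z2, p2 * f1, 0.0) \
            + np.where(z1, q2 * f2, 0.0) + np.where(z1 & z2, p2, 0.0)
        df_dp2 = -q1 * g - np.where(z1, p1 * f2, 0.0) \
            + np.where(z2, q1 * f1, 0.0) + np.where(z1 & z2, p1, 0.0)
        out[:, _I_P1] = df_dp1 * dparam_deta("p1", eta[:, _I_P1]) * inv_f
        out[:, _I_P2] = df_dp2 * dparam_deta("p2", eta[:, _I_P2]) * inv_f
        return out

    def hessian_cells(self, eta, mode: str = "central",
                      s0: np.ndarray | None = None) -> np.ndarray:
        """(n, 7, 7) second derivatives of log f w.r.t. the predictors.

        ``mode='central'`` differences the score symmetrically (used for
        the reported observed Hessian); ``mode='forward'`` uses one-sided
        differences at half the cost for inner Newton iterations.
        """
        h = _FD_HESS
        D = np.empty((self.n, 7, 7))
        if mode == "forward":
            if s0 is None:
                s0 = self.score_cells(eta)
            for a in range(7):
                e_p = eta.copy()
                e_p[:, a] += h
                D[:, a, :] = (self.score_cells(e_p) - s0) / h
        else:
            for a in range(7):
                e_p = eta.copy()
                e_p[:, a] += h
                e_m = eta.copy()
                e_m[:, a] -= h
                D[:, a, :] = (self.score_cells(e_p)
                              - self.score_cells(e_m)) / (2 * h)
        return 0.5 * (D + np.transpose(D, (0, 2, 1)))

    # -- assembly over coefficients -----------------------------------------
    def grad_unpen(self, s_cells) -> np.ndarray:
        return np.einsum("tnp,nt->p", self.W, s_cells)

    def score_matrix(self, s_cells) -> np.ndarray:
        """(n, P) per-cell score in coefficient space (for BHHH)."""
        return np.einsum("tnp,nt->np", self.W, s_cells)

    def hess_unpen(self, D_cells) -> np.ndarray:
        V = np.einsum("anp,nab->bnp", self.W, D_cells)
        return np.einsum("bnp,bnq->pq", V, self.W)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _penalty(blocks: DesignBlocks, state: CoefState):
    pd_ = blocks.penalty_diag(state.lam) if blocks.n_comp else np.zeros(blocks.n_coef)
    return pd_


def penalized_loglik(data: GenePairData, blocks: DesignBlocks,
                     state: CoefState) -> float:
    """Sum of log f over cells minus the ridge penalty on the random effects."""
    kern = PairLikelihood(data, blocks)
    beta = state.beta
    if len(beta) != blocks.n_coef:
        raise ValueError("coefficient vector inconsistent with design")
    pd_ = _penalty(blocks, state)
    return kern.loglik(kern.eta_of_beta(beta)) - 0.5 * float(pd_ @ (beta * beta))


def grad_hess(data: GenePairData, blocks: DesignBlocks, state: CoefState):
    """Gradient and observed Hessian of the penalized log-likelihood."""
    kern = PairLikelihood(data, blocks)
    beta = state.beta
    eta = kern.eta_of_beta(beta)
    pd_ = _penalty(blocks, state)
    g = kern.grad_unpen(kern.score_cells(eta)) - pd_ * beta
    H = kern.hess_unpen(kern.hessian_cells(eta)) - np.diag(pd_)
    return g, H


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _ridge_irls_logistic(A, t, w, ridge, max_iter=40):
    """Weighted ridge logistic regression (initialization only)."""
    from scipy.special import expit
    b = np.zeros(A.shape[1])
    R = np.diag(ridge)
    for _ in range(max_iter):
        eta = np.clip(A @ b, -15, 15)
        p = expit(eta)
        g = A.T @ (w * (t - p)) - ridge * b
        Wd = w * p * (1 - p) + 1e-10
        H = (A * Wd[:, None]).T @ A + R
        step = np.linalg.solve(H, g)
        b = b + step
        if np.max(np.abs(step)) < 1e-9:
            break
    return np.clip(b, -15, 15)


def _moment_margin(y, S, w, X):
    """Weighted moment estimates of the mean-rate and dispersion predictors."""
    patterns, inv = np.unique(X, axis=0, return_inverse=True)
    k = len(patterns)
    if k > max(20, 2 * X.shape[1]):
        # continuous covariates: weighted log-linear regression fallback
        resp = np.log((y + 0.5) / S)
        Wm = np.sqrt(w)
        beta = np.linalg.lstsq(X * Wm[:, None], resp * Wm, rcond=None)[0]
        mu_hat = np.exp(np.clip(X @ beta, -30, 30) + np.log(S))
        num = np.sum(w * ((y - mu_hat) ** 2 - mu_hat))
        den = np.sum(w * mu_hat ** 2)
        sig = np.clip(num / max(den, 1e-12), 1e-3, 50.0)
        return beta, mu_hat, np.full_like(y, sig, dtype=float)
    rates = np.empty(k)
    sigs = np.empty(k)
    mu_hat = np.empty_like(y, dtype=float)
    for j in range(k):
        m = inv == j
        rates[j] = max(np.sum(w[m] * y[m]) / np.sum(w[m] * S[m]), 1e-10)
        mu_hat[m] = rates[j] * S[m]
        num = np.sum(w[m] * ((y[m] - mu_hat[m]) ** 2 - mu_hat[m]))
        den = np.sum(w[m] * mu_hat[m] ** 2)
        sigs[j] = np.clip(num / max(den, 1e-12), 1e-3, 50.0)
    beta = np.linalg.lstsq(patterns, np.log(rates), rcond=None)[0]
    sig_cell = sigs[inv]
    return beta, mu_hat, sig_cell


def _weighted_corr(a, b, w):
    w = w / np.sum(w)
    am = a - np.sum(w * a)
    bm = b - np.sum(w * b)
    den = np.sqrt(np.sum(w * am * am) * np.sum(w * bm * bm))
    if den <= 0:
        return 0.0
    return float(np.sum(w * am * bm) / den)


def starting_values(data: GenePairData, blocks: DesignBlocks) -> CoefState:
    """Weighted starting values: cells with a zero count get weight 0.5.

    Dropout predictors come from a weighted (ridge) logistic regression of
    the zero indicator; mean and dispersion predictors from depth-offset
    weighted moments; the copula predictor from the weighted Pearson
    correlation of marginal normal scores.  Random effects other than the
    dropout ones start at zero.
    """
    y1 = np.asarray(data.y1, dtype=float)
    y2 = np.asarray(data.y2, dtype=float)
    if np.all(y1 == 0) or np.all(y2 == 0):
        raise ValueError("degenerate margin: a gene is zero in every cell")
    S = data.depth
    w1 = np.where(y1 == 0, 0.5, 1.0)
    w2 = np.where(y2 == 0, 0.5, 1.0)
    delta = np.zeros(blocks.n_delta)
    u = np.zeros(blocks.n_u)

    # dropout margins
    for t, y, w in (("p1", y1, w1), ("p2", y2, w2)):
        Xp, Zp = blocks.X[t], blocks.Z[t]
        ds, us = blocks.delta_slices[t], blocks.u_slices[t]
        if not np.any(y == 0):
            delta[ds.start] = -15.0
            continue
        A = np.hstack([Xp, Zp]) if Zp.shape[1] else Xp
        ridge = np.r_[np.full(Xp.shape[1], 1e-6), np.ones(Zp.shape[1])]
        b = _ridge_irls_logistic(A, (y == 0).astype(float), w, ridge)
        delta[ds] = b[:Xp.shape[1]]
        if Zp.shape[1]:
            u[us] = b[Xp.shape[1]:]

    # mean / dispersion margins
    mus, sigs = {}, {}
    for tmu, tsig, y, w in (("mu1", "sigma1", y1, w1), ("mu2", "sigma2", y2, w2)):
        beta, mu_hat, sig_cell = _moment_margin(y, S, w, blocks.X[tmu])
        delta[blocks.delta_slices[tmu]] = beta
        Xs = blocks.X[tsig]
        Wm = np.sqrt(w)
        alpha = np.linalg.lstsq(Xs * Wm[:, None],
                                np.log(sig_cell) * Wm, rcond=None)[0]
        delta[blocks.delta_slices[tsig]] = alpha
        mus[tmu], sigs[tsig] = mu_hat, np.exp(np.clip(Xs @ alpha, -12, 12))

    # copula predictor from normal scores
    u1 = _nb_cdf_raw(y1 - 1.0, mus["mu1"], sigs["sigma1"]) \
        + 0.5 * _nb_pmf_raw(y1, mus["mu1"], sigs["sigma1"])
    u2 = _nb_cdf_raw(y2 - 1.0, mus["mu2"], sigs["sigma2"]) \
        + 0.5 * _nb_pmf_raw(y2, mus["mu2"], sigs["sigma2"])
    z1s = ndtri(np.clip(u1, CDF_CLIP, 1 - CDF_CLIP))
    z2s = ndtri(np.clip(u2, CDF_CLIP, 1 - CDF_CLIP))
    w12 = w1 * w2
    Xr = blocks.X["rho"]
    patterns, inv = np.unique(Xr, axis=0, return_inverse=True)
    if len(patterns) <= max(20, 2 * Xr.shape[1]):
        rs = np.empty(len(patterns))
        for j in range(len(patterns)):
            m = inv == j
            rs[j] = _weighted_corr(z1s[m], z2s[m], w12[m])
        tau = np.linalg.lstsq(patterns,
                              np.arctanh(np.clip(rs, -0.99, 0.99)),
                              rcond=None)[0]
    else:
        r = _weighted_corr(z1s, z2s, w12)
        tau = np.zeros(Xr.shape[1])
        tau[0] = np.arctanh(np.clip(r, -0.99, 0.99))
    delta[blocks.delta_slices["rho"]] = tau
    lam = np.ones(blocks.n_comp)
    return CoefState(delta=delta, u=u, lam=lam)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitControl:
    """Knobs of the nested optimization.

    hessian: curvature model of the inner trust region -- "bhhh" (score
    outer-product preconditioning phase, then an observed-Hessian polish)
    or "exact" (observed Hessian every accepted step).
    lambda_method: outer smoothing-parameter update -- "em" iterates the
    variance-component fixed point lambda_j = r_j / (||u_j||^2 + tr V_jj);
    "aic_grid" runs a per-component coordinate search over ``lambda_grid``
    minimizing AIC with effective degrees of freedom (optionally refined
    by golden section between the best point's grid neighbours).
    """

    max_iter: int = 200
    radius0: float = 1.0
    hessian: str = "bhhh"
    polish_iter: int = 40
    bhhh_impr: float = 1e-9
    lambda_method: str = "em"
    em_max_iter: int = 15
    em_tol: float = 0.05
    lambda_min: float = 1e-4
    lambda_max: float = 1e6
    lambda_init: float = 10.0
    lambda_grid: tuple = tuple(np.logspace(-4, 6, 11))
    outer_passes: int = 1
    refine: bool = True
    refine_tol: float = 0.25
    verbose: bool = False


@dataclass
class FitResult:
    """Optimum of the penalized log-likelihood for one gene pair."""

    state: CoefState
    blocks: DesignBlocks
    loglik: float            # unpenalized, at the optimum
    loglik_pen: float
    grad: np.ndarray
    hessian: np.ndarray      # observed Hessian of the penalized log-lik
    hessian_unpen: np.ndarray
    edf: float
    converged: bool
    n_iter: int
    n_inner_fits: int = 1
    hessian_ridged: bool = field(default=False)
    _cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def coef_names(self):
        return self.blocks.coef_names

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.edf

    def cov(self) -> np.ndarray:
        """Coefficient covariance (-H_pen)^-1, ridged if not neg-definite."""
        if self._cov is None:
            A = -self.hessian
            try:
                ev = np.linalg.eigvalsh(A)
                if ev[0] <= 1e-10 * max(1.0, abs(ev[-1])):
                    ridge = abs(ev[0]) + 1e-8 * max(1.0, abs(ev[-1]))
                    A = A + ridge * np.eye(A.shape[0])
                    self.hessian_ridged = True
                self._cov = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                self._cov = np.full_like(self.hessian, np.nan)
                self.hessian_ridged = True
        return self._cov

    def se(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov()), 0.0))

    def cell_params(self):
        return predict_params(self.blocks, self.state)

    def fixed_effect_table(self) -> pd.DataFrame:
        """Population-level (u = 0, offset excluded) estimates per pattern.

        For the means, 'natural' is the expected count per unit depth.
        """
        rows = []
        for t in THETA:
            X = self.blocks.X[t]
            pats = np.unique(X, axis=0)
            d = self.state.delta[self.blocks.delta_slices[t]]
            for p in pats:
                eta = float(p @ d)
                rows.append(dict(param=t,
                                 pattern=", ".join(
                                     f"{n}={v:g}" for n, v in
                                     zip(self.blocks.xnames[t], p)),
                                 eta=eta, natural=float(inverse_link(t, eta))))
        return pd.DataFrame(rows)


def _edf(H_unpen, pd_):
    H_pen = H_unpen - np.diag(pd_)
    try:
        return float(np.trace(np.linalg.solve(H_pen, H_unpen))), H_pen, False
    except np.linalg.LinAlgError:
        H_pen2 = H_pen - 1e-6 * np.eye(H_pen.shape[0])
        return float(np.trace(np.linalg.solve(H_pen2, H_unpen))), H_pen, True


def fit_inner(data: GenePairData, blocks: DesignBlocks, lam,
              start: CoefState, control: FitControl | None = None,
              kernel: PairLikelihood | None = None,
              final_hessian: bool = True) -> FitResult:
    """Maximize the penalized log-likelihood at fixed smoothing parameters.

    With the default "bhhh" strategy, a cheap trust-region phase using the
    score outer-product as curvature takes the bulk of the steps, then an
    observed-Hessian phase finishes to machine-epsilon improvements.
    ``final_hessian=False`` keeps the (one-sided-difference) Hessian from
    the last Newton phase instead of recomputing a symmetric-difference
    one -- used for intermediate outer-loop iterations.
    """
    control = control or FitControl()
    kern = kernel or PairLikelihood(data, blocks)
    lam = np.asarray(lam, dtype=float)
    pd_ = blocks.penalty_diag(lam) if blocks.n_comp else np.zeros(blocks.n_coef)

    def fun(beta):
        return kern.loglik(kern.eta_of_beta(beta)) \
            - 0.5 * float(pd_ @ (beta * beta))

    def fgh_bhhh(beta):
        eta = kern.eta_of_beta(beta)
        ll = kern.loglik(eta) - 0.5 * float(pd_ @ (beta * beta))
        s = kern.score_cells(eta)
        g = kern.grad_unpen(s) - pd_ * beta
        Smat = kern.score_matrix(s)
        H = -(Smat.T @ Smat) - np.diag(pd_)
        return ll, g, H

    def make_fgh_exact(mode):
        def fgh(beta):
            eta = kern.eta_of_beta(beta)
            ll = kern.loglik(eta) - 0.5 * float(pd_ @ (beta * beta))
            s = kern.score_cells(eta)
            g = kern.grad_unpen(s) - pd_ * beta
            D = kern.hessian_cells(eta, mode=mode, s0=s)
            H = kern.hess_unpen(D) - np.diag(pd_)
            return ll, g, H
        return fgh

    beta0 = start.beta
    if control.hessian == "bhhh":
        res1 = trust_region_maximize(fun, fgh_bhhh, beta0,
                                     radius=control.radius0,
                                     max_iter=control.max_iter,
                                     min_impr_rel=control.bhhh_impr)
        res = trust_region_maximize(fun, make_fgh_exact("forward"), res1.x,
                                    radius=0.5, max_iter=control.polish_iter)
        n_iter = res1.n_iter + res.n_iter
    else:
        res = trust_region_maximize(fun, make_fgh_exact("central"), beta0,
                                    radius=control.radius0,
                                    max_iter=control.max_iter)
        n_iter = res.n_iter
    beta_hat, converged = res.x, res.converged

    g = res.grad
    if final_hessian:
        eta = kern.eta_of_beta(beta_hat)
        H_unpen = kern.hess_unpen(kern.hessian_cells(eta, mode="central"))
    else:
        H_unpen = res.hess + np.diag(pd_)
    edf, H_pen, ridged = _edf(H_unpen, pd_)
    ll = res.fun + 0.5 * float(pd_ @ (beta_hat * beta_hat))
    state = CoefState.from_beta(beta_hat, blocks, lam)
    return FitResult(state=state, blocks=blocks, loglik=ll,
                     loglik_pen=res.fun,
                     grad=g, hessian=H_pen, hessian_unpen=H_unpen, edf=edf,
                     converged=converged, n_iter=n_iter,
                     hessian_ridged=ridged)


def _golden_lambda(evaluate, lo, hi, tol):
    """Golden-section minimization of AIC over log10 lambda in [lo, hi]."""
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = evaluate(10 ** c), evaluate(10 ** d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = evaluate(10 ** c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = evaluate(10 ** d)
    return 10 ** ((a + b) / 2)


def _fit_em(data, blocks, kern, start, control):
    """Iterate the EM-type variance-component fixed point for lambda."""
    K = blocks.n_comp
    lam = np.full(K, control.lambda_init)
    comp_ix = blocks.comp_indices()
    state = start.copy()
    n_inner = 0
    res = None
    for it in range(control.em_max_iter):
        res = fit_inner(data, blocks, lam, state, control, kern,
                        final_hessian=False)
        n_inner += 1
        state = res.state
        try:
            V = np.linalg.inv(-res.hessian)
        except np.linalg.LinAlgError:
            break
        lam_new = lam.copy()
        beta = state.beta
        for j, ix in enumerate(comp_ix):
            denom = float(beta[ix] @ beta[ix]) + float(np.trace(V[np.ix_(ix, ix)]))
            lam_new[j] = np.clip(len(ix) / max(denom, 1e-300),
                                 control.lambda_min, control.lambda_max)
        if np.max(np.abs(np.log10(lam_new) - np.log10(lam))) < control.em_tol:
            lam = lam_new
            break
        lam = lam_new
    final = fit_inner(data, blocks, lam, state, control, kern,
                      final_hessian=True)
    final.n_inner_fits = n_inner + 1
    return final


def _fit_aic_grid(data, blocks, kern, start, control):
    """Per-component coordinate search over the lambda grid, by AIC."""
    K = blocks.n_comp
    grid = np.asarray(control.lambda_grid, dtype=float)
    lam = np.full(K, np.exp(np.mean(np.log(grid))))
    best_state = start.copy()
    cache: dict = {}
    n_inner = 0

    def evaluate(lam_vec):
        nonlocal n_inner, best_state
        key = tuple(np.round(np.log10(np.maximum(lam_vec, 1e-300)), 6))
        if key in cache:
            return cache[key]
        res = fit_inner(data, blocks, lam_vec, best_state.copy(), control,
                        kern, final_hessian=False)
        n_inner += 1
        aic = res.aic if res.converged else res.aic + 1e6
        cache[key] = (aic, res)
        return cache[key]

    best_aic, best_res = evaluate(lam)
    best_state = best_res.state
    for _ in range(control.outer_passes):
        for k in range(K):
            for cand in grid:
                lam_try = lam.copy()
                lam_try[k] = cand
                aic, res = evaluate(lam_try)
                if aic < best_aic - 1e-9:
                    best_aic, best_res, lam = aic, res, lam_try
                    best_state = res.state
            if control.refine:
                j = int(np.argmin(np.abs(np.log10(grid) - np.log10(lam[k]))))
                lo = np.log10(grid[max(j - 1, 0)])
                hi = np.log10(grid[min(j + 1, len(grid) - 1)])
                if hi > lo:
                    def eval_k(lv, k=k):
                        lam_try = lam.copy()
                        lam_try[k] = lv
                        return evaluate(lam_try)[0]
                    lam_k = _golden_lambda(eval_k, lo, hi, control.refine_tol)
                    aic, res = evaluate(np.r_[lam[:k], lam_k, lam[k + 1:]])
                    if aic < best_aic - 1e-9:
                        best_aic, best_res = aic, res
                        lam = np.r_[lam[:k], lam_k, lam[k + 1:]]
                        best_state = res.state
    final = fit_inner(data, blocks, lam, best_res.state, control, kern,
                      final_hessian=True)
    final.n_inner_fits = n_inner + 1
    return final


def fit(data: GenePairData, spec: ModelSpec | None = None,
        control: FitControl | None = None) -> FitResult:
    """Full fit: smoothing-parameter selection wrapped around `fit_inner`.

    The outer loop picks one lambda per variance component (EM fixed point
    by default, or AIC-grid coordinate search; see :class:`FitControl`);
    inner refits warm-start from the previous optimum, and the returned
    result carries the observed Hessian at the selected lambda.
    """
    control = control or FitControl()
    spec = spec or ModelSpec.two_group()
    blocks = build_design(data, spec)
    kern = PairLikelihood(data, blocks)
    start = starting_values(data, blocks)
    if blocks.n_comp == 0:
        return fit_inner(data, blocks, np.zeros(0), start, control, kern)
    if control.lambda_method == "em":
        return _fit_em(data, blocks, kern, start, control)
    if control.lambda_method == "aic_grid":
        return _fit_aic_grid(data, blocks, kern, start, control)
    raise ValueError(f"unknown lambda_method {control.lambda_method!r}")
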