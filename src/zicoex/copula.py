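"""Exact densities for the zero-inflated bivariate Gaussian-copula count model.

The building blocks are:

* the NBII negative binomial (mean ``mu``, variance ``mu + mu**2 * sigma``),
* a bivariate Gaussian copula coupling two NBII marginals through a
  correlation parameter ``rho``,
* independent per-gene dropout (zero-inflation) with probabilities
  ``p1, p2`` mixed in at the joint level.

All functions broadcast over numpy arrays.  Public entry points validate
their domains; the ``_*_raw`` variants skip validation and are used by the
fitting code on pre-validated arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats

__all__ = [
    "CellParams",
    "bvn_cdf",
    "copula_cdf",
    "joint_pmf",
    "nb_cdf",
    "nb_pmf",
    "nb_quantile",
    "zi_joint_pmf",
    "zinb_marginal_pmf",
]

# sigma below this is treated as the Poisson limit (1/sigma would overflow
# the NB parameterization)
POISSON_GUARD = 1e-8
# marginal cdf values are clipped into this range before the normal
# quantile so counts deep in a tail never map to +-inf
CDF_CLIP = 1e-15
# negative rectangle probabilities larger than this signal a broken
# bivariate-normal CDF rather than rounding noise
RECT_TOL = 1e-12
# floor applied before taking logs of clamped-zero probabilities
PMF_FLOOR = 1e-300

_TWO_PI = 2.0 * np.pi


class ConsistencyError(RuntimeError):
    """Internal numerical consistency violated (bad rectangle probability)."""


@dataclass
class CellParams:
    """Natural-scale parameters of one (or many, via arrays) cells.

    mu1, mu2      expected counts of genes 1 and 2 (positive)
    sigma1, sigma2  NBII over-dispersions (positive); variance is mu + mu^2 sigma
    rho           Gaussian-copula correlation, in (-1, 1)
    p1, p2        dropout probabilities, in [0, 1]
    """

    mu1: np.ndarray
    mu2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    rho: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    def validate(self, dropout_open: bool = False) -> None:
        for name in ("mu1", "mu2", "sigma1", "sigma2"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        if np.any(np.abs(np.asarray(self.rho)) >= 1):
            raise ValueError("rho must lie in (-1, 1)")
        for name in ("p1", "p2"):
            p = np.asarray(getattr(self, name))
            if dropout_open:
                if np.any((p <= 0) | (p >= 1)):
                    raise ValueError(f"{name} must lie in (0, 1)")
            elif np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isfinite(y)):
        raise ValueError("counts must be finite")
    if np.any(y != np.floor(y)):
        raise ValueError("counts must be integral")
    return y


def _check_margin(mu, sigma) -> tuple[np.ndarray, np.ndarray]:
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return mu, sigma


# ---------------------------------------------------------------------------
# NBII marginal
# ---------------------------------------------------------------------------

def _nb_pmf_raw(y, mu, sigma):
    """NBII pmf without domain checks; y may be any integer (<0 gives 0).

    Evaluated through gammaln/log1p rather than scipy.stats to keep the
    per-call overhead small inside the fitting loops; agreement with
    scipy.stats.nbinom is covered by the tests.
    """
    y, mu, sigma = np.broadcast_arrays(
        np.asarray(y, dtype=float), np.asarray(mu, dtype=float),
        np.asarray(sigma, dtype=float))
    out = np.zeros(y.shape, dtype=float)
    ok = y >= 0
    small = sigma < POISSON_GUARD
    m = ok & small
    if np.any(m):
        out[m] = np.exp(y[m] * np.log(mu[m]) - mu[m]
                        - special.gammaln(y[m] + 1.0))
    m = ok & ~small
    if np.any(m):
        r = 1.0 / sigma[m]
        sm = sigma[m] * mu[m]
        lp = -np.log1p(sm)              # log of success prob r/(r+mu)
        lq = np.log(sm) + lp            # log of 1 - that
        ym = y[m]
        out[m] = np.exp(special.gammaln(ym + r) - special.gammaln(r)
                        - special.gammaln(ym + 1.0) + r * lp + ym * lq)
    return out


def _nb_cdf_raw(y, mu, sigma):
    """NBII cdf without domain checks; y < 0 gives 0 (empty event)."""
    y, mu, sigma = np.broadcast_arrays(
        np.asarray(y, dtype=float), np.asarray(mu, dtype=float),
        np.asarray(sigma, dtype=float))
    out = np.zeros(y.shape, dtype=float)
    yf = np.floor(y)
    ok = yf >= 0
    small = sigma < POISSON_GUARD
    m = ok & small
    if np.any(m):
        out[m] = special.gammaincc(yf[m] + 1.0, mu[m])
    m = ok & ~small
    if np.any(m):
        r = 1.0 / sigma[m]
        out[m] = special.betainc(r, yf[m] + 1.0, 1.0 / (1.0 + sigma[m] * mu[m]))
    return out


def nb_pmf(y, mu, sigma):
    """NBII negative binomial pmf with mean ``mu``, variance ``mu + mu^2 sigma``.

    Parameterized as a standard negative binomial with size ``r = 1/sigma``
    and success probability ``r / (r + mu)``; ``sigma < 1e-8`` falls back to
    the Poisson(``mu``) limit.
    """
    y = _check_counts(y)
    mu, sigma = _check_margin(mu, sigma)
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    return _nb_pmf_raw(y, mu, sigma)[()]


def nb_cdf(y, mu, sigma):
    """NBII cdf; ``y = -1`` is the empty event and returns 0."""
    mu, sigma = _check_margin(mu, sigma)
    y = np.asarray(y, dtype=float)
    return _nb_cdf_raw(np.floor(y), mu, sigma)[()]


def nb_quantile(prob, mu, sigma, max_prob: float = 1.0 - 1e-12):
    """Smallest integer ``y`` with ``nb_cdf(y) >= prob``.

    Probabilities at or above 1 are capped at ``max_prob`` with a warning;
    ``prob <= 0`` maps to 0.
    """
    import warnings

    mu, sigma = _check_margin(mu, sigma)
    prob = np.asarray(prob, dtype=float)
    if np.any(prob < 0):
        raise ValueError("prob must be non-negative")
    if np.any(prob >= 1):
        warnings.warn(
            f"quantile probabilities >= 1 capped at {max_prob}", RuntimeWarning)
        prob = np.minimum(prob, max_prob)
    prob, mu, sigma = np.broadcast_arrays(prob, mu, sigma)
    out = np.zeros(prob.shape, dtype=float)
    small = sigma < POISSON_GUARD
    if np.any(small):
        out[small] = stats.poisson.ppf(prob[small], mu[small])
    big = ~small
    if np.any(big):
        r = 1.0 / sigma[big]
        out[big] = stats.nbinom.ppf(prob[big], r, r / (r + mu[big]))
    return np.maximum(out, 0.0).astype(np.int64)[()]


# ---------------------------------------------------------------------------
# bivariate standard normal CDF (Owen's T representation)
# ---------------------------------------------------------------------------

def _owens_t_safe(h, a):
    """Owen's T handling a = +-inf via T(h, inf) = (1 - Phi(|h|)) / 2."""
    h = np.asarray(h, dtype=float)
    a = np.asarray(a, dtype=float)
    fin = np.isfinite(a)
    out = np.empty(np.broadcast_shapes(h.shape, a.shape), dtype=float)
    hb, ab = np.broadcast_arrays(h, a)
    if np.any(fin):
        out[fin] = special.owens_t(hb[fin], ab[fin])
    if np.any(~fin):
        tail = 0.5 * special.ndtr(-np.abs(hb[~fin]))
        out[~fin] = np.sign(ab[~fin]) * tail
    return out


def bvn_cdf(x1, x2, rho):
    """P(Z1 <= x1, Z2 <= x2) for standard bivariate normal with correlation rho.

    Uses Owen's (1956) T-function representation, which is vectorized over
    all three arguments and accurate to ~1e-14 in absolute terms.  The
    result is clamped to the Frechet bounds.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("rho must lie in (-1, 1)")
    x1, x2, rho = np.broadcast_arrays(x1, x2, rho)
    s = np.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (x2 - rho * x1) / (x1 * s)
        a2 = (x1 - rho * x2) / (x2 * s)
        # x = 0 denominators: the limiting argument is +-inf with the sign
        # of the numerator (the both-zero case is overwritten below)
        a1 = np.where(x1 == 0.0, np.inf * np.sign(x2 - rho * x1 + 0.0), a1)
        a2 = np.where(x2 == 0.0, np.inf * np.sign(x1 - rho * x2 + 0.0), a2)
    a1 = np.nan_to_num(a1, nan=0.0, posinf=np.inf, neginf=-np.inf)
    a2 = np.nan_to_num(a2, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p1 = special.ndtr(x1)
    p2 = special.ndtr(x2)
    prod = x1 * x2
    beta = np.where((prod < 0) | ((prod == 0) & (x1 + x2 < 0)), 0.5, 0.0)
    out = 0.5 * (p1 + p2) - _owens_t_safe(x1, a1) - _owens_t_safe(x2, a2) - beta
    both_zero = (x1 == 0.0) & (x2 == 0.0)
    if np.any(both_zero):
        out = np.where(both_zero, 0.25 + np.arcsin(rho) / _TWO_PI, out)
    lower = np.maximum(p1 + p2 - 1.0, 0.0)
    upper = np.minimum(p1, p2)
    return np.clip(out, lower, upper)[()]


def _norm_quantile_of_cdf(f):
    """Phi^-1 of a marginal cdf value, clipped away from {0, 1}."""
    return special.ndtri(np.clip(f, CDF_CLIP, 1.0 - CDF_CLIP))


def _copula_cdf_from_f(f1, f2, rho):
    """Copula cdf given marginal cdf values; zeros stay exactly zero."""
    out = bvn_cdf(_norm_quantile_of_cdf(f1), _norm_quantile_of_cdf(f2), rho)
    return np.where((np.asarray(f1) == 0.0) | (np.asarray(f2) == 0.0), 0.0, out)


def copula_cdf(y1, y2, params: CellParams):
    """Joint cdf G(y1, y2) of the Gaussian copula with NBII marginals.

    ``y = -1`` denotes the empty event and yields 0 exactly.
    """
    params.validate()
    f1 = _nb_cdf_raw(np.floor(np.asarray(y1, dtype=float)), params.mu1, params.sigma1)
    f2 = _nb_cdf_raw(np.floor(np.asarray(y2, dtype=float)), params.mu2, params.sigma2)
    return _copula_cdf_from_f(f1, f2, np.asarray(params.rho, dtype=float))[()]


def _rectangle(f1_hi, f1_lo, f2_hi, f2_lo, rho):
    """pmf mass on the rectangle (y1-1, y1] x (y2-1, y2] from marginal cdfs."""
    g11 = _copula_cdf_from_f(f1_hi, f2_hi, rho)
    g01 = _copula_cdf_from_f(f1_lo, f2_hi, rho)
    g10 = _copula_cdf_from_f(f1_hi, f2_lo, rho)
    g00 = _copula_cdf_from_f(f1_lo, f2_lo, rho)
    r = g11 - g01 - g10 + g00
    bad = r < -RECT_TOL
    if np.any(bad):
        raise ConsistencyError(
            "rectangle probability below -1e-12; bivariate normal CDF "
            f"backend inconsistent (min {np.min(r):g})")
    return np.maximum(r, 0.0)


def _joint_pmf_raw(y1, y2, mu1, sigma1, mu2, sigma2, rho):
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    f1_hi = _nb_cdf_raw(y1, mu1, sigma1)
    f1_lo = _nb_cdf_raw(y1 - 1.0, mu1, sigma1)
    f2_hi = _nb_cdf_raw(y2, mu2, sigma2)
    f2_lo = _nb_cdf_raw(y2 - 1.0, mu2, sigma2)
    return _rectangle(f1_hi, f1_lo, f2_hi, f2_lo, rho)


def joint_pmf(y1, y2, params: CellParams):
    """Pre-dropout joint pmf g(y1, y2) via rectangle differencing of the cdf.

    Tiny negative residuals from floating-point cancellation (magnitude
    below 1e-12) are clamped to zero; anything larger raises
    :class:`ConsistencyError`.
    """
    params.validate()
    y1 = _check_counts(y1)
    y2 = _check_counts(y2)
    return _joint_pmf_raw(
        y1, y2, np.asarray(params.mu1, dtype=float),
        np.asarray(params.sigma1, dtype=float),
        np.asarray(params.mu2, dtype=float),
        np.asarray(params.sigma2, dtype=float),
        np.asarray(params.rho, dtype=float))[()]


def _zi_joint_pmf_raw(y1, y2, mu1, sigma1, mu2, sigma2, rho, p1, p2):
    """Four-branch zero-inflated mixture; all inputs broadcastable arrays."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    g = _joint_pmf_raw(y1, y2, mu1, sigma1, mu2, sigma2, rho)
    q1 = 1.0 - p1
    q2 = 1.0 - p2
    out = q1 * q2 * g
    z1 = y1 == 0
    z2 = y2 == 0
    f1 = _nb_pmf_raw(y1, mu1, sigma1)
    f2 = _nb_pmf_raw(y2, mu2, sigma2)
    # y1 > 0, y2 = 0: gene-2 dropout leaves the gene-1 marginal
    out = out + np.where(~z1 & z2, q1 * p2 * f1, 0.0)
    # y1 = 0, y2 > 0
    out = out + np.where(z1 & ~z2, p1 * q2 * f2, 0.0)
    # both zero
    out = out + np.where(z1 & z2, p1 * p2 + q1 * p2 * f1 + p1 * q2 * f2, 0.0)
    return out


def zi_joint_pmf(y1, y2, params: CellParams):
    """Zero-inflated joint pmf f(y1, y2): dropout-weighted four-branch mixture."""
    params.validate()
    y1 = _check_counts(y1)
    y2 = _check_counts(y2)
    for name in ("p1", "p2"):
        p = np.asarray(getattr(params, name))
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    return _zi_joint_pmf_raw(
        y1, y2,
        np.asarray(params.mu1, dtype=float), np.asarray(params.sigma1, dtype=float),
        np.asarray(params.mu2, dtype=float), np.asarray(params.sigma2, dtype=float),
        np.asarray(params.rho, dtype=float),
        np.asarray(params.p1, dtype=float), np.asarray(params.p2, dtype=float))[()]


def zinb_marginal_pmf(y, mu, sigma, p):
    """Zero-inflated NBII marginal: p + (1-p) f_NB(0) at zero, (1-p) f_NB(y) else."""
    y = _check_counts(y)
    mu, sigma = _check_margin(mu, sigma)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    base = _nb_pmf_raw(y, mu, sigma)
    return (np.where(np.asarray(y) == 0, p, 0.0) + (1.0 - p) * base)[()]
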