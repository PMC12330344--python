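"""Wald inference from the observed penalized Hessian, and BH correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from statsmodels.stats.multitest import multipletests

from .design import THETA, inverse_link
from .fitting import FitResult

__all__ = ["TestResult", "bh_adjust", "natural_scale_rho", "wald"]

_Z95 = float(ndtri(0.975))   # 1.959964; exact quantile keeps p/CI duality


@dataclass
class TestResult:
    """Wald test of one coefficient on its link scale.

    The confidence interval is symmetric about the estimate on the link
    scale; ``natural_ci`` maps its endpoints through the coefficient's
    inverse link (meaningful for intercepts / single-pattern predictors).
    ``ok`` is False when the fit did not converge or the Hessian was
    singular, in which case ``p`` is NaN.
    """

    name: str
    estimate: float
    se: float
    z: float
    p: float
    ci: tuple
    natural_ci: tuple
    ok: bool


def wald(fit: FitResult, coefficient: str) -> TestResult:
    """Two-sided Wald test of a fitted coefficient against zero.

    The standard error comes from the corresponding diagonal entry of the
    inverse negative observed Hessian of the penalized log-likelihood.
    """
    names = fit.coef_names
    if coefficient not in names:
        raise KeyError(f"unknown coefficient {coefficient!r}; "
                       f"available: {names}")
    idx = names.index(coefficient)
    est = float(fit.state.beta[idx])
    param = coefficient.split(".", 1)[0]
    cov = fit.cov()
    var = float(cov[idx, idx]) if np.all(np.isfinite(cov)) else np.nan
    ok = bool(fit.converged) and np.isfinite(var) and var > 0
    if not ok:
        return TestResult(name=coefficient, estimate=est, se=np.nan,
                          z=np.nan, p=np.nan, ci=(np.nan, np.nan),
                          natural_ci=(np.nan, np.nan), ok=False)
    se = float(np.sqrt(var))
    z = est / se
    p = float(2.0 * ndtr(-abs(z)))
    lo, hi = est - _Z95 * se, est + _Z95 * se
    return TestResult(name=coefficient, estimate=est, se=se, z=z, p=p,
                      ci=(lo, hi),
                      natural_ci=(float(inverse_link(param, lo)),
                                  float(inverse_link(param, hi))),
                      ok=True)


def natural_scale_rho(fit: FitResult, x0: float = 0.0, x1: float = 1.0):
    """Population-level co-expression in each group and its absolute change.

    Uses only the fixed coefficients of the rho predictor (random effects
    excluded): rho_g = tanh(tau0 + tau1 * x_g) for a single covariate, or
    the corresponding linear combination for richer patterns.
    """
    d = fit.state.delta[fit.blocks.delta_slices["rho"]]
    k = len(d)
    if k == 1:
        eta0 = eta1 = d[0]
    elif k == 2:
        eta0 = d[0] + d[1] * x0
        eta1 = d[0] + d[1] * x1
    else:
        raise ValueError("natural_scale_rho expects an intercept + one "
                         "covariate rho predictor; evaluate blocks.X['rho'] "
                         "patterns manually for richer models")
    r0 = float(np.tanh(eta0))
    r1 = float(np.tanh(eta1))
    return r0, r1, abs(r1 - r0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs (e.g. from non-converged fits) pass through unchanged and are not
    counted in the correction's denominator.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
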