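"""Generic trust-region maximization with an exact subproblem solver.

The quadratic model built from the gradient and (possibly approximate)
Hessian is maximized exactly inside the trust radius via an eigen
decomposition; the radius shrinks (x0.25) when a step's actual improvement
falls well short of the model's prediction and doubles when the model is
accurate and the step hits the boundary.  Iteration stops once an accepted
step improves the objective, or the model predicts an improvement, by less
than machine epsilon (relative to the objective's magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["TRResult", "solve_tr_subproblem", "trust_region_maximize"]

_EPS = np.finfo(float).eps


@dataclass
class TRResult:
    x: np.ndarray
    fun: float
    grad: np.ndarray
    hess: np.ndarray
    converged: bool
    n_iter: int
    n_accepted: int
    radius: float


def solve_tr_subproblem(g: np.ndarray, H: np.ndarray, radius: float) -> np.ndarray:
    """Maximize g.p + p.H.p/2 subject to ||p|| <= radius (exact, via eigh)."""
    lam, Q = np.linalg.eigh(H)
    a = Q.T @ g
    lam_max = lam[-1]

    def p_of(nu):
        return a / (nu - lam)

    # interior Newton step when the model is strictly concave
    if lam_max < 0:
        p = p_of(0.0)
        if np.linalg.norm(p) <= radius:
            return Q @ p
    nu_lo = max(0.0, lam_max) + 1e-12 * max(1.0, abs(lam_max))
    norm_lo = np.linalg.norm(p_of(nu_lo))
    if norm_lo <= radius:
        # hard case: gradient (nearly) orthogonal to the top eigenspace
        p = p_of(nu_lo)
        t = np.sqrt(max(radius * radius - norm_lo * norm_lo, 0.0))
        return Q @ p + t * Q[:, -1]
    gnorm = np.linalg.norm(g)
    nu_hi = max(0.0, lam_max) + gnorm / radius + 1.0
    while np.linalg.norm(p_of(nu_hi)) > radius:
        nu_hi = 2.0 * nu_hi + 1.0
    nu = brentq(lambda v: 1.0 / radius - 1.0 / np.linalg.norm(p_of(v)),
                nu_lo, nu_hi, xtol=1e-12, rtol=1e-12)
    return Q @ p_of(nu)


def trust_region_maximize(fun, fgh, x0, radius: float = 1.0,
                          max_radius: float = 1e6, max_iter: int = 200,
                          min_radius: float = 1e-13,
                          min_impr_rel: float = _EPS) -> TRResult:
    """Maximize ``fun`` starting at ``x0``.

    ``fun(x)`` returns the objective; ``fgh(x)`` returns (objective,
    gradient, Hessian) and is only called at accepted iterates, so an
    expensive or approximate Hessian (e.g. a score outer-product) can be
    supplied.  Accepted steps always strictly increase the objective.
    ``min_impr_rel`` relaxes the machine-epsilon termination threshold for
    cheap preconditioning phases.
    """
    x = np.asarray(x0, dtype=float).copy()
    f, g, H = fgh(x)
    n_iter = n_acc = 0
    converged = False
    while n_iter < max_iter:
        n_iter += 1
        p = solve_tr_subproblem(g, H, radius)
        pred = g @ p + 0.5 * p @ H @ p
        if pred <= min_impr_rel * max(1.0, abs(f)):
            converged = True
            break
        f_new = fun(x + p)
        actual = f_new - f
        ratio = actual / pred if pred > 0 else -np.inf
        accepted = np.isfinite(f_new) and ratio >= 0.05 and actual > 0
        if accepted:
            x = x + p
            f, g, H = fgh(x)
            n_acc += 1
        if ratio < 0.25:
            radius *= 0.25
        elif ratio > 0.75 and np.linalg.norm(p) >= 0.99 * radius:
            radius = min(2.0 * radius, max_radius)
        if accepted and actual <= min_impr_rel * max(1.0, abs(f)):
            converged = True
            break
        if radius < min_radius:
            converged = bool(np.max(np.abs(g)) < 1e-4)
            break
    return TRResult(x=x, fun=f, grad=g, hess=H, converged=converged,
                    n_iter=n_iter, n_accepted=n_acc, radius=radius)
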