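"""Design matrices, penalty structure, and link functions.

Each of the seven natural parameters theta in {mu1, mu2, sigma1, sigma2,
rho, p1, p2} gets its own linear predictor

    eta_theta = X_theta delta_theta + Z_theta u_theta (+ log S for the means)

with a log link for mu and sigma, atanh for rho, and logit for p.  Random
effects are patient-level (optionally patient-by-condition) intercepts whose
one-hot design rows are standard basis vectors; they are shrunk by a ridge
penalty whose smoothing parameter lambda is shared within each variance
component.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .copula import CellParams
from .data import GenePairData

__all__ = [
    "THETA", "ModelSpec", "ParamSpec", "RandomTerm", "DesignBlocks",
    "CoefState", "build_design", "predict_params", "inverse_link", "link",
]

#: canonical parameter order used for every stacked coefficient vector
THETA = ("mu1", "mu2", "sigma1", "sigma2", "rho", "p1", "p2")

# predictor clipping bounds: logit predictors to [-15, 15], the atanh
# predictor to [-7, 7], log-sigma to [-12, 12] (identifiability guard when a
# margin has no excess zeros), log-mu (including the offset) to [-30, 30]
# as a plain overflow guard.
_CLIPS = {
    "mu1": (-30.0, 30.0), "mu2": (-30.0, 30.0),
    "sigma1": (-12.0, 12.0), "sigma2": (-12.0, 12.0),
    "rho": (-7.0, 7.0),
    "p1": (-15.0, 15.0), "p2": (-15.0, 15.0),
}

_FAMILY = {"mu1": "log", "mu2": "log", "sigma1": "log", "sigma2": "log",
           "rho": "atanh", "p1": "logit", "p2": "logit"}


def clip_eta(param: str, eta):
    lo, hi = _CLIPS[param]
    return np.clip(eta, lo, hi)


def inverse_link(param: str, eta):
    """Map a (clipped) linear predictor to the natural parameter scale."""
    eta = clip_eta(param, np.asarray(eta, dtype=float))
    fam = _FAMILY[param]
    if fam == "log":
        return np.exp(eta)
    if fam == "atanh":
        return np.tanh(eta)
    return expit(eta)


def link(param: str, value):
    """Natural scale -> linear predictor scale (log / atanh / logit)."""
    value = np.asarray(value, dtype=float)
    fam = _FAMILY[param]
    if fam == "log":
        return np.log(value)
    if fam == "atanh":
        return np.arctanh(value)
    return np.log(value / (1.0 - value))


def dparam_deta(param: str, eta):
    """Derivative of the natural parameter w.r.t. its predictor (0 where clipped)."""
    eta = np.asarray(eta, dtype=float)
    lo, hi = _CLIPS[param]
    inside = (eta > lo) & (eta < hi)
    val = inverse_link(param, eta)
    fam = _FAMILY[param]
    if fam == "log":
        d = val
    elif fam == "atanh":
        d = 1.0 - val * val
    else:
        d = val * (1.0 - val)
    return np.where(inside, d, 0.0)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomTerm:
    """Random intercepts over the levels of ``group``.

    ``by=None`` gives one intercept per group level sharing a single
    variance component; ``by=<column>`` gives one intercept per
    (group level, by level) cell with a separate variance component for
    each by level (e.g. separate pre/post variance components).
    """

    group: str
    by: str | None = None


@dataclass(frozen=True)
class ParamSpec:
    fixed: tuple[str, ...] = ()
    random: RandomTerm | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Per-parameter formulae for the seven natural parameters.

    ``offset`` controls whether log sequencing depth enters the mean
    predictors (it never enters the other five).
    """

    params: dict = field(default_factory=dict)
    offset: bool = True

    def __post_init__(self):
        full = {t: self.params.get(t, ParamSpec()) for t in THETA}
        extra = set(self.params) - set(THETA)
        if extra:
            raise ValueError(f"unknown parameters in spec: {sorted(extra)}")
        object.__setattr__(self, "params", full)

    @classmethod
    def two_group(cls, condition: str = "group", patient: str = "patient",
                  random_params=("mu1", "mu2", "rho", "p1", "p2"),
                  by_condition: bool = False, offset: bool = True) -> "ModelSpec":
        """Intercept + condition fixed effects for all seven parameters.

        ``by_condition=True`` mirrors the longitudinal analysis layout:
        patient-by-condition random intercepts with separate variance
        components per condition for the means and rho, plain patient
        intercepts for the dropout probabilities, none for the dispersions.
        """
        params = {}
        for t in THETA:
            rnd = None
            if t in random_params:
                by = condition if (by_condition and t in ("mu1", "mu2", "rho")) else None
                rnd = RandomTerm(group=patient, by=by)
            params[t] = ParamSpec(fixed=(condition,), random=rnd)
        return cls(params=params, offset=offset)

    @classmethod
    def from_formulas(cls, formulas, offset: bool = True) -> "ModelSpec":
        """Build a spec from per-parameter formula strings.

        Accepts an iterable of strings (or a newline-separated string), one
        per parameter, e.g.::

            mu1 ~ group + (1 | patient)
            rho ~ group + (group | patient)
            sigma1 ~ group

        Grammar: right-hand terms separated by ``+``; ``1`` denotes the
        (always present) intercept; ``(1 | g)`` adds random intercepts over
        the levels of ``g`` with one shared variance component;
        ``(f | g)`` adds one intercept per (g, f-level) cell with a
        separate variance component per level of ``f``.  Parameters not
        mentioned get an intercept-only predictor.
        """
        if isinstance(formulas, str):
            formulas = [ln for ln in formulas.splitlines() if ln.strip()]
        params = {}
        for line in formulas:
            if "~" not in line:
                raise ValueError(f"formula must contain '~': {line!r}")
            lhs, rhs = line.split("~", 1)
            name = lhs.strip()
            if name not in THETA:
                raise ValueError(f"unknown parameter {name!r} in formula")
            fixed: list[str] = []
            random = None
            for term in _split_terms(rhs):
                m = re.fullmatch(r"\((.+)\|(.+)\)", term.replace(" ", ""))
                if m:
                    if random is not None:
                        raise ValueError(f"multiple random terms in {line!r}")
                    inner, group = m.group(1), m.group(2)
                    random = RandomTerm(group=group,
                                        by=None if inner == "1" else inner)
                elif term in ("1", "0"):
                    continue
                else:
                    fixed.append(term)
            params[name] = ParamSpec(fixed=tuple(fixed), random=random)
        return cls(params=params, offset=offset)

    def replace_param(self, name: str, spec: ParamSpec) -> "ModelSpec":
        new = dict(self.params)
        new[name] = spec
        return replace(self, params=new)


def _split_terms(rhs: str) -> list[str]:
    terms, depth, cur = [], 0, []
    for ch in rhs:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "+" and depth == 0:
            terms.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    if cur:
        terms.append("".join(cur).strip())
    return [t for t in terms if t]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignBlocks:
    """Assembled fixed/random design matrices and penalty layout."""

    n: int
    X: dict
    xnames: dict
    Z: dict
    znames: dict
    zcomp: dict          # per-theta int array: random column -> component id
    comp_names: list
    offset: dict         # per-theta offset vector (log S for the means)

    def __post_init__(self):
        self.delta_slices = {}
        self.u_slices = {}
        pos = 0
        for t in THETA:
            k = self.X[t].shape[1]
            self.delta_slices[t] = slice(pos, pos + k)
            pos += k
        self.n_delta = pos
        pos = 0
        for t in THETA:
            r = self.Z[t].shape[1]
            self.u_slices[t] = slice(pos, pos + r)
            pos += r
        self.n_u = pos
        self.n_comp = len(self.comp_names)

    @property
    def n_coef(self) -> int:
        return self.n_delta + self.n_u

    @property
    def coef_names(self) -> list:
        names = []
        for t in THETA:
            names += [f"{t}.{c}" for c in self.xnames[t]]
        for t in THETA:
            names += [f"{t}.{c}" for c in self.znames[t]]
        return names

    def comp_indices(self) -> list:
        """Global beta indices of the random coefficients in each component."""
        out = [[] for _ in range(self.n_comp)]
        for t in THETA:
            s = self.u_slices[t]
            for local, cid in enumerate(self.zcomp[t]):
                out[cid].append(self.n_delta + s.start + local)
        return [np.asarray(ix, dtype=int) for ix in out]

    def penalty_diag(self, lam: np.ndarray) -> np.ndarray:
        """Per-coefficient ridge weights (0 for fixed effects)."""
        d = np.zeros(self.n_coef)
        for t in THETA:
            s = self.u_slices[t]
            if s.stop > s.start:
                d[self.n_delta + s.start:self.n_delta + s.stop] = lam[self.zcomp[t]]
        return d

    def eta(self, state: "CoefState") -> np.ndarray:
        """(n, 7) matrix of linear predictors (offsets included, no clipping)."""
        out = np.empty((self.n, len(THETA)))
        for j, t in enumerate(THETA):
            e = self.X[t] @ state.delta[self.delta_slices[t]]
            if self.Z[t].shape[1]:
                e = e + self.Z[t] @ state.u[self.u_slices[t]]
            out[:, j] = e + self.offset[t]
        return out

    def global_designs(self) -> np.ndarray:
        """(7, n, P) stacked per-parameter designs in global coefficient layout."""
        P = self.n_coef
        W = np.zeros((len(THETA), self.n, P))
        for j, t in enumerate(THETA):
            W[j, :, self.delta_slices[t]] = self.X[t]
            s = self.u_slices[t]
            if s.stop > s.start:
                W[j, :, self.n_delta + s.start:self.n_delta + s.stop] = self.Z[t]
        return W


@dataclass
class CoefState:
    """Stacked fixed (delta) and random (u) coefficients plus smoothing lambda."""

    delta: np.ndarray
    u: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if np.any(self.lam < 0):
            raise ValueError("lambda must be non-negative")

    @property
    def beta(self) -> np.ndarray:
        return np.concatenate([self.delta, self.u])

    @classmethod
    def from_beta(cls, beta: np.ndarray, blocks: DesignBlocks,
                  lam: np.ndarray) -> "CoefState":
        beta = np.asarray(beta, dtype=float)
        return cls(delta=beta[:blocks.n_delta].copy(),
                   u=beta[blocks.n_delta:].copy(), lam=np.asarray(lam, float))

    def copy(self) -> "CoefState":
        return CoefState(self.delta.copy(), self.u.copy(), self.lam.copy())


def _fixed_columns(data: GenePairData, cols: tuple[str, ...]):
    """Intercept-first fixed design; categoricals coded against the first
    metadata-sorted level."""
    n = data.n_cells
    mats = [np.ones((n, 1))]
    names = ["(Intercept)"]
    for col in cols:
        values = _resolve_column(data, col)
        arr = np.asarray(values)
        if arr.dtype.kind in "ifu" and arr.dtype.kind != "b":
            bad = ~np.isfinite(arr.astype(float))
            if bad.any():
                raise ValueError(
                    f"covariate {col!r} missing for {data.cell_label(int(np.argmax(bad)))}")
            mats.append(arr.astype(float)[:, None])
            names.append(col)
        else:
            if pd.isna(pd.Series(arr)).any():
                i = int(np.argmax(pd.isna(pd.Series(arr)).to_numpy()))
                raise ValueError(
                    f"covariate {col!r} missing for {data.cell_label(i)}")
            levels = sorted(pd.unique(arr).tolist(), key=str)
            for lvl in levels[1:]:
                mats.append((arr == lvl).astype(float)[:, None])
                names.append(col if len(levels) == 2 else f"{col}[{lvl}]")
    return np.hstack(mats), names


def _resolve_column(data: GenePairData, col: str):
    if col == "patient":
        return data.patient
    if col in data.covariates.columns:
        return data.covariates[col].to_numpy()
    raise ValueError(f"covariate column {col!r} not found in metadata")


def _random_columns(data: GenePairData, term: RandomTerm, param: str,
                    comp_names: list):
    group = np.asarray(_resolve_column(data, term.group))
    if pd.isna(pd.Series(group)).any():
        i = int(np.argmax(pd.isna(pd.Series(group)).to_numpy()))
        raise ValueError(f"grouping factor {term.group!r} missing for "
                         f"{data.cell_label(i)}")
    glevels = list(pd.unique(group))        # first-appearance order
    gindex = {g: k for k, g in enumerate(glevels)}
    n = data.n_cells
    if term.by is None:
        Z = np.zeros((n, len(glevels)))
        Z[np.arange(n), [gindex[g] for g in group]] = 1.0
        cid = len(comp_names)
        comp_names.append(f"{param}|{term.group}")
        comp = np.full(len(glevels), cid, dtype=int)
        names = [f"{term.group}[{g}]" for g in glevels]
        return Z, names, comp
    by = np.asarray(_resolve_column(data, term.by))
    blevels = sorted(pd.unique(by).tolist(), key=str)
    cols, names, comp = [], [], []
    for lvl in blevels:
        cid = len(comp_names)
        comp_names.append(f"{param}|{term.group}:{term.by}={lvl}")
        for g in glevels:
            cols.append(((group == g) & (by == lvl)).astype(float))
            names.append(f"{term.group}[{g}]:{term.by}={lvl}")
            comp.append(cid)
    return np.column_stack(cols), names, np.asarray(comp, dtype=int)


def build_design(data: GenePairData, spec: ModelSpec) -> DesignBlocks:
    """Build per-parameter fixed/random designs, offsets, and penalty map.

    Column ordering is deterministic: intercept first, covariates in spec
    order (categorical levels metadata-sorted), random-effect levels in
    first-appearance order.
    """
    X, xnames, Z, znames, zcomp, offs = {}, {}, {}, {}, {}, {}
    comp_names: list = []
    log_s = np.log(data.depth)
    for t in THETA:
        ps = spec.params[t]
        X[t], xnames[t] = _fixed_columns(data, ps.fixed)
        if ps.random is None:
            Z[t] = np.zeros((data.n_cells, 0))
            znames[t] = []
            zcomp[t] = np.zeros(0, dtype=int)
        else:
            Z[t], znames[t], zcomp[t] = _random_columns(
                data, ps.random, t, comp_names)
        offs[t] = log_s if (spec.offset and t in ("mu1", "mu2")) \
            else np.zeros(data.n_cells)
    return DesignBlocks(n=data.n_cells, X=X, xnames=xnames, Z=Z,
                        znames=znames, zcomp=zcomp, comp_names=comp_names,
                        offset=offs)


def predict_params(blocks: DesignBlocks, state: CoefState,
                   cell_index=None) -> CellParams:
    """Map coefficients to per-cell natural parameters via the inverse links."""
    eta = blocks.eta(state)
    if cell_index is not None:
        eta = eta[np.atleast_1d(cell_index)]
    vals = {t: inverse_link(t, eta[:, j]) for j, t in enumerate(THETA)}
    if cell_index is not None and np.isscalar(cell_index):
        vals = {k: v[0] for k, v in vals.items()}
    return CellParams(**vals)
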