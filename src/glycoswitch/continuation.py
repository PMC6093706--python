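"""Steady states, branch continuation, folds and cusps.

The bifurcation machinery used throughout: multi-start steady-state
location with stability from the Jacobian spectrum, pseudo-arclength
predictor–corrector continuation of one-parameter steady-state
branches with saddle-node (fold / limit-point) detection, refinement of
folds by the bordered extended system

    F(y, p) = 0,   J(y, p) v = 0,   ||v||^2 = 1,

two-parameter continuation of the fold locus, and cusp detection along
it by the sign change of the quadratic normal-form coefficient
w . D^2F(v, v) (w, v the left/right null vectors of J).

All routines operate on any object exposing ``n``, ``species``,
``default_params()`` and ``rhs_vec(y, params)``; the lightweight
:class:`UserModel` adapter wraps a plain callable (used, e.g., for the
saddle-node and cusp normal forms in the test-suite).  Jacobians are
central finite differences — the models are smooth rational functions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import brentq, root

log = logging.getLogger("glycoswitch.continuation")

__all__ = [
    "SteadyState",
    "FoldPoint",
    "BranchPoint",
    "BifurcationBranch",
    "CuspPoint",
    "FoldCurve",
    "TangencyResult",
    "UserModel",
    "find_steady_states",
    "continue_branch",
    "tangency_solve",
    "continue_fold_curve",
]

RESIDUAL_TOL = 1e-9          # ||rhs|| at accepted steady states
FOLD_EIG_TOL = 1e-7          # |leading eigenvalue| at a refined fold
DEDUP_TOL = 1e-6             # pairwise distance between distinct roots


@dataclass
class UserModel:
    """Adapter giving a plain callable the model interface.

    ``f(y, params) -> ndarray`` with ``params`` a complete dict of the
    named parameters.
    """

    f: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
    n: int
    params: dict[str, float]
    species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.species:
            self.species = tuple(f"y{i}" for i in range(self.n))

    def default_params(self) -> dict[str, float]:
        return dict(self.params)

    def rhs_vec(self, y: np.ndarray,
                params: Mapping[str, float] | None = None) -> np.ndarray:
        p = dict(self.params)
        if params:
            p.update(params)
        return np.asarray(self.f(np.asarray(y, dtype=float), p), dtype=float)


@dataclass
class SteadyState:
    """A root of the right-hand side with its local stability."""

    state: np.ndarray
    params: dict[str, float]
    stability: str                 # "stable" | "unstable"
    leading_eigenvalue: float
    species: tuple[str, ...] = ()

    @property
    def concentrations(self) -> dict[str, float]:
        return dict(zip(self.species, self.state.tolist()))


@dataclass
class FoldPoint:
    """A saddle-node: rhs = 0 with a one-dimensional Jacobian null space."""

    param_name: str
    param: float
    state: np.ndarray
    null_vector: np.ndarray
    params: dict[str, float] = field(default_factory=dict)


@dataclass
class BranchPoint:
    param: float
    state: np.ndarray
    stability: str
    leading_eigenvalue: float


@dataclass
class BifurcationBranch:
    """An ordered one-parameter steady-state branch with its folds."""

    param_name: str
    points: list[BranchPoint]
    folds: list[FoldPoint]
    status: str = "ok"            # "ok" | "truncated"

    @property
    def fold_params(self) -> list[float]:
        return sorted(f.param for f in self.folds)


@dataclass
class CuspPoint:
    """Codimension-2 point where two fold branches coalesce."""

    param_names: tuple[str, str]
    params: tuple[float, float]
    state: np.ndarray


@dataclass
class FoldCurvePoint:
    p1: float
    p2: float
    state: np.ndarray
    null_vector: np.ndarray
    cusp_test: float


@dataclass
class FoldCurve:
    param_names: tuple[str, str]
    points: list[FoldCurvePoint]
    cusps: list[CuspPoint]
    status: str = "ok"


# ---------------------------------------------------------------------------
# derivatives

def jacobian(model, y: np.ndarray, params: Mapping[str, float],
             rel_step: float = 1e-7) -> np.ndarray:
    """Central-difference Jacobian of rhs with respect to the state."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    J = np.empty((n, n))
    for i in range(n):
        h = rel_step * (1.0 + abs(y[i]))
        yp, ym = y.copy(), y.copy()
        yp[i] += h
        ym[i] -= h
        J[:, i] = (model.rhs_vec(yp, params) - model.rhs_vec(ym, params)) / (2 * h)
    return J


def _dfdp(model, y, params, name, rel_step=1e-7):
    p = dict(params)
    h = rel_step * (1.0 + abs(p[name]))
    pp, pm = dict(p), dict(p)
    pp[name] = p[name] + h
    pm[name] = p[name] - h
    return (model.rhs_vec(y, pp) - model.rhs_vec(y, pm)) / (2 * h)


def _jv(model, y, params, v, rel_step=1e-6):
    """Directional derivative J(y) v by central differences."""
    h = rel_step / max(np.linalg.norm(v), 1e-12)
    return (model.rhs_vec(y + h * v, params)
            - model.rhs_vec(y - h * v, params)) / (2 * h)


def _d2f_vv(model, y, params, v, rel_step=1e-4):
    """Second directional derivative D^2F(v, v)."""
    h = rel_step * (1.0 + np.linalg.norm(y)) / max(np.linalg.norm(v), 1e-12)
    return (model.rhs_vec(y + h * v, params) - 2.0 * model.rhs_vec(y, params)
            + model.rhs_vec(y - h * v, params)) / (h * h)


def _stability(model, y, params) -> tuple[str, float]:
    J = jacobian(model, y, params)
    lead = float(np.max(np.linalg.eigvals(J).real))
    return ("stable" if lead < 0 else "unstable"), lead


# ---------------------------------------------------------------------------
# steady states

def find_steady_states(model, params: Mapping[str, float] | None = None,
                       box: Sequence[tuple[float, float]] | None = None,
                       n_starts: int = 40, seed: int = 0,
                       dense_scan: bool | None = None) -> list[SteadyState]:
    """Locate and classify the steady states inside a search box.

    Multi-start Newton (scipy's hybrid method) from quasi-random points
    in ``box``; for one-dimensional models a dense sign-change scan of
    the rhs supplements (and in practice guarantees) the root set.
    Roots closer than the deduplication tolerance are merged.  An empty
    list (no root found) is a valid result, not an error.
    """
    p = model.default_params()
    if params:
        p.update({k: float(v) for k, v in params.items()})
    n = model.n
    if box is None:
        box = [(0.0, 10.0)] * n
    box = [(float(lo), float(hi)) for lo, hi in box]
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    roots: list[np.ndarray] = []

    def _accept(y: np.ndarray) -> None:
        if np.linalg.norm(model.rhs_vec(y, p)) >= RESIDUAL_TOL:
            return
        for r in roots:
            if np.linalg.norm(r - y) <= DEDUP_TOL:
                return
        roots.append(y)

    if dense_scan is None:
        dense_scan = n == 1
    if dense_scan and n == 1:
        lo, hi = box[0]
        grid = np.linspace(lo, hi, 4001)
        vals = np.array([model.rhs_vec(np.array([g]), p)[0] for g in grid])
        for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
            b = brentq(lambda x: model.rhs_vec(np.array([x]), p)[0],
                       grid[i], grid[i + 1], xtol=1e-13)
            _accept(np.array([b]))
        for i in np.flatnonzero(vals == 0.0):
            _accept(np.array([grid[i]]))

    rng = np.random.default_rng(seed)
    for k in range(n_starts):
        y0 = np.array([lo + rng.random() * (hi - lo) for lo, hi in box])
        sol = root(lambda y: model.rhs_vec(y, p), y0, method="hybr",
                   options={"xtol": 1e-12})
        if sol.success:
            _accept(sol.x)
        # concentrations span orders of magnitude in the stiff network
        # systems; a log-space Levenberg-Marquardt pass finds the roots
        # that plain Newton misses from uniform starts
        if all(lo >= 0 for lo, _ in box):
            floors = np.array([max(lo, 1e-6 * max(hi, 1.0)) for lo, hi in box])
            x0 = rng.uniform(np.log(floors), np.log([hi for _, hi in box]))
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                sol = root(lambda x: model.rhs_vec(np.exp(np.clip(x, -700, 700)), p),
                           x0, method="lm")
                _accept(np.exp(np.clip(sol.x, -700, 700)))

    out = []
    for r in sorted(roots, key=lambda x: tuple(x)):
        stab, lead = _stability(model, r, p)
        out.append(SteadyState(state=r, params=dict(p), stability=stab,
                               leading_eigenvalue=lead, species=model.species))
    return out


def _newton_corrector(residual: Callable[[np.ndarray], np.ndarray],
                      z0: np.ndarray, tol: float = 1e-11,
                      max_iter: int = 10) -> np.ndarray | None:
    """Damped-free Newton on a square system with FD Jacobian."""
    z = z0.copy()
    m = len(z)
    for _ in range(max_iter):
        r = residual(z)
        if np.linalg.norm(r) < tol:
            return z
        Jm = np.empty((m, m))
        for i in range(m):
            h = 1e-7 * (1.0 + abs(z[i]))
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            Jm[:, i] = (residual(zp) - residual(zm)) / (2 * h)
        try:
            dz = np.linalg.solve(Jm, -r)
        except np.linalg.LinAlgError:
            return None
        z = z + dz
        if not np.all(np.isfinite(z)):
            return None
    return z if np.linalg.norm(residual(z)) < 10 * tol else None


def _refine_fold(model, y_guess, p_all: dict, pname: str,
                 tol: float = 1e-10) -> FoldPoint | None:
    """Solve the bordered system {F=0, Jv=0, ||v||^2=1} for a fold."""
    n = model.n
    p_all = dict(p_all)
    J = jacobian(model, y_guess, {**p_all})
    _, _, vt = np.linalg.svd(J)
    v0 = vt[-1]

    def residual(u):
        y, v, pv = u[:n], u[n:2 * n], u[2 * n]
        pars = {**p_all, pname: pv}
        return np.concatenate([
            model.rhs_vec(y, pars),
            _jv(model, y, pars, v),
            [v @ v - 1.0],
        ])

    u0 = np.concatenate([y_guess, v0, [p_all[pname]]])
    u = _newton_corrector(residual, u0, tol=tol, max_iter=25)
    if u is None:
        return None
    y, v, pv = u[:n], u[n:2 * n], u[2 * n]
    pars = {**p_all, pname: float(pv)}
    eigs = np.linalg.eigvals(jacobian(model, y, pars))
    if np.min(np.abs(eigs)) > FOLD_EIG_TOL:
        log.debug("fold refinement rejected: min |eig| = %g", np.min(np.abs(eigs)))
        return None
    return FoldPoint(param_name=pname, param=float(pv), state=y,
                     null_vector=v / np.linalg.norm(v), params=pars)


def continue_branch(model, param: str, prange: tuple[float, float],
                    y0: Sequence[float] | None = None,
                    params: Mapping[str, float] | None = None,
                    ds0: float = 1e-2, ds_min: float = 1e-6,
                    ds_max: float = 5e-2, max_steps: int = 5000,
                    ) -> BifurcationBranch:
    """Trace a steady-state branch through folds by pseudo-arclength.

    ``prange`` is traversed from its first to its second entry; the
    branch may fold back inside the interval and is followed until the
    parameter leaves it (or ``max_steps``).  Folds are detected by a
    sign change of det J along the branch and refined by the bordered
    extended system.
    """
    p_all = model.default_params()
    if params:
        p_all.update({k: float(v) for k, v in params.items()})
    if param not in p_all:
        raise ValueError(f"unknown parameter {param!r}")
    p_start, p_end = float(prange[0]), float(prange[1])
    lo, hi = min(p_start, p_end), max(p_start, p_end)
    n = model.n

    # correct the initial point
    p_all[param] = p_start
    if y0 is None:
        cands = find_steady_states(model, p_all, box=[(0.0, 10.0)] * n)
        if not cands:
            raise ValueError("no steady state found at the start of the range")
        y = cands[0].state
    else:
        sol = root(lambda yy: model.rhs_vec(yy, p_all), np.asarray(y0, float),
                   method="hybr", options={"xtol": 1e-13})
        if not sol.success or np.linalg.norm(model.rhs_vec(sol.x, p_all)) > RESIDUAL_TOL:
            raise ValueError("initial point does not correct to a steady state")
        y = sol.x

    def F(y, pv):
        return model.rhs_vec(y, {**p_all, param: pv})

    def jac(y, pv):
        return jacobian(model, y, {**p_all, param: pv})

    # initial tangent from the branch ODE dy/dp = -J^{-1} F_p
    J = jac(y, p_start)
    fp = _dfdp(model, y, {**p_all, param: p_start}, param)
    try:
        dydp = np.linalg.solve(J, -fp)
        t = np.concatenate([dydp, [1.0]])
    except np.linalg.LinAlgError:
        t = np.concatenate([np.zeros(n), [1.0]])
    t /= np.linalg.norm(t)
    if t[-1] * np.sign(p_end - p_start) < 0:
        t = -t

    stab, lead = _stability(model, y, {**p_all, param: p_start})
    points = [BranchPoint(p_start, y.copy(), stab, lead)]
    folds: list[FoldPoint] = []
    status = "ok"
    z = np.concatenate([y, [p_start]])
    det_prev = float(np.linalg.det(J))
    ds = ds0

    for step in range(max_steps):
        z_pred = z + ds * t

        def residual(u):
            return np.concatenate([F(u[:n], u[n]), [t @ (u - z_pred)]])

        z_new = _newton_corrector(residual, z_pred, tol=1e-11, max_iter=8)
        if z_new is not None and np.linalg.norm(z_new - z) > 3.0 * ds:
            z_new = None  # corrector wandered onto another branch
        if z_new is None:
            if ds > ds_min:
                ds = max(ds / 2.0, ds_min)
                continue
            status = "truncated"
            log.warning("branch truncated at %s = %g (corrector failure)",
                        param, z[n])
            break
        y_new, p_new = z_new[:n], float(z_new[n])
        J_new = jac(y_new, p_new)
        det_new = float(np.linalg.det(J_new))
        if det_prev * det_new < 0:
            mid = 0.5 * (z + z_new)
            fold = _refine_fold(model, mid[:n], {**p_all, param: mid[n]}, param)
            if fold is not None and lo - 1e-9 <= fold.param <= hi + 1e-9:
                duplicate = any(
                    abs(f.param - fold.param) < 1e-6
                    and np.linalg.norm(f.state - fold.state) < 1e-5
                    for f in folds
                )
                if not duplicate:
                    folds.append(fold)
                    log.debug("fold at %s = %.9g", param, fold.param)
        lead = float(np.max(np.linalg.eigvals(J_new).real))
        stab = "stable" if lead < 0 else "unstable"
        points.append(BranchPoint(p_new, y_new.copy(), stab, lead))
        t_new = (z_new - z) / np.linalg.norm(z_new - z)
        z, t, det_prev = z_new, t_new, det_new
        ds = min(ds * 1.3, ds_max)
        if p_new > hi + 1e-9 or p_new < lo - 1e-9:
            break
    else:
        status = "truncated"

    return BifurcationBranch(param_name=param, points=points, folds=folds,
                             status=status)


@dataclass
class TangencyResult:
    """Roots of the tangency condition dv_enz/db = -K and mapped b0."""

    b_star: tuple[float, ...]
    b0_at_tangency: tuple[float, ...]

    def __bool__(self) -> bool:
        return len(self.b_star) >= 2


def tangency_solve(model, params: Mapping[str, float] | None = None,
                   ) -> TangencyResult:
    """Fold parameters of the 1-D model from the tangency geometry.

    A steady state folds where the line K(b0 - b) is tangent to the
    velocity curve, i.e. where dv_enz/db = -K.  With v_enz a rational
    function with quadratic denominator this reduces to a quartic

        Vmax a (c0 - c2 b^2) + K (c0 + c1 b + c2 b^2)^2 = 0,

    solved exactly via its companion matrix.  Each tangency root b*
    maps to the fold parameter b0 = b* + v_enz(b*)/K.  Fewer than two
    positive real roots means the velocity curve is effectively
    Michaelian at this K: no bistability, empty result.
    """
    p = model.default_params()
    if params:
        p.update({k: float(v) for k, v in params.items()})
    c0, c1, c2 = model._denominator_coeffs(p)
    va = model.Vmax * p["a"]
    K = p["K"]
    poly = K * npoly.polypow([c0, c1, c2], 2)
    poly[0] += va * c0
    poly[2] -= va * c2
    roots = npoly.polyroots(poly)
    b_star = sorted(float(r.real) for r in roots
                    if abs(r.imag) < 1e-10 * max(1.0, abs(r)) and r.real > 0)
    if len(b_star) < 2:
        return TangencyResult(b_star=(), b0_at_tangency=())
    b0 = tuple(b + model.v_enz(b, p) / K for b in b_star)
    return TangencyResult(b_star=tuple(b_star), b0_at_tangency=b0)


# ---------------------------------------------------------------------------
# two-parameter fold curves and cusps

def _fold_system(model, p_all: dict, p1: str, p2: str):
    """Residual G(u) of the fold locus, u = (y, v, p1, p2)."""
    n = model.n

    def G(u):
        y, v = u[:n], u[n:2 * n]
        pars = {**p_all, p1: u[2 * n], p2: u[2 * n + 1]}
        return np.concatenate([
            model.rhs_vec(y, pars),
            _jv(model, y, pars, v),
            [v @ v - 1.0],
        ])

    return G


def _cusp_test(model, u, p_all, p1, p2):
    """Quadratic normal-form coefficient w . D^2F(v, v) at a fold point."""
    n = model.n
    y, v = u[:n], u[n:2 * n]
    pars = {**p_all, p1: u[2 * n], p2: u[2 * n + 1]}
    J = jacobian(model, y, pars)
    U, _, _ = np.linalg.svd(J)
    w = U[:, -1]
    # orient w continuously along the curve: at a saddle-node the zero
    # eigenvalue is algebraically simple, so w . v never vanishes there
    if w @ v < 0:
        w = -w
    return float(w @ _d2f_vv(model, y, pars, v))


def _curve_tangent(G, u, prev_t=None):
    """Unit tangent of the fold curve: null vector of DG(u)."""
    m = len(u)
    DG = np.empty((m - 1, m))
    for i in range(m):
        h = 1e-7 * (1.0 + abs(u[i]))
        up, um = u.copy(), u.copy()
        up[i] += h
        um[i] -= h
        DG[:, i] = (G(up) - G(um)) / (2 * h)
    _, _, vt = np.linalg.svd(DG)
    t = vt[-1]
    if prev_t is not None and t @ prev_t < 0:
        t = -t
    return t / np.linalg.norm(t)


def continue_fold_curve(model, fold: FoldPoint,
                        params: tuple[str, str],
                        ranges: Mapping[str, tuple[float, float]],
                        params_base: Mapping[str, float] | None = None,
                        ds0: float = 5e-3, ds_min: float = 1e-7,
                        ds_max: float = 5e-2, max_steps: int = 4000,
                        ) -> FoldCurve:
    """Trace the saddle-node locus in a two-parameter plane.

    Starting from a refined fold of a one-parameter branch, the
    extended system {F = 0, Jv = 0, ||v||^2 = 1} is continued by
    pseudo-arclength in the (p1, p2) plane, in both directions, until a
    parameter leaves its range.  Along the curve the cusp test function
    w . D^2F(v, v) is monitored; a sign change is refined by bisection
    along the curve and reported as a :class:`CuspPoint`.
    """
    p1, p2 = params
    p_all = model.default_params()
    if params_base:
        p_all.update({k: float(v) for k, v in params_base.items()})
    if fold.params:
        for k, v in fold.params.items():
            if k in p_all and k not in (p1, p2):
                p_all[k] = v
    n = model.n
    G = _fold_system(model, p_all, p1, p2)

    # assemble and re-correct the starting point in the extended space
    start_p1 = fold.params.get(p1, p_all[p1]) if fold.param_name != p1 else fold.param
    start_p2 = fold.params.get(p2, p_all[p2]) if fold.param_name != p2 else fold.param
    u0 = np.concatenate([fold.state, fold.null_vector, [start_p1, start_p2]])
    if np.linalg.norm(G(u0)) > 1e-8:
        # re-refine the fold in p1 at fixed p2
        refined = _refine_fold(model, fold.state,
                               {**p_all, p1: start_p1, p2: start_p2}, p1)
        if refined is None:
            raise ValueError("starting fold does not satisfy the extended system")
        u0 = np.concatenate([refined.state, refined.null_vector,
                             [refined.param, start_p2]])

    def in_range(u):
        for name, idx in ((p1, 2 * n), (p2, 2 * n + 1)):
            lo, hi = ranges.get(name, (-np.inf, np.inf))
            if not (lo - 1e-9 <= u[idx] <= hi + 1e-9):
                return False
        return True

    cusps: list[CuspPoint] = []
    status = "ok"

    def trace(direction: float) -> list[FoldCurvePoint]:
        nonlocal status
        u = u0.copy()
        t = _curve_tangent(G, u) * direction
        c = _cusp_test(model, u, p_all, p1, p2)
        pts = [FoldCurvePoint(float(u[2 * n]), float(u[2 * n + 1]),
                              u[:n].copy(), u[n:2 * n].copy(), c)]
        ds = ds0
        for _ in range(max_steps):
            u_pred = u + ds * t

            def residual(w):
                return np.concatenate([G(w), [t @ (w - u_pred)]])

            u_new = _newton_corrector(residual, u_pred, tol=1e-10, max_iter=8)
            if u_new is not None and np.linalg.norm(u_new - u) > 3.0 * ds:
                u_new = None  # corrector wandered off the local curve segment
            if u_new is None:
                if ds > ds_min:
                    ds = max(ds / 2.0, ds_min)
                    continue
                status = "truncated"
                log.warning("fold curve truncated at (%s, %s) = (%g, %g)",
                            p1, p2, u[2 * n], u[2 * n + 1])
                break
            c_new = _cusp_test(model, u_new, p_all, p1, p2)
            if c_new * pts[-1].cusp_test < 0:
                cusp = _bisect_cusp(model, G, u, u_new, p_all, p1, p2)
                if cusp is not None:
                    cusps.append(cusp)
                    log.debug("cusp at (%s, %s) = (%.6g, %.6g)",
                              p1, p2, cusp.params[0], cusp.params[1])
            t = (u_new - u) / np.linalg.norm(u_new - u)
            u = u_new
            pts.append(FoldCurvePoint(float(u[2 * n]), float(u[2 * n + 1]),
                                      u[:n].copy(), u[n:2 * n].copy(), c_new))
            ds = min(ds * 1.3, ds_max)
            if not in_range(u):
                break
        return pts

    fwd = trace(+1.0)
    bwd = trace(-1.0)
    points = bwd[::-1] + fwd[1:]
    return FoldCurve(param_names=(p1, p2), points=points, cusps=cusps,
                     status=status)


def _bisect_cusp(model, G, u_a, u_b, p_all, p1, p2,
                 tol: float = 1e-11, max_iter: int = 60) -> CuspPoint | None:
    """Refine a cusp bracketed between two fold-curve points."""
    n = model.n
    c_a = _cusp_test(model, u_a, p_all, p1, p2)
    c_b = _cusp_test(model, u_b, p_all, p1, p2)
    if c_a * c_b > 0:
        return None
    for _ in range(max_iter):
        t = (u_b - u_a)
        norm = np.linalg.norm(t)
        if norm < tol:
            break
        t = t / norm
        u_mid = 0.5 * (u_a + u_b)

        def residual(w):
            return np.concatenate([G(w), [t @ (w - u_mid)]])

        u_m = _newton_corrector(residual, u_mid, tol=1e-11, max_iter=10)
        if u_m is None:
            u_m = u_mid  # fall back on the secant midpoint
        c_m = _cusp_test(model, u_m, p_all, p1, p2)
        if c_a * c_m <= 0:
            u_b, c_b = u_m, c_m
        else:
            u_a, c_a = u_m, c_m
    u = 0.5 * (u_a + u_b)
    return CuspPoint(param_names=(p1, p2),
                     params=(float(u[2 * n]), float(u[2 * n + 1])),
                     state=u[:n].copy())
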