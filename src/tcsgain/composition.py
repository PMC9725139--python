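"""Composition of the activation, binding and transcription modules.

The closed loop is opened into the chain F(B(A(R_T*))): activation yields the
phosphorylated pool, binding competition yields the free pool, transcription
yields the production level.  Fixed points of the composed map are the steady
states of

    (1/k_dil) dR_T*/dt = F(B(A(R_T*))) - R_T*

and the open-loop log gain LG_3 = LG_F * LG_B * LG_A evaluated at a fixed point
decides its stability (LG_3 > 1 at a fixed point implies instability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .autoregulation import (
    NegativeFeedbackParams,
    coupled_lg_C,
    lg_F,
    production_coupled,
    production_F,
)
from .binding import lg_B, promoter_occupancy, solve_Rf
from .core_params import ConfigurationError, InvalidParameterError, SystemParams
from .phosphorylation import lg_A, rp_approx

_DEGENERATE_TOL = 1e-8


@dataclass
class LGProfile:
    """Per-grid-point gains of the three modules and their product."""

    R_T_grid: np.ndarray
    R_P_star: np.ndarray
    R_f_star: np.ndarray
    LG_A: np.ndarray
    LG_B: np.ndarray
    LG_F: np.ndarray
    LG_3: np.ndarray
    max_LG_3: float
    argmax_R_T_star: float


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of the composed map with its stability label."""

    R_T_star: float
    R_P_star: float
    R_f_star: float
    production: float
    LG_3_at_point: float
    stability: str  # "stable" | "unstable" | "degenerate"


@dataclass
class Bifurcation:
    """Steady-state branches over a Cp* sweep."""

    Cp_grid: np.ndarray
    states: list  # list[list[SteadyState]] parallel to Cp_grid
    bistable_interval: Optional[tuple]  # (Cp_low, Cp_high) or None
    saddle_node_points: list = field(default_factory=list)
    occupancy: Optional[dict] = None  # branch name -> array over Cp_grid


@dataclass
class PhaseDiagram:
    axis1_name: str
    axis1_grid: np.ndarray
    axis2_name: str
    axis2_grid: np.ndarray
    mode: str
    values: np.ndarray  # shape (len(axis2), len(axis1)); row-major over axis2
    contour_at_1: list  # list of (n, 2) arrays in (axis1, axis2) coordinates
    tf_tfbs_ratio: Optional[np.ndarray] = None


# -- composed forward map ----------------------------------------------------

def _free_tf(rt: float, params: SystemParams, nf: Optional[NegativeFeedbackParams]) -> tuple[float, float, float]:
    """(R_P*, R_f*, Cp*_effective) at total TF level rt."""
    if nf is not None and nf.mode == "capacity-inhibition":
        rp_max = rp_approx(rt, params.Cp_star, params.Ct_star)
        rf_max = solve_Rf(rp_max, params.D_star, params.K_star, params.l)

        def g(rf: float) -> float:
            cp_eff = params.Cp_star / (1.0 + (rf / nf.K_I_star) ** nf.h_I)
            rp = rp_approx(rt, cp_eff, params.Ct_star)
            return solve_Rf(rp, params.D_star, params.K_star, params.l) - rf

        if rf_max <= 0 or g(rf_max) >= 0:
            rf = rf_max
        else:
            rf = brentq(g, 0.0, rf_max, xtol=1e-300, rtol=1e-15)
        cp_eff = params.Cp_star / (1.0 + (rf / nf.K_I_star) ** nf.h_I)
        rp = rp_approx(rt, cp_eff, params.Ct_star)
        return rp, rf, cp_eff
    rp = rp_approx(rt, params.Cp_star, params.Ct_star)
    rf = solve_Rf(rp, params.D_star, params.K_star, params.l)
    return rp, rf, params.Cp_star


def composed_production(
    params: SystemParams, nf: Optional[NegativeFeedbackParams] = None
) -> Callable[[float], float]:
    """Return the open-loop map R_T* -> F(B(A(R_T*)))."""

    def fba(rt: float) -> float:
        _, rf, _ = _free_tf(rt, params, nf)
        if nf is not None and nf.mode == "transcriptional-repression":
            return production_coupled(rf, params, nf)
        return production_F(rf, params)

    return fba


def lg3_at(
    rt: float,
    params: SystemParams,
    nf: Optional[NegativeFeedbackParams] = None,
    eps: float = 1e-6,
) -> float:
    """Open-loop log gain at a single R_T* (analytic product when available).

    Capacity-inhibition feedback couples Cp* to R_f*, breaking the analytic
    factorization; in that mode a log-log central difference of the composed
    map is used instead.
    """
    if rt <= 0:
        raise InvalidParameterError("R_T_star must be > 0")
    if nf is not None and nf.mode == "capacity-inhibition":
        fba = composed_production(params, nf)
        lo, hi = rt * np.exp(-eps), rt * np.exp(eps)
        return float((np.log(fba(hi)) - np.log(fba(lo))) / (2.0 * eps))
    rp, rf, _ = _free_tf(rt, params, nf)
    ga = lg_A(rt, params.Cp_star, params.Ct_star) if params.Cp_star > 0 else 0.0
    gb = lg_B(rf, params.D_star, params.K_star, params.l) if rf > 0 else 1.0
    if nf is not None:
        gf = coupled_lg_C(rf, params, nf) if rf > 0 else 0.0
    else:
        gf = lg_F(rf, params.f, params.h)
    return float(ga * gb * gf)


def lg3_profile(
    params: SystemParams,
    R_T_grid: Sequence[float],
    nf: Optional[NegativeFeedbackParams] = None,
    refine: bool = True,
) -> LGProfile:
    """Evaluate all module gains and LG_3 over an ascending R_T* grid."""
    grid = np.asarray(R_T_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise InvalidParameterError("R_T_grid must be ascending and positive")
    n = len(grid)
    rp = np.empty(n)
    rf = np.empty(n)
    ga = np.empty(n)
    gb = np.empty(n)
    gf = np.empty(n)
    for i, rt in enumerate(grid):
        rp[i], rf[i], cp_eff = _free_tf(float(rt), params, nf)
        ga[i] = lg_A(rt, cp_eff, params.Ct_star) if cp_eff > 0 else 0.0
        gb[i] = lg_B(rf[i], params.D_star, params.K_star, params.l) if rf[i] > 0 else 1.0
        if nf is not None and nf.mode == "transcriptional-repression":
            gf[i] = coupled_lg_C(rf[i], params, nf) if rf[i] > 0 else 0.0
        else:
            gf[i] = lg_F(rf[i], params.f, params.h)
    g3 = ga * gb * gf
    if nf is not None and nf.mode == "capacity-inhibition":
        # factorization with Cp*_eff is approximate here; recompute exactly
        g3 = np.array([lg3_at(float(rt), params, nf) for rt in grid])
    i0 = int(np.argmax(g3))
    best_rt, best = float(grid[i0]), float(g3[i0])
    if refine and 0 < i0 < n - 1:
        res = minimize_scalar(
            lambda logt: -lg3_at(float(np.exp(logt)), params, nf),
            bounds=(np.log(grid[i0 - 1]), np.log(grid[i0 + 1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun > best:
            best, best_rt = float(-res.fun), float(np.exp(res.x))
    return LGProfile(grid, rp, rf, ga, gb, gf, g3, best, best_rt)


# -- steady states and bifurcation ------------------------------------------

def steady_states(
    params: SystemParams,
    Cp_star_override: Optional[float] = None,
    nf: Optional[NegativeFeedbackParams] = None,
    n_scan: int = 2000,
) -> list[SteadyState]:
    """All fixed points of the composed map, with stability labels.

    Roots of G(R_T*) = F(B(A(R_T*))) - R_T* are located by a dense log-spaced
    sign-change scan over the production image (padded by 10%) and refined by
    Brent's method.  Stability follows the sign of G' at the root; near-zero
    slopes are labeled degenerate.
    """
    if Cp_star_override is not None:
        params = params.replace(Cp_star=Cp_star_override)
    fba = composed_production(params, nf)
    lo_factor = nf.f_N if (nf is not None and nf.mode == "transcriptional-repression") else 1.0
    lo = 0.9 * params.R_b_star * min(1.0, lo_factor)
    hi = 1.1 * params.f * params.R_b_star
    grid = np.geomspace(lo, hi, n_scan)
    g = np.array([fba(rt) - rt for rt in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if g[i] == 0.0:
            roots.append(float(grid[i]))
        elif g[i] * g[i + 1] < 0:
            roots.append(
                float(brentq(lambda rt: fba(rt) - rt, grid[i], grid[i + 1],
                             xtol=1e-300, rtol=1e-15))
            )
    if g[-1] == 0.0:
        roots.append(float(grid[-1]))
    # merge near-duplicates
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 1e-9 * max(1.0, r):
            merged.append(r)
    out: list[SteadyState] = []
    for rt in merged:
        rp, rf, _ = _free_tf(rt, params, nf)
        g3 = lg3_at(rt, params, nf)
        eps = 1e-6 * max(rt, 1.0)
        gprime = (fba(rt + eps) - fba(rt - eps)) / (2.0 * eps) - 1.0
        if abs(gprime) < _DEGENERATE_TOL:
            label = "degenerate"
            warnings.warn(f"degenerate fixed point at R_T*={rt:.6g} (|G'|<{_DEGENERATE_TOL})")
        else:
            label = "stable" if gprime < 0 else "unstable"
        out.append(SteadyState(rt, rp, rf, fba(rt), g3, label))
    return out


def _count(params, cp, nf):
    return len(steady_states(params, Cp_star_override=cp, nf=nf))


def dose_response(
    params: SystemParams,
    Cp_grid: Sequence[float],
    nf: Optional[NegativeFeedbackParams] = None,
    K_rep_star: float = 1.0,
    h_rep: float = 2.0,
) -> Bifurcation:
    """Steady-state branches over an ascending Cp* grid, with reporter occupancy.

    The bistable interval is the Cp* range carrying three fixed points; its
    boundaries (saddle-node folds) are refined by bisection between adjacent
    grid points to 1e-4 relative.
    """
    cps = np.asarray(Cp_grid, dtype=float)
    if cps.ndim != 1 or len(cps) < 2 or np.any(np.diff(cps) <= 0):
        raise ConfigurationError("Cp_grid must be ascending with >= 2 points")
    all_states = [steady_states(params, Cp_star_override=cp, nf=nf) for cp in cps]
    counts = np.array([len(s) for s in all_states])
    folds: list[float] = []
    for i in range(len(cps) - 1):
        if counts[i] != counts[i + 1]:
            lo, hi = float(cps[i]), float(cps[i + 1])
            c_lo = counts[i]
            while (hi - lo) / max(hi, 1e-300) > 1e-4:
                mid = 0.5 * (lo + hi)
                if _count(params, mid, nf) == c_lo:
                    lo = mid
                else:
                    hi = mid
            folds.append(0.5 * (lo + hi))
    bistable_idx = np.where(counts >= 3)[0]
    interval = (
        (float(cps[bistable_idx[0]]), float(cps[bistable_idx[-1]]))
        if len(bistable_idx)
        else None
    )
    lower = np.full(len(cps), np.nan)
    upper = np.full(len(cps), np.nan)
    for i, states in enumerate(all_states):
        stable = [s for s in states if s.stability == "stable"]
        if stable:
            lower[i] = promoter_occupancy(stable[0].R_f_star, K_rep_star, h_rep)
            upper[i] = promoter_occupancy(stable[-1].R_f_star, K_rep_star, h_rep)
    return Bifurcation(
        Cp_grid=cps,
        states=all_states,
        bistable_interval=interval,
        saddle_node_points=folds,
        occupancy={"lower_branch": lower, "upper_branch": upper},
    )


# -- phase diagrams ----------------------------------------------------------

_SWEEPABLE = {"f", "h", "R_b_star", "D_star", "K_star", "l", "Cp_star", "Ct_star"}


def _max_gain_over_rt(
    params: SystemParams,
    nf: Optional[NegativeFeedbackParams],
    rt_grid: np.ndarray,
    include_phospho: bool,
) -> float:
    if include_phospho:
        prof = lg3_profile(params, rt_grid, nf=nf, refine=True)
        return prof.max_LG_3

    # LG_A frozen at 1: maximize LG_F * LG_B directly over the free-TF level
    def fb(rf: float) -> float:
        gf = lg_F(rf, params.f, params.h)
        gb = lg_B(rf, params.D_star, params.K_star, params.l)
        return gf * gb

    vals = np.array([fb(float(r)) for r in rt_grid])
    i0 = int(np.argmax(vals))
    best = float(vals[i0])
    if 0 < i0 < len(rt_grid) - 1:
        res = minimize_scalar(
            lambda logr: -fb(float(np.exp(logr))),
            bounds=(np.log(rt_grid[i0 - 1]), np.log(rt_grid[i0 + 1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        best = max(best, float(-res.fun))
    return best


def _contours_at_1(ax1: np.ndarray, ax2: np.ndarray, values: np.ndarray) -> list:
    try:
        import contourpy
    except ImportError:  # pragma: no cover
        return []
    gen = contourpy.contour_generator(
        x=ax1, y=ax2, z=values, name="serial", line_type=contourpy.LineType.Separate
    )
    return [np.asarray(line) for line in gen.lines(1.0)]


def phase_diagram(
    params: SystemParams,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    mode: str = "max-over-RT",
    nf: Optional[NegativeFeedbackParams] = None,
    include_phospho: bool = True,
    R_T_scan: Optional[Sequence[float]] = None,
) -> PhaseDiagram:
    """Map max LG_3 (or pointwise LG_3) over a 2-D parameter grid.

    ``mode="max-over-RT"`` maximizes LG_3 over a log-spaced total-TF grid per
    cell; with ``include_phospho=False`` the activation gain is frozen at 1 and
    LG_F*LG_B is maximized over the free-TF level instead.  ``mode="pointwise"``
    requires one axis to be ``R_T_star`` and evaluates LG_3 at that cell.  The
    value-1 contour separates the monostable-guaranteed region (value < 1,
    necessary-condition semantics) from the potentially bistable one.
    """
    name1, grid1 = axis1[0], np.asarray(axis1[1], dtype=float)
    name2, grid2 = axis2[0], np.asarray(axis2[1], dtype=float)
    for name, grid in ((name1, grid1), (name2, grid2)):
        if name != "R_T_star" and name not in _SWEEPABLE:
            raise ConfigurationError(f"cannot sweep parameter {name!r}")
        if grid.ndim != 1 or len(grid) < 2:
            raise ConfigurationError(f"axis {name!r} needs >= 2 grid points")
        if np.any(grid <= 0):
            raise ConfigurationError(f"axis {name!r} grid must be positive")
    if mode not in ("max-over-RT", "pointwise"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if mode == "pointwise" and "R_T_star" not in (name1, name2):
        raise ConfigurationError("pointwise mode requires an R_T_star axis")
    rt_scan = (
        np.asarray(R_T_scan, dtype=float)
        if R_T_scan is not None
        else np.geomspace(0.1, 100.0, 200)
    )
    values = np.empty((len(grid2), len(grid1)))
    for j, v2 in enumerate(grid2):
        for i, v1 in enumerate(grid1):
            updates = {}
            rt_point = None
            for name, v in ((name1, float(v1)), (name2, float(v2))):
                if name == "R_T_star":
                    rt_point = v
                else:
                    updates[name] = v
            p = params.replace(**updates)
            if mode == "pointwise":
                values[j, i] = lg3_at(rt_point, p, nf)
            else:
                values[j, i] = _max_gain_over_rt(p, nf, rt_scan, include_phospho)
    ratio = None
    if "R_T_star" in (name1, name2) and "D_star" in (name1, name2):
        rt_ax = grid1 if name1 == "R_T_star" else grid2
        d_ax = grid1 if name1 == "D_star" else grid2
        if name1 == "R_T_star":
            ratio = rt_ax[np.newaxis, :] / d_ax[:, np.newaxis]
        else:
            ratio = rt_ax[:, np.newaxis] / d_ax[np.newaxis, :]
    return PhaseDiagram(
        axis1_name=name1,
        axis1_grid=grid1,
        axis2_name=name2,
        axis2_grid=grid2,
        mode=mode,
        values=values,
        contour_at_1=_contours_at_1(grid1, grid2, values),
        tf_tfbs_ratio=ratio,
    )


def integrate_dynamics(
    params: SystemParams,
    R_T0: float,
    t_end: float = 200.0,
    nf: Optional[NegativeFeedbackParams] = None,
    n_steps: int = 2000,
) -> np.ndarray:
    """Integrate the dimensionless relaxation dR_T*/dtau = F(B(A(R_T*))) - R_T*.

    Time is in units of 1/k_dil.  Returns an (n, 2) array of (tau, R_T*);
    used as the dynamic oracle for stability labels.
    """
    fba = composed_production(params, nf)
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, y: [fba(max(y[0], 0.0)) - y[0]],
        (0.0, t_end),
        [R_T0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        t_eval=np.linspace(0.0, t_end, n_steps),
    )
    return np.column_stack([sol.t, sol.y[0]])
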