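"""TF-activation module A: total TF -> phosphorylated TF.

Two routes are provided: the two-parameter saturation approximation
(capacity ``Cp*``, half-saturation composite ``Ct*``), valid when the response
regulator (RR) is in large excess over the histidine kinase (HK); and the full
mass-action bifunctional-HK scheme with explicit phosphotransfer and
phosphatase complexes, from which effective (Cp*, Ct*) can be extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, root

from .core_params import InvalidParameterError


class SteadyStateError(RuntimeError):
    """Full-model steady state could not be located."""


def rp_approx(R_T_star, Cp_star: float, Ct_star: float):
    """Phosphorylated TF level from the saturation approximation.

    Smaller root of the quadratic
    R_P*^2 - (Cp* + Ct* + R_T*) R_P* + Cp* R_T* = 0, i.e.

        R_P* = [Cp* + Ct* + R_T* - sqrt((Cp* + Ct* + R_T*)^2 - 4 Cp* R_T*)] / 2

    Bounded by min(R_T*, Cp*); monotone in each argument.
    """
    rt = np.asarray(R_T_star, dtype=float)
    if np.any(rt < 0) or Cp_star < 0 or Ct_star < 0:
        raise InvalidParameterError("rp_approx arguments must be >= 0")
    s = Cp_star + Ct_star + rt
    disc = s * s - 4.0 * Cp_star * rt
    if np.any(disc < 0):
        raise SteadyStateError("negative discriminant in phosphorylation quadratic")
    # smaller root via the product form 2ac/(b + sqrt(disc)): avoids the
    # catastrophic cancellation of (s - sqrt(disc))/2 when Cp* R_T* << s^2
    denom = s + np.sqrt(disc)
    out = np.where(denom > 0, 4.0 * Cp_star * rt / np.where(denom > 0, denom, 1.0) / 2.0, 0.0)
    return out if out.ndim else float(out)


def lg_A(R_T_star, Cp_star: float, Ct_star: float):
    """Logarithmic gain of the activation module.

    LG_A = 1 - (R_T* - R_P*) / (Ct* + Cp* - R_P* + R_T* - R_P*), with R_P*
    from :func:`rp_approx`.  Always in [0, 1]; equals 1/2 exactly at
    R_T* = Cp* + Ct*, and drops below 1/2 beyond it.
    """
    rt = np.asarray(R_T_star, dtype=float)
    if np.any(rt <= 0):
        raise InvalidParameterError("R_T_star must be > 0")
    if Cp_star <= 0:
        raise InvalidParameterError("LG_A is undefined for Cp_star = 0")
    rp = np.asarray(rp_approx(rt, Cp_star, Ct_star))
    out = 1.0 - (rt - rp) / (Ct_star + Cp_star - rp + rt - rp)
    return out if out.ndim else float(out)


# -- full bifunctional-HK mass-action model ---------------------------------

@dataclass(frozen=True)
class FullTcsParams:
    """Elementary rates of the bifunctional-HK phosphorylation cycle.

    Species: HK, HKP (autophosphorylated), RR, RRP (phosphorylated), and the
    transient complexes HKP.RR (phosphotransfer) and HK.RRP (phosphatase).
    Defaults give saturating monotone activation curves at desk scale; they are
    generic, not system-specific, so quantitative claims are made only through
    :func:`effective_capacity`.
    """

    rr_hk_ratio: float = 20.0
    k_k: float = 10.0         # HK autophosphorylation, 1/time
    k_unp: float = 0.1        # HK auto-dephosphorylation, 1/time
    kon_pt: float = 10.0      # HKP + RR association
    koff_pt: float = 0.5
    kcat_pt: float = 5.0      # phosphotransfer: HKP.RR -> HK + RRP
    kon_ph: float = 10.0      # HK + RRP association
    koff_ph: float = 0.5
    kcat_ph: float = 0.1      # phosphatase: HK.RRP -> HK + RR

    def __post_init__(self) -> None:
        if self.rr_hk_ratio <= 0:
            raise InvalidParameterError("rr_hk_ratio must be > 0")
        for name in ("k_k", "k_unp", "kon_pt", "koff_pt", "kcat_pt",
                     "kon_ph", "koff_ph", "kcat_ph"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


def _rhs(t, y, p: FullTcsParams):
    hk, hkp, rr, rrp, c1, c2 = y
    v_auto = p.k_k * hk - p.k_unp * hkp
    v_on1 = p.kon_pt * hkp * rr - p.koff_pt * c1
    v_cat1 = p.kcat_pt * c1
    v_on2 = p.kon_ph * hk * rrp - p.koff_ph * c2
    v_cat2 = p.kcat_ph * c2
    return [
        -v_auto + v_cat1 - v_on2 + v_cat2,   # HK
        v_auto - v_on1,                      # HKP
        -v_on1 + v_cat2,                     # RR
        v_cat1 - v_on2,                      # RRP
        v_on1 - v_cat1,                      # HKP.RR
        v_on2 - v_cat2,                      # HK.RRP
    ]


def full_model_steady(R_T_star: float, params: FullTcsParams) -> dict:
    """Steady state of the mass-action scheme at total RR level ``R_T_star``.

    Total HK is ``R_T_star / rr_hk_ratio``.  The ODE system is integrated to
    near-equilibrium and polished by root finding on the conservation-reduced
    system.  Returns a dict with all six species, ``R_P_star`` (free
    phosphorylated RR) and conservation residuals.
    """
    if R_T_star <= 0:
        raise InvalidParameterError("R_T_star must be > 0")
    hk_t = R_T_star / params.rr_hk_ratio
    y0 = [hk_t, 0.0, R_T_star, 0.0, 0.0, 0.0]
    scale = max(R_T_star, hk_t, 1.0)

    t_end = 50.0
    y = np.array(y0)
    for _ in range(8):
        sol = solve_ivp(_rhs, (0.0, t_end), y, args=(params,), method="LSODA",
                        rtol=1e-10, atol=1e-12 * scale)
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}")
        y = sol.y[:, -1]
        if np.max(np.abs(_rhs(0.0, y, params))) < 1e-10 * scale:
            break
        t_end *= 10.0
    else:
        warnings.warn("slow relaxation; polishing from non-equilibrated state")

    # polish: unknowns (HKP, RRP, C1, C2); HK, RR from conservation
    def reduced(z):
        hkp, rrp, c1, c2 = z
        hk = hk_t - hkp - c1 - c2
        rr = R_T_star - rrp - c1 - c2
        d = _rhs(0.0, [hk, hkp, rr, rrp, c1, c2], params)
        return [d[1], d[3], d[4], d[5]]

    res = root(reduced, [y[1], y[3], y[4], y[5]], method="hybr", tol=1e-14)
    if res.success and np.all(np.asarray(res.x) > -1e-12 * scale):
        hkp, rrp, c1, c2 = np.clip(res.x, 0.0, None)
        y = np.array([hk_t - hkp - c1 - c2, hkp,
                      R_T_star - rrp - c1 - c2, rrp, c1, c2])
    hk, hkp, rr, rrp, c1, c2 = y
    hk_res = abs(hk + hkp + c1 + c2 - hk_t) / max(hk_t, 1e-300)
    rr_res = abs(rr + rrp + c1 + c2 - R_T_star) / R_T_star
    if max(hk_res, rr_res) > 1e-8:
        raise SteadyStateError(
            f"conservation violated: HK residual {hk_res:.2e}, RR residual {rr_res:.2e}"
        )
    return {
        "HK": hk, "HKP": hkp, "RR": rr, "RRP": rrp,
        "HKP_RR": c1, "HK_RRP": c2,
        "R_P_star": rrp,
        "hk_conservation_residual": hk_res,
        "rr_conservation_residual": rr_res,
    }


def activation_curve(R_T_grid, params: FullTcsParams) -> np.ndarray:
    """R_P*(R_T*) from the full model over a grid; shape (n, 2)."""
    out = np.empty((len(R_T_grid), 2))
    for i, rt in enumerate(R_T_grid):
        out[i, 0] = rt
        out[i, 1] = full_model_steady(float(rt), params)["R_P_star"]
    return out


def effective_capacity(curve) -> tuple[float, float, dict]:
    """Extract (Cp*, Ct*) from a monotone activation curve.

    The asymptote of R_P* estimates Cp*; (R_T* - R_P*) at R_P* = Cp*/2
    estimates Ct*.  Both are then refined by least squares against
    :func:`rp_approx`.  Returns ``(Cp_star, Ct_star, info)`` where ``info``
    carries the relative fit residual and a saturation flag.
    """
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 10:
        raise InvalidParameterError("curve must be (n>=10, 2) array of (R_T*, R_P*)")
    rt, rp = arr[:, 0], arr[:, 1]
    if np.any(np.diff(rt) <= 0):
        raise InvalidParameterError("R_T* values must be strictly increasing")
    info: dict = {"saturated": True}
    if rp[-1] <= 0:
        warnings.warn("curve is identically zero; capacity 0, Ct undefined")
        return 0.0, float("nan"), {"saturated": False, "fit_residual": 0.0}
    if rp[-1] - rp[-2] > 0.01 * rp[-1]:
        warnings.warn("curve not saturated at last grid point; extrapolating asymptote")
        info["saturated"] = False
    cp0 = float(rp[-1])
    half = cp0 / 2.0
    rt_half = float(np.interp(half, rp, rt))
    ct0 = max(rt_half - half, 1e-12)

    def resid(theta):
        cp, ct = theta
        return rp_approx(rt, cp, ct) - rp

    fit = least_squares(resid, [cp0, ct0], bounds=([1e-12, 1e-12], [np.inf, np.inf]))
    cp, ct = fit.x
    info["fit_residual"] = float(
        np.max(np.abs(fit.fun)) / max(np.max(rp), 1e-300)
    )
    return float(cp), float(ct), info
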