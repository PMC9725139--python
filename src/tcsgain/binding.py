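"""Competitive DNA-binding module B: phosphorylated TF -> free TF.

Decoy sites sequester active TF: R_P* = R_f* + l D* R_f*^l / (R_f*^l + K*^l).
The inverse map (free TF given total phosphorylated TF) is solved by bracketed
root finding on the monotone forward map.  For cooperativity l = 2 the log gain
has a closed form; other l fall back to a log-log central difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core_params import InvalidParameterError

_RTOL = 1e-12
_MAXITER = 200


class BindingSolveError(RuntimeError):
    """Inverse binding map failed to converge."""


@dataclass(frozen=True)
class BindingState:
    """Partition of phosphorylated TF between free and decoy-bound pools."""

    R_P_star: float
    R_f_star: float
    bound_star: float
    occupancy_fraction: float


def forward_RP(R_f_star, D_star: float, K_star: float, l: float = 2.0):
    """Total phosphorylated TF given free TF: R_f* + l D* R_f*^l/(R_f*^l + K*^l)."""
    x = np.asarray(R_f_star, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("R_f_star must be >= 0")
    if D_star < 0:
        raise InvalidParameterError("D_star must be >= 0")
    if K_star <= 0:
        raise InvalidParameterError("K_star must be > 0")
    xl = x**l
    out = x + l * D_star * xl / (xl + K_star**l)
    return out if out.ndim else float(out)


def solve_Rf(R_P_star: float, D_star: float, K_star: float, l: float = 2.0) -> float:
    """Free TF level: unique root of ``forward_RP(x) = R_P_star`` on [0, R_P*]."""
    if R_P_star < 0:
        raise InvalidParameterError("R_P_star must be >= 0")
    if R_P_star == 0 or D_star == 0:
        return float(R_P_star)

    def g(x: float) -> float:
        return forward_RP(x, D_star, K_star, l) - R_P_star

    hi = R_P_star
    if g(hi) < 0:  # cannot happen for the monotone map, but guard the bracket
        raise BindingSolveError(
            f"bracket failure: forward_RP({hi}) = {forward_RP(hi, D_star, K_star, l)} "
            f"< target {R_P_star}"
        )
    try:
        root = brentq(g, 0.0, hi, xtol=1e-300, rtol=max(_RTOL, 4e-16), maxiter=_MAXITER)
    except RuntimeError as exc:  # pragma: no cover - brentq converges on brackets
        raise BindingSolveError(
            f"no convergence after {_MAXITER} iterations on [0, {hi}]: {exc}"
        ) from exc
    return float(root)


def binding_state(R_P_star: float, D_star: float, K_star: float, l: float = 2.0) -> BindingState:
    """Full partition of TF at equilibrium for a given total phosphorylated pool."""
    rf = solve_Rf(R_P_star, D_star, K_star, l)
    bound = R_P_star - rf
    capacity = l * D_star
    occ = bound / capacity if capacity > 0 else 0.0
    return BindingState(R_P_star, rf, bound, occ)


def _phi(R_f_star, D_star: float, K_star: float):
    x = np.asarray(R_f_star, dtype=float)
    return (
        2.0 * D_star * x * (x + K_star)
        / ((x**2 + K_star**2) ** 2 + 4.0 * D_star * K_star**2 * x)
    )


def lg_B(R_f_star, D_star: float, K_star: float, l: float = 2.0):
    """Logarithmic gain of the binding module, d log R_f* / d log R_P*.

    For l = 2 the analytic form ``1 + phi(R_f*) (R_f* - K*)`` is used, with
    phi = 2 D* R_f* (R_f* + K*) / [(R_f*^2 + K*^2)^2 + 4 D* K*^2 R_f*];
    LG_B > 1 iff R_f* > K* (for D* > 0), and equals 1 when D* = 0 or
    R_f* = K*.  For l != 2 a central difference through the inverse map is
    taken on log-log axes.
    """
    x = np.asarray(R_f_star, dtype=float)
    if np.any(x <= 0):
        raise InvalidParameterError("R_f_star must be > 0")
    if K_star <= 0:
        raise InvalidParameterError("K_star must be > 0")
    if l == 2.0:
        out = 1.0 + _phi(x, D_star, K_star) * (x - K_star)
        return out if out.ndim else float(out)
    return _lg_B_numeric(x, D_star, K_star, l)


def _lg_B_numeric(R_f_star, D_star: float, K_star: float, l: float, eps: float = 1e-6):
    """d log R_f*/d log R_P* by central difference through solve_Rf."""

    def one(xf: float) -> float:
        rp = forward_RP(xf, D_star, K_star, l)
        lo, hi = rp * np.exp(-eps), rp * np.exp(eps)
        flo, fhi = solve_Rf(lo, D_star, K_star, l), solve_Rf(hi, D_star, K_star, l)
        return (np.log(fhi) - np.log(flo)) / (2.0 * eps)

    x = np.asarray(R_f_star, dtype=float)
    out = np.vectorize(one)(x)
    return out if out.ndim else float(out)


def promoter_occupancy(R_f_star, K_rep_star: float = 1.0, h_rep: float = 2.0):
    """Hill occupancy of a reporter promoter: R_f*^h / (R_f*^h + K_rep*^h)."""
    x = np.asarray(R_f_star, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("R_f_star must be >= 0")
    if K_rep_star <= 0:
        raise InvalidParameterError("K_rep_star must be > 0")
    xh = x**h_rep
    out = xh / (xh + K_rep_star**h_rep)
    return out if out.ndim else float(out)
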