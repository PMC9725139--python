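"""Transcription module F: free active TF -> production level, and its log gain.

The autoregulated promoter follows Hill activation between the basal level
``R_b*`` and the fully induced level ``f * R_b*``.  The coupled-negative-feedback
variant layers an independent repression site on the same promoter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_params import InvalidParameterError, SystemParams


@dataclass(frozen=True)
class NegativeFeedbackParams:
    """Parameters of a coupled negative feedback layered on the positive loop.

    ``mode`` selects where the repression acts:

    - ``"transcriptional-repression"``: the active TF binds a repression site in
      its own promoter (fold change ``f_N <= 1``, affinity ``K_N_star``,
      cooperativity ``h_N``).
    - ``"capacity-inhibition"``: the TF induces an inhibitor of its own
      phosphorylation, reducing the effective capacity
      ``Cp*_eff = Cp* / (1 + (R_f*/K_I*)**h_I)`` inside the composed map.
    """

    mode: str = "transcriptional-repression"
    f_N: float = 0.2
    K_N_star: float = 1.0
    h_N: float = 2.0
    K_I_star: float = 1.0
    h_I: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("transcriptional-repression", "capacity-inhibition"):
            raise InvalidParameterError(f"unknown feedback mode: {self.mode!r}")
        if not 0 < self.f_N <= 1:
            raise InvalidParameterError(f"f_N must be in (0, 1], got {self.f_N}")
        for name in ("K_N_star", "h_N", "K_I_star", "h_I"):
            v = getattr(self, name)
            if v <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")


def production_F(R_f_star, params: SystemParams):
    """Steady-state production level R_T* = R_b* (1 + f R_f*^h) / (1 + R_f*^h).

    Strictly increasing in ``R_f_star``; image is [R_b*, f*R_b*).
    """
    x = np.asarray(R_f_star, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("R_f_star must be >= 0")
    xh = x**params.h
    out = params.R_b_star * (1.0 + params.f * xh) / (1.0 + xh)
    return out if out.ndim else float(out)


def lg_F(R_f_star, f: float, h: float = 2.0):
    """Logarithmic gain of the transcription module.

    LG_F = h (f-1) R_f*^h / [(1 + f R_f*^h)(1 + R_f*^h)].  Defined as 0 at
    R_f* = 0 by continuous extension.
    """
    x = np.asarray(R_f_star, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("R_f_star must be >= 0")
    if f < 1:
        raise InvalidParameterError(f"f must be >= 1, got {f}")
    xh = x**h
    out = h * (f - 1.0) * xh / ((1.0 + f * xh) * (1.0 + xh))
    return out if out.ndim else float(out)


def max_lg_F(f: float, h: float = 2.0) -> tuple[float, float]:
    """Closed-form maximum of :func:`lg_F` and its location.

    Returns ``(h (sqrt(f)-1)/(sqrt(f)+1), f**(-1/(2h)))``.  The value is always
    strictly below ``h`` and reaches 1 (for h=2) exactly at f=9.
    """
    if f < 1:
        raise InvalidParameterError(f"f must be >= 1, got {f}")
    if h <= 0:
        raise InvalidParameterError(f"h must be > 0, got {h}")
    s = np.sqrt(f)
    value = h * (s - 1.0) / (s + 1.0)
    argmax = f ** (-1.0 / (2.0 * h))
    return float(value), float(argmax)


def _repression_factor(R_f_star, nf: NegativeFeedbackParams):
    x = (np.asarray(R_f_star, dtype=float) / nf.K_N_star) ** nf.h_N
    return (1.0 + nf.f_N * x) / (1.0 + x)


def production_coupled(R_f_star, params: SystemParams, nf: NegativeFeedbackParams):
    """Promoter output with independent activation and repression sites.

    F_C = R_b* * [(1 + f R_f*^h)/(1 + R_f*^h)] * [(1 + f_N x)/(1 + x)],
    x = (R_f*/K_N*)^h_N.  Only defined for transcriptional repression.
    """
    if nf.mode != "transcriptional-repression":
        raise InvalidParameterError(
            "production_coupled applies only in transcriptional-repression mode; "
            "capacity inhibition acts inside the composed fixed-point map"
        )
    out = production_F(R_f_star, params) * _repression_factor(R_f_star, nf)
    return out if np.ndim(out) else float(out)


def lg_N(R_f_star, nf: NegativeFeedbackParams):
    """Log gain of the repression site alone; always <= 0 for f_N <= 1."""
    x = (np.asarray(R_f_star, dtype=float) / nf.K_N_star) ** nf.h_N
    out = nf.h_N * (nf.f_N - 1.0) * x / ((1.0 + nf.f_N * x) * (1.0 + x))
    return out if out.ndim else float(out)


def coupled_lg_C(R_f_star, params: SystemParams, nf: NegativeFeedbackParams):
    """Log gain of the coupled promoter: LG_C = LG_F + LG_N <= LG_F."""
    if nf.mode != "transcriptional-repression":
        raise InvalidParameterError(
            "coupled_lg_C is undefined in capacity-inhibition mode"
        )
    out = lg_F(R_f_star, params.f, params.h) + lg_N(R_f_star, nf)
    return out if np.ndim(out) else float(out)
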