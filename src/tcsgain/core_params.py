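"""Model parameters, K_auto normalization, and concentration/molecule unit conversion.

All internal computation uses dimensionless ("starred") quantities obtained by
dividing concentrations by the autoregulated-promoter affinity ``K_auto``.
Dimensional inputs are converted once at the boundary via :func:`normalize_params`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Optional

AVOGADRO = 6.02214076e23  # 1/mol, CODATA exact
DEFAULT_CELL_VOLUME_L = 1e-15  # typical bacterial cell volume, liters


class InvalidParameterError(ValueError):
    """A parameter violates its domain constraint."""


class ConfigurationError(ValueError):
    """A required configuration field is missing or malformed."""


@dataclass(frozen=True)
class SystemParams:
    """Dimensionless parameter set for the three-module autoregulation model.

    Attributes
    ----------
    f : float
        Transcriptional fold change (fully induced / basal), >= 1.
    h : float
        Autoregulation Hill coefficient (dimer binding default 2).
    R_b_star : float
        Normalized basal TF production level, alpha / (k_dil * K_auto).
    D_star : float
        Normalized amount of competing (decoy) TF binding sites.
    K_star : float
        Decoy-site affinity relative to the autoregulated promoter, K / K_auto.
    l : float
        Decoy-site binding cooperativity (molecules bound per site).
    Cp_star : float
        Phosphorylation capacity, Cp / K_auto (signal input of the model).
    Ct_star : float
        Phosphotransfer half-saturation composite, Ct / K_auto.
    K_auto : float, optional
        Dimensional promoter affinity (e.g. uM); retained for provenance only.
    k_dil : float, optional
        Dilution/degradation rate (1/time).
    alpha : float, optional
        Lumped production rate constant (concentration/time).
    """

    f: float = 5.0
    h: float = 2.0
    R_b_star: float = 1.0
    D_star: float = 0.0
    K_star: float = 1.0
    l: float = 2.0
    Cp_star: float = 1.0
    Ct_star: float = 3.0
    K_auto: Optional[float] = None
    k_dil: Optional[float] = None
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if self.f < 1:
            raise InvalidParameterError(f"fold change f must be >= 1, got {self.f}")
        if self.h <= 0:
            raise InvalidParameterError(f"Hill coefficient h must be > 0, got {self.h}")
        if self.R_b_star <= 0:
            raise InvalidParameterError(f"R_b_star must be > 0, got {self.R_b_star}")
        if self.K_star <= 0:
            raise InvalidParameterError(f"K_star must be > 0, got {self.K_star}")
        if self.l <= 0:
            raise InvalidParameterError(f"cooperativity l must be > 0, got {self.l}")
        for name in ("D_star", "Cp_star", "Ct_star"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        if self.K_auto is not None and self.K_auto <= 0:
            raise InvalidParameterError(f"K_auto must be > 0, got {self.K_auto}")

    def replace(self, **changes) -> "SystemParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


#: raw-field name -> starred-field name for plain concentration parameters
_STARRED = {"D": "D_star", "K": "K_star", "Cp": "Cp_star", "Ct": "Ct_star"}
#: fields passed through without scaling
_PASSTHROUGH = ("f", "h", "l")


def normalize_params(raw: Mapping[str, float], K_auto: float) -> SystemParams:
    """Convert dimensional parameters to a K_auto-normalized :class:`SystemParams`.

    ``raw`` may contain concentrations ``D``, ``K``, ``Cp``, ``Ct`` (same units
    as ``K_auto``), the dimensionless ``f``, ``h``, ``l``, and either ``Rb``
    (basal concentration) or the pair ``alpha``/``k_dil`` from which
    ``R_b_star = alpha / (k_dil * K_auto)`` is computed.  Keys already carrying
    a ``_star`` suffix are taken verbatim.
    """
    if K_auto <= 0:
        raise InvalidParameterError(f"K_auto must be > 0, got {K_auto}")
    fields = {f.name for f in dataclasses.fields(SystemParams)}
    out: dict = {"K_auto": K_auto}
    for key, value in raw.items():
        if key in _PASSTHROUGH or key in ("k_dil", "alpha"):
            out[key] = float(value)
        elif key in _STARRED:
            if value < 0:
                raise InvalidParameterError(f"{key} must be >= 0, got {value}")
            out[_STARRED[key]] = float(value) / K_auto
        elif key == "Rb":
            if value < 0:
                raise InvalidParameterError(f"Rb must be >= 0, got {value}")
            out["R_b_star"] = float(value) / K_auto
        elif key in fields:
            out[key] = float(value)
        else:
            raise ConfigurationError(f"unknown parameter field: {key!r}")
    if "alpha" in out and "k_dil" in out:
        if out["k_dil"] <= 0:
            raise InvalidParameterError("k_dil must be > 0")
        out["R_b_star"] = out["alpha"] / (out["k_dil"] * K_auto)
    if "R_b_star" not in out:
        raise ConfigurationError(
            "missing required field: supply 'Rb', 'R_b_star', or both 'alpha' and 'k_dil'"
        )
    return SystemParams(**out)


def molecules_from_concentration(
    conc_uM: float, volume_L: float = DEFAULT_CELL_VOLUME_L
) -> float:
    """Number of molecules at concentration ``conc_uM`` (uM) in ``volume_L`` liters."""
    if conc_uM < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {conc_uM}")
    if volume_L <= 0:
        raise InvalidParameterError(f"volume must be > 0, got {volume_L}")
    return conc_uM * 1e-6 * volume_L * AVOGADRO


def concentration_from_molecules(
    n_molecules: float, volume_L: float = DEFAULT_CELL_VOLUME_L
) -> float:
    """Inverse of :func:`molecules_from_concentration`; returns uM."""
    if n_molecules < 0:
        raise InvalidParameterError(f"molecule count must be >= 0, got {n_molecules}")
    if volume_L <= 0:
        raise InvalidParameterError(f"volume must be > 0, got {volume_L}")
    return n_molecules / (1e-6 * volume_L * AVOGADRO)
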