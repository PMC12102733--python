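"""Kinetic rate laws and the inhibition-mechanism taxonomy.

The central objects are the Michaelis–Menten rate law

    v = Vmax * S / (KM + S)

and the general (mixed) inhibitor model

    v = Vmax * S / ( KM * (1 + I/Ki) + S * (1 + I/Ki') )

in which ``Ki`` is the dissociation constant of the inhibitor from free
enzyme (EI complex) and ``Ki'`` from the enzyme–substrate complex (ESI).
The classical mechanisms are the finiteness patterns of ``(Ki, Ki')``:

==============  ==========  ==========
mechanism       Ki          Ki'
==============  ==========  ==========
none            infinite    infinite
competitive     finite      infinite
uncompetitive   infinite    finite
noncompetitive  finite      finite, equal to Ki
mixed           finite      finite, unequal
==============  ==========  ==========

Infinite constants are represented explicitly as ``math.inf`` and the
corresponding ``I/K`` term is exactly zero — never approximated by a huge
number — so the taxonomy is checkable and the algebra exact.

Units: concentrations in uM, velocities in pmol min^-1 ug^-1 (specific
activity). All computation stays in uM; the nM conversion needed by the
substrate-over-velocity secondary plot lives in :mod:`inhibkin.graphical`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Mechanism",
    "KineticParameters",
    "ApparentParameters",
    "mm_velocity",
    "inhibited_velocity",
    "apparent_parameters",
]


class Mechanism(str, Enum):
    """Inhibition-mechanism labels of the general inhibitor model."""

    NONE = "none"
    COMPETITIVE = "competitive"
    NONCOMPETITIVE = "noncompetitive"
    MIXED = "mixed"
    UNCOMPETITIVE = "uncompetitive"
    INDETERMINATE = "indeterminate"  # classifier-only verdict, never a truth


def _check_positive(name: str, value: float, allow_inf: bool = False) -> None:
    if allow_inf and math.isinf(value) and value > 0:
        return
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Ground-truth or fitted kinetic constants.

    Parameters
    ----------
    km : float
        Michaelis–Menten constant, uM.
    vmax : float
        Maximal specific activity, pmol min^-1 ug^-1.
    ki : float
        Inhibition constant of the EI complex, uM; ``math.inf`` when the
        inhibitor does not bind free enzyme.
    ki_prime : float
        Inhibition constant of the ESI complex, uM; ``math.inf`` when the
        inhibitor does not bind the enzyme–substrate complex.
    """

    km: float
    vmax: float
    ki: float = math.inf
    ki_prime: float = math.inf

    def __post_init__(self) -> None:
        _check_positive("km", self.km)
        _check_positive("vmax", self.vmax)
        _check_positive("ki", self.ki, allow_inf=True)
        _check_positive("ki_prime", self.ki_prime, allow_inf=True)

    @property
    def mechanism(self) -> Mechanism:
        ki_fin = math.isfinite(self.ki)
        kip_fin = math.isfinite(self.ki_prime)
        if not ki_fin and not kip_fin:
            return Mechanism.NONE
        if ki_fin and not kip_fin:
            return Mechanism.COMPETITIVE
        if not ki_fin and kip_fin:
            return Mechanism.UNCOMPETITIVE
        if self.ki == self.ki_prime:
            return Mechanism.NONCOMPETITIVE
        return Mechanism.MIXED


@dataclass(frozen=True)
class ApparentParameters:
    """Michaelis–Menten constants at a fixed inhibitor concentration."""

    i: float  # inhibitor concentration, uM
    km_app: float  # uM
    vmax_app: float  # pmol min^-1 ug^-1


def _as_nonneg_array(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def mm_velocity(s, km: float, vmax: float):
    """Michaelis–Menten velocity ``Vmax*S/(KM+S)``.

    Accepts scalar or array ``s`` (uM); returns the same shape.
    Zero at ``s = 0``, strictly increasing in ``s`` and bounded by ``vmax``.
    """
    s_arr = _as_nonneg_array("s", s)
    _check_positive("km", km)
    _check_positive("vmax", vmax)
    out = vmax * s_arr / (km + s_arr)
    return float(out) if np.isscalar(s) or np.ndim(s) == 0 else out


def _inhibition_factor(i_arr: np.ndarray, k: float) -> np.ndarray:
    """``1 + I/K`` with an infinite K contributing exactly zero."""
    if math.isinf(k):
        return np.ones_like(i_arr)
    return 1.0 + i_arr / k


def inhibited_velocity(s, i, params: KineticParameters):
    """General inhibitor-model velocity.

    ``v = Vmax*S / ( KM*(1 + I/Ki) + S*(1 + I/Ki') )`` with infinite
    constants removing the corresponding term. Reduces to
    :func:`mm_velocity` at ``I = 0`` or when both constants are infinite.
    """
    s_arr = _as_nonneg_array("s", s)
    i_arr = _as_nonneg_array("i", i)
    denom = params.km * _inhibition_factor(i_arr, params.ki) + s_arr * _inhibition_factor(
        i_arr, params.ki_prime
    )
    out = params.vmax * s_arr / denom
    scalar = (np.isscalar(s) or np.ndim(s) == 0) and (np.isscalar(i) or np.ndim(i) == 0)
    return float(out) if scalar else out


def apparent_parameters(params: KineticParameters, i: float) -> ApparentParameters:
    """Apparent (KM, Vmax) at inhibitor concentration ``i``.

    ``KM_app = KM*(1+I/Ki)/(1+I/Ki')`` and ``Vmax_app = Vmax/(1+I/Ki')``,
    so that the inhibited velocity at fixed ``i`` is exactly Michaelis–Menten
    in the apparent constants. For an uncompetitive inhibitor the ratio
    ``KM_app/Vmax_app`` is independent of ``i`` — the structural fact behind
    the substrate-over-velocity intersection ordinate ``KM/Vmax``.
    """
    i_arr = _as_nonneg_array("i", float(i))
    f_ei = float(_inhibition_factor(i_arr, params.ki))
    f_esi = float(_inhibition_factor(i_arr, params.ki_prime))
    return ApparentParameters(
        i=float(i), km_app=params.km * f_ei / f_esi, vmax_app=params.vmax / f_esi
    )
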