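"""Shared biophysical primitives.

Hill activation curves, the rapid-buffer approximation for cytosolic and
ER calcium buffering, Nernst reversal potentials with empirical linear-
extrapolation shifts, and the surrogate external calcium concentration
used to mimic zero-calcium media.

Internal unit system: concentrations in μM, potentials in mV,
temperature in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "BufferParams",
    "ElectroParams",
    "hill",
    "buffer_factor",
    "free_fraction",
    "reversal_potential",
    "zero_calcium_surrogate",
]

FARADAY = 96485.0  # C/mol
GAS_CONSTANT = 8.315  # J/(K mol)


@dataclass
class BufferParams:
    """Rapid-buffer parameters for cytosol and ER (all in μM).

    The dominant cytosolic buffer is calmodulin (4 sites per molecule;
    25 μM CaM gives ``b0 = 100`` μM of binding sites); the ER buffer is
    calreticulin, lumped into a single site class with an intermediate
    dissociation constant.
    """

    b0: float = 100.0      # cytosolic binding sites, μM
    K_b: float = 0.1       # cytosolic dissociation constant, μM
    b_ER0: float = 30000.0  # ER binding sites, μM (30 mM)
    K_ERb: float = 100.0   # ER dissociation constant, μM (0.1 mM)

    def __post_init__(self) -> None:
        if self.b0 < 0 or self.b_ER0 < 0:
            raise ValueError("buffer concentrations must be >= 0")
        if self.K_b <= 0 or self.K_ERb <= 0:
            raise ValueError("buffer dissociation constants must be > 0")


@dataclass
class ElectroParams:
    """Membrane-potential and Nernst parameters.

    The membrane potential is held fixed at ``V0`` (calcium currents are
    assumed charge-compensated by other ions) and the ER is electrically
    equilibrated with the cytosol, ``V_ER0 = V0``.  ``dV_C`` and
    ``dV_CER`` are empirical shifts correcting the linear I-V
    extrapolation of CRAC and IP3R respectively.
    """

    V0: float = -60.0       # mV
    V_ER0: float = -60.0    # mV
    T_abs: float = 310.0    # K
    dV_C: float = 78.0      # mV, CRAC reversal shift
    dV_CER: float = 63.0    # mV, IP3R/ER reversal shift (fitted)
    C_ext: float = 2000.0   # μM (2 mM)
    z_Ca: int = 2
    F: float = FARADAY
    R_gas: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.T_abs <= 0:
            raise ValueError("absolute temperature must be positive")
        if self.z_Ca != 2:
            raise ValueError("calcium valence must be 2")

    @property
    def nernst_slope(self) -> float:
        """RT/(z_Ca F) in mV."""
        return 1000.0 * self.R_gas * self.T_abs / (self.z_Ca * self.F)


def hill(X, K: float, n: float):
    """Hill function H(X, K, n) = X^n / (X^n + K^n).

    Evaluated as ``1 / (1 + exp(n (log K - log X)))`` so that large Hill
    coefficients stay finite.  Accepts scalars or arrays; X may be 0.
    """
    if K <= 0:
        raise ValueError(f"half-saturation K must be > 0, got {K}")
    if n <= 0:
        raise ValueError(f"Hill coefficient must be > 0, got {n}")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("Hill argument X must be >= 0")
    out = np.zeros_like(X)
    pos = X > 0
    with np.errstate(over="ignore"):
        out[pos] = 1.0 / (1.0 + np.exp(n * (math.log(K) - np.log(X[pos]))))
    if out.ndim == 0:
        return float(out)
    return out


def buffer_factor(C: float, b_total: float, K: float) -> float:
    """Rapid-buffer factor B = b_total K / (C + K)^2.

    ``1 + B`` divides the raw fluxes in the calcium balance equations.
    """
    if C < 0:
        raise ValueError("concentration must be >= 0")
    return b_total * K / (C + K) ** 2


def free_fraction(C: float, b_total: float, K: float) -> float:
    """Fraction of calcium that is free, f = (1 + b_total/(C+K))^-1."""
    if C < 0:
        raise ValueError("concentration must be >= 0")
    return 1.0 / (1.0 + b_total / (C + K))


def reversal_potential(C_out: float, C_in: float, dV: float,
                       ep: ElectroParams) -> float:
    """Nernst reversal potential (mV) with an empirical shift.

    ``Vbar = (RT / z_Ca F) ln(C_out / C_in) - dV``.  Concentrations must
    be strictly positive (the Nernst equation diverges at zero; the cell
    model enforces a concentration floor before calling this).
    """
    if C_out <= 0 or C_in <= 0:
        raise ValueError(
            f"Nernst concentrations must be > 0 (got {C_out}, {C_in})"
        )
    return ep.nernst_slope * math.log(C_out / C_in) - dV


def zero_calcium_surrogate(C0: float, ep: ElectroParams) -> float:
    """External calcium at which the resting CRAC current vanishes.

    Zero-calcium media cannot be represented directly (the Nernst
    potential diverges), so zero-calcium protocols instead set the
    external concentration to the unique value ``C_ext*`` at which the
    CRAC reversal potential equals the resting membrane potential:

        ``C_ext* = C0 exp((V0 + dV_C) z_Ca F / (R T))``

    so that ``I_CRAC(V0, C0, C_ext*) = 0`` by construction.
    """
    if C0 <= 0:
        raise ValueError("C0 must be > 0")
    return C0 * math.exp((ep.V0 + ep.dV_C) / ep.nernst_slope)
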