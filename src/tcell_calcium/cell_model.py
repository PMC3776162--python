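"""Whole-cell model assembly.

Couples the single-protein models into the 7-variable ODE system

* ``C``      free cytosolic calcium (μM)
* ``C_ER``   free ER calcium (μM)
* ``P``      IP3 (μM)
* ``rho_CRAC``  active CRAC density in the plasma membrane (1/μm²)
* ``g_IP3R``, ``h_IP3R``  IP3R activation/inhibition gates
* ``g_PMCA`` PMCA activation gate

and provides the steady-state closure that fixes the four parameters
(``rho_PMCA``, ``rho_IP3R``, ``gamma_P``, ``rho_CRAC_minus``) not known
from experiment by requiring the resting state to be an exact fixed
point of the dynamics.

Flux bookkeeping: a single-protein current I [A] times a surface density
rho [1/μm²] times a surface-to-volume ratio xi [1/μm] divided by
``z_Ca F`` [C/mol] is a molar rate per μm³; multiplying by 1e15 μm³/L
and 1e6 μM/M gives μM/s — hence the factor 1e21/(z_Ca F).  The rapid
buffers divide each compartment's raw flux by (1 + B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .biophysics import BufferParams, ElectroParams, buffer_factor, hill
from .geometry import GeometryDerived, GeometryParams, derive_geometry
from .transmembrane import (
    CracParams,
    Ip3rParams,
    PmcaParams,
    SercaParams,
    crac_current,
    crac_target_density,
    ip3r_current,
    ip3r_gates_inf,
    pmca_current,
    pmca_gate_inf,
    serca_current,
)

__all__ = [
    "Ip3Params",
    "RestParams",
    "CellParams",
    "CellState",
    "ClosureError",
    "FloorBreach",
    "steady_state_closure",
    "resting_state",
    "rhs",
    "CompiledModel",
    "CONC_FLOOR",
]

#: concentration floor (μM) keeping the Nernst terms finite
CONC_FLOOR = 1e-4

STATE_NAMES = ("C", "C_ER", "P", "rho_CRAC", "g_IP3R", "h_IP3R", "g_PMCA")


class ClosureError(ValueError):
    """Raised when a steady-state closure denominator vanishes."""


class FloorBreach(RuntimeError):
    """Raised when a concentration hits the floor during integration."""


@dataclass
class Ip3Params:
    """IP3 production/degradation: dP/dt = beta_P H(C, C_P, n_P) T(t) - gamma_P P."""

    P0: float = 0.0087       # resting IP3, μM (8.7 nM)
    beta_P: float = 0.0006   # production rate, μM/s (0.6 nM/s)
    gamma_P: float = float("nan")  # degradation rate 1/s, set by closure
    C_P: float = 0.5         # μM, calcium half-point of production
    n_P: float = 1.0

    def __post_init__(self) -> None:
        if self.P0 <= 0 or self.beta_P <= 0:
            raise ValueError("P0 and beta_P must be > 0")


@dataclass
class RestParams:
    """Resting concentrations defining the steady state."""

    C0: float = 0.1       # μM
    C_ER0: float = 400.0  # μM (0.4 mM)

    def __post_init__(self) -> None:
        if self.C0 <= 0 or self.C_ER0 <= 0:
            raise ValueError("resting concentrations must be > 0")


@dataclass
class CellParams:
    """The full parameter set of the cell model."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    buffers: BufferParams = field(default_factory=BufferParams)
    electro: ElectroParams = field(default_factory=ElectroParams)
    crac: CracParams = field(default_factory=CracParams)
    ip3r: Ip3rParams = field(default_factory=Ip3rParams)
    pmca: PmcaParams = field(default_factory=PmcaParams)
    serca: SercaParams = field(default_factory=SercaParams)
    ip3: Ip3Params = field(default_factory=Ip3Params)
    rest: RestParams = field(default_factory=RestParams)

    def derived_geometry(self) -> GeometryDerived:
        return derive_geometry(self.geometry)

    def copy(self) -> "CellParams":
        return CellParams(
            geometry=replace(self.geometry), buffers=replace(self.buffers),
            electro=replace(self.electro), crac=replace(self.crac),
            ip3r=replace(self.ip3r), pmca=replace(self.pmca),
            serca=replace(self.serca), ip3=replace(self.ip3),
            rest=replace(self.rest),
        )


@dataclass
class CellState:
    """The seven dynamical variables."""

    C: float
    C_ER: float
    P: float
    rho_CRAC: float
    g_IP3R: float
    h_IP3R: float
    g_PMCA: float

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.C_ER, self.P, self.rho_CRAC,
                         self.g_IP3R, self.h_IP3R, self.g_PMCA])

    @classmethod
    def from_array(cls, y) -> "CellState":
        return cls(*(float(v) for v in y))


def steady_state_closure(p: CellParams) -> tuple[float, float, float, float]:
    """Fix the four steady-state-derived parameters in place.

    Requires the resting state to be a fixed point of each equation:

    * PMCA density balances the resting CRAC influx,
      ``rho_PMCA = -rho_CRAC0 I_CRAC0 / I_PMCA0``;
    * IP3R density balances the resting SERCA uptake,
      ``rho_IP3R = -rho_SERCA I_SERCA0 / I_IP3R0``;
    * IP3 degradation balances resting production,
      ``gamma_P = beta_P H(C0, C_P, n_P) / P0``;
    * the minimal CRAC density makes the recruitment target equal the
      resting density, ``rho_bar(C_ER0) = rho_CRAC0``, i.e.
      ``rho_minus = rho0 (1 - f_CRAC (1 - H0)) / H0`` with
      ``H0 = H(C_ER0, C_CRAC, n_CRAC)``.

    Returns ``(rho_PMCA, rho_IP3R, gamma_P, rho_CRAC_minus)`` and writes
    them into ``p``.  Idempotent: the derived values depend only on
    non-derived parameters.
    """
    ep, rest = p.electro, p.rest
    C0, C_ER0 = rest.C0, rest.C_ER0

    I_crac0 = crac_current(ep.V0, C0, ep.C_ext, p.crac, ep)
    I_pmca0 = pmca_current(pmca_gate_inf(C0, p.pmca), p.pmca)
    if I_pmca0 == 0.0:
        raise ClosureError("resting PMCA current is zero; rho_PMCA diverges")
    rho_pmca = -p.crac.rho0 * I_crac0 / I_pmca0

    g0, h0 = ip3r_gates_inf(C0, p.ip3.P0, p.ip3r)
    I_ip3r0 = ip3r_current(g0, h0, ep.V0, ep.V_ER0, C0, C_ER0, p.ip3r, ep)
    I_serca0 = serca_current(C0, p.serca)
    if I_ip3r0 == 0.0:
        raise ClosureError("resting IP3R current is zero; rho_IP3R diverges")
    rho_ip3r = -p.serca.rho * I_serca0 / I_ip3r0

    gamma_p = p.ip3.beta_P * hill(C0, p.ip3.C_P, p.ip3.n_P) / p.ip3.P0

    H0 = hill(C_ER0, p.crac.C_CRAC, p.crac.n_CRAC)
    if H0 == 0.0:
        raise ClosureError("resting CRAC recruitment Hill term is zero")
    f = p.crac.f_CRAC
    rho_minus = p.crac.rho0 * (1.0 - f * (1.0 - H0)) / H0
    if rho_minus < 0:
        raise ClosureError(
            "closure yields negative rho_CRAC_minus; rho_plus too large "
            "for the resting ER calcium"
        )
    if not rho_minus <= p.crac.rho0 <= p.crac.rho_plus:
        raise ClosureError(
            "closure violates rho_minus <= rho0 <= rho_plus "
            f"({rho_minus:.4g}, {p.crac.rho0:.4g}, {p.crac.rho_plus:.4g})"
        )

    p.pmca.rho = float(rho_pmca)
    p.ip3r.rho = float(rho_ip3r)
    p.ip3.gamma_P = float(gamma_p)
    p.crac.rho_minus = float(rho_minus)
    return float(rho_pmca), float(rho_ip3r), float(gamma_p), float(rho_minus)


def resting_state(p: CellParams) -> CellState:
    """The closed resting state; an exact fixed point of :func:`rhs`."""
    if math.isnan(p.ip3.gamma_P):
        raise ValueError("apply steady_state_closure before resting_state")
    C0, P0 = p.rest.C0, p.ip3.P0
    g0, h0 = ip3r_gates_inf(C0, P0, p.ip3r)
    return CellState(
        C=C0, C_ER=p.rest.C_ER0, P=P0, rho_CRAC=p.crac.rho0,
        g_IP3R=g0, h_IP3R=h0, g_PMCA=pmca_gate_inf(C0, p.pmca),
    )


class CompiledModel:
    """Parameter set flattened to plain floats for a fast ODE right side.

    Built once per integration; ``__call__(t, y, T, C_ext, blocks)``
    evaluates the 7-component derivative with the protocol segment
    settings passed explicitly.
    """

    def __init__(self, p: CellParams):
        g = p.derived_geometry()
        ep = p.electro
        self.slope = ep.nernst_slope       # mV
        self.V0 = ep.V0
        self.dV_C = ep.dV_C
        self.dV_CER = ep.dV_CER
        self.xi = g.xi
        self.xi_ERC = g.xi_ERC
        self.xi_ER = g.xi_ER
        # A/μm³ → μM/s (see module docstring)
        self.flux = 1e21 / (ep.z_Ca * ep.F)
        b = p.buffers
        self.b0, self.K_b = b.b0, b.K_b
        self.b_ER0, self.K_ERb = b.b_ER0, b.K_ERb
        c = p.crac
        self.g_crac = c.g_bar
        self.rho_minus, self.rho_plus = c.rho_minus, c.rho_plus
        self.C_CRAC, self.n_CRAC, self.tau_CRAC = c.C_CRAC, c.n_CRAC, c.tau_CRAC
        i = p.ip3r
        self.g_ip3r, self.g_max = i.g_bar, i.g_max
        self.C_act, self.n_act = i.C_act, i.n_act
        self.n_inh, self.C_inh_bar = i.n_inh, i.C_inh_bar
        self.n_C, self.P_half = i.n_C, i.P_half
        self.tau_act, self.theta_inh = i.tau_act, i.theta_inh
        self.rho_ip3r = i.rho
        pm = p.pmca
        self.I_pmca_bar, self.C_pmca, self.n_pmca = pm.I_bar, pm.C_half, pm.n
        self.tau_pmca, self.rho_pmca = pm.tau, pm.rho
        s = p.serca
        self.I_serca_bar, self.C_serca, self.n_serca = s.I_bar, s.C_half, s.n
        self.rho_serca = s.rho
        ip3 = p.ip3
        self.beta_P, self.gamma_P = ip3.beta_P, ip3.gamma_P
        self.C_P, self.n_P = ip3.C_P, ip3.n_P
        if math.isnan(self.gamma_P):
            raise ValueError("apply steady_state_closure before compiling")

    def as_vector(self) -> np.ndarray:
        """Flatten to the float64 layout of the compiled RK45 core."""
        return np.array([
            self.slope, self.V0, self.dV_C, self.dV_CER,
            self.xi, self.xi_ERC, self.xi_ER, self.flux,
            self.b0, self.K_b, self.b_ER0, self.K_ERb,
            self.g_crac, self.rho_minus, self.rho_plus, self.C_CRAC,
            self.n_CRAC, self.tau_CRAC,
            self.g_ip3r, self.g_max, self.C_act, self.n_act, self.n_inh,
            self.C_inh_bar, self.n_C, self.P_half, self.tau_act,
            self.theta_inh, self.rho_ip3r,
            self.I_pmca_bar, self.C_pmca, self.n_pmca, self.tau_pmca,
            self.rho_pmca,
            self.I_serca_bar, self.C_serca, self.n_serca, self.rho_serca,
            self.beta_P, self.gamma_P, self.C_P, self.n_P,
        ])

    # -- single-protein currents at a state point ----------------------
    def currents(self, C: float, C_ER: float, g_ip3r: float, h_ip3r: float,
                 g_pmca: float, C_ext: float,
                 serca_blocked: bool = False, pmca_blocked: bool = False,
                 crac_blocked: bool = False) -> tuple[float, float, float, float]:
        """(I_CRAC, I_IP3R, I_PMCA, I_SERCA) in A; blocks zero currents."""
        Cs = max(C, CONC_FLOOR)
        CERs = max(C_ER, CONC_FLOOR)
        if crac_blocked:
            I_crac = 0.0
        else:
            vbar_c = self.slope * math.log(C_ext / Cs) - self.dV_C
            I_crac = self.g_crac * (self.V0 - vbar_c) * 1e-3
        if serca_blocked:
            I_serca = 0.0
        else:
            I_serca = self.I_serca_bar * _hill_f(Cs, self.C_serca, self.n_serca)
        vbar_cer = self.slope * math.log(CERs / Cs) - self.dV_CER
        I_ip3r = self.g_ip3r * g_ip3r * h_ip3r * (-vbar_cer) * 1e-3
        if I_ip3r > 0.0:
            I_ip3r = 0.0  # no ER uptake through the receptor
        I_pmca = 0.0 if pmca_blocked else self.I_pmca_bar * g_pmca
        return I_crac, I_ip3r, I_pmca, I_serca

    def __call__(self, t: float, y, T: float, C_ext: float,
                 serca_blocked: bool, pmca_blocked: bool,
                 crac_blocked: bool) -> np.ndarray:
        C, C_ER, P, rho_crac, g_i, h_i, g_p = y
        Cs = max(C, CONC_FLOOR)
        CERs = max(C_ER, CONC_FLOOR)
        I_crac, I_ip3r, I_pmca, I_serca = self.currents(
            Cs, CERs, g_i, h_i, g_p, C_ext,
            serca_blocked, pmca_blocked, crac_blocked)

        B_C = self.b0 * self.K_b / (Cs + self.K_b) ** 2
        B_CER = self.b_ER0 * self.K_ERb / (CERs + self.K_ERb) ** 2

        er_exchange = (self.rho_serca * I_serca + self.rho_ip3r * I_ip3r)
        dC = -(self.xi * self.rho_pmca * I_pmca
               + self.xi * rho_crac * I_crac
               + self.xi_ERC * er_exchange) * self.flux / (1.0 + B_C)
        dCER = self.xi_ER * er_exchange * self.flux / (1.0 + B_CER)

        dP = self.beta_P * _hill_f(Cs, self.C_P, self.n_P) * T \
            - self.gamma_P * P

        h_er = _hill_f(CERs, self.C_CRAC, self.n_CRAC)
        rho_bar = self.rho_minus + (self.rho_plus - self.rho_minus) * (1.0 - h_er)
        drho = (rho_bar - rho_crac) / self.tau_CRAC

        dg_i = (self.g_max * _hill_f(Cs, self.C_act, self.n_act) - g_i) \
            / self.tau_act
        C_inh = self.C_inh_bar * _hill_f(P, self.P_half, self.n_C)
        h_inf = _hill_rev(C_inh, Cs, self.n_inh)
        dh_i = (h_inf - h_i) / self.theta_inh

        dg_p = (_hill_f(Cs, self.C_pmca, self.n_pmca) - g_p) / self.tau_pmca

        return np.array([dC, dCER, dP, drho, dg_i, dh_i, dg_p])


def _hill_f(X: float, K: float, n: float) -> float:
    """Scalar Hill function in log space (X >= 0)."""
    if X <= 0.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(n * (math.log(K) - math.log(X))))


def _hill_rev(K_arg: float, X: float, n: float) -> float:
    """H(K_arg, X, n): decreasing in X; equals 1 - H(X, K_arg, n)."""
    if K_arg <= 0.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(n * (math.log(X) - math.log(K_arg))))


def rhs(state: CellState, t: float, proto, p: CellParams) -> np.ndarray:
    """Time derivative of the 7 state variables under a protocol.

    Convenience wrapper around :class:`CompiledModel` for single-point
    evaluation; the integrator uses the compiled form directly.
    """
    seg = proto.query(t)
    cm = CompiledModel(p)
    return cm(t, state.as_array(), seg.T, seg.C_ext,
              seg.serca_blocked, seg.pmca_blocked, seg.crac_blocked)
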