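"""Single transmembrane protein models: CRAC, IP3R, PMCA, SERCA.

Each protein is described at the single-molecule level — a conductance or
maximal pump current plus gating — and scaled to whole-cell fluxes by
surface densities elsewhere.  Sign convention: calcium entering the
cytosol is a *negative* electrical current; pumps (PMCA, SERCA) carry
positive currents out of the cytosol.

Units: conductances are stored in S, currents returned in A,
concentrations in μM, potentials in mV (converted to V at the Ohmic
step), densities in 1/μm², times in s.
"""

from __future__ import annotations

from dataclasses import dataclass

from .biophysics import ElectroParams, hill, reversal_potential

__all__ = [
    "CracParams",
    "Ip3rParams",
    "PmcaParams",
    "SercaParams",
    "crac_current",
    "crac_target_density",
    "ip3r_gates_inf",
    "ip3r_current",
    "pmca_gate_inf",
    "pmca_current",
    "serca_current",
]

_MV_TO_V = 1e-3


@dataclass
class CracParams:
    """Calcium-release activated channel (Orai/STIM).

    Active-channel density is dynamic: store depletion (low ER calcium)
    recruits channels toward ``rho_plus``, replete stores relax them
    toward ``rho_minus``.  ``rho_minus`` is fixed by the steady-state
    closure; ``rho_plus = f_CRAC * rho0`` with the fold constrained by
    experiment (about 9–10-fold current increase on full depletion).
    """

    g_bar: float = 2e-15        # single-channel conductance, S (2 fS)
    rho0: float = 0.6           # resting active density, 1/μm²
    rho_plus: float = 3.9       # maximal active density, 1/μm²
    rho_minus: float = 0.5115   # minimal active density, 1/μm² (derived)
    C_CRAC: float = 169.0       # ER-calcium half-point of recruitment, μM
    n_CRAC: float = 4.2         # recruitment Hill coefficient
    tau_CRAC: float = 5.0       # recruitment time scale, s

    def __post_init__(self) -> None:
        if min(self.rho0, self.rho_plus, self.rho_minus) < 0:
            raise ValueError("CRAC densities must be >= 0")
        if not self.rho_minus <= self.rho0 <= self.rho_plus:
            raise ValueError(
                "require rho_minus <= rho0 <= rho_plus, got "
                f"{self.rho_minus}, {self.rho0}, {self.rho_plus}"
            )

    @property
    def f_CRAC(self) -> float:
        """Maximal recruitment fold, rho_plus / rho0."""
        return self.rho_plus / self.rho0


@dataclass
class Ip3rParams:
    """IP3 receptor, Mak–McBride–Foskett gating.

    Open probability is the product of a calcium-activation gate ``g``
    and an inhibition gate ``h`` whose half-point ``C_inh`` rises with
    IP3 — together producing the log-bell-shaped calcium dependence.
    ``C_inh`` follows IP3 in quasi-steady state; only ``g`` and ``h``
    relax with finite time constants.
    """

    g_bar: float = 0.064e-12  # channel conductance, S (0.064 pS)
    g_max: float = 0.81       # maximal activation
    C_act: float = 0.21       # μM, activation half-point
    n_act: float = 1.9
    n_inh: float = 3.9
    C_inh_bar: float = 52.0   # μM, maximal inhibition half-point
    n_C: float = 4.0
    P_half: float = 0.050     # μM, IP3 half-point of C_inh
    tau_act: float = 0.1      # s, activation time constant
    theta_inh: float = 0.3    # s, inactivation time constant
    rho: float = 11.35        # 1/μm² on ER membrane (derived by closure)

    def __post_init__(self) -> None:
        if not 0 < self.g_max <= 1:
            raise ValueError("g_max must be in (0, 1]")
        if min(self.tau_act, self.theta_inh) <= 0:
            raise ValueError("IP3R time constants must be > 0")


@dataclass
class PmcaParams:
    """Plasma-membrane calcium ATPase (isoform 4b in Jurkat cells).

    ``I_bar`` is the single-pump current at full activation, from the
    ~30 Hz turnover rate carrying two charges per cycle.  Activation by
    cytosolic calcium is Hill-shaped and delayed by ``tau`` (~50 s for
    the 4b isoform).
    """

    I_bar: float = 1e-17   # A (1e-5 pA), positive outward
    C_half: float = 0.2    # μM
    n: float = 2.0
    tau: float = 50.0      # s, activation delay
    rho: float = 68.57     # 1/μm² (derived by closure)

    def __post_init__(self) -> None:
        if self.I_bar <= 0 or self.tau <= 0:
            raise ValueError("I_bar and tau must be > 0")


@dataclass
class SercaParams:
    """Sarco/endoplasmic reticulum calcium ATPase (isoform 2b).

    Instantaneous Hill activation by cytosolic calcium; ``I_bar`` from
    the 5 Hz turnover of SERCA2b with two calcium ions per cycle.
    """

    I_bar: float = 3e-18   # A (3e-6 pA), positive cytosol→ER
    C_half: float = 0.25   # μM
    n: float = 2.0
    rho: float = 700.0     # 1/μm² on ER membrane (fitted)

    def __post_init__(self) -> None:
        if min(self.I_bar, self.C_half, self.n, self.rho) <= 0:
            raise ValueError("SERCA parameters must be > 0")


def crac_current(V: float, C: float, C_ext: float, cp: CracParams,
                 ep: ElectroParams) -> float:
    """Single CRAC channel current (A), Ohmic with shifted reversal.

    Negative when calcium flows into the cytosol.  Deliberately *not*
    clamped: a small outward CRAC current at very low external calcium
    is part of the model (it supports extrusion when pumps are blocked).
    """
    vbar = reversal_potential(C_ext, C, ep.dV_C, ep)
    return cp.g_bar * (V - vbar) * _MV_TO_V


def crac_target_density(C_ER: float, cp: CracParams) -> float:
    """Steady-state active CRAC density (1/μm²) at ER calcium ``C_ER``.

    ``rho_bar = rho_minus + (rho_plus - rho_minus)(1 - H(C_ER, C_CRAC,
    n_CRAC))`` — monotone decreasing in ER calcium, bounded by
    [rho_minus, rho_plus].
    """
    if C_ER < 0:
        raise ValueError("C_ER must be >= 0")
    h = hill(C_ER, cp.C_CRAC, cp.n_CRAC)
    return cp.rho_minus + (cp.rho_plus - cp.rho_minus) * (1.0 - h)


def ip3r_gates_inf(C: float, P: float, ip: Ip3rParams) -> tuple[float, float]:
    """Steady-state IP3R gates (g_inf, h_inf) at calcium C and IP3 P."""
    g_inf = ip.g_max * hill(C, ip.C_act, ip.n_act)
    C_inh = ip.C_inh_bar * hill(P, ip.P_half, ip.n_C)
    # H(C_inh, C, n): inhibition gate closed (h→0) when C >> C_inh
    if C <= 0:
        h_inf = 1.0
    else:
        h_inf = hill(C_inh, C, ip.n_inh)
    return float(g_inf), float(h_inf)


def ip3r_current(g: float, h: float, V: float, V_ER: float, C: float,
                 C_ER: float, ip: Ip3rParams, ep: ElectroParams) -> float:
    """Single IP3R current (A); rectified to be non-positive.

    ``I = g_bar g h (V - V_ER - Vbar_CER)``, clamped at zero from above:
    the receptor releases ER calcium but never takes calcium up.
    """
    if not (0.0 <= g <= 1.0 and 0.0 <= h <= 1.0):
        raise ValueError("IP3R gates must lie in [0, 1]")
    vbar = reversal_potential(C_ER, C, ep.dV_CER, ep)
    raw = ip.g_bar * (V - V_ER - vbar) * _MV_TO_V * g * h
    return min(raw, 0.0)


def pmca_gate_inf(C: float, pp: PmcaParams) -> float:
    """Steady-state PMCA activation H(C, C_half, n)."""
    return float(hill(C, pp.C_half, pp.n))


def pmca_current(g: float, pp: PmcaParams) -> float:
    """Single PMCA current (A), positive outward."""
    if not 0.0 <= g <= 1.0:
        raise ValueError("PMCA gate must lie in [0, 1]")
    return pp.I_bar * g


def serca_current(C: float, sp: SercaParams) -> float:
    """Single SERCA current (A), positive cytosol→ER, instantaneous."""
    return sp.I_bar * float(hill(C, sp.C_half, sp.n))
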