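"""Parameter configuration files.

The YAML schema mirrors the parameter-table grouping of the model, with
units spelled out in the key names (values are converted to the internal
unit system — μM, S, A, s — on load).  The four steady-state-derived
parameters (``gamma_P``, ``rho_PMCA``, ``rho_IP3R``, ``rho_CRAC_minus``)
may be absent (they are computed by the closure) or present (they are
then verified against the closure, with a warning on mismatch).
"""

from __future__ import annotations

import math
import warnings
from importlib import resources
from pathlib import Path

import yaml

from .biophysics import BufferParams, ElectroParams
from .cell_model import CellParams, Ip3Params, RestParams, steady_state_closure
from .geometry import GeometryParams
from .transmembrane import CracParams, Ip3rParams, PmcaParams, SercaParams

__all__ = ["load_params", "save_params", "packaged_default_path"]

_DERIVED_RTOL = 5e-4  # printed derived values carry 4 significant figures


def packaged_default_path() -> Path:
    """Path of the packaged default parameter file."""
    return Path(resources.files("tcell_calcium") / "data" / "default_params.yaml")


def load_params(path: str | Path | None = None, close: bool = True) -> CellParams:
    """Load a parameter config; apply the steady-state closure.

    With ``close=False`` the closure is skipped (derived fields stay as
    given or NaN).
    """
    path = packaged_default_path() if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())

    g = raw["geometry"]
    geometry = GeometryParams(
        R_cell=g["R_cell_um"], f_R=g["f_R"], f_V=g["f_V"], f_A=g["f_A"],
        C_m=g["C_m_pF_per_um2"],
    )
    pot = raw["potentials"]
    electro = ElectroParams(
        V0=pot["V0_mV"], V_ER0=pot["V_ER0_mV"], T_abs=pot["T_K"],
        dV_C=pot["dV_C_mV"], dV_CER=pot["dV_CER_mV"],
        C_ext=pot["C_ext_mM"] * 1e3,
    )
    b = raw["buffers"]
    buffers = BufferParams(
        b0=b["b0_uM"], K_b=b["K_b_uM"],
        b_ER0=b["b_ER0_mM"] * 1e3, K_ERb=b["K_ERb_mM"] * 1e3,
    )
    r = raw["resting"]
    rest = RestParams(C0=r["C0_uM"], C_ER0=r["C_ER0_mM"] * 1e3)
    c = raw["crac"]
    crac = CracParams(
        g_bar=c["g_bar_fS"] * 1e-15, rho0=c["rho0_per_um2"],
        rho_plus=c["rho_plus_per_um2"],
        rho_minus=c.get("rho_minus_per_um2", 0.0),
        C_CRAC=c["C_CRAC_uM"], n_CRAC=c["n_CRAC"], tau_CRAC=c["tau_CRAC_s"],
    )
    i = raw["ip3r"]
    ip3r = Ip3rParams(
        g_bar=i["g_bar_pS"] * 1e-12, g_max=i["g_max"], C_act=i["C_act_uM"],
        n_act=i["n_act"], n_inh=i["n_inh"], C_inh_bar=i["C_inh_bar_uM"],
        n_C=i["n_C"], P_half=i["P_half_uM"], tau_act=i["tau_act_s"],
        theta_inh=i["theta_inh_s"], rho=i.get("rho_per_um2", 1.0),
    )
    pm = raw["pmca"]
    pmca = PmcaParams(
        I_bar=pm["I_bar_pA"] * 1e-12, C_half=pm["C_half_uM"], n=pm["n"],
        tau=pm["tau_s"], rho=pm.get("rho_per_um2", 1.0),
    )
    s = raw["serca"]
    serca = SercaParams(
        I_bar=s["I_bar_pA"] * 1e-12, C_half=s["C_half_uM"], n=s["n"],
        rho=s["rho_per_um2"],
    )
    ip = raw["ip3"]
    ip3 = Ip3Params(
        P0=ip["P0_nM"] * 1e-3, beta_P=ip["beta_P_nM_per_s"] * 1e-3,
        gamma_P=ip.get("gamma_P_per_s", float("nan")),
        C_P=ip["C_P_uM"], n_P=ip["n_P"],
    )

    p = CellParams(geometry=geometry, buffers=buffers, electro=electro,
                   crac=crac, ip3r=ip3r, pmca=pmca, serca=serca,
                   ip3=ip3, rest=rest)
    if close:
        stated = {
            "gamma_P": ip.get("gamma_P_per_s"),
            "rho_PMCA": pm.get("rho_per_um2"),
            "rho_IP3R": i.get("rho_per_um2"),
            "rho_CRAC_minus": c.get("rho_minus_per_um2"),
        }
        rho_pmca, rho_ip3r, gamma_p, rho_minus = steady_state_closure(p)
        computed = {"gamma_P": gamma_p, "rho_PMCA": rho_pmca,
                    "rho_IP3R": rho_ip3r, "rho_CRAC_minus": rho_minus}
        for name, given in stated.items():
            if given is None:
                continue
            got = computed[name]
            if not math.isclose(given, got, rel_tol=_DERIVED_RTOL):
                warnings.warn(
                    f"config states {name} = {given:.6g} but the "
                    f"steady-state closure gives {got:.6g}; using the "
                    "closure value", stacklevel=2,
                )
    return p


def save_params(p: CellParams, path: str | Path) -> None:
    """Write a parameter set back to the YAML schema (paper units)."""
    doc = {
        "geometry": {
            "R_cell_um": p.geometry.R_cell, "f_R": p.geometry.f_R,
            "f_V": p.geometry.f_V, "f_A": p.geometry.f_A,
            "C_m_pF_per_um2": p.geometry.C_m,
        },
        "potentials": {
            "T_K": p.electro.T_abs, "V0_mV": p.electro.V0,
            "V_ER0_mV": p.electro.V_ER0, "dV_C_mV": p.electro.dV_C,
            "dV_CER_mV": p.electro.dV_CER, "C_ext_mM": p.electro.C_ext / 1e3,
        },
        "resting": {"C0_uM": p.rest.C0, "C_ER0_mM": p.rest.C_ER0 / 1e3},
        "buffers": {
            "b0_uM": p.buffers.b0, "K_b_uM": p.buffers.K_b,
            "b_ER0_mM": p.buffers.b_ER0 / 1e3,
            "K_ERb_mM": p.buffers.K_ERb / 1e3,
        },
        "ip3": {
            "P0_nM": p.ip3.P0 * 1e3, "beta_P_nM_per_s": p.ip3.beta_P * 1e3,
            "C_P_uM": p.ip3.C_P, "n_P": p.ip3.n_P,
            **({} if math.isnan(p.ip3.gamma_P)
               else {"gamma_P_per_s": p.ip3.gamma_P}),
        },
        "crac": {
            "g_bar_fS": p.crac.g_bar / 1e-15, "rho0_per_um2": p.crac.rho0,
            "rho_plus_per_um2": p.crac.rho_plus,
            "rho_minus_per_um2": p.crac.rho_minus,
            "C_CRAC_uM": p.crac.C_CRAC, "n_CRAC": p.crac.n_CRAC,
            "tau_CRAC_s": p.crac.tau_CRAC,
        },
        "ip3r": {
            "g_bar_pS": p.ip3r.g_bar / 1e-12, "g_max": p.ip3r.g_max,
            "C_act_uM": p.ip3r.C_act, "n_act": p.ip3r.n_act,
            "n_inh": p.ip3r.n_inh, "C_inh_bar_uM": p.ip3r.C_inh_bar,
            "n_C": p.ip3r.n_C, "P_half_uM": p.ip3r.P_half,
            "tau_act_s": p.ip3r.tau_act, "theta_inh_s": p.ip3r.theta_inh,
            "rho_per_um2": p.ip3r.rho,
        },
        "pmca": {
            "I_bar_pA": p.pmca.I_bar / 1e-12, "C_half_uM": p.pmca.C_half,
            "n": p.pmca.n, "tau_s": p.pmca.tau, "rho_per_um2": p.pmca.rho,
        },
        "serca": {
            "I_bar_pA": p.serca.I_bar / 1e-12, "C_half_uM": p.serca.C_half,
            "n": p.serca.n, "rho_per_um2": p.serca.rho,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
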