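"""Protocol integration and trace handling.

Integrates the 7-variable cell model over a protocol with an adaptive
explicit Runge–Kutta scheme (scipy's RK45), restarting at each protocol
discontinuity, and samples state, single-protein currents and the four
whole-cell flux terms of the cytosolic balance on a regular output grid.

Traces are tabular: one row per output time with columns

    t, C, C_ER, P, rho_CRAC, g_IP3R, h_IP3R, g_PMCA,
    I_crac, I_ip3r, I_pmca, I_serca,      # single-protein currents, A
    J_crac, J_ip3r, J_pmca, J_serca       # xi*rho*I whole-cell terms, A/μm³

and round-trip losslessly through CSV plus a JSON metadata sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .cell_model import (
    CONC_FLOOR,
    CellParams,
    CellState,
    CompiledModel,
    FloorBreach,
    resting_state,
)
from .protocols import Protocol

__all__ = ["Trace", "integrate", "whole_cell_currents", "write_trace",
           "read_trace", "param_hash", "TRACE_COLUMNS"]

STATE_COLUMNS = ["C", "C_ER", "P", "rho_CRAC", "g_IP3R", "h_IP3R", "g_PMCA"]
CURRENT_COLUMNS = ["I_crac", "I_ip3r", "I_pmca", "I_serca"]
FLUX_COLUMNS = ["J_crac", "J_ip3r", "J_pmca", "J_serca"]
TRACE_COLUMNS = ["t"] + STATE_COLUMNS + CURRENT_COLUMNS + FLUX_COLUMNS


def param_hash(p: CellParams) -> str:
    """Stable short hash of the full parameter set (provenance)."""
    d = {k: dataclasses.asdict(getattr(p, k))
         for k in ("geometry", "buffers", "electro", "crac", "ip3r",
                   "pmca", "serca", "ip3", "rest")}
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class Trace:
    """A sampled trajectory with per-protein current decomposition."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace missing columns: {missing}")
        t = self.data["t"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trace times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    def __getitem__(self, col: str) -> np.ndarray:
        return self.data[col].to_numpy()

    def state_at(self, i: int) -> CellState:
        row = self.data.iloc[i]
        return CellState(*(float(row[c]) for c in STATE_COLUMNS))

    def window(self, t0: float, t1: float) -> pd.DataFrame:
        """Rows with t in [t0, t1]."""
        m = (self.data["t"] >= t0) & (self.data["t"] <= t1)
        return self.data[m]


def _output_times(proto: Protocol, grid: float,
                  sample_times: np.ndarray | None) -> np.ndarray:
    if sample_times is not None:
        out_t = np.unique(np.asarray(sample_times, dtype=float))
        if len(out_t) == 0:
            raise ValueError("sample_times is empty")
        if out_t[0] < 0 or out_t[-1] > proto.t_end:
            raise ValueError(
                f"sample times [{out_t[0]}, {out_t[-1]}] outside the "
                f"protocol span [0, {proto.t_end}]"
            )
        return out_t
    out_t = np.arange(0.0, proto.t_end + 0.5 * grid, grid)
    out_t[-1] = min(out_t[-1], proto.t_end)
    return out_t


def integrate(p: CellParams, proto: Protocol, rtol: float = 1e-8,
              atol: float = 1e-10, max_step: float = 0.5,
              grid: float = 0.5, y0: np.ndarray | None = None,
              sample_times: np.ndarray | None = None,
              method: str = "dopri") -> Trace:
    """Integrate the cell model over a protocol.

    Starts from the closed resting state unless ``y0`` is given.  The
    integration is restarted at every protocol segment boundary (the
    schedule is piecewise constant, so discontinuities are known
    exactly) and sampled every ``grid`` seconds, or at the explicit
    ``sample_times`` if given (must lie within the protocol span; used
    to align output with target time stamps).

    ``method`` selects the stepper: ``"dopri"`` (default) is the
    compiled Dormand–Prince 5(4) core; ``"scipy"`` runs
    ``scipy.integrate.solve_ivp`` RK45 on the same right-hand side and
    exists as an independent cross-check.

    Raises :class:`FloorBreach` if a concentration reaches the floor
    (10⁻⁴ μM), where the Nernst description stops being meaningful.
    """
    cm = CompiledModel(p)
    if y0 is None:
        y0 = resting_state(p).as_array()
    else:
        y0 = np.asarray(y0, dtype=float)

    out_t = _output_times(proto, grid, sample_times)
    if method == "dopri":
        t_all, y_all = _run_dopri(cm, proto, out_t, y0, rtol, atol, max_step)
    elif method == "scipy":
        t_all, y_all = _run_scipy(cm, proto, out_t, y0, rtol, atol, max_step)
    else:
        raise ValueError(f"unknown method {method!r}")

    df = pd.DataFrame(y_all, columns=STATE_COLUMNS)
    df.insert(0, "t", t_all)
    _append_currents(df, cm, proto)
    meta = {
        "method": method,
        "protocol": proto.name,
        "param_hash": param_hash(p),
        "rtol": rtol, "atol": atol, "max_step": max_step, "grid": grid,
    }
    return Trace(data=df, metadata=meta)


def _segment_arrays(proto: Protocol):
    segs = proto.segments
    return (np.array([s.t_start for s in segs]),
            np.array([s.T for s in segs]),
            np.array([s.C_ext for s in segs]),
            np.array([s.serca_blocked for s in segs]),
            np.array([s.pmca_blocked for s in segs]),
            np.array([s.crac_blocked for s in segs]))


def _run_dopri(cm: CompiledModel, proto: Protocol, out_t: np.ndarray,
               y0: np.ndarray, rtol: float, atol: float,
               max_step: float) -> tuple[np.ndarray, np.ndarray]:
    from ._integrator import (STATUS_FLOOR, STATUS_UNDERFLOW,
                              integrate_segments)

    starts, T, Cext, sb, pb, cb = _segment_arrays(proto)
    Y, status, t_stop = integrate_segments(
        cm.as_vector(), starts, T, Cext, sb, pb, cb, proto.t_end,
        out_t, y0, rtol, atol, max_step, CONC_FLOOR)
    if status == STATUS_FLOOR:
        raise FloorBreach(
            f"concentration floor reached at t = {t_stop:.1f} s in "
            f"protocol {proto.name!r}"
        )
    if status == STATUS_UNDERFLOW:
        raise RuntimeError(
            f"step size underflow at t = {t_stop:.3f} s in protocol "
            f"{proto.name!r}"
        )
    return out_t, Y


def _run_scipy(cm: CompiledModel, proto: Protocol, out_t: np.ndarray,
               y0: np.ndarray, rtol: float, atol: float,
               max_step: float) -> tuple[np.ndarray, np.ndarray]:
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    bounds = proto.boundaries
    y = y0
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        seg = proto.query(t0)
        args = (seg.T, seg.C_ext, seg.serca_blocked, seg.pmca_blocked,
                seg.crac_blocked)
        sol = solve_ivp(cm, (t0, t1), y, method="RK45", rtol=rtol,
                        atol=atol, max_step=max_step, dense_output=True,
                        args=args)
        if not sol.success:
            raise RuntimeError(
                f"integration failed in [{t0}, {t1}] of protocol "
                f"{proto.name!r}: {sol.message}"
            )
        last = t1 == bounds[-1]
        mask = (out_t >= t0) & ((out_t <= t1) if last else (out_t < t1))
        t_seg = out_t[mask]
        y_seg = sol.sol(t_seg).T if len(t_seg) else np.empty((0, 7))
        ts.append(t_seg)
        ys.append(y_seg)
        y = sol.y[:, -1]
        if min(sol.y[0].min(), sol.y[1].min()) <= CONC_FLOOR:
            raise FloorBreach(
                f"concentration floor reached within [{t0:.1f}, {t1:.1f}] s "
                f"in protocol {proto.name!r}"
            )
    return np.concatenate(ts), np.vstack(ys)


def _append_currents(df: pd.DataFrame, cm: CompiledModel,
                     proto: Protocol) -> None:
    n = len(df)
    I = np.zeros((n, 4))
    J = np.zeros((n, 4))
    for i in range(n):
        t = df.at[i, "t"]
        seg = proto.query(min(t, proto.t_end))
        I_crac, I_ip3r, I_pmca, I_serca = cm.currents(
            df.at[i, "C"], df.at[i, "C_ER"], df.at[i, "g_IP3R"],
            df.at[i, "h_IP3R"], df.at[i, "g_PMCA"], seg.C_ext,
            seg.serca_blocked, seg.pmca_blocked, seg.crac_blocked)
        I[i] = (I_crac, I_ip3r, I_pmca, I_serca)
        J[i] = (cm.xi * df.at[i, "rho_CRAC"] * I_crac,
                cm.xi_ERC * cm.rho_ip3r * I_ip3r,
                cm.xi * cm.rho_pmca * I_pmca,
                cm.xi_ERC * cm.rho_serca * I_serca)
    df[CURRENT_COLUMNS] = I
    df[FLUX_COLUMNS] = J


def whole_cell_currents(tr: Trace, p: CellParams | None = None) -> pd.DataFrame:
    """The four xi*rho*I whole-cell flux terms plus their net sum.

    Negative terms carry calcium into the cytosol.  At the resting state
    the net sum is zero by the steady-state closure.
    """
    out = tr.data[["t"] + FLUX_COLUMNS].copy()
    out["J_net"] = out[FLUX_COLUMNS].sum(axis=1)
    return out


def write_trace(tr: Trace, path: str | Path) -> None:
    """Write trace CSV and a `.meta.json` sidecar next to it."""
    path = Path(path)
    tr.data.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(tr.metadata, indent=1, sort_keys=True))


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace` (sidecar optional)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} missing columns: {missing}")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Trace(data=df, metadata=meta)
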