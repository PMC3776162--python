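"""Model/Results front end.

`CalciumModel` wraps a target calcium time series together with a
stimulation protocol and a full cell parameter set; ``fit()`` estimates
the six variable parameters by differential evolution and returns a
`CalciumFitResults` carrying the estimates, the quality index, the
sensitivity ledger and a ``summary()`` table — the familiar
model-object / results-object split of statistical modelling packages.

Example
-------
>>> from tcell_calcium import datasets, model
>>> p = datasets.default_params()
>>> target = datasets.generate_target(
...     datasets.TargetSpec(p, noise_sd=0.05, seed=7))
>>> m = model.CalciumModel(target["C"], target["t"], protocol="fig3")
>>> res = m.fit(seed=1)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cell_model import CellParams, resting_state, steady_state_closure
from .datasets import default_params
from .fitting import (
    DEFAULT_VARIABLE_PARAMS,
    FitProblem,
    FitResult,
    fit_parameters,
    get_param,
    quality_index,
    sensitivity_scan,
    simulate_at,
)
from .protocols import Protocol, preset
from .simulate import Trace, integrate

__all__ = ["CalciumModel", "CalciumFitResults"]


class CalciumModel:
    """Whole-cell T-lymphocyte calcium model bound to a target series.

    Parameters
    ----------
    endog : array-like or None
        Target free cytosolic calcium (μM).  May be None for
        simulation-only use.
    times : array-like or None
        Time stamps of the target (s), within the protocol span.
    protocol : str or Protocol
        A preset name (``fig3`` … ``fig7``) or a resolved protocol.
    params : CellParams, optional
        Full parameter set; defaults to the packaged defaults.  The
        steady-state closure is (re-)applied on construction.
    """

    def __init__(self, endog=None, times=None, protocol="fig3",
                 params: CellParams | None = None,
                 t_end: float | None = None):
        self.params = (default_params() if params is None else params.copy())
        steady_state_closure(self.params)
        if isinstance(protocol, Protocol):
            self.protocol = protocol
        else:
            self.protocol = preset(protocol, self.params, t_end=t_end)
        if endog is None:
            self.endog = None
            self.times = None
        else:
            self.endog = np.asarray(endog, dtype=float)
            self.times = np.asarray(times, dtype=float)
            if self.endog.shape != self.times.shape:
                raise ValueError("endog and times must have equal length")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, protocol="fig3",
                       params: CellParams | None = None,
                       t_col: str = "t", c_col: str = "C",
                       t_end: float | None = None) -> "CalciumModel":
        """Build from a DataFrame with time and calcium columns."""
        return cls(df[c_col].to_numpy(), df[t_col].to_numpy(),
                   protocol=protocol, params=params, t_end=t_end)

    # ------------------------------------------------------------------
    def simulate(self, rtol: float = 1e-8, atol: float = 1e-10,
                 grid: float = 0.5) -> Trace:
        """Integrate the model under its protocol from the resting state."""
        return integrate(self.params, self.protocol, rtol=rtol, atol=atol,
                         grid=grid)

    def qi(self, params: CellParams | None = None, rtol: float = 1e-8,
           atol: float = 1e-10) -> float:
        """Quality index of (possibly alternative) parameters vs target."""
        if self.endog is None:
            raise ValueError("model has no target series")
        p = self.params if params is None else params
        X = simulate_at(p, self.protocol, self.times, rtol=rtol, atol=atol)
        return quality_index(X, self.endog)

    def fit(self, variable=DEFAULT_VARIABLE_PARAMS, bounds=None,
            seed: int | None = None, rtol: float = 1e-6,
            atol: float = 1e-9, **de_settings) -> "CalciumFitResults":
        """Differential-evolution fit of the variable parameters."""
        if self.endog is None:
            raise ValueError("model has no target series to fit against")
        fp = FitProblem(
            params=self.params, protocol=self.protocol,
            target_t=self.times, target_E=self.endog,
            variable=tuple(variable), bounds=dict(bounds or {}),
            rtol=rtol, atol=atol,
        )
        raw = fit_parameters(fp, seed=seed, **de_settings)
        return CalciumFitResults(self, fp, raw)


class CalciumFitResults:
    """Estimates, fit quality and diagnostics of a fitted calcium model."""

    def __init__(self, model: CalciumModel, problem: FitProblem,
                 raw: FitResult):
        self.model = model
        self.problem = problem
        self.raw = raw
        self.params = pd.Series(raw.params, name="estimate")
        self.qi = raw.qi
        self.cell_params = raw.cell_params

    @property
    def resting_state(self):
        return resting_state(self.cell_params)

    def simulate(self, rtol: float = 1e-8, atol: float = 1e-10,
                 grid: float = 0.5) -> Trace:
        """Trajectory under the fitted parameters."""
        return integrate(self.cell_params, self.model.protocol,
                         rtol=rtol, atol=atol, grid=grid)

    def fittedvalues(self) -> np.ndarray:
        """Model calcium at the target time stamps."""
        return simulate_at(self.cell_params, self.model.protocol,
                           self.problem.target_t)

    def sensitivity(self, factor: float = 1.1) -> pd.DataFrame:
        """+10% one-at-a-time sensitivity scan around the fit."""
        return sensitivity_scan(self.cell_params, self.problem,
                                factor=factor)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "T-lymphocyte calcium model — differential evolution fit",
            "=" * 58,
            f"protocol:        {self.model.protocol.name}",
            f"target points:   {len(self.problem.target_t)}",
            f"quality index:   {self.qi:.6g}",
            f"evaluations:     {self.raw.n_evaluations}",
            f"seed:            {self.raw.seed}",
            f"converged:       {self.raw.success}",
            "-" * 58,
            f"{'parameter':<16}{'estimate':>14}{'lower':>14}{'upper':>14}",
        ]
        for name in self.problem.variable:
            lo, hi = self.problem.bounds[name]
            lines.append(
                f"{name:<16}{self.raw.params[name]:>14.6g}"
                f"{lo:>14.6g}{hi:>14.6g}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<CalciumFitResults qi={self.qi:.4g} "
                f"n_params={len(self.params)}>")
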