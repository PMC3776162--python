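"""Stimulation and block protocols.

A protocol is an ordered list of piecewise-constant segments, each
setting the TCR stimulus ``T`` (dimensionless, 1 at rest), the external
calcium concentration, and block flags for SERCA, PMCA and CRAC.
Blocks zero the corresponding single-protein current (not the density),
matching how thapsigargin (SERCA), carboxyeosin (PMCA) and La³⁺
(PMCA + CRAC together) are mimicked in silico.

``ZERO_CA`` is a symbolic external calcium standing for the surrogate
concentration at which the resting CRAC current vanishes; it is
resolved against the cell parameters when the protocol is built.

Presets replicate the five in-model experiments:

* ``fig3`` — sustained TCR stimulation (T: 1 → 1.6 at t = 10 s) at 2 mM
  external calcium.
* ``fig4`` — same stimulation with zero (surrogate) external calcium.
* ``fig5`` — SERCA block at zero external calcium, no stimulation
  (store-depletion / CRAC-recruitment experiment).
* ``fig6`` — SERCA block at zero external calcium with two 50-s pulses
  of 2 mM external calcium (t = 300 s and t = 600 s); PMCA is blocked
  from the second pulse onward.
* ``fig7`` — TCR stimulation with simultaneous PMCA block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .biophysics import zero_calcium_surrogate
from .cell_model import CellParams

__all__ = ["ZERO_CA", "Segment", "Protocol", "build_protocol", "preset",
           "PRESET_NAMES"]


class _ZeroCa:
    """Sentinel: external calcium at which resting CRAC current is zero."""

    def __repr__(self) -> str:  # pragma: no cover
        return "ZERO_CA"


ZERO_CA = _ZeroCa()


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant stretch of a protocol."""

    t_start: float
    T: float = 1.0
    C_ext: float | _ZeroCa = 2000.0  # μM, or ZERO_CA sentinel
    serca_blocked: bool = False
    pmca_blocked: bool = False
    crac_blocked: bool = False


@dataclass
class Protocol:
    """A resolved, queryable schedule of segments.

    Segments must start at t = 0 and have strictly increasing start
    times.  ``query(t)`` is right-continuous: at a boundary the new
    segment's settings apply.
    """

    segments: list[Segment]
    t_end: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.segments[0].t_start != 0.0:
            raise ValueError("first segment must start at t = 0")
        starts = [s.t_start for s in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if self.t_end <= starts[-1]:
            raise ValueError("t_end must exceed the last segment start")
        for s in self.segments:
            if isinstance(s.C_ext, _ZeroCa):
                raise ValueError(
                    "unresolved ZERO_CA segment; use build_protocol with "
                    "cell parameters"
                )
            if s.C_ext <= 0:
                raise ValueError("external calcium must be > 0")
            if s.T < 0:
                raise ValueError("stimulus T must be >= 0")

    def query(self, t: float) -> Segment:
        """Active segment at time t (right-continuous)."""
        if t < 0 or t > self.t_end:
            raise ValueError(f"t = {t} outside protocol span [0, {self.t_end}]")
        active = self.segments[0]
        for s in self.segments[1:]:
            if t >= s.t_start:
                active = s
            else:
                break
        return active

    @property
    def boundaries(self) -> list[float]:
        """Integration breakpoints: segment starts plus t_end."""
        return [s.t_start for s in self.segments] + [self.t_end]


def build_protocol(segments: list[Segment], t_end: float, p: CellParams,
                   name: str = "custom") -> Protocol:
    """Resolve symbolic entries and validate ordering.

    ``ZERO_CA`` resolves to ``zero_calcium_surrogate(C0)`` with the
    cell's resting calcium and electrical parameters.
    """
    c_star = zero_calcium_surrogate(p.rest.C0, p.electro)
    resolved = [
        Segment(s.t_start, s.T,
                c_star if isinstance(s.C_ext, _ZeroCa) else s.C_ext,
                s.serca_blocked, s.pmca_blocked, s.crac_blocked)
        for s in segments
    ]
    return Protocol(segments=resolved, t_end=t_end, name=name)


def _fig3(t_end: float) -> list[Segment]:
    return [Segment(0.0, T=1.0), Segment(10.0, T=1.6)]


_DEFAULT_SPANS = {"fig3": 400.0, "fig4": 400.0, "fig5": 600.0,
                  "fig6": 1000.0, "fig7": 400.0}

PRESET_NAMES = tuple(sorted(_DEFAULT_SPANS))


def preset(name: str, p: CellParams, t_end: float | None = None,
           T_stim: float = 1.6) -> Protocol:
    """Build one of the named experimental protocols.

    ``T_stim`` allows the reduced-stimulus variant (e.g. 1.25) of the
    zero-calcium experiment without a separate preset.
    """
    if name not in _DEFAULT_SPANS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    span = _DEFAULT_SPANS[name] if t_end is None else t_end
    if name == "fig3":
        segs = [Segment(0.0), Segment(10.0, T=T_stim)]
    elif name == "fig4":
        segs = [Segment(0.0), Segment(10.0, T=T_stim, C_ext=ZERO_CA)]
    elif name == "fig5":
        segs = [Segment(0.0),
                Segment(10.0, C_ext=ZERO_CA, serca_blocked=True)]
    elif name == "fig6":
        segs = [
            Segment(0.0),
            Segment(10.0, C_ext=ZERO_CA, serca_blocked=True),
            Segment(300.0, C_ext=2000.0, serca_blocked=True),
            Segment(350.0, C_ext=ZERO_CA, serca_blocked=True),
            Segment(600.0, C_ext=2000.0, serca_blocked=True,
                    pmca_blocked=True),
            Segment(650.0, C_ext=ZERO_CA, serca_blocked=True,
                    pmca_blocked=True),
        ]
    else:  # fig7
        segs = [Segment(0.0), Segment(10.0, T=T_stim, pmca_blocked=True)]
    return build_protocol(segs, span, p, name=name)
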