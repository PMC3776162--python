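"""Three-compartment cell geometry.

The cell is a sphere of radius ``R_cell`` containing a spherical nucleus
(radius fraction ``f_R``) and an endoplasmic reticulum occupying a volume
fraction ``f_V`` of the cell.  The ER is strongly folded; its surface is
``f_A`` times that of a sphere of equal volume.  The nucleus is excluded
volume only — it is never a calcium compartment.

Everything downstream needs only the surface-to-volume ratios ``xi``
(plasma membrane per cytosolic volume), ``xi_ERC`` (ER membrane per
cytosolic volume) and ``xi_ER`` (ER membrane per ER volume), which convert
current surface densities into concentration changes.

Units: lengths in μm, areas in μm², volumes in μm³.  The μm³→L conversion
is owned by the flux assembly in :mod:`tcell_calcium.cell_model`, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GeometryParams",
    "GeometryDerived",
    "derive_geometry",
    "radius_from_capacitance",
]


@dataclass
class GeometryParams:
    """Primitive geometric parameters of the cell.

    Parameters
    ----------
    R_cell : float
        Cell radius in μm.
    f_R : float
        Nucleus radius as a fraction of ``R_cell`` (dimensionless, < 1).
    f_V : float
        ER volume as a fraction of the total cell volume (dimensionless).
    f_A : float
        Fold increase of the ER surface over a spherical ER of equal
        volume (≥ 1).  Only the product ``f_A * f_V**(2/3)`` enters the
        model, so ``f_A`` and ``f_V`` are redundant up to this product.
    C_m : float
        Specific membrane capacitance in pF/μm².
    """

    R_cell: float = 8.0
    f_R: float = 0.25
    f_V: float = 0.01
    f_A: float = 30.0
    C_m: float = 0.028

    def __post_init__(self) -> None:
        if self.R_cell <= 0:
            raise ValueError(f"R_cell must be positive, got {self.R_cell}")
        if not 0 <= self.f_R < 1:
            raise ValueError(f"f_R must be in [0, 1), got {self.f_R}")
        if not 0 <= self.f_V < 1:
            raise ValueError(f"f_V must be in [0, 1), got {self.f_V}")
        if self.f_A < 1:
            raise ValueError(f"f_A must be >= 1, got {self.f_A}")
        if self.f_V + self.f_R**3 >= 1:
            raise ValueError(
                "degenerate cytosol: f_V + f_R^3 = "
                f"{self.f_V + self.f_R**3:.4g} >= 1"
            )


@dataclass(frozen=True)
class GeometryDerived:
    """Derived areas, volumes and surface-to-volume ratios."""

    A_cell: float  # μm²
    V_cell: float  # μm³
    V_cyt: float   # μm³
    V_ER: float    # μm³
    A_ER: float    # μm²
    xi: float      # 1/μm, A_cell / V_cyt
    xi_ERC: float  # 1/μm, A_ER / V_cyt
    xi_ER: float   # 1/μm, A_ER / V_ER


def derive_geometry(p: GeometryParams) -> GeometryDerived:
    """Compute all derived geometric quantities from the primitives.

    The cytosolic volume excludes both the ER and the nucleus,
    ``V_cyt = V_cell (1 - f_V - f_R^3)``.  The ER area is
    ``f_A * (36 π)^{1/3} V_ER^{2/3}``, i.e. ``f_A`` times the area of a
    sphere with the ER's volume.
    """
    R = p.R_cell
    A_cell = 4.0 * math.pi * R * R
    V_cell = (4.0 / 3.0) * math.pi * R**3
    V_cyt = V_cell * (1.0 - p.f_V - p.f_R**3)
    V_ER = p.f_V * V_cell
    # area of a sphere of volume V_ER, times the folding factor
    A_ER_sphere = (36.0 * math.pi) ** (1.0 / 3.0) * V_ER ** (2.0 / 3.0)
    A_ER = p.f_A * A_ER_sphere
    xi = A_cell / V_cyt
    xi_ERC = A_ER / V_cyt
    xi_ER = A_ER / V_ER if V_ER > 0 else 0.0
    return GeometryDerived(
        A_cell=A_cell, V_cell=V_cell, V_cyt=V_cyt, V_ER=V_ER, A_ER=A_ER,
        xi=xi, xi_ERC=xi_ERC, xi_ER=xi_ER,
    )


def radius_from_capacitance(C_cell: float, C_m: float) -> float:
    """Cell radius (μm) from whole-cell capacitance.

    Uses ``C_cell / A_cell = C_m`` for a spherical cell, i.e.
    ``R = sqrt(C_cell / (4 π C_m))``.

    Parameters
    ----------
    C_cell : float
        Whole-cell capacitance in pF.
    C_m : float
        Specific membrane capacitance in pF/μm².
    """
    if C_cell <= 0 or C_m <= 0:
        raise ValueError("C_cell and C_m must be positive")
    return math.sqrt(C_cell / (4.0 * math.pi * C_m))
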