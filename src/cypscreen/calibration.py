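"""Fluorescent-standard calibration and assay-window QC.

The kit's blue fluorescent standard is reconstituted to a 100 µM DMSO stock
and diluted to a 500 nM working standard, then serially two-fold diluted
down a plate column with buffer-only blanks in row H.  A straight line
through the (concentration, RFU) standards gives an RFU-per-nM gain and a
background intercept; its inverse converts raw reads to product
concentrations.  The inhibition statistic itself operates on raw RFU, so
calibration here serves QC and optional unit conversion, not the main
pipeline path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

STOCK_UMOL = 0.1          # amount of standard reconstituted
STOCK_VOLUME_ML = 1.0     # in DMSO


def prepare_standard_stocks(
    stock_umol: float = STOCK_UMOL,
    stock_volume_ml: float = STOCK_VOLUME_ML,
    aliquot_ul: float = 5.0,
    final_ul: float = 1000.0,
) -> tuple[float, float]:
    """Stock and working-standard concentrations from the preparation recipe.

    Returns ``(stock_uM, working_nM)``.  Defaults reproduce the kit recipe:
    0.1 µmol in 1 mL DMSO -> 100 µM stock; 5 µL into 1 mL total -> 500 nM.
    """
    if min(stock_umol, stock_volume_ml, aliquot_ul, final_ul) <= 0:
        raise ValueError("all volumes and amounts must be > 0")
    if aliquot_ul > final_ul:
        raise ValueError("aliquot cannot exceed final volume")
    stock_um = stock_umol / (stock_volume_ml / 1000.0)  # µmol/L = µM
    working_nm = stock_um * 1000.0 * (aliquot_ul / final_ul)
    return stock_um, working_nm


@dataclass(frozen=True)
class StandardCurve:
    """OLS line RFU = slope * conc_nM + intercept through the standards."""

    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...]

    @property
    def n_points(self) -> int:
        return len(self.points)

    def rfu_to_nm(self, rfu: float) -> float:
        """Invert the curve: estimated fluorophore concentration in nM."""
        return (rfu - self.intercept) / self.slope

    def nm_to_rfu(self, conc_nm: float) -> float:
        return self.slope * conc_nm + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Unweighted least-squares line through (conc nM, RFU) standards.

    Blanks enter as concentration-0 points so the intercept estimates
    background rather than being pre-subtracted.  Requires >= 3 distinct
    concentrations.
    """
    pts = [(float(c), float(r)) for c, r in points]
    if len({c for c, _ in pts}) < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    x = np.array([c for c, _ in pts])
    y = np.array([r for _, r in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        points=tuple(sorted(pts)),
    )


@dataclass(frozen=True)
class WindowQC:
    """Assay-window report: separation between solvent and positive controls."""

    window: float                # a_rfu - b_rfu
    background_fraction: float   # blank / solvent signal
    status: str                  # ok | degenerate | inverted

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def assay_window_qc(a_rfu: float, b_rfu: float, blank_rfu: float = 0.0) -> WindowQC:
    """Flag plates whose control separation is zero or inverted.

    Never raises: QC reports flags so a screening run can continue past a
    bad plate and surface it in the report.
    """
    window = a_rfu - b_rfu
    if window > 0:
        status = "ok"
    elif window == 0:
        status = "degenerate"
    else:
        status = "inverted"
    bg = blank_rfu / a_rfu if a_rfu > 0 else float("nan")
    return WindowQC(window=float(window), background_fraction=float(bg), status=status)
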