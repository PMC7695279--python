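"""Absolute quantification from qPCR standard curves.

Total bacteria are quantified from 16S rRNA gene copies (4.2 rRNA operons per
cell on average) and ammonia-oxidising bacteria (AOB) from amoA copies
(2 gene copies per cell).  A standard curve Ct = slope * log10(copies) + b is
fitted on a ten-fold dilution ladder; amplification efficiency is
10^(-1/slope) - 1, with -3.3219 the perfect-doubling slope.

The cell-specific ammonium oxidation rate (CSAOR) divides the volumetric
ammonium oxidation rate (prNOx, mg N L-1 d-1) by the AOB density
(cells L-1), expressed in fmol NH4-N per cell per hour.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Marker-gene copies per cell used to convert copy numbers into cell counts.
COPIES_PER_CELL = {"16S": 4.2, "amoA": 2.0}

#: Nitrogen molar mass, g mol-1.
N_MOLAR_MASS = 14.007

#: Slope of a standard curve with exactly one doubling per cycle.
PERFECT_SLOPE = -1.0 / math.log10(2.0)


@dataclass
class StandardSeries:
    """A dilution-ladder calibration series for one target gene."""

    target: str
    log10_copies: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.log10_copies = np.asarray(self.log10_copies, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.log10_copies.shape != self.ct.shape:
            raise ValueError("log10_copies and ct must align")
        if len(np.unique(self.log10_copies)) < 3:
            raise ValueError("need >=3 distinct dilution points")
        if np.any((self.log10_copies < 1) | (self.log10_copies > 8)):
            warnings.warn("dilution ladder outside the usual 10^1..10^8 range", stacklevel=2)


@dataclass
class StandardCurve:
    """Least-squares line Ct = slope * log10(copies) + intercept."""

    target: str
    slope: float
    intercept: float
    r_squared: float
    #: Fractional amplification efficiency, 10^(-1/slope) - 1 (1.0 = 100%).
    efficiency: float
    ct_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("a valid standard curve has negative slope")
        if not 0.8 <= self.efficiency <= 1.2:
            warnings.warn(
                f"amplification efficiency {self.efficiency:.2f} outside [0.8, 1.2]",
                stacklevel=2,
            )


@dataclass
class CellAbundance:
    """Cell abundance converted from gene copies."""

    target: str
    cells_per_gvss: float
    copies_per_cell: float
    cells_per_l: float | None = None


@dataclass
class CsaorRecord:
    """Cell-specific ammonium oxidation rate at one sampling date."""

    t: float
    csaor_fmol_cell_h: float
    log10_csaor: float


def fit_standard_curve(series: StandardSeries) -> StandardCurve:
    """Fit Ct on log10(copies) and derive the amplification efficiency."""
    if np.ptp(series.log10_copies) == 0:
        raise ValueError("zero variance in log10 copies")
    res = stats.linregress(series.log10_copies, series.ct)
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0 if res.slope < 0 else float("nan")
    if res.slope < 0 and res.slope > -3.0:
        warnings.warn(
            f"standard-curve slope {res.slope:.3f} shallower than -3.0 "
            f"(efficiency {efficiency:.2f})",
            stacklevel=2,
        )
    return StandardCurve(
        target=series.target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(efficiency),
        ct_range=(float(series.ct.min()), float(series.ct.max())),
    )


def quantify(
    curve: StandardCurve,
    ct_replicates: np.ndarray | list[float],
    aggregate: str = "copies",
) -> tuple[float, float]:
    """Invert the standard curve for a set of Ct replicates.

    copies = 10^((Ct - intercept)/slope).  Replicates are aggregated on the
    copy scale by default (``aggregate="copies"``); ``aggregate="ct"`` averages
    Ct first.  Returns (mean copies uL-1, replicate CV of copies).
    """
    ct = np.asarray(ct_replicates, dtype=float)
    lo, hi = curve.ct_range
    if np.any((ct < lo) | (ct > hi)):
        warnings.warn("Ct outside the standard ladder range: extrapolating", stacklevel=2)
    copies = 10.0 ** ((ct - curve.intercept) / curve.slope)
    cv = float(copies.std(ddof=0) / copies.mean()) if copies.mean() > 0 else float("nan")
    if aggregate == "copies":
        mean_copies = float(copies.mean())
    elif aggregate == "ct":
        mean_copies = float(10.0 ** ((ct.mean() - curve.intercept) / curve.slope))
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    return mean_copies, cv


def copies_to_cells(
    copies: float,
    target: str,
    vss_g_per_l: float | None = None,
    copies_per_cell: float | None = None,
) -> CellAbundance:
    """Convert gene copies (per g VSS) to cells using the per-cell copy number.

    16S uses 4.2 rRNA operons per cell, amoA 2 gene copies per cell; any other
    target requires an explicit ``copies_per_cell`` override.  If a VSS
    concentration is supplied, cells per litre are reported too.
    """
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if copies_per_cell is None:
        try:
            copies_per_cell = COPIES_PER_CELL[target]
        except KeyError:
            raise ValueError(
                f"no copies-per-cell constant for target {target!r}; pass copies_per_cell"
            ) from None
    cells = copies / copies_per_cell
    cells_per_l = cells * vss_g_per_l if vss_g_per_l is not None else None
    return CellAbundance(
        target=target,
        cells_per_gvss=cells,
        copies_per_cell=copies_per_cell,
        cells_per_l=cells_per_l,
    )


def csaor(
    pr_nox: float,
    aob_per_gvss: float,
    vss_g_per_l: float,
    t: float = 0.0,
) -> CsaorRecord:
    """Cell-specific ammonium oxidation rate in fmol NH4-N cell-1 h-1.

    prNOx (mg N L-1 d-1) is converted to fmol N L-1 h-1
    (1 mg N = 1e12/14.007 fmol; / 24 h) and divided by the AOB density
    aob_per_gvss * vss (cells L-1).  Negative prNOx is clipped to zero with a
    warning (no oxidation), giving CSAOR = 0.
    """
    if aob_per_gvss <= 0 or vss_g_per_l <= 0:
        raise ZeroDivisionError("CSAOR undefined without AOB cells and biomass")
    if pr_nox < 0:
        warnings.warn("negative prNOx clipped to 0 for CSAOR", stacklevel=2)
        pr_nox = 0.0
    cells_per_l = aob_per_gvss * vss_g_per_l
    fmol_per_l_h = pr_nox * 1e12 / N_MOLAR_MASS / 24.0
    value = fmol_per_l_h / cells_per_l
    log10_value = math.log10(value) if value > 0 else float("-inf")
    return CsaorRecord(t=t, csaor_fmol_cell_h=value, log10_csaor=log10_value)
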