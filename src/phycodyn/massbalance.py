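"""Reactor performance from interval mass balances.

Both photobioreactor configurations (bubble column and raceway pond) are treated
as completely stirred tank reactors (CSTR).  For an analyte with influent
concentration ``C_in`` and reactor concentration ``C_out`` sampled at
consecutive dates ``t_{i-1} < t_i``, the volumetric net production rate over
the interval is

    pr = (C_out,i - C_out,i-1) / (t_i - t_i-1)
         + mean(C_out,i, C_out,i-1) / HRT
         - mean(C_in,i,  C_in,i-1) / HRT        [mg L-1 d-1]

where HRT is the mean hydraulic retention time over the interval.  Negative
``pr`` means the analyte is removed; its magnitude is then reported as a
removal rate ``rr``.  Removal efficiency at a sampling instant is
``eta = (C_in - C_out)/C_in * 100``.

Free ammonia (the un-ionised NH3 fraction of total ammoniacal nitrogen) follows
the Anthonisen speciation: FA = (17/14) * TAN * 10^pH / (exp(6344/(273+T)) + 10^pH).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Analytes carried through the campaign tables (nitrogen forms on the N basis).
ANALYTES = ("sCOD", "NH4-N", "NO2-N", "NO3-N", "PO4-P", "TSS", "VSS")


@dataclass
class SampleEvent:
    """One sampling date's influent and reactor physicochemistry.

    Parameters
    ----------
    t : float
        Days since campaign start; strictly increasing within a campaign.
    analytes_in, analytes_out : dict
        Analyte -> concentration (mg L-1) in the feed and in the suspension.
    pH : float
        Reactor pH (0-14).
    T_r : float
        Reactor temperature, degrees C.
    HRT : float, optional
        Mean hydraulic retention time over the preceding interval, days.
    DO, turbidity, OD680 : float, optional
        Dissolved oxygen (mg L-1), turbidity, and 680-nm absorbance.
    """

    t: float
    analytes_in: dict[str, float] = field(default_factory=dict)
    analytes_out: dict[str, float] = field(default_factory=dict)
    pH: float = 7.0
    T_r: float = 20.0
    HRT: float | None = None
    DO: float | None = None
    turbidity: float | None = None
    OD680: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH {self.pH} outside [0, 14]")
        if self.HRT is not None and self.HRT <= 0:
            raise ValueError(f"HRT must be positive, got {self.HRT}")
        for name, conc in {**self.analytes_in, **self.analytes_out}.items():
            if conc is not None and not np.isnan(conc) and conc < 0:
                raise ValueError(f"negative concentration for {name}: {conc}")


@dataclass
class RateEstimate:
    """Signed volumetric production rate over one sampling interval.

    ``pr`` < 0 means the analyte was removed; ``rr`` then holds ``-pr``.
    """

    analyte: str
    t_start: float
    t_end: float
    pr: float
    rr: float | None = None

    def __post_init__(self) -> None:
        if self.rr is None and self.pr < 0:
            self.rr = -self.pr
        if self.rr is not None and self.rr < 0:
            raise ValueError("removal rate must be non-negative")


@dataclass
class EfficiencyRecord:
    """Removal efficiency (percent) of an analyte at one sampling instant."""

    analyte: str
    t: float
    eta: float

    def __post_init__(self) -> None:
        if self.eta > 100.0 + 1e-12:
            raise ValueError("efficiency cannot exceed 100%")


def _present(mapping: dict[str, float], analyte: str) -> bool:
    v = mapping.get(analyte)
    return v is not None and not (isinstance(v, float) and math.isnan(v))


def volumetric_rate(
    events: list[SampleEvent],
    analyte: str,
    fallback_hrt: float | None = None,
) -> list[RateEstimate]:
    """Interval CSTR mass-balance rates for one analyte.

    Intervals missing the analyte at either endpoint are skipped with a
    warning (no imputation).  When the later event carries no HRT, the
    campaign-mean HRT (or ``fallback_hrt``) is used, with a warning.
    """
    if len(events) < 2:
        raise ValueError("need at least two sampling events")
    times = [e.t for e in events]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("sampling times must be strictly increasing")

    if fallback_hrt is None:
        hrts = [e.HRT for e in events if e.HRT is not None]
        fallback_hrt = float(np.mean(hrts)) if hrts else None

    out: list[RateEstimate] = []
    for prev, curr in zip(events, events[1:]):
        ok = all(
            _present(m, analyte)
            for m in (prev.analytes_in, prev.analytes_out, curr.analytes_in, curr.analytes_out)
        )
        if not ok:
            logger.warning(
                "skipping interval (%.1f, %.1f]: %s missing at an endpoint",
                prev.t, curr.t, analyte,
            )
            continue
        hrt = curr.HRT
        if hrt is None:
            if fallback_hrt is None:
                raise ValueError("no HRT available for interval and no fallback")
            logger.warning(
                "interval (%.1f, %.1f]: HRT missing, using campaign mean %.2f d",
                prev.t, curr.t, fallback_hrt,
            )
            hrt = fallback_hrt
        if hrt <= 0:
            raise ValueError(f"HRT must be positive, got {hrt}")
        dt = curr.t - prev.t
        c_out0, c_out1 = prev.analytes_out[analyte], curr.analytes_out[analyte]
        c_in0, c_in1 = prev.analytes_in[analyte], curr.analytes_in[analyte]
        pr = (c_out1 - c_out0) / dt + 0.5 * (c_out1 + c_out0) / hrt - 0.5 * (c_in1 + c_in0) / hrt
        out.append(RateEstimate(analyte=analyte, t_start=prev.t, t_end=curr.t, pr=pr))
    return out


def removal_efficiency(event: SampleEvent, analyte: str) -> EfficiencyRecord:
    """Percent removal ``(C_in - C_out)/C_in * 100`` at one sampling instant."""
    c_in = event.analytes_in.get(analyte)
    c_out = event.analytes_out.get(analyte)
    if c_in is None or c_out is None:
        raise ValueError(f"{analyte} missing from event at t={event.t}")
    if c_in == 0:
        raise ZeroDivisionError(f"removal efficiency undefined: influent {analyte} is zero")
    return EfficiencyRecord(analyte=analyte, t=event.t, eta=(c_in - c_out) / c_in * 100.0)


def ammonium_oxidation_rate(pr_no2: float, pr_no3: float) -> float:
    """Ammonium oxidation rate: sum of the produced oxidised nitrogen forms.

    Both inputs on the mg N L-1 d-1 scale; prNOx = prNO2 + prNO3.
    """
    return pr_no2 + pr_no3


def free_ammonia(
    tan: float | np.ndarray,
    pH: float | np.ndarray,
    T_celsius: float | np.ndarray,
    basis: str = "NH3",
) -> float | np.ndarray:
    """Un-ionised free ammonia from TAN, pH and temperature (Anthonisen).

    FA = k * TAN * 10^pH / (exp(6344/(273+T)) + 10^pH), with k = 17/14 on the
    default NH3-mass basis (mg NH3 L-1) or k = 1 for ``basis="NH3-N"``
    (mg NH3-N L-1).  Strictly increasing in pH and T; bounded by k*TAN.
    """
    tan = np.asarray(tan, dtype=float)
    pH_a = np.asarray(pH, dtype=float)
    T_a = np.asarray(T_celsius, dtype=float)
    if np.any(tan < 0):
        raise ValueError("TAN must be non-negative")
    if np.any((pH_a <= 0) | (pH_a >= 14)):
        raise ValueError("pH must lie strictly inside (0, 14)")
    if np.any((T_a <= -5) | (T_a >= 60)):
        raise ValueError("temperature outside the valid range (-5, 60) C")
    if basis == "NH3":
        k = 17.0 / 14.0
    elif basis == "NH3-N":
        k = 1.0
    else:
        raise ValueError(f"unknown basis {basis!r}; use 'NH3' or 'NH3-N'")
    ten_ph = np.power(10.0, pH_a)
    fa = k * tan * ten_ph / (np.exp(6344.0 / (273.0 + T_a)) + ten_ph)
    return float(fa) if fa.ndim == 0 else fa


def productivity_stability(pr_vss: list[float] | np.ndarray) -> np.ndarray:
    """Rolling sample sd of three consecutive biomass production rates.

    The stability of biomass productivity at an interior index is the sample
    standard deviation (n-1 denominator) of the previous, current and next
    prVSS values.  Fewer than three inputs give an empty result with a warning.
    """
    values = np.asarray(pr_vss, dtype=float)
    if values.size < 3:
        warnings.warn("fewer than 3 prVSS values: stability undefined", stacklevel=2)
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(values, 3)
    return windows.std(axis=1, ddof=1)


def _rates_frame(rates: dict[str, list[RateEstimate]]) -> pd.DataFrame:
    rows = [
        {"analyte": a, "t_start": r.t_start, "t_end": r.t_end, "pr": r.pr, "rr": r.rr}
        for a, lst in rates.items()
        for r in lst
    ]
    return pd.DataFrame(rows, columns=["analyte", "t_start", "t_end", "pr", "rr"])


def summarize_campaign(
    events_a: list[SampleEvent],
    rates_a: dict[str, list[RateEstimate]],
    events_b: list[SampleEvent],
    rates_b: dict[str, list[RateEstimate]],
    corr_vars: dict[str, np.ndarray] | None = None,
) -> dict:
    """Summary and paired comparison of two reactor campaigns.

    Returns per-analyte mean +/- sd of rates for each reactor, two-sided
    paired t statistics on rate series aligned at shared interval endpoints,
    free-ammonia series statistics, and (optionally) a Pearson correlation
    matrix over user-supplied campaign variables.
    """
    summary: dict = {"reactors": {}, "paired_tests": {}, "free_ammonia": {}}
    for label, rates in (("A", rates_a), ("B", rates_b)):
        frame = _rates_frame(rates)
        per_analyte = {}
        for analyte, grp in frame.groupby("analyte"):
            per_analyte[analyte] = {
                "pr_mean": float(grp["pr"].mean()),
                "pr_sd": float(grp["pr"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "n_intervals": int(len(grp)),
            }
        summary["reactors"][label] = per_analyte

    for label, events in (("A", events_a), ("B", events_b)):
        fa = np.array(
            [
                free_ammonia(e.analytes_out["NH4-N"], e.pH, e.T_r)
                for e in events
                if _present(e.analytes_out, "NH4-N")
            ]
        )
        summary["free_ammonia"][label] = {
            "mean": float(fa.mean()) if fa.size else float("nan"),
            "sd": float(fa.std(ddof=1)) if fa.size > 1 else 0.0,
            "n": int(fa.size),
        }

    shared_analytes = set(rates_a) & set(rates_b)
    for analyte in sorted(shared_analytes):
        a_by_end = {r.t_end: r.pr for r in rates_a[analyte]}
        b_by_end = {r.t_end: r.pr for r in rates_b[analyte]}
        shared_t = sorted(set(a_by_end) & set(b_by_end))
        dropped = (len(a_by_end) - len(shared_t)) + (len(b_by_end) - len(shared_t))
        if dropped:
            logger.info("paired %s comparison: %d unmatched intervals dropped", analyte, dropped)
        if len(shared_t) < 2:
            logger.warning("paired %s comparison omitted: <2 shared intervals", analyte)
            continue
        xa = np.array([a_by_end[t] for t in shared_t])
        xb = np.array([b_by_end[t] for t in shared_t])
        if np.allclose(xa, xb):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(xa, xb)
        summary["paired_tests"][analyte] = {
            "t": float(t_stat),
            "p": float(p),
            "n_pairs": int(len(shared_t)),
        }

    if corr_vars:
        names = sorted(corr_vars)
        mat = np.vstack([np.asarray(corr_vars[n], dtype=float) for n in names])
        if len({len(v) for v in mat}) > 1:
            raise ValueError("correlation variables must have equal length")
        corr = pd.DataFrame(np.corrcoef(mat), index=names, columns=names)
        summary["pearson_matrix"] = corr
    return summary
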