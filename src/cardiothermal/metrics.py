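"""Per-individual cardiac thermal-performance indices.

A larva's maximum heart rate (f_H, beats/min) is measured at each step of a
temperature ramp. Four temperatures summarise its thermal performance:

* ``T_AB`` — Arrhenius breakpoint temperature: where the slope of
  log10(f_H) against inverse absolute temperature (1000/K) changes,
  a proxy for the thermal optimum.
* ``T_peak`` — temperature eliciting the highest observed f_H.
* ``T_Arr`` — lowest temperature at which cardiac arrhythmia is observed
  (right-censored at the top of the ramp if it never occurs).

plus the rate metrics f_H0 (heart rate at the first step), f_Hpeak,
their difference (cardiac scope) and df_H/dT, the linear warming response
below the breakpoint.

``fit_two_segment`` estimates T_AB by continuous two-segment least squares
with an exhaustive candidate-grid search, which is deterministic and finds
the global optimum, unlike iterative segmented-regression estimators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HeartRateSeries",
    "ArrheniusFit",
    "CardiacMetrics",
    "celsius_to_arrhenius",
    "arrhenius_to_celsius",
    "arrhenius_points",
    "fit_two_segment",
    "compute_metrics",
]

KELVIN_OFFSET = 273.15


def celsius_to_arrhenius(temp_c):
    """Inverse absolute temperature, in 1000/K, from degrees Celsius."""
    return 1000.0 / (np.asarray(temp_c, dtype=float) + KELVIN_OFFSET)


def arrhenius_to_celsius(x):
    """Degrees Celsius from inverse absolute temperature in 1000/K."""
    return 1000.0 / np.asarray(x, dtype=float) - KELVIN_OFFSET


@dataclass(frozen=True)
class HeartRateSeries:
    """One individual's heart rate at each step of the temperature ramp.

    ``f_h`` entries are NaN exactly where ``arrhythmic`` is True: heart rate
    is not measurable once the heart is arrhythmic, and arrhythmia flags are
    upward-closed in temperature (once arrhythmic, always arrhythmic).
    """

    individual_id: str
    clutch_id: str
    incubation_c: float
    step_temps_c: tuple[float, ...]
    f_h: tuple[float, ...]
    arrhythmic: tuple[bool, ...]

    def __post_init__(self):
        temps = np.asarray(self.step_temps_c, dtype=float)
        fh = np.asarray(self.f_h, dtype=float)
        arr = np.asarray(self.arrhythmic, dtype=bool)
        if not (len(temps) == len(fh) == len(arr)):
            raise ValueError("step_temps_c, f_h and arrhythmic must be equal length")
        if len(temps) == 0:
            raise ValueError("empty series")
        if np.any(np.diff(temps) <= 0):
            raise ValueError("step temperatures must be strictly increasing")
        if not np.array_equal(np.isnan(fh), arr):
            raise ValueError("f_h must be missing exactly at arrhythmic steps")
        if np.any(np.diff(arr.astype(int)) < 0):
            raise ValueError("arrhythmia flags must be upward-closed in temperature")

    @property
    def n_measured(self) -> int:
        return int(np.sum(~np.asarray(self.arrhythmic)))


@dataclass(frozen=True)
class ArrheniusFit:
    """Result of the two-segment breakpoint fit in Arrhenius coordinates.

    ``slope_lo`` is the segment slope on the low-x (warm) side of the
    breakpoint, ``slope_hi`` on the high-x (cold) side; both are
    d(log10 f_H) / d(1000/K). ``status`` is ``"ok"`` when a breakpoint was
    accepted and ``"no_breakpoint"`` when the two-segment model does not
    improve enough on a single line (or the slopes barely differ).
    """

    status: str
    breakpoint_x: float = math.nan
    t_ab_c: float = math.nan
    slope_lo: float = math.nan
    slope_hi: float = math.nan
    sse: float = math.nan
    sse_line: float = math.nan
    n_points: int = 0


@dataclass(frozen=True)
class CardiacMetrics:
    """Derived thermal-performance indices for one individual."""

    individual_id: str
    clutch_id: str
    incubation_c: float
    f_h0: float
    f_hpeak: float
    delta_f: float  # cardiac scope, f_Hpeak - f_H0
    dfdt: float  # beats/min/degC below T_AB; NaN if T_AB absent
    t_ab_c: float  # NaN when no breakpoint
    t_peak_c: float
    t_arr_c: float  # step of first arrhythmia, or last step if censored
    t_arr_censored: bool
    fit_status: str = "ok"


def arrhenius_points(series: HeartRateSeries) -> tuple[np.ndarray, np.ndarray]:
    """Transform measured steps to Arrhenius coordinates.

    Returns ``(x, y)`` with ``x = 1000/(T_C + 273.15)`` and ``y = log10 f_H``,
    ordered by increasing temperature (decreasing x). Arrhythmic (missing)
    steps are excluded.

    Raises
    ------
    ValueError
        If no measured steps remain or any measured f_H is non-positive.
    """
    temps = np.asarray(series.step_temps_c, dtype=float)
    fh = np.asarray(series.f_h, dtype=float)
    keep = ~np.isnan(fh)
    if not keep.any():
        raise ValueError("series has no measured heart rates")
    if np.any(fh[keep] <= 0):
        raise ValueError("heart rates must be positive for the Arrhenius transform")
    x = celsius_to_arrhenius(temps[keep])
    y = np.log10(fh[keep])
    return x, y


def _two_segment_design(x: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Stacked design matrices, one per candidate breakpoint.

    Model at candidate c:  y = b0 + b1*(x - c) + b2*max(x - c, 0),
    which is continuous at c with slope b1 for x < c and b1 + b2 for x > c.
    Shape (n_candidates, n_points, 3).
    """
    d = x[None, :] - candidates[:, None]
    ones = np.ones_like(d)
    return np.stack([ones, d, np.maximum(d, 0.0)], axis=2)


def fit_two_segment(
    x: Sequence[float],
    y: Sequence[float],
    *,
    n_candidates: int = 200,
    sse_ratio: float = 0.95,
    min_slope_delta: float = 0.05,
) -> ArrheniusFit:
    """Continuous two-segment least squares with exhaustive breakpoint search.

    Candidate breakpoints are ``n_candidates`` equally spaced x-values
    strictly between the 2nd and (n-1)th sorted x, guaranteeing at least two
    points on each side. At each candidate the continuity-constrained least
    squares problem is solved exactly; the global SSE minimum wins (ties go
    to the lowest candidate x). A breakpoint is only accepted when the best
    two-segment SSE is below ``sse_ratio`` times the single-line SSE and the
    two slopes differ by at least ``min_slope_delta``; otherwise the status
    is ``"no_breakpoint"``.

    Parameters are in Arrhenius coordinates but the routine is generic
    piecewise-linear regression; ``t_ab_c`` is only meaningful when x is
    1000/K.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 points for a two-segment fit, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all x values equal")

    order = np.argsort(x)
    xs, ys = x[order], y[order]

    # single straight line as the null model
    coef_line = np.polyfit(xs, ys, 1)
    sse_line = float(np.sum((np.polyval(coef_line, xs) - ys) ** 2))

    lo, hi = xs[1], xs[-2]
    candidates = np.linspace(lo, hi, n_candidates)

    X = _two_segment_design(xs, candidates)  # (c, n, 3)
    # batched normal equations; 3x3 solves are cheap and deterministic
    XtX = np.einsum("cni,cnj->cij", X, X)
    Xty = np.einsum("cni,n->ci", X, ys)
    # guard exactly singular candidates (e.g. breakpoint on a duplicated x)
    with np.errstate(all="ignore"):
        try:
            beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.stack(
                [np.linalg.lstsq(X[i], ys, rcond=None)[0] for i in range(len(candidates))]
            )
    resid = np.einsum("cni,ci->cn", X, beta) - ys
    sse = np.einsum("cn,cn->c", resid, resid)
    sse = np.where(np.isfinite(sse), sse, np.inf)

    best = int(np.argmin(sse))  # argmin takes the first (lowest-x) tie
    b0, b1, b2 = beta[best]
    sse_best = float(sse[best])
    bx = float(candidates[best])

    if sse_best >= sse_ratio * sse_line or abs(b2) < min_slope_delta:
        return ArrheniusFit(status="no_breakpoint", sse=sse_best, sse_line=sse_line,
                            n_points=n)
    return ArrheniusFit(
        status="ok",
        breakpoint_x=bx,
        t_ab_c=float(arrhenius_to_celsius(bx)),
        slope_lo=float(b1),
        slope_hi=float(b1 + b2),
        sse=sse_best,
        sse_line=sse_line,
        n_points=n,
    )


def fit_series_breakpoint(series: HeartRateSeries, **kwargs) -> ArrheniusFit:
    """Arrhenius-transform a series and fit its breakpoint.

    Individuals with fewer than five measured steps (arrhythmic too early)
    get status ``"too_few_points"`` rather than an error, mirroring assay
    practice where such fish are excluded from the breakpoint dataset.
    """
    xarr, yarr = arrhenius_points(series)
    if len(xarr) < 5:
        return ArrheniusFit(status="too_few_points", n_points=len(xarr))
    return fit_two_segment(xarr, yarr, **kwargs)


def compute_metrics(series: HeartRateSeries, fit: ArrheniusFit) -> CardiacMetrics:
    """Assemble the per-individual index table entry.

    * f_H0 is the heart rate at the first ramp step.
    * f_Hpeak / T_peak are the maximum measured heart rate and its
      temperature (ties broken toward the lower temperature).
    * df_H/dT is the OLS slope of f_H on temperature over steps at or below
      the estimated T_AB (NaN when T_AB is absent or fewer than two such
      steps exist).
    * T_Arr is the lowest arrhythmic step temperature; when no step is
      arrhythmic it is right-censored at the last step.

    T_Arr > T_peak is checked but not enforced (a warning is emitted),
    since measured data can violate it.
    """
    temps = np.asarray(series.step_temps_c, dtype=float)
    fh = np.asarray(series.f_h, dtype=float)
    arr = np.asarray(series.arrhythmic, dtype=bool)
    measured = ~np.isnan(fh)
    if not measured.any():
        raise ValueError("series has no measured heart rates")

    f_h0 = float(fh[0]) if measured[0] else math.nan
    i_peak = int(np.nanargmax(fh))  # first occurrence of the max -> lowest temp
    f_hpeak = float(fh[i_peak])
    t_peak = float(temps[i_peak])

    t_ab = fit.t_ab_c if fit.status == "ok" else math.nan
    dfdt = math.nan
    if not math.isnan(t_ab):
        below = measured & (temps <= t_ab)
        if below.sum() >= 2:
            dfdt = float(np.polyfit(temps[below], fh[below], 1)[0])

    if arr.any():
        t_arr = float(temps[arr][0])
        censored = False
        if t_arr <= t_peak:
            warnings.warn(
                f"individual {series.individual_id}: T_Arr ({t_arr}) <= T_peak "
                f"({t_peak}); retained as observed",
                stacklevel=2,
            )
    else:
        t_arr = float(temps[-1])
        censored = True

    return CardiacMetrics(
        individual_id=series.individual_id,
        clutch_id=series.clutch_id,
        incubation_c=series.incubation_c,
        f_h0=f_h0,
        f_hpeak=f_hpeak,
        delta_f=f_hpeak - f_h0,
        dfdt=dfdt,
        t_ab_c=t_ab,
        t_peak_c=t_peak,
        t_arr_c=t_arr,
        t_arr_censored=censored,
        fit_status=fit.status,
    )
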