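"""Liquid-growth kinetics from OD600 time series.

Doubling time is estimated from sliding log-linear windows over ln(OD).
Because OD noise and logistic saturation both bias the raw maximum window
slope, the default estimator divides each window slope by (1 - OD/K_hat)
— the logistic specific-rate correction, with K_hat the observed saturation
— and takes the median over growth-phase windows.  The plain maximum-slope
window (``method="window_max"``) and a full logistic model fit
(``method="logistic"``) are available as alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

__all__ = [
    "GrowthCurve",
    "GrowthStats",
    "preprocess",
    "doubling_time",
    "compare_to_wildtype",
    "summarize_replicates",
    "pool_replicates",
    "curves_to_frame",
    "frame_to_curves",
]

_OD_FLOOR = 1e-4


@dataclass
class GrowthCurve:
    """OD600 time series for one well."""

    strain: str
    medium: str
    temperature_c: float
    replicate: int
    times_min: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times_min.shape != self.od600.shape:
            raise ValueError("times_min and od600 must have equal length")
        if self.times_min.ndim != 1:
            raise ValueError("curve arrays must be 1-D")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if np.any(self.od600 < 0):
            raise ValueError("od600 must be non-negative")


@dataclass
class GrowthStats:
    """Kinetic summary of one growth curve."""

    strain: str
    doubling_time_min: float | None
    max_specific_rate_per_min: float | None
    saturation_od: float
    lag_min: float | None
    window: tuple[float, float] | None
    replicate: int = 0
    notes: list = field(default_factory=list)


def preprocess(
    curve: GrowthCurve, blank_od: float = 0.0, smooth_window: int = 1
) -> GrowthCurve:
    """Blank-subtract, floor at a small positive OD, and median-smooth.

    Identity (up to flooring) for ``blank_od=0`` and ``smooth_window=1``.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd count >= 1")
    od = curve.od600 - blank_od
    if np.all(od <= 0):
        raise ValueError("blank exceeds all readings: no signal")
    od = np.clip(od, _OD_FLOOR, None)
    if smooth_window > 1:
        od = median_filter(od, size=smooth_window, mode="nearest")
    return GrowthCurve(
        curve.strain, curve.medium, curve.temperature_c, curve.replicate,
        curve.times_min.copy(), od,
    )


def _window_slopes(t: np.ndarray, y: np.ndarray, fit_points: int):
    """Least-squares slope of ln(OD) and mean OD for every sliding window."""
    ly = np.log(np.clip(y, _OD_FLOOR, None))
    n = t.size - fit_points + 1
    slopes = np.empty(n)
    mids = np.empty(n)
    for i in range(n):
        tt = t[i : i + fit_points]
        yy = ly[i : i + fit_points]
        tm = tt.mean()
        slopes[i] = np.dot(tt - tm, yy - yy.mean()) / np.dot(tt - tm, tt - tm)
        mids[i] = y[i : i + fit_points].mean()
    return slopes, mids


def _logistic(t, od0, r, lag, K):
    out = np.full_like(t, od0, dtype=float)
    g = t >= lag
    e = np.exp(r * (t[g] - lag))
    out[g] = K * od0 * e / (K + od0 * (e - 1.0))
    return out


def _fit_logistic_rate(t, y, initial, smax, lag, saturation) -> float:
    """Nonlinear least-squares logistic fit; returns the specific rate.

    Falls back to the raw max window slope when the optimizer fails.
    """
    p0 = [initial, smax, lag or 0.0, max(saturation, initial * 2)]
    try:
        popt, _ = curve_fit(
            _logistic, t, y, p0=p0, maxfev=20000,
            bounds=([_OD_FLOOR, 1e-6, 0.0, _OD_FLOOR], [10.0, 1.0, t[-1], 50.0]),
        )
        return float(popt[1])
    except RuntimeError:
        return smax


def doubling_time(
    curve: GrowthCurve, fit_points: int = 9, method: str = "window"
) -> GrowthStats:
    """Estimate doubling time, maximum specific rate, lag and saturation.

    ``fit_points`` is the sliding-window length (default 9, a 2-h window at
    the 15-min cadence).  Saturation is the mean of the final 5% of
    readings; lag is the first time OD exceeds 1.5x its initial value.
    Doubling time is null when no positive growth is detected.
    """
    t, y = curve.times_min, curve.od600
    if t.size < fit_points:
        raise ValueError(f"need at least fit_points={fit_points} samples, have {t.size}")
    n_tail = max(1, int(round(0.05 * y.size)))
    saturation = float(np.mean(y[-n_tail:]))
    initial = max(float(y[0]), _OD_FLOOR)
    above = np.nonzero(y > 1.5 * initial)[0]
    lag = float(t[above[0]]) if above.size else None

    slopes, mids = _window_slopes(t, y, fit_points)
    # windows still at baseline OD carry read noise, not growth signal;
    # only windows clear of 1.5x the inoculum compete for the max slope
    grown = mids >= 1.5 * initial
    candidates = slopes[grown] if grown.any() else slopes
    smax = float(candidates.max())
    notes = []
    if smax <= 0:
        return GrowthStats(curve.strain, None, None, saturation, lag, None,
                           curve.replicate, ["no positive growth detected"])
    imax = int(np.flatnonzero(slopes == smax)[0])
    window = (float(t[imax]), float(t[imax + fit_points - 1]))

    if method == "window_max":
        rate = smax
    elif method == "window":
        # the saturation correction needs a genuine plateau; a curve still
        # decelerating at the end is fit with the logistic model instead,
        # and a still-exponential curve keeps the raw max slope
        late = float(slopes[-1])
        K = saturation
        sel = grown & (slopes > 0.5 * smax) & (mids < 0.8 * K)
        if late < 0.1 * smax and sel.any():
            rate = float(np.median(slopes[sel] / (1.0 - mids[sel] / K)))
        elif late < 0.5 * smax:
            rate = _fit_logistic_rate(t, y, initial, smax, lag, saturation)
            notes.append("plateau not reached; logistic model fit used")
        else:
            rate = smax
            notes.append("curve not saturated; raw max window slope used")
    elif method == "logistic":
        rate = _fit_logistic_rate(t, y, initial, smax, lag, saturation)
    else:
        raise ValueError(f"unknown method: {method}")

    return GrowthStats(
        strain=curve.strain,
        doubling_time_min=float(math.log(2) / rate),
        max_specific_rate_per_min=rate,
        saturation_od=saturation,
        lag_min=lag,
        window=window,
        replicate=curve.replicate,
        notes=notes,
    )


def compare_to_wildtype(stats: GrowthStats, wt: GrowthStats):
    """(doubling_ratio, saturation_ratio) of a strain relative to wild type.

    Returns (None, None) flagged in the strain's notes when either doubling
    time is null.
    """
    if stats.doubling_time_min is None or wt.doubling_time_min is None:
        stats.notes.append("doubling ratio undefined: null doubling time")
        return None, None
    return (
        stats.doubling_time_min / wt.doubling_time_min,
        stats.saturation_od / wt.saturation_od,
    )


def pool_replicates(curves: Sequence[GrowthCurve]) -> GrowthCurve:
    """Average replicate curves point-wise onto their common time grid."""
    if not curves:
        raise ValueError("need at least one curve")
    t0 = curves[0].times_min
    for c in curves[1:]:
        if not np.array_equal(c.times_min, t0):
            raise ValueError("replicates must share a common schedule to pool")
    od = np.mean([c.od600 for c in curves], axis=0)
    c0 = curves[0]
    return GrowthCurve(c0.strain, c0.medium, c0.temperature_c, 0, t0.copy(), od)


def summarize_replicates(stats: Sequence[GrowthStats]) -> pd.DataFrame:
    """Mean / SD / n per numeric field, nulls excluded with reported n."""
    if not stats:
        raise ValueError("need at least one replicate")
    fields = ["doubling_time_min", "max_specific_rate_per_min", "saturation_od", "lag_min"]
    rows = {}
    for f in fields:
        vals = np.array([getattr(s, f) for s in stats if getattr(s, f) is not None],
                        dtype=float)
        rows[f] = {
            "mean": float(vals.mean()) if vals.size else None,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else (0.0 if vals.size else None),
            "n": int(vals.size),
        }
    return pd.DataFrame(rows).T


def curves_to_frame(curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    """Long-format table (strain, medium, temperature_c, replicate, time_min, od600)."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "strain": c.strain,
                    "medium": c.medium,
                    "temperature_c": c.temperature_c,
                    "replicate": c.replicate,
                    "time_min": c.times_min,
                    "od600": c.od600,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_curves(df: pd.DataFrame) -> list[GrowthCurve]:
    """Parse a long-format growth table into curves."""
    required = {"strain", "medium", "temperature_c", "replicate", "time_min", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    curves = []
    for (strain, medium, temp, rep), g in df.groupby(
        ["strain", "medium", "temperature_c", "replicate"], sort=True
    ):
        g = g.sort_values("time_min")
        curves.append(
            GrowthCurve(strain, medium, float(temp), int(rep),
                        g["time_min"].to_numpy(), g["od600"].to_numpy())
        )
    return curves
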