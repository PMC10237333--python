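"""Specific growth rate from plate-reader OD600 curves.

Procedure: smooth the blank-corrected curve with a centered moving average,
fit a least-squares line to ln(OD - blank) versus time (hours) in every
contiguous sliding window, and take the tenth-fastest window slope as the
growth rate.  The rank-10 rule suppresses occasional artifactually steep
windows (bubbles, condensation) without averaging away the true maximum
specific rate; on a noise-free exponential every window returns mu exactly,
so the choice of window sizes is immaterial there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthCurve",
    "GrowthRateResult",
    "smooth_curve",
    "window_slopes",
    "select_growth_rate",
    "estimate_growth_rate",
]


@dataclass
class GrowthCurve:
    """An OD600 time series for one well.

    ``blank`` is the medium-only OD; if unknown, the estimator falls back
    to the minimum of the first three readings.
    """

    time_h: np.ndarray
    od: np.ndarray
    blank: float | None = None
    well: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.size != self.od.size:
            raise ValueError("time and OD must have equal length")
        if self.time_h.size and np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class GrowthRateResult:
    """Sliding-window slopes and the selected (tenth-fastest) rate, per hour."""

    window_slopes: np.ndarray
    window_starts: np.ndarray
    selected_rate: float
    smoothing_window: int
    regression_window: int
    blank: float = 0.0
    well: str = ""
    notes: list = field(default_factory=list)


def resolve_blank(curve: GrowthCurve) -> float:
    """The curve's blank, or the minimum of the first three readings."""
    if curve.blank is not None:
        return float(curve.blank)
    return float(np.min(curve.od[:3]))


def smooth_curve(curve: GrowthCurve, window: int = 5) -> GrowthCurve:
    """Centered moving average of the OD series; edges use shrunken windows."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd count")
    if window > curve.od.size:
        raise ValueError("smoothing window longer than the series")
    if window == 1:
        return GrowthCurve(curve.time_h, curve.od.copy(), curve.blank, curve.well)
    half = window // 2
    n = curve.od.size
    csum = np.concatenate([[0.0], np.cumsum(curve.od)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return GrowthCurve(curve.time_h, smoothed, curve.blank, curve.well)


def window_slopes(
    curve: GrowthCurve, window: int, blank: float | None = None, log: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope of ln(OD - blank) vs time (h) in every window.

    ``window`` is a count of consecutive retained points.  Points with
    non-positive blank-corrected OD are excluded before forming windows.
    With ``log=False`` the regression is on plain blank-corrected OD
    (for comparison only; rates are then in OD units per hour).
    Returns (slopes, window start times).
    """
    if window < 3:
        raise ValueError("regression window must span at least 3 points")
    b = resolve_blank(curve) if blank is None else float(blank)
    corrected = curve.od - b
    keep = corrected > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("%d points with non-positive blank-corrected OD excluded", n_excluded)
    t = curve.time_h[keep]
    y = np.log(corrected[keep]) if log else corrected[keep]
    if t.size < window:
        raise ValueError("fewer than one full regression window of usable points")
    tw = sliding_window_view(t, window)
    yw = sliding_window_view(y, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
    return slopes, tw[:, 0]


def select_growth_rate(slopes: np.ndarray, rank: int = 10) -> float:
    """The ``rank``-th largest slope (default tenth-fastest).

    With fewer than ``rank`` windows the smallest slope is returned, with
    a warning: too few windows to apply the outlier-robust rank rule.
    """
    s = np.asarray(slopes, dtype=float)
    if s.size == 0:
        raise ValueError("no window slopes to select from")
    if s.size < rank:
        warnings.warn(
            f"only {s.size} windows; returning the slowest instead of rank {rank}",
            stacklevel=2,
        )
        rank = s.size
    return float(np.sort(s)[::-1][rank - 1])


def estimate_growth_rate(
    curve: GrowthCurve,
    smoothing_window: int = 15,
    regression_minutes: float = 90.0,
    blank: float | None = None,
    rank: int = 10,
    log: bool = True,
) -> GrowthRateResult:
    """Full estimator: smooth, sliding-window log-linear fits, rank selection.

    ``regression_minutes`` is converted to a point count from the median
    sampling interval (default 90 min of points).  A centered moving
    average leaves the log-slope of an exponential unchanged (it rescales
    the curve by a constant factor), so a wide default smoothing window
    buys variance reduction in the low-OD windows at no bias cost during
    the exponential phase.
    """
    b = resolve_blank(curve) if blank is None else float(blank)
    smoothed = smooth_curve(curve, smoothing_window)
    interval_min = float(np.median(np.diff(curve.time_h))) * 60.0
    window = max(3, int(round(regression_minutes / interval_min)) + 1)
    slopes, starts = window_slopes(smoothed, window, blank=b, log=log)
    rate = select_growth_rate(slopes, rank=rank)
    return GrowthRateResult(
        window_slopes=slopes,
        window_starts=starts,
        selected_rate=rate,
        smoothing_window=smoothing_window,
        regression_window=window,
        blank=b,
        well=curve.well,
    )
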