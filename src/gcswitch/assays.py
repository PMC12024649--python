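"""Plate-reader kinetics processing.

Implements the bulk measurement pipeline: channel-wise background
correction, extraction of the exponential "growth segment" of each curve,
growth-rate estimation by log-linear regression, beta-galactosidase (Miller)
activity from OD420 kinetics, promoter activity, and the sliding-window
estimate of expression per biomass for fluorimetry curves.

Conventions: time in hours; OD420 slopes in per-minute units (Miller-assay
convention); growth rates reported in doublings/hour (slope of log2 OD).
OD600 values are assumed already adjusted to a 1-cm light path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

BACKGROUND_WINDOW = 20   # points averaged around the channel minimum
MIN_SEGMENT_POINTS = 21  # shorter growth segments are rejected


@dataclass(frozen=True)
class PlateTimeSeries:
    """One well's kinetics: OD600 and a reporter channel (OD420 or
    fluorescence), with free-form metadata (strain, media, TMG, replicate)."""

    time: np.ndarray    # hours, strictly increasing
    od600: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if not (len(t) == len(od) == len(sig)):
            raise ValueError("time, od600, signal must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od600", od)
        object.__setattr__(self, "signal", sig)

    def __len__(self) -> int:
        return len(self.time)


def _window_background(channel: np.ndarray) -> float:
    n = len(channel)
    i_min = int(np.argmin(channel))
    start = min(max(i_min - BACKGROUND_WINDOW // 2, 0), n - BACKGROUND_WINDOW)
    return float(channel[start:start + BACKGROUND_WINDOW].mean())


def background_correct(series: PlateTimeSeries) -> PlateTimeSeries:
    """Subtract, channel-wise, the mean over a 20-point window centered on
    the channel minimum (window clipped at the series edges)."""
    if len(series) < BACKGROUND_WINDOW:
        raise ValueError(f"need >= {BACKGROUND_WINDOW} points for background estimation")
    return replace(
        series,
        od600=series.od600 - _window_background(series.od600),
        signal=series.signal - _window_background(series.signal),
    )


# ---------------------------------------------------------------------------
# growth segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentResult:
    """Typed accept/reject outcome of growth-segment extraction."""

    accepted: bool
    sl: Optional[slice]
    reason: Optional[str] = None


def find_growth_segment(series: PlateTimeSeries, od_floor: float = 0.01) -> SegmentResult:
    """Exponential window of a background-corrected growth curve.

    From the index of maximal OD going backward, the maximal contiguous run
    of points with OD < OD_max/3, OD > ``od_floor`` and signal > 0; the
    backward scan stops at the first violating point once the run has
    started.  Runs shorter than 21 points are rejected (typed result, not an
    exception).
    """
    od, sig = series.od600, series.signal
    i_peak = int(np.argmax(od))
    od_max = od[i_peak]
    if od_max <= od_floor:
        return SegmentResult(False, None, "no growth: OD never exceeds the floor")

    def ok(j: int) -> bool:
        return (od[j] < od_max / 3.0) and (od[j] > od_floor) and (sig[j] > 0)

    j = i_peak
    while j >= 0 and not ok(j):
        j -= 1
    if j < 0:
        return SegmentResult(False, None, "no point satisfies the segment rules")
    end = j  # inclusive
    while j >= 0 and ok(j):
        j -= 1
    start = j + 1
    n = end - start + 1
    if n < MIN_SEGMENT_POINTS:
        return SegmentResult(
            False, None, f"segment has {n} points (< {MIN_SEGMENT_POINTS})"
        )
    return SegmentResult(True, slice(start, end + 1))


def growth_rate_of_segment(series: PlateTimeSeries, sl: slice) -> tuple[float, float]:
    """Doubling rate (doublings/hour) and its SE: OLS slope of log2(OD)
    versus time over the segment."""
    od = series.od600[sl]
    if np.any(od <= 0):
        raise ValueError("segment contains non-positive OD (violates segment contract)")
    res = stats.linregress(series.time[sl], np.log2(od))
    return float(res.slope), float(res.stderr)


@dataclass(frozen=True)
class GrowthSegment:
    """Per-well summary of the exponential window."""

    sl: slice
    lam_dbl: float  # doublings/hour
    lam_se: float
    y_expr: float   # mean log(signal/OD)
    y_se: float


# ---------------------------------------------------------------------------
# Miller assay
# ---------------------------------------------------------------------------

def miller_activity(
    time_h: np.ndarray, od420: np.ndarray, od600_sample: float
) -> float:
    """Beta-galactosidase activity in Miller units, A = 1000 s / (0.5 OD600).

    The slope s (per minute) is the OLS slope of OD420 over the first 30
    minutes of the reaction; an initial decreasing phase of up to one hour
    (occasionally seen at low enzyme concentrations) is discarded first.
    """
    t = np.asarray(time_h, dtype=float)
    a = np.asarray(od420, dtype=float)
    if len(t) != len(a) or len(t) < 3:
        raise ValueError("need matched OD420 kinetics with >= 3 points")
    if od600_sample <= 0:
        raise ValueError("od600_sample must be > 0")
    # discard the initial decreasing phase (first local minimum within 1 h)
    start = 0
    while start + 1 < len(a) and a[start + 1] < a[start]:
        start += 1
        if t[start] - t[0] > 1.0:
            raise ValueError("OD420 still decreasing one hour into the assay")
    window = (t >= t[start]) & (t <= t[start] + 0.5 + 1e-9)
    if window.sum() < 2 or t[window].max() - t[start] < 0.5 - 1e-6:
        raise ValueError("need >= 30 min of OD420 kinetics after the initial phase")
    slope_per_h = stats.linregress(t[window], a[window]).slope
    s = slope_per_h / 60.0
    return 1000.0 * s / (0.5 * od600_sample)


def promoter_activity(miller_units: float, lam_dbl: float) -> float:
    """Promoter activity alpha = A * lambda: for a stable enzyme at balanced
    growth, turnover is set by dilution, so activity per biomass times the
    doubling rate estimates the production rate."""
    if lam_dbl <= 0:
        raise ValueError("doubling rate must be > 0")
    return miller_units * lam_dbl


# ---------------------------------------------------------------------------
# fluorimetry sliding windows
# ---------------------------------------------------------------------------

def _inverse_variance_combine(values: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    if np.all(ses == 0):
        return float(values.mean()), 0.0
    floor = ses[ses > 0].min() * 1e-6
    w = 1.0 / np.maximum(ses, floor) ** 2
    mean = float((w * values).sum() / w.sum())
    return mean, float(1.0 / math.sqrt(w.sum()))


def expression_sliding_windows(
    series: PlateTimeSeries, sl: slice, w: int = 21
) -> GrowthSegment:
    """Sliding-window estimate of expression per biomass and growth rate.

    A window of length ``w`` moves across the growth segment; each window
    yields a growth rate (slope of log2 OD vs time) and a log expression
    ratio y = mean(log signal - log OD), both with SEs; window estimates are
    combined by inverse-variance weighting.
    """
    time = series.time[sl]
    od = series.od600[sl]
    sig = series.signal[sl]
    n = len(time)
    if w < 3:
        raise ValueError("window length must be >= 3")
    if n < w:
        raise ValueError(f"segment length {n} is shorter than the window {w}")
    if np.any(od <= 0) or np.any(sig <= 0):
        raise ValueError("segment must have positive OD and signal")
    lams, lam_ses, ys, y_ses = [], [], [], []
    for i in range(n - w + 1):
        tw = time[i:i + w]
        res = stats.linregress(tw, np.log2(od[i:i + w]))
        lams.append(res.slope)
        lam_ses.append(res.stderr)
        diff = np.log(sig[i:i + w]) - np.log(od[i:i + w])
        ys.append(diff.mean())
        y_ses.append(diff.std(ddof=1) / math.sqrt(w))
    lam, lam_se = _inverse_variance_combine(np.array(lams), np.array(lam_ses))
    y, y_se = _inverse_variance_combine(np.array(ys), np.array(y_ses))
    return GrowthSegment(sl=sl, lam_dbl=lam, lam_se=lam_se, y_expr=y, y_se=y_se)
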