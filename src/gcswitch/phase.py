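"""Phase classification of (doubling time x signal) space.

Classifies each operating point of a switch model as off / on / bistable
from the fixed-point structure of the reduced dynamics, extracts the
saddle-node (bistability) boundaries in signal space by bisection on the
number of stable fixed points, and measures the power-law scaling of the
critical signal with doubling time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .models import (
    GrowthContext,
    ModelSpec,
    _production_bounds,
    _two_component_dimer,
    find_fixed_points,
    lac_threshold_relation,
)

logger = logging.getLogger(__name__)

OFF, ON, BISTABLE = "off", "on", "bistable"


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def x_mid(spec: ModelSpec, signal: float, ctx: GrowthContext) -> float:
    """Discriminating concentration separating 'off' from 'on' monostable states.

    Geometric mean of the concentration at which the promoter input is
    half-maximal and the maximal attainable concentration.  A unique stable
    state above this level is called induced.
    """
    pmin, pmax, decay = _production_bounds(spec, signal, ctx)
    x_max = pmax / decay
    p = spec.params
    if spec.kind in ("autoactivator", "protease"):
        x_half = p.K if spec.kind == "autoactivator" else p.auto.K
    elif spec.kind == "two_component":
        if signal == 0:
            return math.inf

        def f(x):
            return float(_two_component_dimer(p, x, p.rho * x, signal)) - p.auto.K

        hi = x_max
        while f(hi) < 0:
            hi *= 10.0
            if hi > 1e12 * x_max:
                return math.inf  # promoter cannot reach half induction
        x_half = brentq(f, 1e-12 * x_max, hi)
    else:  # lac: LacY level at which intracellular inducer reaches K_tau
        if signal == 0:
            return math.inf
        k_tau = p.k_tau(ctx.lam)
        if p.k_hyd == 0:
            x_half = k_tau * ctx.g / (p.alpha_imp * signal)
        else:
            denom = p.alpha_imp * signal - p.k_hyd * k_tau
            if denom <= 0:
                return math.inf
            x_half = k_tau * ctx.g / denom
    return math.sqrt(x_half * x_max)


def classify(spec: ModelSpec, signal: float, ctx: GrowthContext, **fp_kw) -> str:
    """'bistable' when two stable fixed points coexist; otherwise 'off'/'on'
    by whether the unique stable state lies below/above ``x_mid``."""
    fps = find_fixed_points(spec, signal, ctx, **fp_kw)
    stable = [fp.x for fp in fps if fp.stable]
    if len(stable) >= 2:
        return BISTABLE
    if not stable:  # only marginal points (exact saddle-node): treat extremes
        stable = [fps[0].x]
    return ON if stable[0] > x_mid(spec, signal, ctx) else OFF


# ---------------------------------------------------------------------------
# phase grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseGrid:
    """Classification of a (doubling time x signal) grid."""

    t_axis: np.ndarray  # doubling times, h
    s_axis: np.ndarray  # signal levels
    phase: np.ndarray   # shape (len(t_axis), len(s_axis)), values off/on/bistable

    def __post_init__(self) -> None:
        if self.phase.shape != (len(self.t_axis), len(self.s_axis)):
            raise ValueError("phase matrix shape must match axes")

    def to_frame(self):
        import pandas as pd

        t, s = np.meshgrid(self.t_axis, self.s_axis, indexing="ij")
        return pd.DataFrame(
            {
                "doubling_time_h": t.ravel(),
                "signal": s.ravel(),
                "phase": self.phase.ravel(),
            }
        )


def phase_diagram(
    spec: ModelSpec,
    t_axis,
    s_axis,
    *,
    delta: float = 0.0,
    **fp_kw,
) -> PhaseGrid:
    """Classify every (doubling time, signal) grid cell."""
    t_axis = np.asarray(t_axis, dtype=float)
    s_axis = np.asarray(s_axis, dtype=float)
    if np.any(t_axis <= 0) or np.any(np.diff(t_axis) < 0):
        raise ValueError("t_axis must be positive and sorted")
    if np.any(s_axis < 0) or np.any(np.diff(s_axis) < 0):
        raise ValueError("s_axis must be non-negative and sorted")
    phase = np.empty((len(t_axis), len(s_axis)), dtype=object)
    for i, t in enumerate(t_axis):
        ctx = GrowthContext.from_doubling_time(t, delta)
        for j, s in enumerate(s_axis):
            phase[i, j] = classify(spec, float(s), ctx, **fp_kw)
    return PhaseGrid(t_axis=t_axis, s_axis=s_axis, phase=phase)


# ---------------------------------------------------------------------------
# bistability boundaries and critical curves
# ---------------------------------------------------------------------------

def _signal_scale(spec: ModelSpec, ctx: GrowthContext) -> float:
    p = spec.params
    if spec.kind == "protease":
        return p.s0
    if spec.kind == "two_component":
        return p.k_act
    if spec.kind == "lac":
        try:
            return lac_threshold_relation(p, ctx, "center")
        except ValueError:
            return p.k_tau0 * ctx.g / p.alpha_imp
    raise ValueError(
        "the autoactivator has no external signal; its control parameter is growth rate"
    )


@dataclass(frozen=True)
class BistabilityWindow:
    s_low: float
    s_high: float  # nan when bistable beyond the scan ceiling

    @property
    def s_center(self) -> float:
        return math.sqrt(self.s_low * self.s_high)


def _n_stable(spec, signal, ctx, fp_kw) -> int:
    return sum(1 for fp in find_fixed_points(spec, signal, ctx, **fp_kw) if fp.stable)


def bistability_boundaries(
    spec: ModelSpec,
    doubling_time_h: float,
    *,
    delta: float = 0.0,
    span_decades: float = 6.0,
    n_scan: int = 400,
    rel_tol: float = 1e-4,
    **fp_kw,
) -> BistabilityWindow | None:
    """Saddle-node signal boundaries at a given doubling time, or None.

    A log-spaced scan over ``span_decades`` decades around the model's
    natural signal scale locates changes in the number of stable fixed
    points; each transition is then refined by bisection in log signal to
    relative tolerance ``rel_tol``.
    """
    if doubling_time_h <= 0:
        raise ValueError("doubling time must be > 0")
    ctx = GrowthContext.from_doubling_time(doubling_time_h, delta)
    scale = _signal_scale(spec, ctx)
    s_grid = np.geomspace(scale * 10 ** (-span_decades), scale * 10 ** span_decades, n_scan)
    counts = np.array([_n_stable(spec, float(s), ctx, fp_kw) for s in s_grid])
    bi = counts >= 2
    if not bi.any():
        logger.warning(
            "no bistable signal found for %s at T=%.3g h over scan range "
            "[%.3g, %.3g]", spec.kind, doubling_time_h, s_grid[0], s_grid[-1]
        )
        return None

    def refine(lo: float, hi: float) -> float:
        # invariant: exactly one of (lo, hi) is bistable
        lo_bi = _n_stable(spec, lo, ctx, fp_kw) >= 2
        while hi / lo - 1.0 > rel_tol:
            mid = math.sqrt(lo * hi)
            if (_n_stable(spec, mid, ctx, fp_kw) >= 2) == lo_bi:
                lo = mid
            else:
                hi = mid
        return math.sqrt(lo * hi)

    first = int(np.flatnonzero(bi)[0])
    last = int(np.flatnonzero(bi)[-1])
    if first == 0:
        logger.warning("bistable region extends below scan floor at T=%.3g h", doubling_time_h)
        s_low = float(s_grid[0])
    else:
        s_low = refine(float(s_grid[first - 1]), float(s_grid[first]))
    if last == len(s_grid) - 1:
        logger.warning("bistable region extends beyond scan ceiling at T=%.3g h", doubling_time_h)
        s_high = math.nan
    else:
        s_high = refine(float(s_grid[last]), float(s_grid[last + 1]))
    return BistabilityWindow(s_low=s_low, s_high=s_high)


@dataclass(frozen=True)
class CriticalCurve:
    """Bistability boundaries along a doubling-time axis."""

    t: np.ndarray         # doubling times, h
    s_low: np.ndarray     # onset boundary (nan where monostable throughout)
    s_high: np.ndarray
    s_center: np.ndarray  # geometric mean of the boundaries

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "doubling_time_h": self.t,
                "s_low": self.s_low,
                "s_high": self.s_high,
                "s_center": self.s_center,
            }
        )


def critical_curve(
    spec: ModelSpec,
    t_axis,
    *,
    delta: float = 0.0,
    **kw,
) -> CriticalCurve:
    """Bistability boundaries and their geometric center per doubling time."""
    t_axis = np.asarray(t_axis, dtype=float)
    if np.any(t_axis <= 0):
        raise ValueError("doubling times must be > 0")
    lows, highs = [], []
    for t in t_axis:
        win = bistability_boundaries(spec, float(t), delta=delta, **kw)
        if win is None:
            lows.append(math.nan)
            highs.append(math.nan)
        else:
            lows.append(win.s_low)
            highs.append(win.s_high)
    lows_a = np.array(lows)
    highs_a = np.array(highs)
    return CriticalCurve(
        t=t_axis, s_low=lows_a, s_high=highs_a, s_center=np.sqrt(lows_a * highs_a)
    )


def scaling_exponent(curve: CriticalCurve, t_min: float, t_max: float) -> float:
    """OLS slope of log10(s_center) vs log10(doubling time) inside [t_min, t_max]."""
    mask = (curve.t >= t_min) & (curve.t <= t_max) & np.isfinite(curve.s_center)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 finite curve points in [{t_min}, {t_max}], have {int(mask.sum())}"
        )
    slope = np.polyfit(np.log10(curve.t[mask]), np.log10(curve.s_center[mask]), 1)[0]
    return float(slope)
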