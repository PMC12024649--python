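"""Monod growth kinetics and concentration-dependent sugar preferences.

Growth rate on a single carbon source follows the hyperbolic Monod law
``lam(c) = lam_max * c / (K_s + c)``.  A cell currently growing at rate
``lam`` should only induce the catabolic operon of an alternative sugar if
that sugar's concentration supports a higher growth rate, i.e. if the
concentration exceeds the inverse Monod value ``K_s * lam / (lam_max - lam)``.

Growth-coupled sensitivity realizes this optimum without cross-regulation:
when the full-induction expression of the operon decreases linearly with
growth rate (the catabolic "C-line", y_h(lam) = y0 (1 - lam/lam_star)), the
center of the operon's bistable region tracks the inverse Monod curve of
its sugar.  ``calibrate_cline`` finds the (y0, lam_star) pair minimizing the
log-space tracking error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .models import CLine, GrowthContext, LacParams, ModelSpec, lac_threshold_relation

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Monod kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonodParams:
    """Hyperbolic growth law; ``lam_max`` in 1/h, ``K_s`` in µM."""

    lam_max: float
    K_s: float

    def __post_init__(self) -> None:
        if self.lam_max <= 0 or self.K_s <= 0:
            raise ValueError("lam_max and K_s must be > 0")


def monod(c, p: MonodParams):
    """Growth rate (1/h) at external sugar concentration ``c`` (µM)."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be >= 0")
    out = p.lam_max * c_arr / (p.K_s + c_arr)
    return out if isinstance(c, np.ndarray) else float(out)


def inverse_monod(lam, p: MonodParams):
    """Sugar concentration (µM) needed to attain growth rate ``lam`` (1/h)."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0) or np.any(lam_arr >= p.lam_max):
        raise ValueError(f"unattainable growth rate: need 0 <= lam < lam_max={p.lam_max:g}")
    out = p.K_s * lam_arr / (p.lam_max - lam_arr)
    return out if isinstance(lam, np.ndarray) else float(out)


def monod_from_anchors(c1: float, lam1: float, c2: float, lam2: float) -> MonodParams:
    """Solve (lam_max, K_s) from two (concentration, growth-rate) anchors."""
    if c1 == c2 or lam1 == lam2:
        raise ValueError("anchors must differ in both concentration and rate")
    K_s = c1 * c2 * (lam2 - lam1) / (lam1 * c2 - lam2 * c1)
    lam_max = lam1 * (K_s + c1) / c1
    if K_s <= 0 or lam_max <= 0:
        raise ValueError("anchors are not consistent with a Monod law")
    return MonodParams(lam_max=lam_max, K_s=K_s)


#: Glucose growth law anchored at 11.1 mM -> 1.06 doublings/h and 2 µM ->
#: 0.19 doublings/h (internal rates in 1/h).
GLUCOSE = monod_from_anchors(11100.0, 1.06 * LN2, 2.0, 0.19 * LN2)

#: Lactose growth law: K_s chosen at 100 µM; lam_max set so that growth on
#: saturating lactose (550 µM) equals growth on 50 µM glucose, placing the
#: induced/uninduced crossover of glucose-lactose mixtures at ~50 µM glucose.
LACTOSE = MonodParams(
    lam_max=monod(50.0, GLUCOSE) * (100.0 + 550.0) / 550.0,
    K_s=100.0,
)


# ---------------------------------------------------------------------------
# C-line calibration
# ---------------------------------------------------------------------------

def _cline_center(lac: LacParams, y0: float, lam_star: float, lam: float, delta: float) -> float:
    from dataclasses import replace

    params = replace(lac, regulation=CLine(y0=y0, lam_star=lam_star))
    return lac_threshold_relation(params, GrowthContext(lam, delta), "center")


def calibrate_cline(
    lac: LacParams,
    target: MonodParams,
    lam_grid: Sequence[float],
    *,
    delta: float = 0.0,
    max_lam_star_factor: float = 2.0,
) -> tuple[CLine, float]:
    """Fit (y0, lam_star) so the lac bistable center tracks the inverse
    Monod curve of ``target`` over ``lam_grid``.

    Minimizes the sup norm of |log(s_center(lam) / inverse_monod(lam))|.
    Default decay ``delta = 0``: the optimal-tracking argument holds for
    molecules whose loss is dominated by dilution.  Returns the calibrated
    C-line and the achieved tracking error (natural-log units).
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if np.any(lam_grid <= 0) or np.any(lam_grid >= target.lam_max):
        raise ValueError("lam_grid must lie strictly inside (0, target.lam_max)")
    targets = inverse_monod(lam_grid, target)
    lam_hi = max_lam_star_factor * target.lam_max
    lam_floor = float(lam_grid.max()) * (1 + 1e-9)

    def unpack(theta):
        y0 = math.exp(theta[0])
        lam_star = lam_floor + (lam_hi - lam_floor) / (1.0 + math.exp(-theta[1]))
        return y0, lam_star

    def objective(theta):
        y0, lam_star = unpack(theta)
        try:
            errs = [
                abs(math.log(_cline_center(lac, y0, lam_star, lam, delta) / t))
                for lam, t in zip(lam_grid, targets)
            ]
        except (ValueError, OverflowError):
            return 1e6
        return max(errs)

    best = None
    for y0_guess in (1.0, 10.0, 100.0):
        for ls_guess in (1.05 * target.lam_max, 1.5 * target.lam_max):
            t1 = (ls_guess - lam_floor) / (lam_hi - lam_floor)
            t1 = min(max(t1, 1e-6), 1 - 1e-6)
            theta0 = [math.log(y0_guess), math.log(t1 / (1 - t1))]
            res = minimize(
                objective, theta0, method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-13, maxiter=5000, maxfev=5000),
            )
            if best is None or res.fun < best.fun:
                best = res
    y0, lam_star = unpack(best.x)
    if best.fun >= 1e6:
        raise RuntimeError(
            f"C-line calibration failed; best found y0={y0:g}, lam_star={lam_star:g}"
        )
    return CLine(y0=y0, lam_star=lam_star), float(best.fun)


def tracking_error(
    centers: Sequence[float], lam_grid: Sequence[float], target: MonodParams
) -> float:
    """Sup-norm log-space deviation of given bistable centers from the
    inverse Monod curve (amplitude-free: deviations about their own log-mean
    are not removed — this compares absolute tracking)."""
    centers = np.asarray(centers, dtype=float)
    ratio = np.log(centers / inverse_monod(np.asarray(lam_grid, dtype=float), target))
    return float(np.max(np.abs(ratio)))


# ---------------------------------------------------------------------------
# winner-take-all sugar choice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SugarOption:
    name: str
    concentration: float  # µM
    monod: MonodParams
    switch: Optional[ModelSpec] = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class InducedSetPrediction:
    induced: tuple[str, ...]
    attainable: dict
    tie: bool


def predict_induced_set(
    options: Sequence[SugarOption],
    current_lam: Optional[float] = None,
    *,
    rel_tie_tol: float = 1e-12,
) -> InducedSetPrediction:
    """Which sugars' switches are supercritical: only the option whose
    concentration supports the highest attainable growth rate induces (and
    only if it beats the designated current growth rate).  Exact ties are
    returned as a set and flagged, never broken randomly."""
    if not options:
        raise ValueError("need at least one sugar option")
    lams = {opt.name: monod(opt.concentration, opt.monod) for opt in options}
    best = max(lams.values())
    floor = current_lam if current_lam is not None else -math.inf
    winners = tuple(
        name for name, lam in lams.items()
        if lam >= best * (1.0 - rel_tie_tol) and lam > floor
    )
    tie = len(winners) > 1
    return InducedSetPrediction(induced=winners, attainable=lams, tie=tie)
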