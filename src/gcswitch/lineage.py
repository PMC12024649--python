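"""Single-cell lineage analysis for mother-machine style data.

Works on per-cell frame tables (time, length, total fluorescence): growth
rates by log-length regression, induction classification against a
molecule-count threshold, photobleaching correction, windowed instantaneous
estimates of growth rate / volumic production / concentration, quadrant-based
detection of on/off switches on three-cell lineages (parent + focal +
daughter average), and the growth comparison of switching versus returning
lineages.

Quadrants are defined on natural-log scales of LacZ-GFP concentration (x)
and volumic production rate (y) against a common threshold (default 5.5):
"blue" = both low (uninduced), "yellow" = both high (induced), "green" =
production high but concentration still low (switching on), "orange" =
production low but concentration still high (switching off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

MIN_CELL_FRAMES = 10          # cells observed for fewer frames are filtered
INDUCTION_THRESHOLD = 250.0   # molecules separating induced / uninduced
MIXED_LOW, MIXED_HIGH = 0.05, 0.95  # induced-fraction band discarded as mixed
LOG_QUADRANT_THRESHOLD = 5.5  # natural-log threshold for both quadrant axes


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRecord:
    """One cell cycle: frames of (time h, length µm, total fluorescence
    in molecule equivalents)."""

    cell_id: str
    parent_id: Optional[str]
    time: np.ndarray
    length: np.ndarray
    fluor: np.ndarray
    daughters: tuple = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        ln = np.asarray(self.length, dtype=float)
        fl = np.asarray(self.fluor, dtype=float)
        if not (len(t) == len(ln) == len(fl)) or len(t) < 1:
            raise ValueError("frames must be non-empty and of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(ln <= 0):
            raise ValueError("lengths must be > 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "length", ln)
        object.__setattr__(self, "fluor", fl)

    @property
    def n_frames(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# per-cell operations
# ---------------------------------------------------------------------------

def cell_growth_rate(cell: CellRecord) -> Optional[tuple[float, float]]:
    """Single-cell growth rate in doublings/hour (slope of log2 length vs
    time) with SE; ``None`` when the cell has fewer than 10 frames (the
    reliability filter, a typed rejection rather than an error)."""
    if cell.n_frames < MIN_CELL_FRAMES:
        return None
    res = stats.linregress(cell.time, np.log2(cell.length))
    return float(res.slope), float(res.stderr)


def bleach_correct(c_u: float, beta: float, lam: float) -> float:
    """Total concentration from the unbleached-only concentration.

    At steady state the unbleached pool obeys c_u = q/(lam + beta) while the
    total is c = q/lam, hence c = c_u (1 + beta/lam).  ``beta`` is the
    photobleaching rate (1/h), ``lam`` the growth rate (1/h).
    """
    if lam <= 0:
        raise ValueError("growth rate must be > 0 for bleach correction")
    if beta < 0:
        raise ValueError("bleach rate must be >= 0")
    return c_u * (1.0 + beta / lam)


def classify_trace(cell: CellRecord, threshold_molecules: float = INDUCTION_THRESHOLD) -> str:
    """'induced' when >=95% of frames exceed the molecule threshold,
    'uninduced' when <=5% do; traces induced for more than 5% but less than
    95% of their frames are 'mixed' and discarded downstream."""
    frac = float(np.mean(cell.fluor > threshold_molecules))
    if frac >= MIXED_HIGH:
        return "induced"
    if frac <= MIXED_LOW:
        return "uninduced"
    return "mixed"


def spherocylinder_volume(length, radius: float):
    """Cell volume (µm^3 = fL) for a spherocylinder of given length and
    per-condition mean radius: V = pi r^2 (L - 2r) + (4/3) pi r^3."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    length = np.asarray(length, dtype=float)
    cyl = np.maximum(length - 2.0 * radius, 0.0)
    return math.pi * radius ** 2 * cyl + (4.0 / 3.0) * math.pi * radius ** 3


def _rolling_slope(t: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Centered rolling OLS slope with edge windows clipped to the trace."""
    n = len(t)
    half = w // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + half + 1, n)
        if hi - lo < w:  # clip at edges, keep window length when possible
            lo = max(min(lo, n - w), 0)
            hi = min(lo + w, n)
        tt = t[lo:hi]
        yy = y[lo:hi]
        tm = tt.mean()
        out[i] = ((tt - tm) * (yy - yy.mean())).sum() / ((tt - tm) ** 2).sum()
    return out


@dataclass(frozen=True)
class InstantaneousEstimates:
    """Per-frame windowed-regression estimates for one cell."""

    time: np.ndarray
    growth_dbl: np.ndarray    # doublings/hour
    production: np.ndarray    # molecules per fL per hour (volumic production)
    concentration: np.ndarray # molecules per fL


def estimate_instantaneous(
    cell: CellRecord, radius: float, w: int = 5
) -> InstantaneousEstimates:
    """Windowed-regression estimates of instantaneous growth rate, volumic
    production rate and concentration for a single cell.

    The regression is strictly per cell (never across divisions).  Growth is
    the rolling slope of log2(length); volumic production is the rolling
    slope of total fluorescence divided by the spherocylinder volume;
    concentration is total fluorescence over volume.  ``w`` must be odd
    (centered windows).
    """
    if w % 2 == 0:
        raise ValueError("window length w must be odd for centered regression")
    if cell.n_frames < w:
        raise ValueError(f"trace has {cell.n_frames} frames (< window {w})")
    vol = spherocylinder_volume(cell.length, radius)
    growth = _rolling_slope(cell.time, np.log2(cell.length), w)
    dfdt = _rolling_slope(cell.time, cell.fluor, w)
    return InstantaneousEstimates(
        time=cell.time,
        growth_dbl=growth,
        production=dfdt / vol,
        concentration=cell.fluor / vol,
    )


# ---------------------------------------------------------------------------
# three-cell lineage traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageTrace:
    """Per-frame estimates along parent -> focal -> daughter-average."""

    lineage_id: str
    time: np.ndarray
    growth_dbl: np.ndarray
    production: np.ndarray
    concentration: np.ndarray


def build_lineage_trace(
    focal: CellRecord,
    cells: dict,
    radius: float,
    w: int = 5,
    *,
    bleach_rate_h: float = 0.0,
) -> LineageTrace:
    """Append parent frames before and the frame-wise average of the two
    daughters after the focal cell (truncated at the shorter daughter).
    Instantaneous estimates are computed per cell, never across divisions.
    With a non-zero ``bleach_rate_h`` the concentration (and production) are
    photobleach-corrected per cell via c = c_u (1 + beta/lam).
    """

    def _estimate(cell: CellRecord) -> InstantaneousEstimates:
        est = estimate_instantaneous(cell, radius, w)
        if bleach_rate_h > 0:
            gr = cell_growth_rate(cell)
            lam_h = max(
                (gr[0] if gr else float(np.median(est.growth_dbl))) * math.log(2.0), 0.05
            )
            corr = bleach_correct(1.0, bleach_rate_h, lam_h)
            est = InstantaneousEstimates(
                time=est.time,
                growth_dbl=est.growth_dbl,
                production=est.production * corr,
                concentration=est.concentration * corr,
            )
        return est

    pieces = []
    parent = cells.get(focal.parent_id) if focal.parent_id else None
    if parent is not None and parent.n_frames >= w:
        pieces.append(_estimate(parent))
    pieces.append(_estimate(focal))
    daughters = [cells[d] for d in focal.daughters if d in cells]
    daughters = [d for d in daughters if d.n_frames >= w]
    if len(daughters) == 2:
        e1, e2 = (_estimate(d) for d in daughters)
        n = min(len(e1.time), len(e2.time))
        pieces.append(
            InstantaneousEstimates(
                time=e1.time[:n],
                growth_dbl=(e1.growth_dbl[:n] + e2.growth_dbl[:n]) / 2.0,
                production=(e1.production[:n] + e2.production[:n]) / 2.0,
                concentration=(e1.concentration[:n] + e2.concentration[:n]) / 2.0,
            )
        )
    elif len(daughters) == 1:
        pieces.append(_estimate(daughters[0]))
    time = np.concatenate([p.time for p in pieces])
    order = np.argsort(time, kind="stable")
    return LineageTrace(
        lineage_id=focal.cell_id,
        time=time[order],
        growth_dbl=np.concatenate([p.growth_dbl for p in pieces])[order],
        production=np.concatenate([p.production for p in pieces])[order],
        concentration=np.concatenate([p.concentration for p in pieces])[order],
    )


# ---------------------------------------------------------------------------
# switch detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchEvent:
    lineage_id: str
    direction: str        # 'on' or 'off'
    t_switch: float       # time the volumic production crossed the threshold
    pre_growth_dbl: float # mean growth rate in the pre-switch window


@dataclass(frozen=True)
class QuadrantVisit:
    """One lineage's first visit to a transition quadrant and its fate."""

    lineage_id: str
    quadrant: str      # 'green' (switching on) or 'orange' (switching off)
    growth_dbl: float  # mean growth rate during the visit
    switched: bool     # True if the visit ended in the opposite stable state


def _log_or_neginf(values: np.ndarray) -> np.ndarray:
    out = np.full(len(values), -np.inf)
    pos = values > 0
    out[pos] = np.log(values[pos])
    return out


def _cross_time(t0, t1, y0, y1, theta) -> float:
    """Linear interpolation of the time y crosses theta between two frames."""
    if not np.isfinite(y0) or y1 == y0:
        return float(t1)
    frac = (theta - y0) / (y1 - y0)
    return float(t0 + frac * (t1 - t0))


def detect_switches(
    trace: LineageTrace,
    log_threshold: float = LOG_QUADRANT_THRESHOLD,
    *,
    pre_window_h: float = 0.5,
    min_dwell_h: float = 0.25,
    collect_visits: bool = False,
):
    """On/off switches of a lineage in (concentration, production) space.

    An on-switch goes from both variables below the threshold (blue
    quadrant) to both above (yellow); an off-switch is the mirror image.
    Excursions in which production crosses but concentration never follows
    are not events, and a stable quadrant only counts as reached once the
    lineage dwells in it for at least ``min_dwell_h`` (or to the end of the
    trace) — crossings too brief for the state to settle do not qualify.
    The switch time is the time at which the volumic production rate
    crossed the threshold (linearly interpolated between frames).  With
    ``collect_visits`` the transition-quadrant occupancies (green/orange)
    and their fates are returned as well.
    """
    lc = _log_or_neginf(trace.concentration)
    lp = _log_or_neginf(trace.production)
    lo_c = lc < log_threshold
    lo_p = lp < log_threshold
    n = len(trace.time)
    # a stable-quadrant frame "settles" only if its run lasts >= min_dwell_h
    settled = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        blue = lo_c[i] and lo_p[i]
        yellow = (not lo_c[i]) and (not lo_p[i])
        if blue or yellow:
            j = i
            while j + 1 < n and (
                (lo_c[j + 1] and lo_p[j + 1]) == blue
                and ((not lo_c[j + 1]) and (not lo_p[j + 1])) == yellow
            ):
                j += 1
            if trace.time[j] - trace.time[i] >= min_dwell_h:
                settled[i:j + 1] = True
            i = j + 1
        else:
            i += 1
    events: list[SwitchEvent] = []
    visits: list[QuadrantVisit] = []
    committed: Optional[str] = None
    up_cross: Optional[float] = None
    down_cross: Optional[float] = None
    visit_frames: list[int] = []
    visit_quadrant: Optional[str] = None

    def close_visit(switched: bool) -> None:
        nonlocal visit_frames, visit_quadrant
        if visit_quadrant is not None and visit_frames:
            visits.append(
                QuadrantVisit(
                    lineage_id=trace.lineage_id,
                    quadrant=visit_quadrant,
                    growth_dbl=float(np.mean(trace.growth_dbl[visit_frames])),
                    switched=switched,
                )
            )
        visit_frames, visit_quadrant = [], None

    def pre_growth(t_sw: float) -> float:
        mask = (trace.time >= t_sw - pre_window_h) & (trace.time <= t_sw)
        if not mask.any():
            return math.nan
        return float(np.mean(trace.growth_dbl[mask]))

    for i in range(len(trace.time)):
        if i > 0:
            if lo_p[i - 1] and not lo_p[i]:
                up_cross = _cross_time(
                    trace.time[i - 1], trace.time[i], lp[i - 1], lp[i], log_threshold
                )
            elif not lo_p[i - 1] and lo_p[i]:
                down_cross = _cross_time(
                    trace.time[i - 1], trace.time[i], lp[i - 1], lp[i], log_threshold
                )
        if lo_c[i] and lo_p[i] and settled[i]:  # blue
            if committed == "high":
                # full off-switch completed only if it passed through orange;
                # a committed-high lineage reaching blue has by construction
                # crossed production downward
                t_sw = down_cross if down_cross is not None else float(trace.time[i])
                events.append(
                    SwitchEvent(trace.lineage_id, "off", t_sw, pre_growth(t_sw))
                )
            close_visit(switched=(committed == "high" and visit_quadrant == "orange"))
            committed = "low"
        elif not lo_c[i] and not lo_p[i] and settled[i]:  # yellow
            if committed == "low":
                t_sw = up_cross if up_cross is not None else float(trace.time[i])
                events.append(
                    SwitchEvent(trace.lineage_id, "on", t_sw, pre_growth(t_sw))
                )
            close_visit(switched=(committed == "low" and visit_quadrant == "green"))
            committed = "high"
        elif lo_c[i] != lo_p[i]:  # transition quadrants
            quadrant = "green" if lo_c[i] else "orange"
            if visit_quadrant is None:
                visit_quadrant = quadrant
                visit_frames = [i]
            elif visit_quadrant == quadrant:
                visit_frames.append(i)
            else:  # jumped between transition quadrants; restart the visit
                close_visit(switched=False)
                visit_quadrant = quadrant
                visit_frames = [i]
        else:  # unsettled flicker into a stable quadrant: part of the visit
            if visit_quadrant is not None:
                visit_frames.append(i)
    close_visit(switched=False)
    if collect_visits:
        return events, visits
    return events


def dedupe_switches(
    grouped_events: Sequence[tuple], min_sep_h: float = 1.0
) -> list[tuple]:
    """Collapse repeated detections of one physical switch.

    ``grouped_events`` is a sequence of (group, SwitchEvent) pairs, where
    the group identifies the physical unit (e.g. a mother-machine channel):
    the same switch appears in up to three overlapping three-cell lineage
    traces.  Events of one group and direction closer than ``min_sep_h``
    are merged, keeping the earliest.
    """
    clusters: dict = {}
    for group, ev in sorted(
        grouped_events, key=lambda ge: (str(ge[0]), ge[1].direction, ge[1].t_switch)
    ):
        key = (group, ev.direction)
        if key in clusters and ev.t_switch - clusters[key][-1][1].t_switch < min_sep_h:
            clusters[key][-1] = (group, ev)  # same physical switch: keep the
            # latest detection (the crossing closest to commitment)
        else:
            clusters.setdefault(key, []).append((group, ev))
    out = [ge for lst in clusters.values() for ge in lst]
    out.sort(key=lambda ge: (str(ge[0]), ge[1].t_switch))
    return out


# ---------------------------------------------------------------------------
# switcher vs returner growth comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthComparison:
    direction: str
    n_switched: int
    n_returned: int
    median_switched: float
    iqr_switched: tuple
    median_returned: float
    iqr_returned: tuple
    t_stat: float
    p_value: float


def _first_visit_per_lineage(visits: Iterable[QuadrantVisit], quadrant: str):
    seen = {}
    for v in visits:
        if v.quadrant == quadrant and v.lineage_id not in seen:
            seen[v.lineage_id] = v
    return list(seen.values())


def compare_switcher_growth(
    visits: Sequence[QuadrantVisit], direction: str
) -> GrowthComparison:
    """Welch two-sample t test of growth rates: lineages whose transition-
    quadrant visit ended in a completed switch versus lineages that returned.

    ``direction='on'`` compares green-quadrant visits (candidate on-switches),
    ``direction='off'`` orange-quadrant visits.  Each lineage is sampled once
    per quadrant (its first visit).
    """
    if direction not in ("on", "off"):
        raise ValueError("direction must be 'on' or 'off'")
    quadrant = "green" if direction == "on" else "orange"
    sampled = _first_visit_per_lineage(visits, quadrant)
    switched = np.array([v.growth_dbl for v in sampled if v.switched])
    returned = np.array([v.growth_dbl for v in sampled if not v.switched])
    if len(switched) < 2 or len(returned) < 2:
        raise ValueError(
            f"need >= 2 lineages per group, have {len(switched)} switched / "
            f"{len(returned)} returned"
        )
    t_stat, p = stats.ttest_ind(switched, returned, equal_var=False)
    q = lambda a: (float(np.percentile(a, 25)), float(np.percentile(a, 75)))
    return GrowthComparison(
        direction=direction,
        n_switched=len(switched),
        n_returned=len(returned),
        median_switched=float(np.median(switched)),
        iqr_switched=q(switched),
        median_returned=float(np.median(returned)),
        iqr_returned=q(returned),
        t_stat=float(t_stat),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# population bookkeeping
# ---------------------------------------------------------------------------

def induced_fraction(
    cells: Iterable[CellRecord],
    *,
    threshold_molecules: float = INDUCTION_THRESHOLD,
    burn_in_h: float = 5.0,
) -> tuple[float, dict]:
    """Fraction of induced cells at steady state.

    Cells are classified on their frames after the burn-in; mixed traces
    (induced between 5% and 95% of frames) are discarded, as are cells with
    fewer than 10 post-burn-in frames.  Returns (fraction, counts dict).
    """
    counts = {"induced": 0, "uninduced": 0, "mixed": 0, "filtered": 0}
    for cell in cells:
        mask = cell.time >= burn_in_h
        if mask.sum() < MIN_CELL_FRAMES:
            counts["filtered"] += 1
            continue
        sub = CellRecord(
            cell.cell_id, cell.parent_id,
            cell.time[mask], cell.length[mask], cell.fluor[mask],
        )
        counts[classify_trace(sub, threshold_molecules)] += 1
    total = counts["induced"] + counts["uninduced"]
    frac = counts["induced"] / total if total else math.nan
    return frac, counts
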