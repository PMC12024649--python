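"""Synthetic-data generators with ground-truth sidecars.

Every generator is a pure function of (config, seed): the same config and
seed give identical output.  Three generators cover the package's input
types:

* ``gen_plate_dataset`` — plate-reader growth curves (OD600 + reporter)
  for a grid of media conditions x inducer concentrations x replicates,
  with Hill-shaped steady-state induction and multiplicative noise.
* ``gen_threshold_dataset`` — (log doubling time, log critical inducer)
  points generated from a switch model's critical curve with log-normal
  replicate scatter, feeding the Bayesian slope fit.
* ``gen_lineage_dataset`` — mother-machine style single-cell lineages on
  glucose/lactose mixtures: Ornstein-Uhlenbeck growth-rate fluctuations
  drive a growth-rate-aware lac ODE, producing stochastic on/off switches;
  cells grow exponentially in length, divide at a threshold length with
  binomial fluorophore partitioning, and are observed with per-exposure
  photobleaching.  The truth sidecar records latent states and switch times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import phase
from .assays import PlateTimeSeries
from .bulkfit import SlopePoint, hill_activity
from .lineage import CellRecord
from .models import ModelSpec
from .presets import DELTA_48H
from .sugar import GLUCOSE, LACTOSE, MonodParams, monod

LN2 = math.log(2.0)
UM_FL_TO_MOLECULES = 602.214076


# ---------------------------------------------------------------------------
# plate-reader generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateCondition:
    """One media condition: its true doubling rate and induction curve."""

    label: str
    lam_dbl: float                           # doublings/hour
    hill: tuple  # (b, f, k, m) of the steady-state activity vs inducer


@dataclass(frozen=True)
class PlateGenConfig:
    conditions: tuple
    tmg_grid: tuple = (0.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0)
    replicates: int = 3
    od_noise_cv: float = 0.01
    signal_noise_cv: float = 0.02
    sampling_interval_min: float = 4.0
    #: run length in hours; None sizes each condition's run so the culture
    #: saturates (the plate-reader practice of tuning dilution and delay per
    #: growth rate, expressed as time instead)
    duration_h: Optional[float] = None
    lag_h: float = 1.0
    #: inoculum OD; small enough that the background window (which absorbs
    #: it) does not bias growth slopes above the 0.01 segment floor
    od_init: float = 1e-5
    od_max: float = 0.45
    od_background: float = 0.04
    signal_background: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for cond in self.conditions:
            if cond.lam_dbl <= 0:
                raise ValueError("doubling rates must be > 0")


def _batch_od(t: np.ndarray, lam_h: float, lag: float, od0: float, od_max: float) -> np.ndarray:
    """Exponential growth after a lag, saturating at od_max (nutrient
    exhaustion); growth is cleanly exponential below the cap so the
    extracted growth segment carries no curvature bias."""
    te = np.maximum(t - lag, 0.0)
    return np.minimum(od0 * np.exp(lam_h * te), od_max)


def gen_plate_dataset(cfg: PlateGenConfig) -> tuple[list[PlateTimeSeries], pd.DataFrame]:
    """Plate curves plus a tidy truth table of every generating parameter.

    The reporter channel is OD times the condition's steady-state expression
    at its inducer concentration (the Hill curve), so the downstream
    pipeline's activity estimate exp(mean(log signal - log OD)) targets the
    Hill value directly.
    """
    rng = np.random.default_rng(cfg.seed)
    series: list[PlateTimeSeries] = []
    rows = []
    for cond in cfg.conditions:
        b, f, k, m = cond.hill
        lam_h = cond.lam_dbl * LN2
        if cfg.duration_h is not None:
            duration = cfg.duration_h
        else:
            duration = cfg.lag_h + math.log2(cfg.od_max / cfg.od_init) / cond.lam_dbl + 2.0
        t = np.arange(0.0, duration + 1e-9, cfg.sampling_interval_min / 60.0)
        for tmg in cfg.tmg_grid:
            expr = float(hill_activity(np.array([tmg]), b, f, k, m)[0])
            for rep in range(cfg.replicates):
                od = _batch_od(t, lam_h, cfg.lag_h, cfg.od_init, cfg.od_max)
                od_obs = cfg.od_background + od * rng.lognormal(
                    0.0, cfg.od_noise_cv, len(t)
                )
                sig_obs = cfg.signal_background + od * expr * rng.lognormal(
                    0.0, cfg.signal_noise_cv, len(t)
                )
                well = f"{cond.label}_tmg{tmg:g}_r{rep}"
                series.append(
                    PlateTimeSeries(
                        time=t, od600=od_obs, signal=sig_obs,
                        meta={
                            "well": well, "media": cond.label,
                            "tmg_uM": tmg, "replicate": rep,
                        },
                    )
                )
                rows.append(
                    {
                        "well": well, "media": cond.label, "tmg_uM": tmg,
                        "replicate": rep, "true_lam_dbl": cond.lam_dbl,
                        "true_expr": expr, "hill_b": b, "hill_f": f,
                        "hill_k": k, "hill_m": m,
                    }
                )
    return series, pd.DataFrame(rows)


def gen_miller_kinetics(
    activity_miller: float,
    od600_sample: float,
    *,
    duration_h: float = 1.0,
    interval_min: float = 1.0,
    initial_decline_min: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """OD420 kinetics whose initial 30-min slope encodes a known Miller
    activity, optionally preceded by a transient decline."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    s_per_min = activity_miller * 0.5 * od600_sample / 1000.0
    od420 = np.empty_like(t)
    t_dec = initial_decline_min / 60.0
    base = 0.05
    dec = t < t_dec
    od420[dec] = base + 0.02 * (t_dec - t[dec]) / max(t_dec, 1e-9)
    od420[~dec] = base + s_per_min * 60.0 * (t[~dec] - t_dec)
    if noise_sd > 0:
        od420 = od420 + rng.normal(0.0, noise_sd, len(t))
    return t, od420


# ---------------------------------------------------------------------------
# threshold (slope-fit) generator
# ---------------------------------------------------------------------------

def gen_threshold_dataset(
    spec: ModelSpec,
    t_list: Sequence[float],
    sigma_rep: float,
    n_rep: int,
    seed: int,
    *,
    delta: float = DELTA_48H,
    **curve_kw,
) -> tuple[list[SlopePoint], dict]:
    """Critical-concentration replicates from a model's critical curve.

    For each doubling time T_i the numerical bistable-region center
    s_center(T_i) is computed; each of ``n_rep`` replicates is
    s_center * exp(eps) with eps ~ Normal(0, sigma_rep), and sigma_i is set
    to sigma_rep.  Points carry natural-log coordinates.
    """
    t_list = np.asarray(t_list, dtype=float)
    if np.any(t_list <= 0):
        raise ValueError("doubling times must be > 0")
    if sigma_rep < 0:
        raise ValueError("sigma_rep must be >= 0")
    rng = np.random.default_rng(seed)
    curve = phase.critical_curve(spec, t_list, delta=delta, **curve_kw)
    if not np.all(np.isfinite(curve.s_center)):
        raise RuntimeError("critical curve has missing centers on the requested grid")
    sigma_i = sigma_rep if sigma_rep > 0 else 1e-6
    points = []
    for t_i, s_c in zip(curve.t, curve.s_center):
        eps = rng.normal(0.0, sigma_rep, n_rep) if sigma_rep > 0 else np.zeros(n_rep)
        for e in eps:
            points.append(
                SlopePoint(x=math.log(t_i), y=math.log(s_c) + float(e), sigma_i=sigma_i)
            )
    slope_true = np.polyfit(np.log(curve.t), np.log(curve.s_center), 1)[0]
    truth = {
        "t": curve.t.tolist(),
        "s_center": curve.s_center.tolist(),
        "sigma_rep": sigma_rep,
        "noiseless_slope": float(slope_true),
    }
    return points, truth


# ---------------------------------------------------------------------------
# single-cell lineage generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageGenConfig:
    """Mother-machine channel simulation on a glucose/lactose mixture.

    The lac operon follows the growth-rate-aware reduced ODE with C-line
    (catabolic) regulation; the cell grows on glucose while uninduced and
    on lactose once induced; an Ornstein-Uhlenbeck factor multiplies the
    attainable growth rate, coupling expression dynamics to growth
    fluctuations (the mechanism behind stochastic switching near the tie
    point).  Fluorescence is observed every ``fluor_interval_min`` with
    per-exposure bleaching and linear interpolation onto the phase frames.
    """

    glucose_uM: float = 50.0
    lactose_uM: float = 550.0
    glucose_monod: MonodParams = GLUCOSE
    lactose_monod: MonodParams = LACTOSE
    cline_y0: float = 70.0          # µM, full-induction concentration at lam=0
    cline_lam_star: float = 0.7226  # 1/h
    leak: float = 0.01
    alpha_imp: float = 0.00373      # lactose import, 1/(µM h) per µM LacY
    k_tau: float = 10.0             # µM
    n_tau: float = 2.0
    delta: float = DELTA_48H        # 1/h molecular decay
    ou_reversion: float = 2.0       # 1/h mean reversion of the growth factor
    ou_cv: float = 0.2              # stationary CV of the growth factor
    div_length_um: float = 5.0
    div_asymmetry_sd: float = 0.05
    birth_length_um: float = 2.5
    radius_um: float = 0.5
    bleach_per_exposure: float = 0.02
    phase_interval_min: float = 3.0
    fluor_interval_min: float = 9.0
    n_channels: int = 20
    duration_h: float = 20.0
    init_state: str = "uninduced"   # 'uninduced' | 'induced'
    seed: int = 0

    #: GFP molecules observed per LacY-equivalent; sets the fluorescence
    #: scale so induced/uninduced concentrations straddle the e^5.5 threshold
    gfp_per_lacy: float = 0.3

    # concentration threshold (µM LacY) deciding which sugar fuels growth;
    # sits between the unstable point and the induced branch
    state_threshold_uM: float = 2.68

    @property
    def bleach_rate_h(self) -> float:
        """Continuous-rate equivalent of per-exposure bleaching (1/h)."""
        return self.bleach_per_exposure / (self.fluor_interval_min / 60.0)

    @property
    def volume_at_birth_fl(self) -> float:
        from .lineage import spherocylinder_volume

        return float(spherocylinder_volume(self.birth_length_um, self.radius_um))


def _lac_production(cfg: LineageGenConfig, y: float, lam: float) -> float:
    """Production rate (µM/h) of the C-line lac operon at LacY level y,
    growth rate lam, with external lactose as the inducer.  Full-induction
    expression is clamped at zero above lam_star."""
    g = lam + cfg.delta
    y_h = cfg.cline_y0 * max(1.0 - lam / cfg.cline_lam_star, 0.0)
    prod_full = g * y_h
    tau = cfg.alpha_imp * y * cfg.lactose_uM / g
    hill = tau ** cfg.n_tau / (tau ** cfg.n_tau + cfg.k_tau ** cfg.n_tau) if tau > 0 else 0.0
    return prod_full * (cfg.leak + (1.0 - cfg.leak) * hill)


@dataclass
class _CellSim:
    """Latent per-cell state during simulation."""

    length: float
    y: float       # LacY-equivalent concentration, µM
    g_unbleached: float  # unbleached fluorophores, molecules
    g_total: float       # all fluorophores, molecules
    phi: float     # OU growth factor


def _simulate_cell(
    cfg: LineageGenConfig,
    sim: _CellSim,
    t_birth: float,
    t_stop: float,
    rng: np.random.Generator,
    latent_log,
) -> tuple[float, _CellSim, dict]:
    """Advance one cell from birth to division (or t_stop).

    Returns (end time, state at end, frame record dict).  ``latent_log`` is
    a callable(time, production_vol, conc_vol, lam) recording the latent
    (noise-free observation) trajectory for the truth sidecar.
    """
    from .lineage import spherocylinder_volume

    dt = 1.0 / 60.0  # 1-minute Euler step
    phase_dt = cfg.phase_interval_min / 60.0
    fluor_dt = cfg.fluor_interval_min / 60.0
    rho = math.exp(-cfg.ou_reversion * dt)
    ou_innov = cfg.ou_cv * math.sqrt(1.0 - rho * rho)

    times, lengths, fluor_t, fluor_v = [], [], [], []
    t = t_birth
    next_phase = t_birth
    # align exposures to the global fluor grid
    next_fluor = math.ceil(t_birth / fluor_dt - 1e-9) * fluor_dt
    while t < t_stop - 1e-9 and sim.length < cfg.div_length_um:
        if t >= next_phase - 1e-9:
            times.append(t)
            lengths.append(sim.length)
            next_phase += phase_dt
        if t >= next_fluor - 1e-9:
            fluor_t.append(t)
            fluor_v.append(sim.g_unbleached)
            sim.g_unbleached *= math.exp(-cfg.bleach_per_exposure)
            next_fluor += fluor_dt
        induced = sim.y > cfg.state_threshold_uM
        lam_base = monod(cfg.lactose_uM, cfg.lactose_monod) if induced else monod(
            cfg.glucose_uM, cfg.glucose_monod
        )
        lam = max(sim.phi, 0.05) * lam_base
        prod = _lac_production(cfg, sim.y, lam)
        vol = float(spherocylinder_volume(sim.length, cfg.radius_um))
        latent_log(
            t, cfg.gfp_per_lacy * prod * UM_FL_TO_MOLECULES, sim.g_total / vol, lam
        )
        # Euler updates
        sim.length *= math.exp(lam * dt)
        sim.y += (prod - (lam + cfg.delta) * sim.y) * dt
        made = cfg.gfp_per_lacy * prod * vol * UM_FL_TO_MOLECULES * dt
        sim.g_total += made
        sim.g_unbleached += made
        sim.phi = 1.0 + (sim.phi - 1.0) * rho + ou_innov * rng.normal()
        t += dt
    frames = {
        "time": np.array(times),
        "length": np.array(lengths),
        "fluor_time": np.array(fluor_t),
        "fluor_val": np.array(fluor_v),
    }
    return t, sim, frames


def _quadrant_walk(
    lat: np.ndarray, theta: float, min_dwell_h: float = 0.25
) -> tuple[list[tuple[float, str]], Optional[str]]:
    """Truth-side switch walk on a latent (t, production, conc, ...) array.

    Mirrors the detector's semantics: commitment to a stable quadrant
    requires both variables on one side of the threshold for at least
    ``min_dwell_h``; the switch time is the last production crossing before
    commitment.  Returns (events, final committed state).
    """
    n = len(lat)
    with np.errstate(divide="ignore"):
        lp = np.where(lat[:, 1] > 0, np.log(np.maximum(lat[:, 1], 1e-300)), -np.inf)
        lc = np.where(lat[:, 2] > 0, np.log(np.maximum(lat[:, 2], 1e-300)), -np.inf)
    is_low = (lp < theta) & (lc < theta)
    is_high = (lp >= theta) & (lc >= theta)
    settled = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if is_low[i] or is_high[i]:
            j = i
            kind = is_low[i]
            while j + 1 < n and (is_low[j + 1] == kind) and (is_high[j + 1] != kind):
                j += 1
            if lat[j, 0] - lat[i, 0] >= min_dwell_h:
                settled[i:j + 1] = True
            i = j + 1
        else:
            i += 1
    events: list[tuple[float, str]] = []
    committed: Optional[str] = None
    cross: Optional[float] = None
    for i in range(n):
        if i > 0 and (lp[i - 1] < theta) != (lp[i] < theta):
            cross = float(lat[i, 0])
        if is_low[i] and settled[i]:
            if committed == "high":
                events.append((cross if cross is not None else float(lat[i, 0]), "off"))
            committed = "low"
        elif is_high[i] and settled[i]:
            if committed == "low":
                events.append((cross if cross is not None else float(lat[i, 0]), "on"))
            committed = "high"
    return events, committed


def _frames_to_record(cell_id, parent_id, frames, daughters=()) -> Optional[CellRecord]:
    t = frames["time"]
    ft = frames["fluor_time"]
    if len(t) < 1 or len(ft) < 2:
        return None
    # keep only phase frames inside the observed fluorescence span: outside
    # it interpolation would hold the signal flat and fake a production crash
    keep = (t >= ft[0] - 1e-9) & (t <= ft[-1] + 1e-9)
    if keep.sum() < 1:
        return None
    t = t[keep]
    fl = np.interp(t, ft, frames["fluor_val"])
    return CellRecord(
        cell_id=cell_id, parent_id=parent_id,
        time=t, length=frames["length"][keep], fluor=fl,
        daughters=tuple(daughters),
    )


def gen_lineage_dataset(cfg: LineageGenConfig) -> tuple[list[CellRecord], dict]:
    """Simulate mother-machine channels; returns cell records and truth.

    Truth sidecar keys: ``switches`` (list of dicts with channel, direction,
    t_switch from the latent production/concentration quadrant path),
    ``channel_of`` (cell id -> channel), ``lam_mean`` (per-channel mean
    latent growth rate), ``final_state`` (per-channel induced flag).
    """
    from .lineage import LOG_QUADRANT_THRESHOLD

    rng = np.random.default_rng(cfg.seed)
    all_cells: list[CellRecord] = []
    switches: list[dict] = []
    channel_of: dict = {}
    lam_means: list[float] = []
    final_states: list[bool] = []
    latents: list[np.ndarray] = []

    for ch in range(cfg.n_channels):
        # latent trajectory logger for the truth quadrant walk
        latent: list[tuple[float, float, float, float]] = []

        def latent_log(t, prod_vol, conc_vol, lam, _latent=latent):
            _latent.append((t, prod_vol, conc_vol, lam))

        sibling_branches: list[tuple[float, np.ndarray]] = []

        lam0_base = (
            monod(cfg.lactose_uM, cfg.lactose_monod)
            if cfg.init_state == "induced"
            else monod(cfg.glucose_uM, cfg.glucose_monod)
        )
        g0 = lam0_base + cfg.delta
        if cfg.init_state == "induced":
            y_h = cfg.cline_y0 * max(1.0 - lam0_base / cfg.cline_lam_star, 0.0)
            y_init = max(y_h, 2.0 * cfg.state_threshold_uM)
        else:
            # leak-level steady state (feedback negligible at leak expression)
            y_init = cfg.leak * cfg.cline_y0 * max(
                1.0 - lam0_base / cfg.cline_lam_star, 0.0
            )
        length0 = cfg.birth_length_um * (1.0 + 0.1 * rng.uniform(-1, 1))
        vol0 = cfg.volume_at_birth_fl
        g_tot0 = cfg.gfp_per_lacy * y_init * vol0 * UM_FL_TO_MOLECULES
        sim = _CellSim(
            length=length0, y=y_init, g_unbleached=g_tot0, g_total=g_tot0,
            phi=1.0 + cfg.ou_cv * rng.normal(),
        )

        t = 0.0
        k = 0
        prev_id: Optional[str] = None
        pending: Optional[tuple[str, Optional[str], dict]] = None  # awaiting daughters
        while t < cfg.duration_h - 1e-9:
            cid = f"ch{ch}_c{k}"
            t_end, sim, frames = _simulate_cell(cfg, sim, t, cfg.duration_h, rng, latent_log)
            divided = t_end < cfg.duration_h - 1e-9
            cont_id = f"ch{ch}_c{k + 1}"
            sib_id = f"ch{ch}_c{k}s"
            daughters = (cont_id, sib_id) if divided else ()
            rec = _frames_to_record(cid, prev_id, frames, daughters)
            if rec is not None:
                all_cells.append(rec)
                channel_of[rec.cell_id] = ch
            if not divided:
                break
            # division: split length and fluorophores
            frac = min(max(0.5 + cfg.div_asymmetry_sd * rng.normal(), 0.3), 0.7)
            sib = _CellSim(
                length=sim.length * (1.0 - frac),
                y=sim.y,
                g_unbleached=float(rng.binomial(max(int(sim.g_unbleached), 0), 1.0 - frac)),
                g_total=sim.g_total * (1.0 - frac),
                phi=sim.phi,
            )
            sim.length *= frac
            keep_u = float(rng.binomial(max(int(sim.g_unbleached), 0), frac))
            sim.g_unbleached = keep_u
            sim.g_total *= frac
            # simulate the sibling for one cell cycle (not tracked further),
            # logging its latent branch so its switches also enter the truth
            sib_latent: list[tuple[float, float, float, float]] = []
            _, _, sib_frames = _simulate_cell(
                cfg, sib, t_end, min(t_end + 4.0, cfg.duration_h), rng,
                lambda tt, p, c, l, _sl=sib_latent: _sl.append((tt, p, c, l)),
            )
            sib_rec = _frames_to_record(sib_id, cid, sib_frames)
            if sib_rec is not None:
                all_cells.append(sib_rec)
                channel_of[sib_rec.cell_id] = ch
                if sib_latent:
                    sibling_branches.append((t_end, np.array(sib_latent)))
            prev_id = cid
            t = t_end
            k += 1

        # truth: quadrant walk on the mother-line latent trajectory, plus
        # each sibling branch walked over (mother prefix + sibling segment)
        lat = np.array(latent)
        lam_means.append(float(lat[:, 3].mean()))
        theta = LOG_QUADRANT_THRESHOLD
        events, committed = _quadrant_walk(lat, theta)
        for t_sw, direction in events:
            switches.append({"channel": ch, "direction": direction, "t_switch": t_sw})
        for t_div, sib_lat in sibling_branches:
            prefix = lat[lat[:, 0] < t_div - 1e-9]
            branch = np.vstack([prefix, sib_lat]) if len(prefix) else sib_lat
            for t_sw, direction in _quadrant_walk(branch, theta)[0]:
                if t_sw >= t_div - 1e-9:  # only events on the sibling segment
                    switches.append(
                        {"channel": ch, "direction": direction, "t_switch": t_sw}
                    )
        final_states.append(committed == "high")
        latents.append(lat[::3])  # latent trajectory at phase cadence

    truth = {
        "latent": latents,  # per channel: columns (t, production, conc, lam)
        "switches": switches,
        "channel_of": channel_of,
        "lam_mean": lam_means,
        "final_state": final_states,
        "config": cfg,
    }
    return all_cells, truth


def score_switch_detection(
    cells: Sequence[CellRecord],
    truth: dict,
    cfg: LineageGenConfig,
    *,
    w: int = 5,
    dedupe_h: float = 1.5,
    match_tol_h: float = 2.0,
) -> dict:
    """Run the lineage switch detector over a generated dataset and score it
    against the truth sidecar.

    Detections from all three-cell lineage traces are deduplicated per
    channel (overlapping traces see the same physical switch); the truth
    events are deduplicated with the identical rule, then matched greedily
    by channel, direction and time.  Returns precision, recall, the matched
    timing errors, and the deduplicated event lists.
    """
    from dataclasses import dataclass as _dc

    from . import lineage as _lin

    by_id = {c.cell_id: c for c in cells}
    grouped = []
    for c in cells:
        if c.parent_id is None:
            continue
        try:
            trace = _lin.build_lineage_trace(
                c, by_id, cfg.radius_um, w=w, bleach_rate_h=cfg.bleach_rate_h
            )
        except ValueError:
            continue
        for ev in _lin.detect_switches(trace):
            grouped.append((truth["channel_of"][c.cell_id], ev))
    detected = _lin.dedupe_switches(grouped, dedupe_h)

    @_dc(frozen=True)
    class _TruthEvent:
        direction: str
        t_switch: float

    truth_grouped = [
        (s["channel"], _TruthEvent(s["direction"], s["t_switch"]))
        for s in truth["switches"]
    ]
    truth_events = _lin.dedupe_switches(truth_grouped, dedupe_h)

    used: set = set()
    t_errors: list[float] = []
    for g_t, ev_t in truth_events:
        best = None
        for i, (g_d, ev_d) in enumerate(detected):
            if i in used or g_d != g_t or ev_d.direction != ev_t.direction:
                continue
            err = abs(ev_d.t_switch - ev_t.t_switch)
            if best is None or err < best[1]:
                best = (i, err)
        if best is not None and best[1] < match_tol_h:
            used.add(best[0])
            t_errors.append(best[1])
    n_match = len(used)
    return {
        "n_true": len(truth_events),
        "n_detected": len(detected),
        "n_matched": n_match,
        "precision": n_match / max(len(detected), 1),
        "recall": n_match / max(len(truth_events), 1),
        "t_errors_h": t_errors,
        "median_t_error_h": float(np.median(t_errors)) if t_errors else math.nan,
        "detected": detected,
        "truth_events": truth_events,
    }
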