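"""Single-cell lineage analysis: growth rates, classification, bleach
correction, instantaneous estimates, quadrant switch detection and the
switcher-vs-returner growth comparison."""

import math

import numpy as np
import pytest

from gcswitch import lineage, synth
from gcswitch.lineage import (
    CellRecord,
    LineageTrace,
    QuadrantVisit,
    bleach_correct,
    build_lineage_trace,
    cell_growth_rate,
    classify_trace,
    compare_switcher_growth,
    dedupe_switches,
    detect_switches,
    estimate_instantaneous,
    induced_fraction,
    spherocylinder_volume,
)


def _cell(cid="c", parent=None, t=None, length=None, fluor=None, daughters=()):
    n = len(t)
    return CellRecord(cell_id=cid, parent_id=parent, time=np.asarray(t, float),
                      length=np.asarray(length, float),
                      fluor=np.asarray(fluor if fluor is not None else np.ones(n), float),
                      daughters=tuple(daughters))


def _exp_cell(rate_dbl=1.0, n=20, dt=0.05, L0=2.0, **kw):
    t = np.arange(n) * dt
    return _cell(t=t, length=L0 * 2 ** (rate_dbl * t), **kw)


class TestCellGrowthRate:
    def test_doubling_in_one_hour(self):
        g = cell_growth_rate(_exp_cell(rate_dbl=1.0))
        assert g[0] == pytest.approx(1.0, abs=1e-12)

    def test_nine_frames_filtered_ten_accepted(self):
        assert cell_growth_rate(_exp_cell(n=9)) is None
        assert cell_growth_rate(_exp_cell(n=10)) is not None

    def test_monte_carlo_two_sigma_coverage(self, rng):
        hits = 0
        t = np.arange(30) * 0.05
        for _ in range(500):
            L = 2.0 * 2 ** (0.5 * t) * rng.lognormal(0, 0.01, 30)
            lam, se = cell_growth_rate(_cell(t=t, length=L))
            hits += abs(lam - 0.5) <= 2 * se
        assert hits / 500 >= 0.90


class TestBleachCorrect:
    def test_trivial_cases(self):
        assert bleach_correct(3.0, 0.0, 0.5) == 3.0
        assert bleach_correct(3.0, 0.5, 0.5) == pytest.approx(6.0)
        with pytest.raises(ValueError):
            bleach_correct(1.0, 0.1, 0.0)

    def test_recovers_total_concentration_on_simulated_traces(self):
        """Steady-state generator traces: c_u (1 + beta/lam) matches the
        latent total concentration within 3%."""
        cfg = synth.LineageGenConfig(glucose_uM=1110.0, lactose_uM=550.0,
                                     init_state="uninduced", ou_cv=0.05,
                                     n_channels=4, duration_h=10.0, seed=9)
        # uninduced at high glucose: stable low expression; use induced
        # start instead for a strong signal
        cfg = synth.LineageGenConfig(glucose_uM=2.0, lactose_uM=550.0,
                                     init_state="induced", ou_cv=0.05,
                                     n_channels=4, duration_h=10.0, seed=9)
        cells, truth = synth.gen_lineage_dataset(cfg)
        ratios = []
        for ch in range(cfg.n_channels):
            lat = truth["latent"][ch]
            mask = lat[:, 0] > 3.0
            true_conc = lat[mask, 2].mean()
            obs = []
            for c in cells:
                if truth["channel_of"][c.cell_id] != ch or c.cell_id.endswith("s"):
                    continue
                g = cell_growth_rate(c)
                if g is None or c.time[0] < 3.0:
                    continue
                vol = spherocylinder_volume(c.length, cfg.radius_um)
                c_u = float(np.mean(c.fluor / vol))
                obs.append(bleach_correct(c_u, cfg.bleach_rate_h, g[0] * math.log(2)))
            if obs:
                ratios.append(np.mean(obs) / true_conc)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.03)


class TestClassifyTrace:
    def test_clear_states(self):
        n = 20
        t = np.arange(n) * 0.05
        low = _cell(t=t, length=np.full(n, 2.0), fluor=np.full(n, 10.0))
        high = _cell(t=t, length=np.full(n, 2.0), fluor=np.full(n, 1e4))
        assert classify_trace(low) == "uninduced"
        assert classify_trace(high) == "induced"

    def test_half_split_is_mixed(self):
        t = np.arange(20) * 0.05
        fl = np.r_[np.full(10, 10.0), np.full(10, 1e4)]
        assert classify_trace(_cell(t=t, length=np.full(20, 2.0), fluor=fl)) == "mixed"

    def test_threshold_boundary(self):
        t = np.arange(20) * 0.05
        just_below = _cell(t=t, length=np.full(20, 2.0), fluor=np.full(20, 249.0))
        just_above = _cell(t=t, length=np.full(20, 2.0), fluor=np.full(20, 251.0))
        assert classify_trace(just_below) == "uninduced"
        assert classify_trace(just_above) == "induced"


class TestInstantaneous:
    def test_deterministic_growth_and_production(self):
        t = np.arange(31) * 0.05
        L = 2.0 * 2 ** (0.8 * t)
        vol = spherocylinder_volume(L, 0.5)
        fl = np.cumsum(np.r_[100.0, 50.0 * vol[:-1] * 0.05])  # prod 50 /fL/h
        est = estimate_instantaneous(_cell(t=t, length=L, fluor=fl), 0.5, w=5)
        interior = slice(4, -4)
        assert est.growth_dbl[interior] == pytest.approx(0.8, rel=0.02)
        assert est.production[interior] == pytest.approx(50.0, rel=0.05)

    def test_zero_increments_zero_production(self):
        t = np.arange(11) * 0.05
        est = estimate_instantaneous(
            _cell(t=t, length=np.full(11, 2.0), fluor=np.full(11, 500.0)), 0.5)
        assert est.production == pytest.approx(np.zeros(11), abs=1e-9)

    def test_even_window_errors(self):
        with pytest.raises(ValueError):
            estimate_instantaneous(_exp_cell(n=20), 0.5, w=4)

    def test_division_does_not_spike_growth(self):
        """Per-cell regression: halving at division must not leak into the
        growth estimate of either cell."""
        t1 = np.arange(15) * 0.05
        parent = _cell("p", None, t1, 2.5 * 2 ** t1, np.full(15, 1000.0),
                       daughters=("d1", "d2"))
        t2 = t1 + t1[-1] + 0.05
        L2 = parent.length[-1] / 2 * 2 ** (1.0 * (t2 - t2[0]))
        d1 = _cell("d1", "p", t2, L2, np.full(15, 500.0))
        d2 = _cell("d2", "p", t2, L2, np.full(15, 500.0))
        trace = build_lineage_trace(parent, {"p": parent, "d1": d1, "d2": d2}, 0.5)
        assert np.all(np.abs(trace.growth_dbl - 1.0) < 0.05)

    def test_spherocylinder_volume_formula(self):
        # L = 2r degenerates to a sphere
        assert spherocylinder_volume(1.0, 0.5) == pytest.approx(4 / 3 * math.pi * 0.125)
        v = spherocylinder_volume(4.0, 0.5)
        assert v == pytest.approx(math.pi * 0.25 * 3.0 + 4 / 3 * math.pi * 0.125)


def _trace(times, conc, prod, growth=None):
    n = len(times)
    return LineageTrace(
        lineage_id="L", time=np.asarray(times, float),
        growth_dbl=np.asarray(growth if growth is not None else np.full(n, 1.0), float),
        production=np.asarray(prod, float), concentration=np.asarray(conc, float))


class TestDetectSwitches:
    TH = math.e ** 5.5

    def test_full_on_switch_timed_at_production_crossing(self):
        t = np.arange(0, 4.0, 0.1)
        lo, hi = self.TH / 20, self.TH * 20
        prod = np.where(t < 1.0, lo, hi)       # crosses up between 0.9 and 1.0
        conc = np.where(t < 2.0, lo, hi)       # follows one hour later
        events = detect_switches(_trace(t, conc, prod))
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "on"
        assert 0.9 <= ev.t_switch <= 1.0

    def test_excursion_without_concentration_is_not_an_event(self):
        t = np.arange(0, 4.0, 0.1)
        lo, hi = self.TH / 20, self.TH * 20
        prod = np.where((t > 1.0) & (t < 2.0), hi, lo)  # blue -> green -> blue
        conc = np.full(len(t), lo)
        assert detect_switches(_trace(t, conc, prod)) == []

    def test_constant_uninduced_trace_is_quiet(self):
        t = np.arange(0, 3.0, 0.1)
        lo = self.TH / 50
        assert detect_switches(_trace(t, np.full(len(t), lo), np.full(len(t), lo))) == []

    def test_off_switch_mirrored(self):
        t = np.arange(0, 4.0, 0.1)
        lo, hi = self.TH / 20, self.TH * 20
        prod = np.where(t < 1.0, hi, lo)
        conc = np.where(t < 2.0, hi, lo)
        events = detect_switches(_trace(t, conc, prod))
        assert [e.direction for e in events] == ["off"]
        assert 0.9 <= events[0].t_switch <= 1.0

    def test_brief_commitment_does_not_settle(self):
        # yellow occupancy shorter than the dwell time is not a switch
        t = np.arange(0, 4.0, 0.1)
        lo, hi = self.TH / 20, self.TH * 20
        both = np.where((t > 2.0) & (t < 2.15), hi, lo)
        assert detect_switches(_trace(t, both, both)) == []

    def test_visits_record_fate_and_growth(self):
        t = np.arange(0, 4.0, 0.1)
        lo, hi = self.TH / 20, self.TH * 20
        prod = np.where(t < 1.0, lo, hi)
        conc = np.where(t < 2.0, lo, hi)
        growth = np.where(t < 2.0, 0.4, 1.0)
        _, visits = detect_switches(_trace(t, conc, prod, growth), collect_visits=True)
        green = [v for v in visits if v.quadrant == "green"]
        assert len(green) == 1
        assert green[0].switched
        assert green[0].growth_dbl == pytest.approx(0.4)


class TestDedupe:
    def _ev(self, d, t):
        from gcswitch.lineage import SwitchEvent

        return SwitchEvent("x", d, t, 1.0)

    def test_cluster_keeps_last(self):
        events = [(0, self._ev("on", 1.0)), (0, self._ev("on", 1.4)),
                  (0, self._ev("on", 2.2)), (0, self._ev("off", 1.2))]
        out = dedupe_switches(events, min_sep_h=1.5)
        ons = [e.t_switch for g, e in out if e.direction == "on"]
        assert ons == [2.2]
        assert len(out) == 2

    def test_groups_are_independent(self):
        events = [(0, self._ev("on", 1.0)), (1, self._ev("on", 1.2))]
        assert len(dedupe_switches(events, 1.5)) == 2


class TestCompareSwitcherGrowth:
    def _visits(self, sw, rt, quadrant="green"):
        out = [QuadrantVisit(f"s{i}", quadrant, g, True) for i, g in enumerate(sw)]
        out += [QuadrantVisit(f"r{i}", quadrant, g, False) for i, g in enumerate(rt)]
        return out

    def test_identical_groups_give_zero_t(self):
        g = [0.5, 0.6, 0.7, 0.8]
        rep = compare_switcher_growth(self._visits(g, g), "on")
        assert rep.t_stat == pytest.approx(0.0, abs=1e-12)

    def test_power_with_twenty_percent_effect(self, rng):
        """n=100/group with switchers drawn 20% slower: p<0.05 in >=90%
        of simulations."""
        reject = 0
        for _ in range(200):
            sw = rng.normal(0.8 * 0.9, 0.25, 100)
            rt = rng.normal(0.9, 0.25, 100)
            rep = compare_switcher_growth(self._visits(sw, rt), "on")
            reject += rep.p_value < 0.05
        assert reject / 200 >= 0.90

    def test_type_one_error_calibrated(self, rng):
        reject = 0
        n_sim = 1000
        for _ in range(n_sim):
            sw = rng.normal(0.9, 0.25, 100)
            rt = rng.normal(0.9, 0.25, 100)
            rep = compare_switcher_growth(self._visits(sw, rt), "on")
            reject += rep.p_value < 0.05
        assert 0.03 <= reject / n_sim <= 0.07

    def test_degenerate_groups_error(self):
        with pytest.raises(ValueError):
            compare_switcher_growth(self._visits([0.5], [0.6, 0.7]), "on")


class TestInducedFraction:
    def test_burn_in_gating_is_stable_at_steady_state(self):
        cfg = synth.LineageGenConfig(glucose_uM=2.0, init_state="induced",
                                     n_channels=6, duration_h=14.0, seed=12)
        cells, _ = synth.gen_lineage_dataset(cfg)
        f5, _ = induced_fraction(cells, burn_in_h=5.0)
        f8, _ = induced_fraction(cells, burn_in_h=8.0)
        assert abs(f5 - f8) < 0.02

    def test_mixed_traces_are_excluded(self):
        t = np.arange(20) * 0.05 + 6.0
        mixed = _cell("m", None, t, np.full(20, 2.0),
                      np.r_[np.full(10, 10.0), np.full(10, 1e4)])
        clean = _cell("c", None, t, np.full(20, 2.0), np.full(20, 1e4))
        frac, counts = induced_fraction([mixed, clean], burn_in_h=5.0)
        assert counts["mixed"] == 1
        assert frac == 1.0


class TestGeneratorAsymmetry:
    def test_on_switchers_grow_slower_than_population(self):
        """Growth-coupled switching: lineages that switch on out of the
        green quadrant grew slower than the population median."""
        pop = []
        sw_growth = []
        for seed in (11, 21):
            cfg = synth.LineageGenConfig(glucose_uM=50.0, n_channels=30,
                                         duration_h=20.0, seed=seed)
            cells, truth = synth.gen_lineage_dataset(cfg)
            by_id = {c.cell_id: c for c in cells}
            for c in cells:
                g = cell_growth_rate(c)
                if g:
                    pop.append(g[0])
                if c.parent_id:
                    try:
                        tr = build_lineage_trace(c, by_id, cfg.radius_um,
                                                 bleach_rate_h=cfg.bleach_rate_h)
                    except ValueError:
                        continue
                    _, visits = detect_switches(tr, collect_visits=True)
                    sw_growth += [v.growth_dbl for v in visits
                                  if v.quadrant == "green" and v.switched]
        assert len(sw_growth) >= 5
        assert np.median(sw_growth) < np.median(pop)

    def test_off_switchers_grow_faster_than_population(self):
        pop = []
        sw_growth = []
        for seed in (11, 21):
            cfg = synth.LineageGenConfig(glucose_uM=64.0, init_state="induced",
                                         n_channels=30, duration_h=20.0, seed=seed)
            cells, truth = synth.gen_lineage_dataset(cfg)
            by_id = {c.cell_id: c for c in cells}
            for c in cells:
                g = cell_growth_rate(c)
                if g:
                    pop.append(g[0])
                if c.parent_id:
                    try:
                        tr = build_lineage_trace(c, by_id, cfg.radius_um,
                                                 bleach_rate_h=cfg.bleach_rate_h)
                    except ValueError:
                        continue
                    _, visits = detect_switches(tr, collect_visits=True)
                    sw_growth += [v.growth_dbl for v in visits
                                  if v.quadrant == "orange" and v.switched]
        assert len(sw_growth) >= 5
        assert np.median(sw_growth) > np.median(pop)
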