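"""Plate-reader processing: background correction, growth segments, Miller
activity, promoter activity and sliding-window expression estimates."""

import math

import numpy as np
import pytest

from gcswitch import assays, bulkfit, synth
from gcswitch.assays import (
    PlateTimeSeries,
    background_correct,
    expression_sliding_windows,
    find_growth_segment,
    growth_rate_of_segment,
    miller_activity,
    promoter_activity,
)


def _series(time, od, sig, **meta):
    return PlateTimeSeries(time=np.asarray(time, float), od600=np.asarray(od, float),
                           signal=np.asarray(sig, float), meta=meta)


class TestBackgroundCorrect:
    def test_constant_series_become_zero(self):
        t = np.arange(30) / 4.0
        s = _series(t, np.full(30, 0.04), np.full(30, 7.0))
        out = background_correct(s)
        assert out.od600 == pytest.approx(np.zeros(30))
        assert out.signal == pytest.approx(np.zeros(30))

    def test_window_clipped_at_edge(self):
        # minimum at index 3: the 20-point window must span indices 0-19
        t = np.arange(40) / 4.0
        od = np.linspace(1, 2, 40)
        od[3] = 0.0
        s = _series(t, od, np.ones(40))
        out = background_correct(s)
        assert out.od600[5] == pytest.approx(od[5] - od[0:20].mean())

    def test_known_background_plus_exponential_recovered(self):
        t = np.arange(0, 15, 0.25)
        od_true = 1e-4 * np.exp(0.5 * t)
        s = _series(t, 0.04 + od_true, 10.0 + 0 * t)
        out = background_correct(s)
        # bias bounded by the mean of the exponential over the 20-pt window
        bias = od_true[:20].mean()
        assert np.max(np.abs(out.od600 - od_true)) <= bias + 1e-12

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            background_correct(_series(np.arange(10), np.ones(10), np.ones(10)))


class TestGrowthSegment:
    @staticmethod
    def _growth_curve(n_ok):
        """Curve whose qualifying run (OD in (0.01, max/3), signal>0) has
        exactly n_ok points before the peak."""
        pre = np.full(5, 0.005)
        run = np.geomspace(0.011, 0.14, n_ok)
        post = np.geomspace(0.2, 0.45, 10)
        od = np.concatenate([pre, run, post])
        t = np.arange(len(od)) / 4.0
        return _series(t, od, np.ones(len(od)))

    def test_segment_matches_the_three_rules(self):
        s = self._growth_curve(30)
        res = find_growth_segment(s)
        assert res.accepted
        od = s.od600[res.sl]
        assert np.all((od > 0.01) & (od < 0.45 / 3.0))
        assert res.sl == slice(5, 35)

    def test_twenty_point_run_rejected(self):
        res = find_growth_segment(self._growth_curve(20))
        assert not res.accepted and "20 points" in res.reason

    def test_twenty_one_point_run_accepted(self):
        assert find_growth_segment(self._growth_curve(21)).accepted

    def test_zero_signal_rejected(self):
        s = self._growth_curve(30)
        s2 = _series(s.time, s.od600, np.zeros(len(s)))
        assert not find_growth_segment(s2).accepted


class TestGrowthRate:
    def test_exact_doubling(self):
        t = np.linspace(0, 5, 40)
        s = _series(t, 0.02 * 2 ** t, np.ones(40))
        lam, se = growth_rate_of_segment(s, slice(0, 40))
        assert lam == pytest.approx(1.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_natural_exponential_base_conversion(self):
        t = np.linspace(0, 3, 30)
        s = _series(t, 0.02 * np.exp(t), np.ones(30))
        lam, _ = growth_rate_of_segment(s, slice(0, 30))
        assert lam == pytest.approx(1.0 / math.log(2.0), rel=1e-10)

    def test_monte_carlo_two_sigma_coverage(self, rng):
        t = np.linspace(0, 8, 60)
        hits = 0
        for _ in range(500):
            od = 0.02 * 2 ** (0.5 * t) * rng.lognormal(0, 0.02, 60)
            lam, se = growth_rate_of_segment(_series(t, od, np.ones(60)), slice(0, 60))
            hits += abs(lam - 0.5) <= 2 * se
        assert hits / 500 >= 0.90

    def test_nonpositive_od_in_segment_errors(self):
        s = _series([0, 1, 2], [0.1, -0.1, 0.2], [1, 1, 1])
        with pytest.raises(ValueError):
            growth_rate_of_segment(s, slice(0, 3))


class TestMiller:
    def test_formula_arithmetic(self):
        t = np.arange(0, 0.55, 1 / 60.0)
        od420 = 0.05 + 0.01 * (t * 60.0)  # slope 0.01 per minute
        A = miller_activity(t, od420, od600_sample=0.2)
        assert A == pytest.approx(1000 * 0.01 / (0.5 * 0.2), rel=1e-9)

    def test_zero_slope_gives_zero(self):
        t = np.arange(0, 0.6, 1 / 60.0)
        assert miller_activity(t, np.full(len(t), 0.05), 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_initial_decline_discarded(self):
        t, od420 = synth.gen_miller_kinetics(150.0, 0.2, initial_decline_min=40.0,
                                             duration_h=1.5)
        A = miller_activity(t, od420, 0.2)
        assert A == pytest.approx(150.0, rel=1e-6)

    def test_everlasting_decline_errors(self):
        t = np.arange(0, 2.0, 1 / 60.0)
        with pytest.raises(ValueError, match="decreasing"):
            miller_activity(t, 1.0 - 0.1 * t, 0.2)

    def test_promoter_activity(self):
        assert promoter_activity(100.0, 0.5) == pytest.approx(50.0)
        assert promoter_activity(123.0, 1.0) == pytest.approx(123.0)
        with pytest.raises(ValueError):
            promoter_activity(100.0, 0.0)


class TestSlidingWindows:
    def test_proportional_signal_gives_constant_ratio(self):
        t = np.linspace(0, 8, 60)
        od = 0.02 * 2 ** (0.6 * t)
        s = _series(t, od, 50.0 * od)
        est = expression_sliding_windows(s, slice(0, 60))
        assert est.y_expr == pytest.approx(math.log(50.0), abs=1e-9)
        assert est.y_se == pytest.approx(0.0, abs=1e-9)
        assert est.lam_dbl == pytest.approx(0.6, abs=1e-9)

    def test_matches_whole_segment_fit_on_noisy_balanced_growth(self, rng):
        t = np.linspace(0, 8, 80)
        od = 0.02 * 2 ** (0.5 * t) * rng.lognormal(0, 0.01, 80)
        sig = 30.0 * 0.02 * 2 ** (0.5 * t) * rng.lognormal(0, 0.02, 80)
        s = _series(t, od, sig)
        est = expression_sliding_windows(s, slice(0, 80))
        whole = float(np.mean(np.log(sig) - np.log(od)))
        se_whole = float(np.std(np.log(sig) - np.log(od), ddof=1) / math.sqrt(80))
        assert abs(est.y_expr - whole) <= se_whole

    def test_window_longer_than_segment_errors(self):
        t = np.linspace(0, 2, 10)
        s = _series(t, 0.02 * 2 ** t, np.ones(10))
        with pytest.raises(ValueError):
            expression_sliding_windows(s, slice(0, 10), w=21)


class TestPipelines:
    def test_full_bulk_recovery_of_critical_concentration(self):
        """Generator -> background -> segment -> windows -> Hill fit
        recovers the generating k within 15% at default noise."""
        conds = (synth.PlateCondition("glycerol", 0.6, (1.0, 80.0, 30.0, 2.0)),)
        series, _ = synth.gen_plate_dataset(synth.PlateGenConfig(conditions=conds, seed=7))
        rows = {}
        for s in series:
            corr = background_correct(s)
            seg = find_growth_segment(corr)
            if not seg.accepted:
                continue
            est = expression_sliding_windows(corr, seg.sl)
            rows.setdefault(s.meta["tmg_uM"], []).append(est.y_expr)
        concs = sorted(rows)
        act = np.array([np.exp(np.mean(rows[c])) for c in concs])
        fit = bulkfit.fit_hill(bulkfit.InductionCurve(
            conc=np.array(concs), activity=act, sigma=0.05 * act))
        assert fit.k == pytest.approx(30.0, rel=0.15)

    def test_miller_and_fluorimetry_concordance(self, rng):
        """Critical concentrations from the Miller path and the fluorimetry
        path agree across conditions (same rank order, r > 0.9)."""
        ks_true = [10.0, 30.0, 90.0, 250.0]
        conds = tuple(
            synth.PlateCondition(f"m{i}", 0.5 + 0.15 * i, (1.0, 60.0, k, 2.0))
            for i, k in enumerate(ks_true)
        )
        tmg = np.geomspace(1, 1000, 8)
        series, _ = synth.gen_plate_dataset(synth.PlateGenConfig(
            conditions=conds, tmg_grid=tuple(tmg), replicates=2, seed=3))
        # fluorimetry path
        k_fluor = {}
        rows = {}
        for s in series:
            corr = background_correct(s)
            seg = find_growth_segment(corr)
            if not seg.accepted:
                continue
            est = expression_sliding_windows(corr, seg.sl)
            rows.setdefault((s.meta["media"], s.meta["tmg_uM"]), []).append(est)
        for i, cond in enumerate(conds):
            concs = sorted(c for (m, c) in rows if m == cond.label)
            act = np.array([np.exp(np.mean([e.y_expr for e in rows[(cond.label, c)]]))
                            for c in concs])
            fit = bulkfit.fit_hill(bulkfit.InductionCurve(
                conc=np.array(concs), activity=act, sigma=0.05 * act))
            k_fluor[cond.label] = fit.k
        # Miller path: activity alpha = A * lambda from OD420 kinetics whose
        # slope encodes the same steady-state expression
        k_miller = {}
        for i, cond in enumerate(conds):
            b, f, k, m = cond.hill
            acts = []
            for j, c in enumerate(tmg):
                expr = float(bulkfit.hill_activity(np.array([c]), b, f, k, m)[0])
                t, od420 = synth.gen_miller_kinetics(
                    expr / cond.lam_dbl, 0.2, noise_sd=2e-4, seed=100 * i + j)
                A = miller_activity(t, od420, 0.2)
                acts.append(promoter_activity(A, cond.lam_dbl))
            acts = np.maximum(np.array(acts), 1e-6)
            fit = bulkfit.fit_hill(bulkfit.InductionCurve(
                conc=tmg, activity=acts, sigma=0.05 * acts))
            k_miller[cond.label] = fit.k
        kf = np.array([k_fluor[c.label] for c in conds])
        km = np.array([k_miller[c.label] for c in conds])
        assert list(np.argsort(kf)) == list(np.argsort(km))
        r = np.corrcoef(np.log(kf), np.log(km))[0, 1]
        assert r > 0.9

    def test_background_correction_preserves_segments_without_background(self):
        t = np.linspace(0, 14, 120)
        od = np.minimum(1e-4 * 2 ** (0.8 * t), 0.45)
        s = _series(t, od, 20.0 * od)
        before = find_growth_segment(s)
        after = find_growth_segment(background_correct(s))
        assert before.accepted == after.accepted
        assert before.sl == after.sl
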