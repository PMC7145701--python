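"""Event extraction: time zero, steps, arrivals, dwells, SNBR, survival."""

import math

import numpy as np
import pytest
from scipy import stats

from ribotrace import SimParams, simulate_field, simulate_timeline, synthesize_trace
from ribotrace.events import (StepEvent, analyze_trace,
                              binding_count_timecourse, compute_snbr,
                              detect_steps, detect_time_zero, dwell_times,
                              field_time_zero, first_arrival,
                              nonspecific_count_timecourse, survival_curve)
from ribotrace.simulate import Trace


def _ramp_trace(frame_interval=1.0, start=10.0, rise=4.0, plateau=30.0,
                n=120, noise=0.0, rng=None):
    times = np.arange(n) * frame_interval
    y = np.clip((times - start) / rise, 0, 1) * plateau
    if noise > 0:
        y = y + rng.normal(0, noise, n)
    return Trace(trace_id=0, times=times, intensities=y,
                 frame_interval=frame_interval)


class TestTimeZero:
    def test_zero_noise_ramp_is_exact_to_one_frame(self):
        tr = _ramp_trace()
        t0 = detect_time_zero(tr)
        assert abs(t0 - (10.0 + 0.9 * 4.0)) <= 1.0

    def test_noisy_ramp_within_one_frame(self, rng):
        tr = _ramp_trace(noise=1.0, rng=rng)
        t0 = detect_time_zero(tr)
        assert abs(t0 - 14.0) <= 1.5

    def test_trace_already_at_plateau_raises(self):
        times = np.arange(50.0)
        tr = Trace(trace_id=0, times=times, intensities=np.full(50, 30.0),
                   frame_interval=1.0)
        with pytest.raises(ValueError, match="no reagent delivery"):
            detect_time_zero(tr)

    def test_field_median_t0(self, rng):
        traces = [_ramp_trace(noise=1.0, rng=rng) for _ in range(9)]
        t0 = field_time_zero(traces)
        assert abs(t0 - 13.6) <= 1.5


class TestSteps:
    def test_noiseless_single_step_found_at_true_frame(self):
        y = np.zeros(100)
        y[40:] = 10.0
        tr = Trace(trace_id=0, times=np.arange(100.0), intensities=y,
                   frame_interval=1.0)
        ev = detect_steps(tr, min_amplitude_sigma=5.0, noise_sd=1.0)
        assert len(ev) == 1
        assert ev[0].direction == "up"
        assert ev[0].time == 40.0
        assert ev[0].amplitude == pytest.approx(10.0)

    def test_flat_noise_rarely_yields_events(self):
        false_runs = 0
        for s in range(1000):
            y = np.random.default_rng(s).normal(0, 1, 200)
            tr = Trace(trace_id=0, times=np.arange(200.0), intensities=y,
                       frame_interval=1.0)
            if detect_steps(tr, min_amplitude_sigma=5.0):
                false_runs += 1
        assert false_runs <= 10  # >= 99% of runs clean

    def test_simulated_traces_recover_true_events(self):
        p = SimParams(seed=17, reinit_mean=math.inf, movie_length=1500.0)
        t0 = p.start_offset + p.dead_time
        n_true = n_found = n_det = n_spur = 0
        for i in range(40):
            tl = simulate_timeline(p, i)
            tr = synthesize_trace(tl, p)
            ev = detect_steps(tr, min_amplitude_sigma=5.0, t0=t0)
            truth = sorted(
                [b + t0 for b in tl.binding_times if b + t0 < tr.times[-1]]
                + [u + t0 for u in tl.unbind_times if u + t0 < tr.times[-1]])
            det = [e.time for e in ev]
            n_true += len(truth)
            n_det += len(det)
            for t in truth:
                if any(abs(t - d) <= p.frame_interval for d in det):
                    n_found += 1
            for d in det:
                if not any(abs(t - d) <= p.frame_interval for t in truth):
                    n_spur += 1
        assert n_true > 50
        assert n_found / n_true >= 0.95
        assert n_spur <= 0.05 * n_det


class TestFirstArrival:
    def test_single_up_event(self):
        ev = [StepEvent(time=220.0, direction="up", amplitude=30.0)]
        t1, cens = first_arrival(ev, t0=100.0, movie_end=2000.0)
        assert t1 == 120.0 and not cens

    def test_no_events_is_censored_at_movie_end(self):
        t1, cens = first_arrival([], t0=100.0, movie_end=2000.0)
        assert cens and t1 == 1900.0

    def test_pre_delivery_event_raises(self):
        ev = [StepEvent(time=50.0, direction="up", amplitude=30.0)]
        with pytest.raises(ValueError, match="pre-delivery"):
            first_arrival(ev, t0=100.0, movie_end=2000.0)

    def test_simulated_t1_distribution_matches_generating_law(self):
        """First binding = initiation + tag translation + recognition; the
        simulated ensemble must follow that composite law (KS, alpha=0.01)."""
        p = SimParams(seed=23, reinit_mean=math.inf, bleach_rate=0.0)
        t1 = []
        for i in range(10_000):
            tl = simulate_timeline(p, i)
            if tl.binding_times:
                t1.append(tl.binding_times[0])
        t1 = np.array(t1)
        rng = np.random.default_rng(5)
        n = len(t1)
        ref = (p.first_init_x0 + rng.lognormal(p.first_init_mu, p.first_init_sigma, n)
               + p.exposure_delay
               + np.where(rng.random(n) < p.fast_fraction,
                          rng.exponential(p.tau_fast, n),
                          rng.exponential(p.tau_slow, n)))
        assert stats.ks_2samp(t1, ref).pvalue > 0.01


class TestDwells:
    def test_simple_pairing(self):
        ev = [StepEvent(100.0, "up", 30.0), StepEvent(334.0, "down", 30.0)]
        dw = dwell_times(ev, movie_end=2000.0)
        assert len(dw) == 1
        d = dw[0]
        assert d.duration == 234.0 and not d.censored and d.monosome

    def test_overlapping_bindings_flagged_polysome(self):
        ev = [StepEvent(100.0, "up", 30.0), StepEvent(150.0, "up", 40.0),
              StepEvent(300.0, "down", 30.0), StepEvent(400.0, "down", 40.0)]
        dw = dwell_times(ev, movie_end=2000.0)
        assert len(dw) == 2
        assert not dw[0].monosome and not dw[1].monosome

    def test_unmatched_up_censored_at_movie_end(self):
        ev = [StepEvent(1800.0, "up", 30.0)]
        dw = dwell_times(ev, movie_end=2000.0)
        assert dw[0].censored and dw[0].duration == 200.0

    def test_orphan_down_ignored_with_warning(self):
        ev = [StepEvent(100.0, "down", 30.0)]
        with pytest.warns(UserWarning, match="without a prior binding"):
            dw = dwell_times(ev, movie_end=2000.0)
        assert dw == []

    def test_event_count_conservation(self):
        p = SimParams(seed=31)
        t0 = p.start_offset + p.dead_time
        for i in range(20):
            tr = synthesize_trace(simulate_timeline(p, i), p)
            s = analyze_trace(tr, t0=t0)
            ups = sum(e.direction == "up" for e in s.events)
            downs = sum(e.direction == "down" for e in s.events)
            open_censored = sum(d.censored for d in s.dwells)
            assert ups - downs - open_censored == 0

    def test_monosome_dwell_mean_matches_decoding_time(self):
        p = SimParams(seed=37, reinit_mean=math.inf, bleach_rate=0.0,
                      movie_length=2400.0)
        t0 = p.start_offset + p.dead_time
        dwells = []
        for i in range(150):
            tr = synthesize_trace(simulate_timeline(p, i), p)
            s = analyze_trace(tr, t0=t0)
            dwells += [d.duration for d in s.dwells
                       if d.monosome and not d.censored]
        dwells = np.array(dwells)
        # dwell = decode time - recognition delay (epitope already bound)
        expected = (p.n_codons - p.tag_exposure_aa) / p.elongation_rate \
            - (p.fast_fraction * p.tau_fast + (1 - p.fast_fraction) * p.tau_slow)
        sem = dwells.std(ddof=1) / math.sqrt(len(dwells))
        assert len(dwells) >= 50
        assert abs(dwells.mean() - expected) < 3 * sem + p.frame_interval


class TestTimecourses:
    def test_no_events_gives_zero_counts(self):
        tc = binding_count_timecourse([], np.arange(10.0))
        assert np.all(tc.counts == 0)

    def test_counts_equal_cumulative_ups_minus_downs(self):
        """Bookkeeping identity: counting ground-truth up/down events frame
        by frame reproduces the true instantaneous occupancy exactly."""
        from ribotrace.events import EventSeries
        p = SimParams(seed=41, noise_sigma=0.0)
        t0 = p.start_offset + p.dead_time
        timelines = [simulate_timeline(p, i) for i in range(10)]
        times = synthesize_trace(timelines[0], p).times
        series = []
        for tl in timelines:
            events = sorted(
                [StepEvent(b + t0, "up", 1.0) for b in tl.binding_times]
                + [StepEvent(u + t0, "down", 1.0) for u in tl.unbind_times],
                key=lambda e: e.time)
            series.append(EventSeries(trace_id=tl.mrna_id, t0=t0, events=events))
        tc = binding_count_timecourse(series, times)
        truth = np.zeros(len(times), dtype=int)
        for tl in timelines:
            truth += tl.bound_count(times - t0)
        np.testing.assert_array_equal(tc.counts, truth)

    def test_nonspecific_slope_matches_rate(self):
        p = SimParams(seed=43, nonspecific_rate=0.1, movie_length=3000.0,
                      start_offset=0.0, dead_time=0.0)
        f = simulate_field(p, 0)
        times = np.arange(0, 3000.0, 2.0)
        tc = nonspecific_count_timecourse(f.nonspecific_times, times)
        slope = np.polyfit(times, tc.counts, 1)[0]
        assert slope == pytest.approx(0.1, rel=0.10)


class TestSNBR:
    def test_identical_curves_give_unity(self):
        from ribotrace.events import CountTimecourse
        t = np.arange(100.0)
        c = np.minimum(np.arange(100), 50)
        a = CountTimecourse(t, c)
        assert compute_snbr(a, CountTimecourse(t, c.copy()), 1.0) == 1.0

    def test_known_plateau_ratio_recovered(self):
        from ribotrace.events import CountTimecourse
        t = np.arange(1000.0)
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(20):
            spec = np.clip(rng.poisson(np.minimum(t / 200, 1.0) * 250), 0, None)
            nons = rng.poisson(np.full_like(t, 10.0))
            ratios.append(compute_snbr(CountTimecourse(t, spec),
                                       CountTimecourse(t, nons), 1.0))
        assert np.mean(ratios) == pytest.approx(25.0, rel=0.05)

    def test_default_conditions_give_snbr_of_at_least_20(self):
        """YE-like defaults: specific plateau >> density-corrected nonspecific."""
        from ribotrace.events import CountTimecourse
        p = SimParams(seed=47)
        f = simulate_field(p, 80)
        times = f.traces[0].times
        t0 = p.start_offset + p.dead_time
        counts = np.zeros(len(times), dtype=int)
        for tr in f.traces:
            counts += tr.truth.bound_count(times - t0)
        # nonspecific channel carries 2.3-fold more immobilized mRNA
        p_ns = p.replace(nonspecific_rate=p.nonspecific_rate * 2.3, seed=48)
        ns = simulate_field(p_ns, 0)
        tc_ns = nonspecific_count_timecourse(ns.nonspecific_times, times)
        snbr = compute_snbr(CountTimecourse(times, counts), tc_ns,
                            mrna_density_ratio=2.3)
        assert snbr >= 20.0


class TestSurvival:
    def test_no_losses_survival_stays_one(self):
        sc = survival_curve(np.full(50, 100.0), np.zeros(50, dtype=bool))
        assert np.all(sc.survival == 1.0)

    def test_exponential_losses_match_closed_form(self, rng):
        lam = 1 / 400.0
        n = 1500
        dur = rng.exponential(1 / lam, n)
        cens = dur > 1800.0
        sc = survival_curve(np.minimum(dur, 1800.0), ~cens)
        for t in (200.0, 600.0, 1200.0):
            expected = math.exp(-lam * t)
            band = 3 * math.sqrt(expected * (1 - expected) / n)
            assert abs(sc.at(t) - expected) < band

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty cohort"):
            survival_curve(np.empty(0), np.empty(0, dtype=bool))

    def test_stalled_translation_cohort_survives_90pct_at_30min(self):
        from ribotrace.pipeline import generate_fixtures
        dur, obs = generate_fixtures("stalled_survival", seed=3)
        sc = survival_curve(dur, obs)
        assert sc.at(30 * 60 - 1) == pytest.approx(0.90, abs=0.03)

    def test_survival_invariant_to_frame_interval(self, rng):
        lam, n = 1 / 500.0, 1200
        dur = rng.exponential(1 / lam, n)
        for dt in (0.5, 2.0):
            q = np.ceil(dur / dt) * dt  # frame-quantised loss times
            cens = q > 1800.0
            sc = survival_curve(np.minimum(q, 1800.0), ~cens)
            expected = math.exp(-lam * 900.0)
            band = 3 * math.sqrt(expected * (1 - expected) / n)
            assert abs(sc.at(900.0) - expected) < band
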