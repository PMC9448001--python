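import numpy as np
import pytest

import fissionlapse as fl
from fissionlapse.kinetics_events import (
    ASSUMED_ZERO,
    NOT_RECORDED,
    Event,
    EventLog,
    detect_trace_landmarks,
    event_pair_duration,
    fit_degradation_halflife,
    interval_statistics,
    score_mitotic_events,
    scored_duration,
    trough_to_division_interval,
)


def trace_from(times, values):
    times = np.asarray(times, float)
    return fl.CellTrace(1, times, np.asarray(values, float),
                        np.full(times.size, np.nan), np.zeros(times.size))


def simulated_trace(k, dt=3.0, extra=5.0):
    from fissionlapse.synthetic_data import trace_schedule
    sched = trace_schedule(k)
    end = (sched[-1]["division"] or 0) + extra if sched else 30.0
    t = np.arange(0.0, end, dt)
    return trace_from(t, fl.simulate_trace(k, t)), sched


class TestDetectTraceLandmarks:
    def test_noiseless_single_cycle_matches_schedule(self):
        k = fl.KineticParams()
        tr, sched = simulated_trace(k)
        lms = detect_trace_landmarks(tr)
        assert len(lms) == 1
        lm = lms[0]
        dt = 3.0
        assert abs(tr.times[lm["onset"]] - sched[0]["onset"]) <= dt
        assert abs(tr.times[lm["peak"]] - sched[0]["peak"]) <= dt
        assert abs(tr.times[lm["trough"]] - sched[0]["trough"]) <= dt
        assert lm["baseline"] == pytest.approx(k.baseline)

    def test_flat_trace_yields_no_landmarks(self):
        tr = trace_from(np.arange(10) * 3.0, np.full(10, 5.0))
        assert detect_trace_landmarks(tr) == []

    def test_two_cycles_detected_in_order(self):
        # measured inter-division spacing (~37 min) leaves a baseline gap
        # of a few 3-min frames between the cycles
        k = fl.KineticParams(n_divisions=2, inter_division_interval=37.0)
        tr, sched = simulated_trace(k)
        lms = detect_trace_landmarks(tr)
        assert len(lms) == 2
        assert lms[0]["trough"] < lms[1]["onset"] <= lms[1]["peak"]


class TestFitDegradationHalflife:
    @pytest.mark.parametrize("h", [0.7, 2.0, 3.0, 5.0])
    def test_exact_on_noiseless_exponential(self, h):
        t = np.arange(0.0, 6 * h, 1.5)
        y = 10.0 + 100.0 * np.exp2(-t / h)
        fit = fit_degradation_halflife(trace_from(t, y), 0, t.size - 1,
                                       baseline=10.0)
        assert fit.halflife == pytest.approx(h, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_spec_example_three_minute_frames(self):
        t = np.arange(0.0, 13.0, 3.0)
        y = 5.0 + 100.0 * np.exp2(-t / 3.0)
        fit = fit_degradation_halflife(trace_from(t, y), 0, t.size - 1,
                                       baseline=5.0)
        assert fit.halflife == pytest.approx(3.0, rel=1e-9)

    def test_noisy_recovery_within_20_percent(self):
        rng = np.random.default_rng(55)
        for h in (2.0, 3.0, 5.0):
            ests = []
            for _ in range(15):
                t = np.arange(0.0, 12.01, 3.0)
                y = 10.0 + 1000.0 * np.exp2(-t / h)
                y = y * (1 + 0.05 * rng.standard_normal(t.size))
                fit = fit_degradation_halflife(trace_from(t, y), 0,
                                               t.size - 1, baseline=10.0)
                ests.append(fit.halflife)
            assert np.mean(ests) == pytest.approx(h, rel=0.20)

    def test_single_decay_point_rejected(self):
        t = np.array([0.0, 3.0, 6.0])
        y = np.array([100.0, 10.0, 10.0])
        with pytest.raises(ValueError, match="fewer than two"):
            fit_degradation_halflife(trace_from(t, y), 0, 2, baseline=10.0)

    def test_rising_segment_rejected(self):
        t = np.arange(5.0)
        y = 10.0 + np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        with pytest.raises(ValueError, match="slope"):
            fit_degradation_halflife(trace_from(t, y), 0, 4, baseline=10.0)


class TestIntervals:
    def test_trough_to_division_direct(self):
        assert trough_to_division_interval(40, 41, 3.0) == 3.0
        assert trough_to_division_interval(40, 40, 3.0) == 0.0
        assert trough_to_division_interval(41, 40, 3.0) == -3.0

    def test_scored_duration(self):
        assert scored_duration(10, 12, 3.0) == 6.0
        assert scored_duration(7, 7, 3.0) == 0.0
        with pytest.raises(ValueError):
            scored_duration(12, 10, 3.0)

    def test_quantized_scoring_cohort_recovers_lag(self):
        # trough/division frames quantized from continuous times still give
        # the configured lag on average, within one frame interval
        rng = np.random.default_rng(2)
        dt, lag = 3.0, 1.2
        vals = []
        for _ in range(500):
            trough_t = rng.uniform(30, 60)
            f_trough = int(np.ceil(trough_t / dt))
            f_div = int(np.ceil((trough_t + lag) / dt))
            vals.append(trough_to_division_interval(f_trough, f_div, dt))
        assert abs(np.mean(vals) - lag) <= dt


class TestIntervalStatistics:
    @staticmethod
    def _log(frames, frame_interval=3.0, cell_id=1):
        events = [Event(t, 0, f) for t, f in frames.items()]
        return EventLog(cell_id=cell_id, events=events,
                        frame_interval=frame_interval)

    def test_constant_durations(self):
        logs = [self._log({"SP": 10, "SPB": 11}) for _ in range(3)]
        st = interval_statistics(logs, "SP1->SP1B")
        assert (st.mean, st.sd, st.n) == (3.0, 0.0, 3)

    def test_no_qualifying_cells_is_nd(self):
        log = EventLog(1, [Event("SP", 0, None, NOT_RECORDED),
                           Event("SPB", 0, None, NOT_RECORDED)], 3.0)
        st = interval_statistics([log], "SP1->SP1B")
        assert st.is_nd
        assert "ND" in str(st)

    def test_assumed_zero_duration_counts_as_zero(self):
        censored = EventLog(1, [Event("PS", 0, 5),
                                Event("SP", 0, None, ASSUMED_ZERO),
                                Event("SPB", 0, None, NOT_RECORDED)], 3.0)
        observed = self._log({"SP": 10, "SPB": 12})
        st = interval_statistics([censored, observed], "SP1->SP1B")
        assert st.n == 2
        assert st.mean == pytest.approx(3.0)  # (0 + 6) / 2

    def test_duration_scoring_unbiased_under_uniform_phase(self):
        # brute-force phase-sampling oracle: expected tick count in a
        # length-L window on a dt grid is L/dt
        rng = np.random.default_rng(6)
        L, dt = 4.0, 3.0
        durs = []
        for ph in rng.uniform(0, dt, 5000):
            f_a = int(np.ceil(ph / dt))
            f_b = int(np.ceil((ph + L) / dt))
            durs.append(scored_duration(f_a, f_b, dt))
        assert np.mean(durs) == pytest.approx(L, rel=0.02)

    def test_translation_invariance_of_duration(self):
        assert scored_duration(100, 104, 3.0) == scored_duration(0, 4, 3.0)


class TestScoreMitoticEvents:
    def test_wildtype_events_within_one_frame(self, wildtype_eb1_run):
        run = wildtype_eb1_run
        log, truth = run["log"], run["truth"]
        for name in ("PS", "SP", "SPB", "CF"):
            ev = log.get(name, 0)
            assert ev is not None and ev.censoring_flag == "observed"
            assert abs(ev.frame - truth.event_frame(0, name)) <= 1

    def test_event_order_in_log(self, wildtype_eb1_run):
        log = wildtype_eb1_run["log"]
        frames = [log.get(n, 0).frame for n in ("PS", "SP", "SPB", "CF")]
        assert frames == sorted(frames)

    def test_apc_mutant_persistent_spindle(self):
        scene, k = fl.make_preset_config("apc_mutant", reporter="eb1")
        movie, truth = fl.simulate_movie(scene, k, seed=31, frame_interval=1.0)
        unmixed, _ = fl.unmix_movie(movie)
        g = np.asarray(unmixed.channel("reporter"))
        r = np.asarray(movie.channel("reference"))
        masks = [fl.build_mask_set(g[i], r[i]) for i in range(movie.n_frames)]
        log = score_mitotic_events(unmixed, masks)
        assert log.get("SP", 0).censoring_flag == "observed"
        assert log.get("SPB", 0).censoring_flag == NOT_RECORDED
        assert log.get("CF", 0).censoring_flag == NOT_RECORDED

    def test_cycb1_mutant_no_events(self):
        scene, k = fl.make_preset_config("cycb1_mutant", reporter="eb1")
        movie, _ = fl.simulate_movie(scene, k, seed=32, frame_interval=1.0)
        unmixed, _ = fl.unmix_movie(movie)
        g = np.asarray(unmixed.channel("reporter"))
        r = np.asarray(movie.channel("reference"))
        masks = [fl.build_mask_set(g[i], r[i]) for i in range(movie.n_frames)]
        log = score_mitotic_events(unmixed, masks)
        assert all(ev.censoring_flag == NOT_RECORDED for ev in log.events)
        assert all(ev.frame is None for ev in log.events)


class TestEventPairDuration:
    def test_not_recorded_cell_excluded(self):
        log = EventLog(1, [Event("PS", 0, None, NOT_RECORDED),
                           Event("SP", 0, None, NOT_RECORDED)], 3.0)
        assert event_pair_duration(log, "PS->SP1") is None

    def test_pair_label_parsing(self):
        log = EventLog(1, [Event("SP", 1, 20), Event("SPB", 1, 22),
                           Event("CF", 1, 23)], 3.0)
        assert event_pair_duration(log, "SP2->SP2B") == 6.0
        assert event_pair_duration(log, "SP2B->CF2") == 3.0
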