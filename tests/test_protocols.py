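"""Minimum-elastance titration loop, apnoea and kink detection."""

import numpy as np
import pytest

from ventloop.protocols import (
    SimulatedVentilator,
    TitrationConfig,
    TitrationState,
    _argmin_setting,
    detect_apnoea,
    detect_kink,
    run_titration,
    titration_cycle,
)
from ventloop.sensing import FlowStream
from ventloop.simulator import LungParams, VentSettings


def parabola_lung(p_star, e_min=20.0, curvature=0.5, resistance=5.0):
    return LungParams(elastance=lambda p: e_min + curvature * (p - p_star) ** 2,
                      resistance=resistance)


def sim_vent(lung, seed=0, noise_sd=0.0, bits=None, fs=160.0):
    return SimulatedVentilator(lung, VentSettings(peep=5.0, rate=15.0),
                               fs=fs, seed=seed, noise_sd=noise_sd,
                               quantization_bits=bits)


class TestArgmin:
    def test_plain_argmin(self):
        emap = {8: 30.0, 9: 26.0, 10: 24.0, 11: 27.0, 12: 31.0}
        assert _argmin_setting(emap, centre=10) == 10

    def test_flat_map_stays_at_centre(self):
        emap = {8: 24.0, 9: 24.0, 10: 24.0, 11: 24.0, 12: 24.0}
        assert _argmin_setting(emap, centre=10) == 10

    def test_tie_breaks_toward_centre_then_lower(self):
        assert _argmin_setting({8: 24.0, 12: 24.0, 10: 25.0}, centre=11) == 12
        assert _argmin_setting({9: 24.0, 11: 24.0, 10: 25.0}, centre=10) == 9


class TestTitrationGrid:
    def test_ascending_grid(self):
        cfg = TitrationConfig()
        assert cfg.grid(10.0) == [8.0, 9.0, 10.0, 11.0, 12.0]

    def test_grid_clamps_to_safety_bounds(self):
        cfg = TitrationConfig(pressure_bounds=(5.0, 30.0))
        assert cfg.grid(6.0) == [5.0, 6.0, 7.0, 8.0]
        assert cfg.grid(30.0) == [28.0, 29.0, 30.0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TitrationConfig(grid_step=3.0, query_halfwidth=2.0)
        with pytest.raises(ValueError):
            TitrationConfig(breaths_per_setting=0)


class TestTitrationNoiseFree:
    def test_known_parabola_trace(self):
        # E(p) = 20 + 0.5 (p-12)^2 starting at 8: centre 8 -> 10 -> 12,
        # then two confirming cycles
        res = run_titration(sim_vent(parabola_lung(12.0)), TitrationConfig(), 8.0)
        centres = [rec.centre for rec in res.trajectory]
        moves = [rec.new_centre for rec in res.trajectory]
        assert centres == [8.0, 10.0, 12.0, 12.0]
        assert moves == [10.0, 12.0, 12.0, 12.0]
        assert res.converged and res.centre == 12.0

    def test_start_at_optimum_never_moves(self):
        res = run_titration(sim_vent(parabola_lung(12.0)), TitrationConfig(), 12.0)
        assert res.converged
        assert res.cycles_used == TitrationConfig().convergence_k
        assert all(rec.new_centre == 12.0 for rec in res.trajectory)

    @pytest.mark.parametrize("p_star", [10.0, 12.0, 14.0])
    @pytest.mark.parametrize("offset", [-4.0, -1.0, 3.0])
    def test_unimodal_map_reaches_argmin(self, p_star, offset):
        res = run_titration(sim_vent(parabola_lung(p_star)),
                            TitrationConfig(max_cycles=12), p_star + offset)
        assert res.converged
        assert abs(res.centre - p_star) <= TitrationConfig().grid_step

    def test_centre_moves_at_most_halfwidth_per_cycle(self):
        cfg = TitrationConfig()
        res = run_titration(sim_vent(parabola_lung(14.0)), cfg, 6.0)
        for rec in res.trajectory:
            assert abs(rec.new_centre - rec.centre) <= cfg.query_halfwidth

    def test_monotone_decreasing_map_walks_to_bound(self):
        lung = LungParams(elastance=lambda p: 60.0 - p, resistance=5.0)
        cfg = TitrationConfig(pressure_bounds=(5.0, 20.0), max_cycles=12)
        res = run_titration(sim_vent(lung), cfg, 10.0)
        assert res.centre == 20.0
        assert res.at_pressure_bound  # parked on the edge, not an interior optimum


class _RecordingVent:
    """Fake ventilator: remembers the commanded setting for the estimator."""

    def __init__(self):
        self.p_set = None
        self.n_breaths = None

    def hold(self, p_set, n_breaths):
        self.p_set = p_set
        self.n_breaths = n_breaths
        return None


class TestTitrationNoisy:
    def test_more_breaths_per_setting_reduce_wrong_argmin(self):
        # Monte-Carlo at fixed seeds: per-breath estimate noise sd 1.0 on a
        # parabola whose adjacent grid settings differ by only 0.5 cmH2O/L;
        # a longer dwell (median of more breaths) must not mis-pick more often
        def wrong_rate(dwell, reps=60):
            rng = np.random.default_rng(99)
            vent = _RecordingVent()

            def estimator(_frames):
                e_true = 20.0 + 0.5 * (vent.p_set - 12.0) ** 2
                return float(np.median(e_true + rng.normal(0, 1.0, vent.n_breaths)))

            wrong = 0
            for _ in range(reps):
                cfg = TitrationConfig(breaths_per_setting=dwell, max_cycles=1,
                                      convergence_k=1)
                state = TitrationState(centre=12.0)
                titration_cycle(state, cfg, vent, estimator=estimator)
                wrong += state.centre != 12.0
            return wrong

        assert wrong_rate(9) < wrong_rate(3) < wrong_rate(1)


def flow_stream(q, p=None, fs=160.0):
    n = len(q)
    t = np.arange(n) * 1000.0 / fs
    return FlowStream(t, np.asarray(q, float),
                      np.zeros(n) if p is None else np.asarray(p, float))


class TestApnoea:
    def test_zero_flow_events_every_window(self):
        flow = flow_stream(np.zeros(int(30 * 160) + 1))
        events = detect_apnoea(flow, window_s=10.0)
        assert [e.raised_at_ms for e in events] == [10000.0, 20000.0, 30000.0]
        assert events[0].window_start_ms == 0.0

    def test_continuous_breathing_no_events(self, flow_factory):
        flow, _ = flow_factory(duration_s=60.0)
        assert detect_apnoea(flow, window_s=10.0) == []

    def test_event_exactly_one_window_after_last_onset(self, flow_factory):
        flow, _ = flow_factory(duration_s=20.0)
        # breathing stops: append 15 s of zero flow
        n_tail = 15 * 160
        t_tail = flow.t_ms[-1] + (np.arange(n_tail) + 1) * 6.25
        flow2 = FlowStream(np.concatenate([flow.t_ms, t_tail]),
                           np.concatenate([flow.q_lpm, np.zeros(n_tail)]),
                           np.concatenate([flow.p_gauge, np.zeros(n_tail)]))
        from ventloop.breaths import segment_breaths

        last_onset = flow2.t_ms[segment_breaths(flow2)[-1]]
        events = detect_apnoea(flow2, window_s=10.0)
        assert len(events) >= 1
        assert events[0].raised_at_ms == pytest.approx(last_onset + 10000.0)

    def test_no_false_events_when_gaps_below_window(self, flow_factory):
        # property: any stream whose inter-onset gaps are all < window is clean
        flow, _ = flow_factory(duration_s=45.0)
        from ventloop.breaths import segment_breaths

        gaps = np.diff([flow.t_ms[i] for i in segment_breaths(flow)])
        assert np.all(gaps < 10000.0)
        assert detect_apnoea(flow, window_s=10.0) == []


class TestKink:
    vent = VentSettings(p_set=10.0, peep=5.0, rate=15.0)

    def test_total_occlusion_raises_after_hold(self):
        # pressure pinned at command, zero flow: the inspiratory phase
        # (1.33 s > 1 s hold) triggers each breath
        n = int(8 * 160)
        flow = flow_stream(np.zeros(n), p=np.full(n, 15.0))
        events = detect_kink(flow, self.vent)
        assert len(events) == 2
        assert events[0].start_ms == 0.0

    def test_normal_breathing_no_events(self, flow_factory):
        flow, _ = flow_factory(duration_s=20.0)
        assert detect_kink(flow, self.vent) == []

    def test_high_resistance_with_flow_is_not_a_kink(self, flow_factory):
        flow, _ = flow_factory(lung=LungParams(elastance=20.0, resistance=10.0),
                               duration_s=20.0)
        assert detect_kink(flow, self.vent) == []
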