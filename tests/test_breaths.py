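"""Breath segmentation, volume integration and elastance estimation."""

import numpy as np
import pytest

from ventloop.breaths import (
    Breath,
    elastance_least_squares,
    elastance_of_breath,
    extract_breaths,
    integrate_volume,
    segment_breaths,
)
from ventloop.sensing import FlowStream
from ventloop.simulator import LungParams, VentSettings


def flow_stream(q_lpm, fs=160.0, p=None):
    n = len(q_lpm)
    t = np.arange(n) * 1000.0 / fs
    p = p if p is not None else np.zeros(n)
    return FlowStream(t, np.asarray(q_lpm, float), np.asarray(p, float))


class TestIntegrateVolume:
    def test_constant_flow_rectangle(self):
        # 60 L/min for 1 s integrates to exactly 1 L
        flow = flow_stream(np.full(161, 60.0))
        integrate_volume(flow, [0])
        assert flow.v_l[160] == pytest.approx(1.0, rel=1e-12)

    def test_half_sine_matches_analytic_integral(self):
        # integral of Q0*sin(pi t/T) over [0,T] = (2/pi) Q0 T / 60 litres
        fs, T, Q0 = 160.0, 2.0, 90.0
        n = int(T * fs) + 1
        t = np.arange(n) / fs
        flow = flow_stream(Q0 * np.sin(np.pi * t / T))
        integrate_volume(flow, [0])
        expected = (2 / np.pi) * Q0 * T / 60.0
        assert flow.v_l[-1] == pytest.approx(expected, rel=1e-3)

    def test_zero_flow_zero_volume(self):
        flow = flow_stream(np.zeros(100))
        integrate_volume(flow, [0])
        assert np.all(flow.v_l == 0.0)

    def test_non_monotone_time_rejected(self):
        flow = flow_stream(np.zeros(10))
        flow.t_ms = flow.t_ms[::-1].copy()
        with pytest.raises(ValueError):
            integrate_volume(flow, [0])

    def test_volume_resets_at_each_onset(self):
        flow = flow_stream(np.full(100, 60.0))
        integrate_volume(flow, [0, 50])
        assert flow.v_l[50] == 0.0
        assert flow.breath_idx[49] == 0 and flow.breath_idx[50] == 1


class TestSegmentBreaths:
    def test_known_breath_rate(self, flow_factory):
        flow, _ = flow_factory(duration_s=60.0)
        onsets = segment_breaths(flow)
        assert abs(len(onsets) - 15) <= 1

    def test_all_zero_flow_no_onsets(self):
        assert segment_breaths(flow_stream(np.zeros(1000))) == []

    def test_subthreshold_noise_no_onsets(self):
        # flow-domain noise sd 0.5 L/min against a 2 L/min threshold with
        # 100 ms debounce: no spurious onsets
        rng = np.random.default_rng(3)
        flow = flow_stream(rng.normal(0, 0.5, 16000))
        assert segment_breaths(flow) == []


class TestElastance:
    def test_direct_quotient(self):
        b = Breath(index=0, onset_ms=0, offset_ms=4000,
                   p_inhale=np.array([5.0, 15.0]), v_inhale=np.array([0.0, 0.5]),
                   tidal_volume=0.5, dp_inhale=10.0, dv_inhale=0.5,
                   elastance=20.0, valid=True)
        assert elastance_of_breath(b) == 20.0

    def test_invalid_breath_raises(self):
        b = Breath(index=0, onset_ms=0, offset_ms=4000,
                   p_inhale=np.array([5.0]), v_inhale=np.array([0.0]),
                   tidal_volume=0.0, dp_inhale=10.0, dv_inhale=0.0,
                   elastance=float("nan"), valid=False,
                   invalid_reason="non-positive inhaled volume")
        with pytest.raises(ValueError):
            elastance_of_breath(b)

    @pytest.mark.parametrize("e_true", [10.0, 20.0, 30.0, 40.0])
    @pytest.mark.parametrize("r_true", [2.0, 5.0, 10.0])
    def test_noise_free_recovery_grid(self, flow_factory, e_true, r_true):
        # plateaued square breaths, noise off: endpoint quotient within 2%
        lung = LungParams(elastance=e_true, resistance=r_true)
        vent = VentSettings(p_set=10.0, peep=5.0, rate=5.0, i_fraction=0.5)
        flow, _ = flow_factory(lung=lung, vent=vent, duration_s=48.0)
        est = [b.elastance for b in extract_breaths(flow) if b.valid]
        assert len(est) >= 2
        assert np.mean(est) == pytest.approx(e_true, rel=0.02)

    def test_gauge_offset_cancels(self, flow_factory):
        flow, _ = flow_factory(duration_s=20.0)
        est0 = [b.elastance for b in extract_breaths(flow) if b.valid]
        flow2 = FlowStream(flow.t_ms.copy(), flow.q_lpm.copy(),
                           flow.p_gauge + 7.3)
        est1 = [b.elastance for b in extract_breaths(flow2) if b.valid]
        assert np.allclose(est0, est1)

    def test_shallow_breath_flagged(self):
        # 8 L/min for 0.3 s inhales only 0.04 L, under the 0.05 L floor
        q = np.zeros(600)
        q[100:148] = 8.0
        breaths = extract_breaths(flow_stream(q))
        assert len(breaths) == 1 and not breaths[0].valid
        assert "tidal volume" in breaths[0].invalid_reason

    def test_short_breath_flagged(self):
        # a burst right at the end of the stream: breath lasts < 0.5 s
        q = np.zeros(600)
        q[550:] = 60.0
        breaths = extract_breaths(flow_stream(q))
        assert len(breaths) == 1 and not breaths[0].valid
        assert "duration" in breaths[0].invalid_reason

    def test_least_squares_variant_on_linear_loop(self):
        p = np.linspace(5.0, 15.0, 50)
        v = (p - 5.0) / 25.0  # slope 1/25 L per cmH2O -> E = 25
        assert elastance_least_squares(p, v) == pytest.approx(25.0, rel=1e-9)


def test_tidal_volumes_sum_to_total_inspired_volume(flow_factory):
    flow, _ = flow_factory(duration_s=40.0)
    onsets = segment_breaths(flow)
    breaths = extract_breaths(flow, onsets=onsets)
    # total inspired volume between first and last onset
    t_s = flow.t_ms / 1000.0
    q_in = np.maximum(flow.q_lpm, 0.0) / 60.0
    i0, i1 = onsets[0], onsets[-1]
    total = np.trapezoid(q_in[i0:i1 + 1], t_s[i0:i1 + 1])
    tidal_sum = sum(b.tidal_volume for b in breaths[:-1])
    assert tidal_sum == pytest.approx(total, rel=0.02)


def test_estimate_sd_shrinks_with_median_aggregation(flow_factory):
    # with default sensor noise, medians of n breaths spread ~1/sqrt(n)
    lung = LungParams(elastance=20.0, resistance=5.0)
    vent = VentSettings(p_set=10.0, peep=5.0, rate=15.0)
    singles, medians9 = [], []
    for seed in range(12):
        flow, _ = flow_factory(lung=lung, vent=vent, duration_s=40.0, seed=seed,
                               noise_sd=0.05, quantization_bits=12)
        est = np.array([b.elastance for b in extract_breaths(flow) if b.valid])
        singles.extend(est[:9])
        medians9.append(np.median(est[:9]))
    ratio = np.std(medians9) / np.std(singles)
    # median of 9 ~ 1.25/sqrt(9) = 0.42 of the single-breath sd
    assert ratio < 0.7
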