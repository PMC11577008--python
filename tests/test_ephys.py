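"""Spike detection, z-score classification and intrinsic-property tests."""

import math

import numpy as np
import pytest

from satglia import ephys, simulate
from satglia.ephys import (
    CurrentStep,
    TrialRaster,
    VoltageTrace,
    ZeroBaselineError,
    bin_rates,
    classify_offset,
    classify_response,
    detect_spikes,
    estimate_onset_latency,
    extract_intrinsic_properties,
    zscore_response,
)

FS = 20_000.0


def make_raster(trials, onset=2.0, duration=0.5, T=4.0):
    return TrialRaster(neuron_id="t", trials=tuple(np.asarray(t, float)
                                                   for t in trials),
                       light_onset=onset, light_duration=duration,
                       trial_duration=T)


class TestDetectSpikes:
    def test_sine_crossings(self):
        t = np.arange(0, 0.3, 1 / FS)
        trace = VoltageTrace(FS, 20.0 * np.sin(2 * math.pi * 10 * t))
        assert detect_spikes(trace).size == 3

    def test_subthreshold_trace_has_no_spikes(self):
        trace = VoltageTrace(FS, np.full(1000, -60.0))
        assert detect_spikes(trace).size == 0

    def test_recovers_programmed_times_within_one_sample(self):
        cfg = simulate.TraceConfig(spont_rate_hz=5.0)
        traces = simulate.generate_current_step_traces(cfg)
        rest = next(t for t in traces if t.step.amplitude_pa == 0)
        times = detect_spikes(rest)
        expected = np.arange(0.1, rest.duration - 0.05, 0.2)
        assert times.size == expected.size
        # spikes cross 0 mV partway up the template rise
        assert np.all(np.abs(times - expected) < 0.002)


class TestBinRates:
    def test_two_spikes_in_a_bin_is_20_hz(self):
        raster = make_raster([[2.01, 2.05]])
        rates, starts = bin_rates(raster)
        i = np.argmin(np.abs(starts - 2.0))
        assert rates[0, i] == pytest.approx(20.0)

    def test_empty_trial_all_zero(self):
        rates, _ = bin_rates(make_raster([[]]))
        assert not rates.any()

    def test_total_count_conserved(self):
        rng = np.random.default_rng(5)
        trials = [np.sort(rng.uniform(0, 4.0, rng.integers(5, 30)))
                  for _ in range(6)]
        raster = make_raster(trials)
        rates, _ = bin_rates(raster)
        assert rates.sum() * 0.1 == pytest.approx(
            sum(len(t) for t in trials))


class TestZScore:
    def test_flat_rates_give_zero_z(self):
        # identical light-epoch and baseline means -> z = 0
        trials = [np.arange(0.05, 4.0, 0.25)] * 4  # 4 Hz regular
        # perturb one baseline spike so the baseline SD is nonzero
        t0 = trials[0].copy()
        t0[2] += 0.06
        z, _, _, _ = zscore_response(make_raster([t0] + trials[1:]))
        assert abs(z) < 0.5

    def test_arithmetic_example(self):
        # baseline bins mean 5 Hz / SD 2 Hz, light bins mean 9 Hz -> z = 2
        rates = np.array([5.0] * 10 + [9.0] * 5)
        mu, sd = rates[:10].mean(), 2.0
        assert (rates[10:].mean() - mu) / sd == pytest.approx(2.0)

    def test_silent_baseline_raises(self):
        with pytest.raises(ZeroBaselineError):
            zscore_response(make_raster([[]] * 3))

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(8)
        trials = [np.sort(rng.uniform(0, 4.0, 20)) for _ in range(10)]
        z1, *_ = zscore_response(make_raster(trials))
        z2, *_ = zscore_response(make_raster(trials[::-1]))
        assert z1 == pytest.approx(z2)


class TestClassification:
    @pytest.mark.parametrize("z,expected", [
        (0.7, "excited"), (-0.7, "inhibited"), (0.5, "non-responder"),
        (-0.5, "non-responder"), (0.0, "non-responder")])
    def test_onset_thresholds_strict(self, z, expected):
        assert classify_response(z) == expected

    @pytest.mark.parametrize("z,expected", [
        (-1.2, "inhibited"), (0.0, "none"), (-0.5, "none")])
    def test_offset_threshold_strict(self, z, expected):
        assert classify_offset(z) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_response(float("nan"))

    def test_programmed_effects_recovered_across_seeds(self):
        """Rate doubling / quartering is classified correctly in >=95 of
        100 seeded simulated neurons."""
        ok_exc = ok_inh = 0
        for seed in range(100):
            exc = simulate.generate_spike_trains(
                simulate.SpikeTrainConfig(light_multiplier=2.0), seed=seed)
            inh = simulate.generate_spike_trains(
                simulate.SpikeTrainConfig(light_multiplier=0.25),
                seed=10_000 + seed)
            ok_exc += ephys.analyze_raster(exc).class_onset == "excited"
            ok_inh += ephys.analyze_raster(inh).class_onset == "inhibited"
        assert ok_exc >= 95
        assert ok_inh >= 95

    def test_false_response_rate_at_null(self):
        """With no programmed effect the true false-call rate stays near or
        below 10%; tested with a 2-SE binomial allowance at n=400."""
        false_calls = 0
        n = 400
        for seed in range(n):
            r = simulate.generate_spike_trains(
                simulate.SpikeTrainConfig(light_multiplier=1.0),
                seed=40_000 + seed)
            if ephys.analyze_raster(r).class_onset != "non-responder":
                false_calls += 1
        assert false_calls / n <= 0.10 + 2 * math.sqrt(0.1 * 0.9 / n)


class TestOnsetLatency:
    def test_step_at_3_ms(self):
        v = np.full(int(0.4 * FS), -60.0)
        i = int(0.2 * FS) + int(0.003 * FS)
        v[i:] = -50.0
        lat = estimate_onset_latency(VoltageTrace(FS, v), 0.2)
        assert lat == pytest.approx(3.0, abs=0.1)

    def test_flat_trace_has_no_onset(self):
        v = np.full(int(0.4 * FS), -60.0)
        assert estimate_onset_latency(VoltageTrace(FS, v), 0.2) is None

    @pytest.mark.parametrize("true_ms", [1.0, 4.0, 10.0])
    def test_recovered_within_1_ms_under_noise(self, true_ms):
        rng = np.random.default_rng(int(true_ms * 10))
        v = np.full(int(0.5 * FS), -60.0) + rng.normal(0, 0.5, int(0.5 * FS))
        i = int(0.2 * FS) + int(true_ms / 1000 * FS)
        v[i:] += 10.0
        lat = estimate_onset_latency(VoltageTrace(FS, v), 0.2)
        assert lat == pytest.approx(true_ms, abs=1.0)


@pytest.fixture(scope="module")
def noiseless_props():
    cfg = simulate.TraceConfig()
    traces = simulate.generate_current_step_traces(cfg)
    return cfg, extract_intrinsic_properties(traces)


class TestIntrinsicProperties:

    def test_exact_recovery_on_noiseless_traces(self, noiseless_props):
        cfg, props = noiseless_props
        assert props.input_resistance_mohm == pytest.approx(cfg.rin_mohm,
                                                            rel=1e-6)
        assert props.sag_ratio == pytest.approx(cfg.sag_fraction, rel=1e-6)
        assert props.ap_threshold_mv == pytest.approx(cfg.ap_threshold_mv,
                                                      abs=1e-9)
        assert props.ap_amplitude_mv == pytest.approx(cfg.ap_amplitude_mv,
                                                      abs=1e-9)
        assert props.ap_halfwidth_ms == pytest.approx(cfg.ap_halfwidth_ms,
                                                      abs=1e-6)
        assert props.ahp_amplitude_mv == pytest.approx(cfg.ahp_mv, abs=1e-9)
        assert props.adaptation_index == pytest.approx(1.5, rel=1e-9)
        assert props.missing == ()

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_recovery_within_5_pct_under_noise(self, seed):
        cfg = simulate.TraceConfig(noise_sd_mv=0.5)
        props = extract_intrinsic_properties(
            simulate.generate_current_step_traces(cfg, seed=seed))
        assert props.input_resistance_mohm == pytest.approx(cfg.rin_mohm,
                                                            rel=0.05)
        assert props.sag_ratio == pytest.approx(cfg.sag_fraction, rel=0.05)
        assert props.ap_threshold_mv == pytest.approx(cfg.ap_threshold_mv,
                                                      rel=0.05)
        assert props.ap_amplitude_mv == pytest.approx(cfg.ap_amplitude_mv,
                                                      rel=0.05)
        assert props.ap_halfwidth_ms == pytest.approx(cfg.ap_halfwidth_ms,
                                                      rel=0.05)
        assert props.ahp_amplitude_mv == pytest.approx(cfg.ahp_mv, rel=0.05)
        assert props.adaptation_index == pytest.approx(1.5, rel=0.05)

    def test_hand_built_sag_example(self):
        # trough -80, steady -75 from a -60 baseline -> sag 15/20 = 0.75
        n_pre, n_step = int(0.2 * FS), int(0.75 * FS)
        v = np.full(n_pre + n_step + 1000, -60.0)
        t = np.arange(n_step) / FS
        v[n_pre:n_pre + n_step] = -75.0 - 5.0 * np.exp(-t / 0.03)
        tr = VoltageTrace(FS, v, step=CurrentStep(-200.0, 0.2, 0.75))
        props = extract_intrinsic_properties([tr])
        assert props.sag_ratio == pytest.approx(0.75, abs=1e-3)

    def test_missing_protocol_steps_flagged(self):
        cfg = simulate.TraceConfig()
        traces = simulate.generate_current_step_traces(
            cfg, amplitudes_pa=(-100.0, -50.0))
        props = extract_intrinsic_properties(traces)
        assert props.input_resistance_mohm is not None
        assert "sag_ratio" in props.missing
        assert "adaptation_index" in props.missing
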