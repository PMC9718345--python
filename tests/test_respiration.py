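"""Cycle extraction: extrema detection, segmentation, summaries, integration."""

import numpy as np
import pytest

from thermoresp import (BreathingProfile, NoRespirationError, RespCycle,
                        SampledTrace, SensorModel, detect_extrema,
                        integrate_chest_movement, segment_cycles, summarize)
from thermoresp.respiration import Extrema, anchor_times

from .conftest import make_session, random_smooth_trace
from .oracles import brute_force_extrema


class TestDetectExtrema:
    def test_sine_extrema_at_analytic_times(self):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        trace = SampledTrace(np.sin(2 * np.pi * 0.5 * t), fs=fs)
        ex = detect_extrema(trace)
        peaks = ex.of_kind("peak")
        troughs = ex.of_kind("trough")
        for p in peaks:
            assert abs((p - 0.5) % 2.0) < 0.011 or abs((p - 0.5) % 2.0 - 2.0) < 0.011
        for q in troughs:
            assert abs((q - 1.5) % 2.0) < 0.011 or abs((q - 1.5) % 2.0 - 2.0) < 0.011
        assert len(peaks) == 10 and len(troughs) == 10

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(400, 2000))
            trace = random_smooth_trace(rng, n=n)
            try:
                fast = detect_extrema(trace)
            except NoRespirationError:
                with pytest.raises(NoRespirationError):
                    brute_force_extrema(trace)
                continue
            slow = brute_force_extrema(trace)
            np.testing.assert_array_equal(fast.kinds, slow.kinds)
            np.testing.assert_allclose(fast.times, slow.times, atol=1e-12)

    def test_constant_trace_raises(self):
        trace = SampledTrace(np.full(1000, 2.5), fs=100.0)
        with pytest.raises(NoRespirationError):
            detect_extrema(trace)

    def test_too_short_trace_rejected(self):
        trace = SampledTrace(np.sin(np.arange(100) / 5), fs=100.0)
        with pytest.raises(ValueError, match="refractory"):
            detect_extrema(trace)

    def test_alternation_always_holds(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            trace = random_smooth_trace(rng, n=1200)
            try:
                ex = detect_extrema(trace)
            except NoRespirationError:
                continue
            assert np.all(ex.kinds[1:] != ex.kinds[:-1])
            assert np.all(np.diff(ex.times) > 0)


class TestSegmentCycles:
    def _extrema(self, times, kinds):
        return Extrema(times=np.asarray(times, float), kinds=np.asarray(kinds))

    def test_temperature_convention(self):
        ex = self._extrema([1.0, 2.0, 3.0], ["peak", "trough", "peak"])
        (cyc,) = segment_cycles(ex, "temperature")
        assert cyc.insp_start == 1.0 and cyc.exp_start == 2.0
        assert cyc.insp_duration == 1.0 and cyc.exp_duration == 1.0

    def test_chest_convention_swaps_phases(self):
        ex = self._extrema([1.0, 2.0, 3.0, 4.0],
                           ["peak", "trough", "peak", "trough"])
        (t_cyc,) = segment_cycles(ex, "temperature")[:1]
        (c_cyc,) = segment_cycles(ex, "chest_diameter")
        # on a chest trace the trough marks inspiration start
        assert t_cyc.insp_start == 1.0 and t_cyc.exp_start == 2.0
        assert c_cyc.insp_start == 2.0 and c_cyc.exp_start == 3.0

    def test_unknown_kind_rejected(self):
        ex = self._extrema([1.0, 2.0, 3.0], ["peak", "trough", "peak"])
        with pytest.raises(ValueError, match="signal_kind"):
            segment_cycles(ex, "pressure")

    def test_ie_ratio_recovered_from_synthetic_session(self):
        bundle = make_session(seed=3, duration=600.0,
                              profile=BreathingProfile(ie_ratio=0.88))
        cycles = segment_cycles(detect_extrema(bundle.temperature), "temperature")
        est = summarize(cycles).ie_ratio
        assert est == pytest.approx(0.88, abs=0.05)


class TestSummarize:
    def _cycles(self, specs):
        out = []
        t = 0.0
        for insp, exp in specs:
            out.append(RespCycle(insp_start=t, exp_start=t + insp,
                                 insp_duration=insp, exp_duration=exp))
            t += insp + exp
        return out

    def test_periodic_cycles_zero_sd(self):
        cycles = self._cycles([(1.0, 1.0)] * 5)
        s = summarize(cycles)
        np.testing.assert_allclose(s.ipi_series, 2.0)
        assert s.sd_ipi == 0.0 and s.mean_ipi == 2.0 and s.n_cycles == 5

    def test_ie_ratio_is_mean_of_per_cycle_ratios(self):
        cycles = self._cycles([(0.9, 1.0), (0.88, 1.0)])
        assert summarize(cycles).ie_ratio == pytest.approx((0.9 + 0.88) / 2)

    def test_anchor_selection(self):
        cycles = self._cycles([(1.0, 2.0), (1.0, 2.0), (1.0, 2.0)])
        peaks = anchor_times(cycles, "peak", "temperature")
        troughs = anchor_times(cycles, "trough", "temperature")
        np.testing.assert_allclose(peaks, [0.0, 3.0, 6.0])
        np.testing.assert_allclose(troughs, [1.0, 4.0, 7.0])

    def test_fewer_than_two_cycles_rejected(self):
        with pytest.raises(ValueError, match="2 cycles"):
            summarize(self._cycles([(1.0, 1.0)]))

    def test_mean_ipi_recovered_within_2pct(self):
        bundle = make_session(seed=11, duration=600.0)
        cycles = segment_cycles(detect_extrema(bundle.temperature), "temperature")
        est = summarize(cycles).mean_ipi
        truth = bundle.truth.per_cycle_ipi.mean()
        assert abs(est - truth) / truth < 0.02


class TestIntegrateChest:
    def test_zero_movement_zero_diameter(self):
        m = SampledTrace(np.zeros(1000), fs=100.0)
        d = integrate_chest_movement(m)
        np.testing.assert_array_equal(d.values, 0.0)

    def test_cosine_integrates_to_sine(self):
        fs, f = 100.0, 0.5
        t = np.arange(0, 60, 1 / fs)
        m = SampledTrace(np.cos(2 * np.pi * f * t), fs=fs)
        d = integrate_chest_movement(m, detrend_window=30.0)
        expected = np.sin(2 * np.pi * f * t) / (2 * np.pi * f)
        # skip the half-detrend-window edge region on both sides
        core = slice(int(16 * fs), int(44 * fs))
        err = (np.linalg.norm(d.values[core] - expected[core])
               / np.linalg.norm(expected[core]))
        assert err < 1e-3

    def test_round_trip_recovers_generator_diameter(self):
        bundle = make_session(seed=5, duration=200.0)
        d = integrate_chest_movement(bundle.chest_movement, detrend_window=0)
        err = (np.linalg.norm(d.values - (bundle.chest_diameter.values
                                          - bundle.chest_diameter.values[0]))
               / np.linalg.norm(bundle.chest_diameter.values))
        assert err < 1e-6


class TestRecoveryProperties:
    def test_temperature_and_chest_ipi_agree(self):
        bundle = make_session(seed=21, duration=600.0)
        t_cycles = segment_cycles(detect_extrema(bundle.temperature), "temperature")
        c_cycles = segment_cycles(detect_extrema(bundle.chest_diameter),
                                  "chest_diameter")
        ipi_t = summarize(t_cycles).mean_ipi
        ipi_c = summarize(c_cycles, signal_kind="chest_diameter").mean_ipi
        assert abs(ipi_t - ipi_c) / ipi_c < 0.02

    def test_errors_degrade_gracefully_with_noise(self):
        # I/E-ratio error and peak-timing jitter should grow, on average,
        # along a 4-point noise sweep
        noise_levels = [0.0, 0.3, 0.9, 1.8]
        ie_errs, jitters = [], []
        for noise in noise_levels:
            ie, jit = [], []
            for seed in range(20):
                bundle = make_session(
                    seed=seed, duration=300.0,
                    sensor=SensorModel(noise_sd=noise,
                                       transport_delay_per_kg=0.0),
                    include_chest=False)
                ex = detect_extrema(bundle.temperature)
                cycles = segment_cycles(ex, "temperature")
                ie.append(abs(summarize(cycles).ie_ratio - 0.88))
                peaks = ex.of_kind("peak")
                d = [np.min(np.abs(peaks - t))
                     for t in bundle.truth.insp_starts[2:-2]]
                jit.append(np.std(d))
            ie_errs.append(np.mean(ie))
            jitters.append(np.mean(jit))
        assert all(a <= b + 1e-6 for a, b in zip(ie_errs, ie_errs[1:]))
        assert all(a <= b + 1e-6 for a, b in zip(jitters, jitters[1:]))
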