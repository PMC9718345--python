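"""Generator behaviour: cycle statistics, channel physics, determinism."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from thermoresp import (BreathingProfile, SensorModel, build_default_schedule,
                        first_order_lag, generate_cycle_train,
                        render_chest_channels, render_lick_channel,
                        render_nasal_temperature, simulate_session)
from thermoresp.schedule import SessionSchedule
from thermoresp.synthetic import respiratory_phase


class TestCycleTrain:
    def test_zero_variance_symmetric_cycles(self):
        prof = BreathingProfile(mean_ipi=2.0, ipi_cv=0.0, ie_ratio=1.0)
        truth = generate_cycle_train(prof, None, 10.0, seed=0)
        np.testing.assert_allclose(truth.insp_starts, [0, 2, 4, 6, 8])
        np.testing.assert_allclose(truth.insp_durations(), 1.0)
        np.testing.assert_allclose(truth.exp_durations(), 1.0)

    def test_ie_ratio_exact_in_truth(self):
        prof = BreathingProfile(ie_ratio=0.88, ipi_cv=0.2)
        truth = generate_cycle_train(prof, None, 120.0, seed=3)
        ratios = truth.insp_durations() / truth.exp_durations()
        np.testing.assert_allclose(ratios, 0.88, rtol=1e-12)

    def test_gamma_mean_recovered_across_seeds(self):
        # empirical mean IPI within 3 SE of the target for ~all seeds
        prof = BreathingProfile(mean_ipi=1.5, ipi_cv=0.1)
        hits = 0
        seeds = range(300)
        for seed in seeds:
            truth = generate_cycle_train(prof, None, 600.0, seed=seed)
            ipis = truth.per_cycle_ipi
            se = 1.5 * 0.1 / np.sqrt(len(ipis))
            hits += abs(ipis.mean() - 1.5) <= 3 * se
        assert hits / len(seeds) >= 0.97

    def test_duration_too_short_names_minimum(self):
        prof = BreathingProfile(mean_ipi=2.0)
        with pytest.raises(ValueError, match="6"):
            generate_cycle_train(prof, None, 5.0, seed=0)

    def test_music_blocks_shorten_ipis_every_seed(self):
        prof = BreathingProfile(music_ipi_factor=0.85, ipi_cv=0.15)
        for seed in range(5):
            sched = build_default_schedule(seed)
            truth = generate_cycle_train(prof, sched, sched.end, seed=seed)
            kinds = np.array([
                sched.blocks[i].kind if (i := sched.block_at(t)) is not None else "gap"
                for t in truth.insp_starts])
            music = truth.per_cycle_ipi[kinds == "music"]
            noise = truth.per_cycle_ipi[kinds == "noise"]
            assert music.mean() < noise.mean()

    def test_ipi_truncated_at_floor(self):
        prof = BreathingProfile(mean_ipi=0.5, ipi_cv=1.0)
        truth = generate_cycle_train(prof, None, 200.0, seed=1)
        assert truth.per_cycle_ipi.min() >= 0.3


class TestChestChannels:
    def test_diameter_peaks_at_inspiration_end(self):
        prof = BreathingProfile(mean_ipi=2.0, ipi_cv=0.0, ie_ratio=1.0)
        truth = generate_cycle_train(prof, None, 10.0, seed=0)
        d, _ = render_chest_channels(truth, 1.0, fs=100.0, noise_sd=0.0, seed=0)
        # global maxima occur at expiration starts (inspiration ends)
        for t_exp in truth.exp_starts:
            i = int(round(t_exp * 100))
            assert d.values[i] >= d.values.max() - 1e-9

    def test_trapezoid_integration_inverts_movement(self):
        truth = generate_cycle_train(BreathingProfile(), None, 120.0, seed=2)
        d, m = render_chest_channels(truth, 1.3, fs=100.0, noise_sd=0.0, seed=0)
        rec = cumulative_trapezoid(m.values, dx=0.01, initial=0.0) + d.values[0]
        err = np.linalg.norm(rec - d.values) / np.linalg.norm(d.values)
        assert err < 1e-6

    def test_zero_amplitude_leaves_noise_floor(self):
        truth = generate_cycle_train(BreathingProfile(), None, 30.0, seed=0)
        d, m = render_chest_channels(truth, 0.0, fs=100.0, noise_sd=0.0, seed=0)
        assert np.all(d.values == 0) and np.all(m.values == 0)
        d, m = render_chest_channels(truth, 0.0, fs=100.0, noise_sd=0.1, seed=0)
        assert 0 < np.std(d.values) < 0.2 and 0 < np.std(m.values) < 0.2

    def test_low_sampling_rate_rejected(self):
        truth = generate_cycle_train(BreathingProfile(), None, 30.0, seed=0)
        with pytest.raises(ValueError, match="20"):
            render_chest_channels(truth, 1.0, fs=10.0, noise_sd=0.0, seed=0)


class TestNasalTemperature:
    def test_identity_sensor_extrema_on_phase_boundaries(self, ideal_sensor):
        prof = BreathingProfile(ipi_cv=0.1)
        truth = generate_cycle_train(prof, None, 60.0, seed=5)
        temp = render_nasal_temperature(truth, ideal_sensor, prof, 100.0, seed=0)
        fs = 100.0
        for t_pk in truth.insp_starts[1:-1]:
            i = int(round(t_pk * fs))
            seg = temp.values[i - 30:i + 31]
            assert abs(np.argmax(seg) - 30) <= 1
        for t_tr in truth.exp_starts[1:-1]:
            i = int(round(t_tr * fs))
            seg = temp.values[i - 30:i + 31]
            assert abs(np.argmin(seg) - 30) <= 1

    def test_sinusoid_through_lag_matches_arctan_delay(self):
        fs, tau, f = 100.0, 0.1, 0.5
        t = np.arange(0, 40, 1 / fs)
        x = np.sin(2 * np.pi * f * t)
        y = first_order_lag(x, tau, fs)
        predicted = np.arctan(2 * np.pi * f * tau) / (2 * np.pi * f)
        i = np.argmax(y[2000:2000 + int(fs / f)]) + 2000

        def refine(sig, i):
            a, b, c = sig[i - 1], sig[i], sig[i + 1]
            return (i + 0.5 * (a - c) / (a - 2 * b + c)) / fs

        j = np.argmax(x[2000:2000 + int(fs / f)]) + 2000
        measured = refine(y, i) - refine(x, j)
        assert abs(measured - predicted) < 1.0 / fs

    def test_lag_zero_is_identity(self):
        x = np.random.default_rng(0).normal(size=500)
        np.testing.assert_array_equal(first_order_lag(x, 0.0, 100.0), x)

    def test_lag_dc_gain_is_one(self):
        y = first_order_lag(np.full(2000, 3.7), 0.1, 100.0)
        np.testing.assert_allclose(y, 3.7, rtol=1e-9)

    def test_default_time_constant_is_100ms(self):
        assert SensorModel().time_constant == pytest.approx(0.1)

    def test_peak_lag_monotone_in_tau_and_weight(self, quiet_sensor):
        prof = BreathingProfile(ipi_cv=0.0)
        truth = generate_cycle_train(prof, None, 60.0, seed=0)
        fs = 100.0

        def mean_peak_delay(sensor, profile):
            temp = render_nasal_temperature(truth, sensor, profile, fs, seed=0)
            delays = []
            for t_pk in truth.insp_starts[2:-2]:
                i = int(round(t_pk * fs))
                seg = temp.values[i - 5:i + 45]
                delays.append((np.argmax(seg) - 5) / fs)
            return np.mean(delays)

        by_tau = [mean_peak_delay(
            SensorModel(time_constant=tau, noise_sd=0.0,
                        transport_delay_per_kg=0.0),
            prof) for tau in (0.0, 0.05, 0.1, 0.2)]
        assert all(a <= b + 1e-12 for a, b in zip(by_tau, by_tau[1:]))

        by_weight = [mean_peak_delay(
            SensorModel(noise_sd=0.0),
            BreathingProfile(ipi_cv=0.0, body_weight=w)) for w in (5, 6, 7)]
        assert all(a <= b + 1e-12 for a, b in zip(by_weight, by_weight[1:]))

    def test_respiratory_phase_hits_boundaries_exactly(self):
        prof = BreathingProfile(ipi_cv=0.2)
        truth = generate_cycle_train(prof, None, 60.0, seed=4)
        theta_i = respiratory_phase(truth, truth.insp_starts)
        theta_e = respiratory_phase(truth, truth.exp_starts)
        np.testing.assert_allclose(theta_i, np.arange(len(theta_i)), atol=1e-9)
        np.testing.assert_allclose(theta_e, np.arange(len(theta_e)) + 0.5,
                                   atol=1e-9)


class TestLickChannel:
    def test_no_licks_gives_pure_noise(self):
        sched = build_default_schedule(0)
        trace, onsets = render_lick_channel(sched, 0, fs=100.0, seed=1)
        assert len(onsets) == 0
        assert np.std(trace.values) < 0.2

    def test_burst_count_matches_rewards(self):
        sched = build_default_schedule(1)
        block = sched.blocks[0]
        rewards = sched.reward_times[(sched.reward_times >= block.start)
                                     & (sched.reward_times < block.end)]
        assert len(rewards) == 6
        trace, onsets = render_lick_channel(sched, 8, fs=100.0, seed=2)
        in_block = onsets[(onsets >= block.start) & (onsets < block.end)]
        # six bursts of up to 8 licks each
        gaps = np.diff(in_block)
        n_bursts = 1 + np.sum(gaps > 5.0)
        assert n_bursts == 6

    def test_onsets_contained_in_blocks(self):
        for seed in range(20):
            sched = build_default_schedule(seed)
            _, onsets = render_lick_channel(sched, 8, fs=100.0, seed=seed)
            for t in onsets:
                assert sched.block_at(t) is not None

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="100"):
            render_lick_channel(build_default_schedule(0), 8, fs=50.0, seed=0)


class TestSchedule:
    def test_total_span(self):
        assert build_default_schedule(3).end == 6 * 180 + 5 * 60

    def test_music_tempos(self):
        sched = build_default_schedule(11)
        tempos = sorted(b.tempo_bpm for b in sched.blocks if b.kind == "music")
        assert tempos == [85, 113, 212]
        assert sum(b.kind == "noise" for b in sched.blocks) == 3

    def test_rewards_six_per_block_with_spacing(self):
        sched = build_default_schedule(7)
        for b in sched.blocks:
            r = sched.reward_times[(sched.reward_times >= b.start)
                                   & (sched.reward_times < b.end)]
            assert len(r) == 6
            assert np.min(np.diff(r)) >= 10.0

    def test_same_seed_identical(self):
        a, b = build_default_schedule(9), build_default_schedule(9)
        assert a.to_dict() == b.to_dict()

    def test_reward_outside_blocks_rejected(self):
        sched = build_default_schedule(0)
        with pytest.raises(ValueError, match="outside"):
            SessionSchedule(blocks=sched.blocks, reward_times=[sched.end + 50.0])


class TestDeterminism:
    def test_identical_seed_bit_identical_session(self):
        a = simulate_session(seed=42, duration=100.0)
        b = simulate_session(seed=42, duration=100.0)
        np.testing.assert_array_equal(a.temperature.values, b.temperature.values)
        np.testing.assert_array_equal(a.chest_movement.values,
                                      b.chest_movement.values)
        np.testing.assert_array_equal(a.lick.values, b.lick.values)
        np.testing.assert_array_equal(a.truth.cycle_boundaries,
                                      b.truth.cycle_boundaries)

    def test_different_seed_differs(self):
        a = simulate_session(seed=1, duration=100.0)
        b = simulate_session(seed=2, duration=100.0)
        assert not np.array_equal(a.temperature.values, b.temperature.values)
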