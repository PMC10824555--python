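import numpy as np
import pytest

from tetracal import OpenField, TMaze, calcium_kernel, generate_dataset
from tetracal import synthetic as syn
from tetracal.config import SyntheticConfig


class TestTrajectory:
    def test_open_field_bounds_and_length(self, open_field, rng):
        track = syn.simulate_trajectory(open_field, 60.0, 20.0, rng)
        assert track.n_samples == 1200
        assert (track.xy >= 0).all() and (track.xy <= 40).all()

    def test_tmaze_visits_start_zone(self, rng):
        maze = TMaze()
        track = syn.simulate_trajectory(maze, 300.0, 20.0, rng, mean_speed=15)
        # start zone = within 4 cm of (0, 0); count distinct visits
        near = np.linalg.norm(track.xy - [0.0, 0.0], axis=1) < 4.0
        visits = np.sum(np.diff(near.astype(int)) == 1) + near[0]
        assert visits >= 5
        assert maze.contains(track.xy, tol=1e-3).all()

    def test_seeded_determinism(self, open_field):
        a = syn.simulate_trajectory(open_field, 30.0, 20.0, np.random.default_rng(7))
        b = syn.simulate_trajectory(open_field, 30.0, 20.0, np.random.default_rng(7))
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_too_short_rejected(self, open_field, rng):
        with pytest.raises(ValueError):
            syn.simulate_trajectory(open_field, 0.01, 20.0, rng)


class TestSpikes:
    def test_parked_at_field_center_poisson_count(self, parked_track, rng):
        """Mouse parked at the field center: count ~ Poisson(peak+baseline)*T."""
        centers = np.array([[20.0, 20.0]])
        spikes = syn.simulate_spikes(parked_track, np.array([True]), centers, rng,
                                     sigma_cm=8.0, peak_rate=8.0, baseline_rate=0.0)
        count = spikes.sum()
        expect = 8.0 * 100.0
        assert abs(count - expect) <= 3 * np.sqrt(expect)

    def test_zero_baseline_silent(self, short_track, rng):
        spikes = syn.simulate_spikes(short_track, np.array([False]),
                                     np.full((1, 2), np.nan), rng,
                                     baseline_rate=0.0)
        assert spikes.sum() == 0

    def test_doubling_peak_doubles_infield_count(self, parked_track):
        counts = []
        for peak in (4.0, 8.0):
            r = np.random.default_rng(3)
            s = syn.simulate_spikes(parked_track, np.array([True]),
                                    np.array([[20.0, 20.0]]), r,
                                    peak_rate=peak, baseline_rate=0.0)
            counts.append(s.sum())
        ratio = counts[1] / counts[0]
        assert 1.7 < ratio < 2.3

    def test_rate_above_fs_rejected(self, short_track, rng):
        with pytest.raises(ValueError, match="probability"):
            syn.simulate_spikes(short_track, np.array([True]),
                                np.array([[20.0, 20.0]]), rng, peak_rate=25.0)


class TestCalciumForwardModel:
    def test_single_spike_unit_peak(self, rng):
        spikes = np.zeros((1, 200))
        spikes[0, 50] = 1
        tr = syn.spikes_to_calcium(spikes, 20.0, rng, noise_sd=0.0)
        assert tr.max() == pytest.approx(1.0)
        kernel = calcium_kernel(20.0)
        assert tr[0].argmax() == 50 + kernel.argmax()

    def test_noise_moments(self, rng):
        tr = syn.spikes_to_calcium(np.zeros((1, 20000)), 20.0, rng, noise_sd=0.3)
        assert abs(tr.mean()) < 0.02
        assert tr.std() == pytest.approx(0.3, abs=0.02)

    def test_two_spikes_superposition(self, rng):
        """Second transient rides on the first's tail: peak = 1 + e^(-3/1.5)."""
        spikes = np.zeros((1, 400))
        spikes[0, 100] = 1
        spikes[0, 160] = 1     # 3 s later at 20 Hz
        tr = syn.spikes_to_calcium(spikes, 20.0, rng, noise_sd=0.0)[0]
        second_peak = tr[160:220].max()
        assert second_peak == pytest.approx(1.0 + np.exp(-2.0), rel=0.01)

    def test_linearity_in_spikes(self, rng):
        s1 = np.zeros((1, 300)); s1[0, 40] = 1
        s2 = np.zeros((1, 300)); s2[0, 200] = 1
        both = s1 + s2
        f = lambda s: syn.spikes_to_calcium(s, 20.0, rng, noise_sd=0.0)
        np.testing.assert_allclose(f(both), f(s1) + f(s2), atol=1e-12)


class TestAssemblyInjection:
    def test_members_spike_in_event_windows(self, rng):
        spikes = np.zeros((10, 2000), dtype=np.int8)
        times = np.array([10.0, 40.0, 70.0])
        members = [np.arange(10)]
        out = syn.inject_assembly_events(spikes, 20.0, members, [times],
                                         lags={}, rng=rng, jitter_s=0.0)
        for t in times:
            f0, f1 = int(t * 20), int((t + 1.0) * 20)
            assert (out[:, f0:f1].sum(axis=1) > 0).all()

    def test_lag_order_recovered_in_noiseless_calcium(self, rng):
        n = 8
        lags = {i: 0.45 * i / (n - 1) for i in range(n)}
        spikes = np.zeros((n, 4000), dtype=np.int8)
        times = np.arange(20.0, 180.0, 20.0)
        out = syn.inject_assembly_events(spikes, 20.0, [np.arange(n)], [times],
                                         lags=lags, rng=rng, jitter_s=0.0)
        cal = syn.spikes_to_calcium(out, 20.0, rng, noise_sd=0.0)
        first_event = cal[:, 360:560]    # window around t=20 s
        peak_frames = first_event.argmax(axis=1)
        assert list(np.argsort(peak_frames, kind="stable")) == list(range(n))


class TestLFP:
    def test_no_ripples_band_power_at_background(self, rng):
        from tetracal.ephys import bandpass_ripple
        lfp, times = syn.simulate_lfp(120.0, 1000.0, rng, n_ripples=0)
        assert times.size == 0
        band_sd = bandpass_ripple(lfp.data[0], 1000.0).std()
        # in-band SD of the unit-variance 1/f background is a small fraction
        assert 0.0 < band_sd < 0.5

    def test_ripple_envelope_peaks_exceed_3sd(self, rng):
        from tetracal.ephys import bandpass_ripple, ripple_envelope
        lfp, times = syn.simulate_lfp(300.0, 1000.0, rng, n_ripples=10, snr=5.0)
        filt = bandpass_ripple(lfp.data[0], 1000.0)
        env = ripple_envelope(filt, 1000.0)
        # background SD estimated away from ripples
        mask = np.ones(lfp.n_samples, bool)
        for t in times:
            mask[int((t - 0.2) * 1000): int((t + 0.2) * 1000)] = False
        sd = filt[mask].std()
        for t in times:
            i = int(t * 1000)
            assert env[i - 60: i + 60].max() > 3 * sd

    def test_seeded_determinism(self):
        a, _ = syn.simulate_lfp(30.0, 1000.0, np.random.default_rng(5), n_ripples=3)
        b, _ = syn.simulate_lfp(30.0, 1000.0, np.random.default_rng(5), n_ripples=3)
        np.testing.assert_array_equal(a.data, b.data)


class TestStimExperiment:
    def test_schedule_count(self):
        onsets = syn.stim_schedule(600.0, 60.0)
        assert len(onsets) == 10

    def test_responsive_neurons_rise_after_onset(self, rng):
        tm, events, resp = syn.simulate_stim_experiment(
            40, 10 * 60.0, 20.0, rng, period=60.0, responsive_fraction=0.25,
            effect_noise_units=5.0, noise_sd=0.3)
        half = int(2.0 * 20)
        pre_post = []
        for t in events.onset_times:
            f = int(t * 20)
            pre_post.append(tm.values[resp, f:f + half].mean(axis=1)
                            - tm.values[resp, f - half:f].mean(axis=1))
        assert (np.mean(pre_post, axis=0) > 0).all()

    def test_zero_effect_no_systematic_shift(self, rng):
        tm, events, resp = syn.simulate_stim_experiment(
            60, 10 * 60.0, 20.0, rng, period=60.0, responsive_fraction=0.25,
            effect_noise_units=0.0, noise_sd=0.3)
        half = int(2.0 * 20)
        diffs = []
        for t in events.onset_times:
            f = int(t * 20)
            diffs.append(tm.values[:, f:f + half].mean() - tm.values[:, f - half:f].mean())
        assert abs(np.mean(diffs)) < 0.05


class TestGenerateDataset:
    def test_default_shape_and_regions(self, rng):
        cfg = SyntheticConfig(duration=120.0, n_neurons_per_region=10,
                              n_assemblies=2, assembly_size=6,
                              events_per_assembly=5, n_ripples=2)
        ds = generate_dataset(cfg, rng)
        assert ds.traces.n_neurons == 40
        regions, counts = np.unique(ds.traces.region_labels, return_counts=True)
        assert len(regions) == 4 and (counts == 10).all()
        assert ds.lfp.sampling_rate == 1000.0
        assert all(len(m) == 6 for m in ds.truth.assembly_membership)
        # everything on one clock
        assert ds.track.times[0] == 0.0 and ds.traces.t0 == 0.0 == ds.lfp.t0

    def test_different_seeds_differ(self):
        cfg = SyntheticConfig(duration=60.0, n_neurons_per_region=5,
                              n_assemblies=0, n_ripples=0)
        d1 = generate_dataset(cfg, np.random.default_rng(1))
        d2 = generate_dataset(cfg, np.random.default_rng(2))
        assert not np.array_equal(d1.traces.values, d2.traces.values)
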