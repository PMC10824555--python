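import numpy as np
import pytest

from tetracal import (SCE, assembly_positions, assign_assemblies, detect_sces,
                      order_by_peak_time, robust_kmeans, sce_matrix, select_k,
                      select_m, silhouette_mean, TraceMatrix)
from tetracal import synthetic as syn


def make_z(active_blocks, n_neurons=5, n_frames=200):
    """z matrix with z=2 inside the given (neuron, start, stop) blocks."""
    z = np.zeros((n_neurons, n_frames))
    for i, s, e in active_blocks:
        z[i, s:e] = 2.0
    return z


class TestDetectSCEs:
    def test_simple_construction(self):
        # 3 neurons co-active for 600 ms at 20 Hz (12 frames), M=3
        z = make_z([(i, 50, 62) for i in range(3)], n_neurons=3)
        sces = detect_sces(z, 3, 20.0)
        assert len(sces) == 1
        assert sces[0].participation.all()
        assert sces[0].onset_frame == 50 and sces[0].offset_frame == 62

    def test_400ms_run_rejected(self):
        # strictly-more-than-500 ms rule: 8 frames at 20 Hz = 400 ms
        z = make_z([(i, 50, 58) for i in range(3)], n_neurons=3)
        assert detect_sces(z, 3, 20.0) == []

    def test_exactly_500ms_rejected(self):
        z = make_z([(i, 50, 60) for i in range(3)], n_neurons=3)
        assert detect_sces(z, 3, 20.0) == []

    def test_participation_any_frame(self):
        blocks = [(0, 50, 64), (1, 50, 64), (2, 50, 64), (3, 60, 62)]
        z = make_z(blocks)
        sces = detect_sces(z, 3, 20.0)
        assert len(sces) == 1
        # neuron 3 active for only 2 frames of the run still participates
        assert sces[0].participation[3]
        assert not sces[0].participation[4]

    def test_m_above_population_warns_empty(self):
        with pytest.warns(UserWarning, match="exceeds"):
            assert detect_sces(np.zeros((3, 100)), 10, 20.0) == []

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            detect_sces(np.zeros((3, 100)), 1, 20.0)

    def test_matches_brute_force_oracle(self, sce_oracle, rng):
        """Random rasters: fast detection equals an independent frame scan."""
        for _ in range(10):
            z = rng.normal(0.6, 0.8, (12, 800))
            for m in (2, 4, 6):
                got = detect_sces(z, m, 20.0)
                want = sce_oracle(z, m, 20.0)
                assert [(s.onset_frame, s.offset_frame) for s in got] == \
                       [(s, e) for s, e, _ in want]
                assert [tuple(s.participation) for s in got] == \
                       [p for _, _, p in want]


class TestSelectM:
    def test_enumeration_on_fixture(self, rng):
        z = rng.normal(0.7, 0.8, (15, 1500))
        m_star, counts = select_m(z, 20.0, candidates=range(2, 10))
        best = max(counts.values())
        assert counts[m_star] == best
        assert m_star == min(m for m, c in counts.items() if c == best)

    def test_tie_takes_smallest(self):
        # one event with exactly 5 co-active neurons: counts equal for M=2..5
        z = make_z([(i, 50, 64) for i in range(5)], n_neurons=6)
        m_star, counts = select_m(z, 20.0, candidates=[2, 3, 4, 5])
        assert counts == {2: 1, 3: 1, 4: 1, 5: 1}
        assert m_star == 2

    def test_all_silent_rejected(self):
        with pytest.raises(ValueError, match="no SCEs"):
            select_m(np.zeros((5, 400)), 20.0, candidates=[2, 3])


class TestSCEMatrix:
    def test_rows_are_participation(self):
        z = make_z([(i, 50, 64) for i in range(4)], n_neurons=4)
        sces = detect_sces(z, 4, 20.0)
        X = sce_matrix(sces)
        assert X.shape == (1, 4)
        assert (X.sum(axis=1) >= 4).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sce_matrix([])


class TestRobustKMeans:
    def _blocks(self, rng, n_per=20):
        a = np.tile([1, 1, 1, 0, 0, 0], (n_per, 1)).astype(float)
        b = np.tile([0, 0, 0, 1, 1, 1], (n_per, 1)).astype(float)
        X = np.vstack([a, b])
        return X, np.repeat([0, 1], n_per)

    def test_separable_blocks_split_exactly(self, rng):
        X, truth = self._blocks(rng)
        _, labels = robust_kmeans(X, 2, rng, n_runs=20)
        same = (labels == truth).mean()
        assert same in (0.0, 1.0)   # up to label swap

    def test_stable_centers_across_master_seeds(self):
        X, _ = self._blocks(np.random.default_rng(0))
        c1, _ = robust_kmeans(X, 2, np.random.default_rng(1), n_runs=30)
        c2, _ = robust_kmeans(X, 2, np.random.default_rng(2), n_runs=30)
        c1 = c1[np.argsort(c1[:, 0])]
        c2 = c2[np.argsort(c2[:, 0])]
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_k_outside_range_rejected(self, rng):
        X, _ = self._blocks(rng)
        with pytest.raises(ValueError, match=r"\[2, 10\]"):
            robust_kmeans(X, 1, rng)


class TestSilhouette:
    def test_matches_brute_force(self, rng):
        X = rng.normal(0, 1, (30, 4))
        labels = rng.integers(0, 3, 30)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        svals = []
        for i in range(len(X)):
            own = labels == labels[i]
            if own.sum() == 1:
                svals.append(0.0)
                continue
            a = d[i, own & (np.arange(len(X)) != i)].mean()
            b = min(d[i, labels == c].mean()
                    for c in np.unique(labels) if c != labels[i])
            svals.append((b - a) / max(a, b))
        assert silhouette_mean(X, labels) == pytest.approx(np.mean(svals), abs=1e-12)

    def test_separated_blocks_high(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (20, 3)), rng.normal(5, 0.05, (20, 3))])
        labels = np.repeat([0, 1], 20)
        assert silhouette_mean(X, labels) > 0.9

    def test_random_labels_near_zero(self, rng):
        X = rng.normal(0, 1, (100, 5))
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        assert abs(silhouette_mean(X, labels)) < 0.1

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_mean(rng.normal(0, 1, (10, 2)), np.zeros(10, int))


class TestSelectK:
    def test_four_motifs_recovered(self, rng):
        motifs = np.eye(4).repeat(10, axis=1)   # 4 disjoint 10-neuron motifs
        X = motifs[rng.integers(0, 4, 80)]
        X = np.abs(X - (rng.random(X.shape) < 0.05))   # 5% bit flips
        cl = select_k(X, rng, n_runs=30)
        assert cl.k == 4
        assert 2 <= cl.k <= 10

    def test_too_few_sces_rejected(self, rng):
        with pytest.raises(ValueError, match="too few"):
            select_k(np.ones((2, 4)), rng)


class TestAssignAssemblies:
    def test_exclusive_participant_joins_only_its_cluster(self, rng):
        # 30 SCEs in 2 clusters; neuron 0 in all of cluster 0, none of 1;
        # neurons 1..5 participate uniformly
        labels = np.repeat([0, 1], 15)
        X = (rng.random((30, 6)) < 0.5).astype(float)
        X[:, 0] = (labels == 0).astype(float)
        asms = assign_assemblies(X, labels, rng, n_perm=500)
        member_of = [a.id for a in asms if 0 in a.members]
        assert member_of == [0]

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_assemblies(np.ones((4, 2)), np.array([0, 0, 1, 1]), rng, n_perm=0)


class TestAssemblyCharacterization:
    def _setup(self, rng):
        z = make_z([(i, 100, 120) for i in range(4)]
                   + [(i, 500, 520) for i in range(4)], n_neurons=4, n_frames=1200)
        sces = detect_sces(z, 4, 20.0)
        labels = np.zeros(len(sces), int)
        from tetracal.assemblies import Assembly
        asm = Assembly(0, np.arange(4), np.repeat("A", 4), 0, np.zeros(4))
        return z, sces, labels, asm

    def test_positions_interpolated_from_track(self, short_track, rng):
        z, sces, labels, asm = self._setup(rng)
        out = assembly_positions(asm, sces, labels, short_track)
        assert out["positions"].shape == (2, 2)
        assert np.isfinite(out["dispersion"])
        assert short_track.arena.contains(out["positions"]).all()

    def test_onsets_outside_track_excluded(self, rng, open_field):
        from tetracal import PositionTrack
        z, sces, labels, asm = self._setup(rng)
        track = PositionTrack(np.arange(100) / 20.0 + 4.0,
                              np.tile([5.0, 5.0], (100, 1)), open_field)
        with pytest.warns(UserWarning, match="excluded"):
            out = assembly_positions(asm, sces, labels, track)
        assert len(out["onsets"]) == 1   # only the t=5 s SCE is inside

    def test_lag_ordering_recovered(self, rng):
        n = 6
        lags = {i: 0.45 * i / (n - 1) for i in range(n)}
        spikes = np.zeros((n, 4000), dtype=np.int8)
        times = np.arange(20.0, 180.0, 20.0)
        out = syn.inject_assembly_events(spikes, 20.0, [np.arange(n)], [times],
                                         lags=lags, rng=rng, jitter_s=0.0)
        cal = syn.spikes_to_calcium(out, 20.0, rng, noise_sd=0.0)
        z = (cal - cal.mean(1, keepdims=True)) / cal.std(1, keepdims=True)
        sces = detect_sces(z, n, 20.0)
        assert len(sces) == len(times)
        labels = np.zeros(len(sces), int)
        from tetracal.assemblies import Assembly
        asm = Assembly(0, np.arange(n), np.repeat("A", n), 0, np.zeros(n))
        tm = TraceMatrix(cal, np.arange(n), np.repeat("A", n), 20.0)
        res = order_by_peak_time(asm, tm, sces, labels, window=10.0)
        assert list(res["ordered_members"]) == list(range(n))

    def test_flat_neuron_placed_last(self, rng):
        z, sces, labels, _ = self._setup(rng)
        cal = np.vstack([z, np.zeros(z.shape[1])])   # a 5th, flat neuron
        from tetracal.assemblies import Assembly
        asm = Assembly(0, np.arange(5), np.repeat("A", 5), 0, np.zeros(5))
        tm = TraceMatrix(cal, np.arange(5), np.repeat("A", 5), 20.0)
        res = order_by_peak_time(asm, tm, sces, labels)
        assert res["ordered_members"][-1] == 4
        assert res["flat_flags"][4]
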