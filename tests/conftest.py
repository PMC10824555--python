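import numpy as np
import pytest

from tetracal import OpenField, TraceMatrix, PositionTrack
from tetracal import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def open_field():
    return OpenField(40.0, 40.0)


@pytest.fixture
def short_track(open_field, rng):
    """60 s open-field trajectory at 20 Hz."""
    return syn.simulate_trajectory(open_field, 60.0, 20.0, rng)


@pytest.fixture
def parked_track(open_field):
    """Mouse sitting at the arena center for 100 s (20 Hz)."""
    n = 2000
    times = np.arange(n) / 20.0
    xy = np.tile([20.0, 20.0], (n, 1))
    return PositionTrack(times, xy, open_field)


@pytest.fixture
def toy_traces(rng):
    values = rng.normal(0.0, 1.0, (4, 1200))
    return TraceMatrix(values, np.arange(4), np.array(["A", "A", "B", "B"]),
                       sampling_rate=20.0)


def brute_force_sces(z, m, fs, min_duration=0.5, merge_gap=0.5, thr=1.0):
    """Independent frame-scan SCE oracle (deliberately naive).

    Returns a list of (onset_frame, offset_frame_exclusive, participation
    tuple) for comparison with the fast implementation.
    """
    n_neurons, n_frames = z.shape
    marked = []
    for t in range(n_frames):
        count = 0
        for i in range(n_neurons):
            if z[i, t] > thr:
                count += 1
        marked.append(count >= m)
    # maximal runs
    runs = []
    t = 0
    while t < n_frames:
        if marked[t]:
            s = t
            while t < n_frames and marked[t]:
                t += 1
            runs.append([s, t])
        else:
            t += 1
    # merge runs separated by fewer than merge-gap frames
    gap = max(int(round(merge_gap * fs)), 1)
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if (e - s) / fs > min_duration:
            part = tuple(bool((z[i, s:e] > thr).any()) for i in range(n_neurons))
            out.append((s, e, part))
    return out


@pytest.fixture
def sce_oracle():
    return brute_force_sces
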