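"""LFP filtering, sharp-wave-ripple detection, spectrograms, and
ripple-triggered calcium alignment.

Ripples are 150-250 Hz transients; detection operates on the z-scored
smoothed Hilbert envelope of the zero-phase band-passed signal: events must
exceed ``z_on`` continuously, reach ``z_peak`` at their maximum, and last
20-200 ms.  Because detection is z-based it is invariant to amplitude
rescaling of the LFP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io import LFPRecord, TraceMatrix
from .preprocess import zscore_traces

__all__ = [
    "RippleEvent", "bandpass_ripple", "ripple_envelope", "detect_ripples",
    "spectrogram", "ripple_triggered_calcium",
]


@dataclass
class RippleEvent:
    channel: int
    onset_s: float
    peak_s: float
    offset_s: float
    peak_z: float

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.peak_s < self.offset_s):
            raise ValueError("ripple event needs onset <= peak < offset")

    @property
    def duration(self) -> float:
        return self.offset_s - self.onset_s


def bandpass_ripple(x: np.ndarray, fs: float, low: float = 150.0,
                    high: float = 250.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    if not 0 < low < high < fs / 2:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, float), axis=-1)


def ripple_envelope(filtered: np.ndarray, fs: float,
                    smooth_s: float = 0.005) -> np.ndarray:
    """Magnitude of the analytic signal, Gaussian-smoothed (default 5 ms)."""
    env = np.abs(signal.hilbert(np.asarray(filtered, float), axis=-1))
    if smooth_s > 0:
        env = ndimage.gaussian_filter1d(env, smooth_s * fs, axis=-1)
    return env


def detect_ripples(filtered: np.ndarray, fs: float, z_on: float = 3.0,
                   z_peak: float = 5.0, min_duration: float = 0.03,
                   max_duration: float = 0.2, merge_gap: float = 0.01,
                   smooth_s: float = 0.005, channel: int = 0,
                   t0: float = 0.0) -> list[RippleEvent]:
    """Detect ripple events in a band-passed single-channel signal.

    Candidate events are maximal runs where the envelope z-score exceeds
    ``z_on``; runs closer than ``merge_gap`` are merged; an event is kept iff
    its peak z reaches ``z_peak`` and its duration lies in
    [min_duration, max_duration].
    """
    if z_on > z_peak:
        raise ValueError("z_on must not exceed z_peak")
    x = np.asarray(filtered, float)
    if x.ndim != 1:
        raise ValueError("detect_ripples works on one channel at a time")
    env = ripple_envelope(x, fs, smooth_s)
    z = (env - env.mean()) / env.std()
    above = z > z_on
    d = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    gap = int(round(merge_gap * fs))
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        dur = (e - s) / fs
        if not (min_duration <= dur <= max_duration):
            continue
        pk = s + int(np.argmax(z[s:e]))
        if z[pk] < z_peak:
            continue
        events.append(RippleEvent(channel, t0 + s / fs, t0 + pk / fs,
                                  t0 + e / fs, float(z[pk])))
    return events


def spectrogram(x: np.ndarray, fs: float, window_s: float = 0.128,
                overlap: float = 0.75) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power spectral density (Hann window).

    Returns (frequencies, times, Sxx) with Sxx in power density units so that
    integrating over frequency recovers the signal variance (Parseval).
    """
    nper = int(round(window_s * fs))
    f, t, S = signal.spectrogram(np.asarray(x, float), fs=fs, nperseg=nper,
                                 noverlap=int(nper * overlap),
                                 scaling="density", detrend=False)
    return f, t, S


def ripple_triggered_calcium(traces: TraceMatrix, ripple_times: np.ndarray,
                             window: float = 2.0, sync_z: float = 1.0,
                             sync_window: float = 0.5) -> dict:
    """Onset-centered calcium snippets around ripples plus, per ripple, the
    set of neurons synchronously active (z > sync_z within
    [onset, onset + sync_window))."""
    ripple_times = np.asarray(ripple_times, float)
    if ripple_times.size == 0:
        return {"times": np.empty(0), "snippets": np.empty((0, traces.n_neurons, 0)),
                "sync_sets": [], "region_counts": []}
    fs = traces.sampling_rate
    half = int(round(window * fs))
    nsync = int(round(sync_window * fs))
    z = zscore_traces(traces)
    frames = np.round((ripple_times - traces.t0) * fs).astype(int)
    keep = (frames - half >= 0) & (frames + half <= traces.n_frames)
    frames = frames[keep]
    snippets = np.stack([z[:, f - half: f + half] for f in frames]) \
        if len(frames) else np.empty((0, traces.n_neurons, 2 * half))
    sync_sets, region_counts = [], []
    for f in frames:
        active = (z[:, f: f + nsync] > sync_z).any(axis=1)
        ids = np.nonzero(active)[0]
        sync_sets.append(ids)
        regions, counts = np.unique(traces.region_labels[ids], return_counts=True)
        region_counts.append(dict(zip(regions.tolist(), counts.tolist())))
    rel = (np.arange(2 * half) - half) / fs
    return {"times": ripple_times[keep], "rel_times": rel, "snippets": snippets,
            "sync_sets": sync_sets, "region_counts": region_counts}
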