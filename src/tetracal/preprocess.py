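"""Noise estimation, z-scoring, onset-centering, and trace-position
alignment/binning shared by all downstream stages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import EventTable, PositionTrack, TraceMatrix

__all__ = [
    "AlignedDataset", "estimate_noise_level", "zscore_traces",
    "align_and_bin", "trim_silent_ends", "center_on_events",
]

#: MAD-to-SD factor for Gaussian noise
_MAD_NORM = 0.6744897501960817


@dataclass
class AlignedDataset:
    """Population activity and positions on a common time grid.

    binned_activity : (n_neurons, n_bins), mean activity per bin
    bin_positions : (n_bins, 2) cm, mean tracked position per bin
    valid_mask : bins that contain at least one position sample
    bin_times : bin centers, s
    """

    binned_activity: np.ndarray
    bin_size: float
    bin_positions: np.ndarray
    valid_mask: np.ndarray
    bin_times: np.ndarray
    neuron_ids: np.ndarray
    region_labels: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.binned_activity.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.binned_activity.shape[0]

    def subset_neurons(self, idx: np.ndarray) -> "AlignedDataset":
        idx = np.asarray(idx)
        return AlignedDataset(self.binned_activity[idx], self.bin_size,
                              self.bin_positions, self.valid_mask, self.bin_times,
                              self.neuron_ids[idx], self.region_labels[idx])

    def slice_bins(self, sl: slice) -> "AlignedDataset":
        return AlignedDataset(self.binned_activity[:, sl], self.bin_size,
                              self.bin_positions[sl], self.valid_mask[sl],
                              self.bin_times[sl], self.neuron_ids, self.region_labels)


def estimate_noise_level(trace: np.ndarray) -> float:
    """Robust noise SD from first differences.

    sigma = median(|x[t+1]-x[t]|) / (0.6745 * sqrt(2)).  First differencing
    removes slow transients; the median absolute deviation makes the estimate
    insensitive to the sparse large excursions calcium transients produce.
    Returns 0 for a constant trace.
    """
    trace = np.asarray(trace, float)
    if trace.size < 10:
        raise ValueError("trace too short for noise estimation (need >= 10 samples)")
    return float(np.median(np.abs(np.diff(trace))) / (_MAD_NORM * np.sqrt(2)))


def zscore_traces(traces: TraceMatrix | np.ndarray) -> np.ndarray:
    """Per-neuron z-score over the whole session; constant rows map to zeros
    (flagged with a warning)."""
    values = traces.values if isinstance(traces, TraceMatrix) else np.atleast_2d(traces)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = (sd.ravel() == 0)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant trace(s) z-scored to all zeros")
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mu) / sd


def align_and_bin(traces: TraceMatrix, track: PositionTrack,
                  bin_size: float = 0.1,
                  activity: np.ndarray | None = None) -> AlignedDataset:
    """Average activity and tracked position within consecutive time bins.

    Bins tile the overlap of the trace and track time ranges (half-open
    [start, start+bin_size) bins); bins without any position sample are
    masked invalid.  `activity` overrides the raw values (e.g. pass z-scored
    traces) but must share the trace clock.
    """
    values = traces.values if activity is None else np.atleast_2d(activity)
    t_frames = traces.times()
    t_start = max(t_frames[0], track.times[0])
    t_end = min(t_frames[-1] + 1.0 / traces.sampling_rate, track.times[-1])
    n_bins = int(np.floor((t_end - t_start) / bin_size))
    if n_bins < 1:
        raise ValueError("traces and track do not overlap in time")

    # epsilon guards frames/samples sitting exactly on a bin edge
    fi = np.floor((t_frames - t_start) / bin_size + 1e-9).astype(int)
    fok = (fi >= 0) & (fi < n_bins) & (t_frames >= t_start - 1e-12)
    counts = np.bincount(fi[fok], minlength=n_bins)
    sums = np.zeros((values.shape[0], n_bins))
    np.add.at(sums.T, fi[fok], values[:, fok].T)
    with np.errstate(invalid="ignore"):
        binned = sums / counts

    pi = np.floor((track.times - t_start) / bin_size + 1e-9).astype(int)
    pok = (pi >= 0) & (pi < n_bins) & (track.times >= t_start - 1e-12)
    pcount = np.bincount(pi[pok], minlength=n_bins)
    psum = np.zeros((n_bins, 2))
    np.add.at(psum, pi[pok], track.xy[pok])
    valid = (pcount > 0) & (counts > 0)
    with np.errstate(invalid="ignore"):
        positions = psum / pcount[:, None]
    binned = np.nan_to_num(binned, nan=0.0)
    centers = t_start + bin_size * (np.arange(n_bins) + 0.5)
    return AlignedDataset(binned, bin_size, positions, valid, centers,
                          traces.neuron_ids, traces.region_labels)


def trim_silent_ends(dataset: AlignedDataset, threshold: float = 0.0,
                     min_run_s: float = 5.0) -> AlignedDataset:
    """Drop leading/trailing bins where the population-mean activity stays
    below `threshold` for at least `min_run_s` (automated stand-in for
    manually removing silent periods at the start/end of trials).  Interior
    bins are never touched."""
    pop = dataset.binned_activity.mean(axis=0)
    silent = pop < threshold
    min_run = int(np.ceil(min_run_s / dataset.bin_size))
    start = 0
    n = len(pop)
    i = 0
    while i < n and silent[i]:
        i += 1
    if i >= min_run:
        start = i
    j = n
    while j > 0 and silent[j - 1]:
        j -= 1
    end = j if (n - j) >= min_run else n
    if start == 0 and end == n:
        return dataset
    return dataset.slice_bins(slice(start, end))


def center_on_events(traces: TraceMatrix, events: EventTable,
                     window: float = 2.0) -> dict:
    """Noise-normalized, onset-centered per-trial snippets.

    Each snippet covers [onset-window, onset+window), is divided by the
    neuron's estimated noise level and shifted so its value at the onset
    frame is 0.  Events whose window falls outside the recording are skipped
    with a warning.

    Returns dict with 'snippets' (n_neurons, n_trials, n_t), 'times'
    (relative s), 'mean', 'sem'.
    """
    fs = traces.sampling_rate
    half = int(round(window * fs))
    n_t = 2 * half
    rel = (np.arange(n_t) - half) / fs
    onset_frames = np.round((events.onset_times - traces.t0) * fs).astype(int)
    keep = (onset_frames - half >= 0) & (onset_frames + half <= traces.n_frames)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} event(s) fall outside the recording; skipped")
    onset_frames = onset_frames[keep]
    n_trials = len(onset_frames)
    noise = np.array([estimate_noise_level(v) for v in traces.values])
    noise = np.where(noise == 0, 1.0, noise)
    snippets = np.empty((traces.n_neurons, n_trials, n_t))
    for k, f0 in enumerate(onset_frames):
        seg = traces.values[:, f0 - half: f0 + half] / noise[:, None]
        snippets[:, k, :] = seg - seg[:, [half]]
    mean = snippets.mean(axis=1) if n_trials else np.zeros((traces.n_neurons, n_t))
    sem = (snippets.std(axis=1, ddof=1) / np.sqrt(n_trials)
           if n_trials > 1 else np.zeros_like(mean))
    return {"snippets": snippets, "times": rel, "mean": mean, "sem": sem,
            "kept_events": np.nonzero(keep)[0]}
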