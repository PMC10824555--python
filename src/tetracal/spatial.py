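"""Spatial tuning: occupancy and rate maps, spatial mutual information, and a
circular-shift shuffle test flagging spatially modulated neurons.

The tuning statistic is the plug-in mutual information (bits) between a
neuron's discretized activity (default: binary, binned z-score > 1) and the
animal's discretized position.  Significance comes from a null distribution
built by circularly shifting the activity relative to the trajectory by at
least `min_shift` seconds, which preserves each signal's autocorrelation
while destroying their relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Arena, PositionTrack
from .preprocess import AlignedDataset

__all__ = [
    "OccupancyMap", "RateMap", "compute_occupancy", "compute_rate_map",
    "mutual_information_bits", "spatial_mutual_information",
    "discretize_positions", "shuffle_tuning_test", "tuned_fractions",
    "run_tuning",
]


@dataclass
class OccupancyMap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    seconds: np.ndarray        # (nx, ny) time spent per spatial bin


@dataclass
class RateMap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray
    rate: np.ndarray           # NaN where occupancy < min_occupancy
    smoothing_sigma_bins: float

    def peak_bin(self) -> tuple[int, int]:
        r = np.where(np.isnan(self.rate), -np.inf, self.rate)
        return tuple(np.unravel_index(np.argmax(r), r.shape))  # type: ignore

    def peak_position(self) -> np.ndarray:
        i, j = self.peak_bin()
        return np.array([(self.x_edges[i] + self.x_edges[i + 1]) / 2,
                         (self.y_edges[j] + self.y_edges[j + 1]) / 2])


def _edges(arena: Arena, bin_cm: float) -> tuple[np.ndarray, np.ndarray]:
    x0, x1, y0, y1 = arena.bounds()
    return (np.arange(x0, x1 + bin_cm, bin_cm), np.arange(y0, y1 + bin_cm, bin_cm))


def compute_occupancy(track: PositionTrack, bin_cm: float = 2.0) -> OccupancyMap:
    """Time spent per spatial bin; sums to the total tracked time."""
    dt = np.diff(track.times)
    dt = np.append(dt, np.median(dt))
    xe, ye = _edges(track.arena, bin_cm)
    h, _, _ = np.histogram2d(track.xy[:, 0], track.xy[:, 1],
                             bins=[xe, ye], weights=dt)
    return OccupancyMap(xe, ye, h)


def compute_rate_map(activity: np.ndarray, track: PositionTrack,
                     bin_cm: float = 2.0, smoothing_sigma_bins: float = 1.0,
                     min_occupancy: float = 0.2) -> RateMap:
    """Occupancy-normalized mean activity per spatial bin, Gaussian-smoothed.

    `activity` is sampled at the track's timestamps.  Bins visited for less
    than `min_occupancy` seconds are undefined (NaN).  Smoothing uses
    normalized convolution so undefined bins neither leak nor shrink the map.
    """
    activity = np.asarray(activity, float)
    if len(activity) != track.n_samples:
        raise ValueError("activity must be sampled at the track's timestamps")
    occ = compute_occupancy(track, bin_cm)
    dt = np.diff(track.times)
    dt = np.append(dt, np.median(dt))
    num, _, _ = np.histogram2d(track.xy[:, 0], track.xy[:, 1],
                               bins=[occ.x_edges, occ.y_edges],
                               weights=activity * dt)
    defined = occ.seconds >= min_occupancy
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(defined, num / occ.seconds, np.nan)
    if smoothing_sigma_bins > 0:
        filled = np.where(defined, rate, 0.0)
        sm = ndimage.gaussian_filter(filled, smoothing_sigma_bins)
        norm = ndimage.gaussian_filter(defined.astype(float), smoothing_sigma_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(defined, sm / norm, np.nan)
    return RateMap(occ.x_edges, occ.y_edges, occ.seconds, rate, smoothing_sigma_bins)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def mutual_information_bits(counts: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a joint count table.

    MI = sum_ij p_ij log2(p_ij / (p_i. p_.j)) with zero-count cells
    contributing zero.
    """
    counts = np.asarray(counts, float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts / total
    pa = p.sum(axis=1, keepdims=True)
    ps = p.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = p * np.log2(p / (pa * ps))
    return float(np.nansum(terms))


def discretize_positions(positions: np.ndarray, arena: Arena,
                         bin_cm: float = 2.0) -> np.ndarray:
    """Map xy samples to linear spatial-bin indices."""
    xe, ye = _edges(arena, bin_cm)
    ix = np.clip(np.digitize(positions[:, 0], xe) - 1, 0, len(xe) - 2)
    iy = np.clip(np.digitize(positions[:, 1], ye) - 1, 0, len(ye) - 2)
    return ix * (len(ye) - 1) + iy


def spatial_mutual_information(activity_states: np.ndarray,
                               position_bins: np.ndarray) -> float:
    """MI (bits) between discretized activity and discretized position."""
    a = np.asarray(activity_states, int)
    s = np.asarray(position_bins, int)
    if len(a) != len(s):
        raise ValueError("activity and position vectors must align")
    if len(np.unique(s)) < 2:
        warnings.warn("single occupied position bin; MI is 0 by definition")
        return 0.0
    na = a.max() + 1
    ns = s.max() + 1
    counts = np.bincount(a * ns + s, minlength=na * ns).reshape(na, ns)
    return mutual_information_bits(counts)


def _mi_binary_shifted(active_idx: np.ndarray, pos_bins: np.ndarray,
                       shifts: np.ndarray, n_pos: int) -> np.ndarray:
    """MI for a binary activity vector circularly shifted by each offset.

    Vectorized over shifts: only the joint counts of the active state move,
    the occupancy and activity marginals are shift-invariant.
    """
    n = len(pos_bins)
    occ = np.bincount(pos_bins, minlength=n_pos).astype(float)
    k = len(active_idx)
    n_sh = len(shifts)
    idx = (active_idx[None, :] + shifts[:, None]) % n
    codes = pos_bins[idx] + n_pos * np.arange(n_sh)[:, None]
    c1 = np.bincount(codes.ravel(), minlength=n_pos * n_sh).reshape(n_sh, n_pos).astype(float)
    c0 = occ[None, :] - c1
    p1, p0 = k / n, 1 - k / n
    ps = occ / n
    mi = np.zeros(n_sh)
    for c, pa in ((c1, p1), (c0, p0)):
        pj = c / n
        with np.errstate(invalid="ignore", divide="ignore"):
            t = pj * np.log2(pj / (pa * ps[None, :]))
        mi += np.nansum(t, axis=1)
    return mi


def shuffle_tuning_test(activity_states: np.ndarray, position_bins: np.ndarray,
                        rng: np.random.Generator, n_shuffles: int = 1000,
                        min_shift_bins: int = 200,
                        percentile: float = 95.0) -> dict:
    """Circular-shift significance test of spatial MI.

    Null MI values come from shifting the activity relative to position by a
    random offset in [min_shift_bins, n - min_shift_bins]; a neuron is tuned
    iff its observed MI exceeds the null's `percentile` (default 95th).
    Binary activity uses a fast vectorized path.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    a = np.asarray(activity_states, int)
    s = np.asarray(position_bins, int)
    n = len(a)
    if n <= 2 * min_shift_bins:
        raise ValueError("session too short for the requested minimum shift")
    shifts = rng.integers(min_shift_bins, n - min_shift_bins, size=n_shuffles)
    observed = spatial_mutual_information(a, s)
    if a.max() <= 1:
        null = _mi_binary_shifted(np.nonzero(a)[0], s, shifts, int(s.max()) + 1)
    else:
        null = np.array([spatial_mutual_information(np.roll(a, sh), s)
                         for sh in shifts])
    thr = float(np.percentile(null, percentile))
    pctl = float(100.0 * np.mean(null < observed))
    return {"mi": observed, "null": null, "threshold": thr,
            "percentile": pctl, "is_tuned": bool(observed > thr)}


def tuned_fractions(flags: np.ndarray, region_labels: np.ndarray) -> pd.DataFrame:
    """Tuned counts and fractions per region (exact integers alongside)."""
    flags = np.asarray(flags, bool)
    region_labels = np.asarray(region_labels)
    rows = []
    for region in pd.unique(region_labels):
        m = region_labels == region
        rows.append({"region": region, "n_tuned": int(flags[m].sum()),
                     "n_total": int(m.sum()),
                     "fraction": float(flags[m].mean())})
    return pd.DataFrame(rows)


def run_tuning(dataset: AlignedDataset, arena: Arena, rng: np.random.Generator,
               bin_cm: float = 2.0, z_threshold: float = 1.0,
               n_shuffles: int = 1000, min_shift_s: float = 20.0,
               percentile: float = 95.0,
               activity_is_z: bool = True) -> pd.DataFrame:
    """Shuffle-MI tuning test for every neuron of an aligned dataset.

    Expects z-scored binned activity; the binary state is binned z >
    z_threshold.  Returns one row per neuron: mi, percentile, is_tuned.
    """
    valid = dataset.valid_mask
    pos_bins = discretize_positions(dataset.bin_positions[valid], arena, bin_cm)
    min_shift_bins = int(round(min_shift_s / dataset.bin_size))
    rows = []
    for i in range(dataset.n_neurons):
        act = (dataset.binned_activity[i, valid] > z_threshold).astype(int)
        res = shuffle_tuning_test(act, pos_bins, rng, n_shuffles=n_shuffles,
                                  min_shift_bins=min_shift_bins,
                                  percentile=percentile)
        rows.append({"neuron_id": dataset.neuron_ids[i],
                     "region": dataset.region_labels[i],
                     "mi_bits": res["mi"], "percentile": res["percentile"],
                     "is_tuned": res["is_tuned"]})
    return pd.DataFrame(rows)
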