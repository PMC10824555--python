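"""Synchronous calcium events (SCEs) and neuronal assemblies.

An SCE is a maximal run of frames in which at least M neurons are
simultaneously active (z-scored trace strictly > 1) lasting more than 500 ms.
M is chosen by scanning candidates and keeping the one that maximizes the
number of detected SCEs (smallest M on ties — a small M gives longer but
fewer events).  Each SCE becomes a binary neuron-participation vector; the
vectors are clustered with a two-stage robust K-means (stage 1: 100
independently seeded K-means runs; stage 2: K-means over the pooled stage-1
centers), K in [2, 10] selected by mean silhouette.  A neuron joins the
assembly of an SCE cluster when its activation rate in that cluster exceeds
the 95th percentile of a label-permutation null; neurons may join several
assemblies or none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .io import PositionTrack, TraceMatrix

__all__ = [
    "SCE", "SCEClustering", "Assembly",
    "detect_sces", "select_m", "sce_matrix", "robust_kmeans",
    "silhouette_mean", "select_k", "assign_assemblies",
    "assembly_positions", "order_by_peak_time",
]


@dataclass
class SCE:
    """One synchronous calcium event (half-open frame interval)."""

    onset_frame: int
    offset_frame: int           # exclusive
    onset_s: float
    offset_s: float
    participation: np.ndarray   # bool per neuron: active at any frame of the run
    peak_coactive: int

    @property
    def n_participants(self) -> int:
        return int(self.participation.sum())


@dataclass
class SCEClustering:
    k: int
    labels: np.ndarray
    centers: np.ndarray
    silhouettes: dict = field(default_factory=dict)   # K candidate -> mean silhouette

    def __post_init__(self) -> None:
        if not 2 <= self.k <= 10:
            raise ValueError("K must lie in [2, 10]")


@dataclass
class Assembly:
    id: int
    members: np.ndarray          # neuron indices
    member_regions: np.ndarray
    sce_cluster: int
    rate_thresholds: np.ndarray  # per-member null 95th percentile used


# ---------------------------------------------------------------------------
# SCE detection
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open (start, stop) pairs."""
    d = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def detect_sces(z_matrix: np.ndarray, m: int, fs: float,
                min_duration: float = 0.5, merge_gap: float = 0.5,
                z_threshold: float = 1.0, t0: float = 0.0) -> list[SCE]:
    """Detect SCEs in a z-scored activity matrix.

    Frames with >= m co-active neurons (z strictly > z_threshold) are marked;
    maximal marked runs separated by less than `merge_gap` seconds are merged
    (bridging brief sub-threshold dropouts within one synchronous episode);
    runs lasting strictly more than `min_duration` seconds become SCEs.
    Participation = active at any frame of the run.
    """
    z = np.atleast_2d(np.asarray(z_matrix, float))
    if m < 2:
        raise ValueError("M must be >= 2")
    if m > z.shape[0]:
        warnings.warn(f"M={m} exceeds the {z.shape[0]} available neurons; no SCEs")
        return []
    gap_frames = max(int(round(merge_gap * fs)), 1)
    active = z > z_threshold
    coactive = active.sum(axis=0)
    runs = _runs(coactive >= m)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap_frames:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if (e - s) / fs > min_duration:
            seg = active[:, s:e]
            out.append(SCE(int(s), int(e), t0 + s / fs, t0 + e / fs,
                           seg.any(axis=1), int(coactive[s:e].max())))
    return out


def select_m(z_matrix: np.ndarray, fs: float,
             candidates: np.ndarray | None = None,
             min_duration: float = 0.5, merge_gap: float = 0.5,
             z_threshold: float = 1.0) -> tuple[int, dict]:
    """Choose M maximizing the number of detected SCEs (smallest M on ties)."""
    z = np.atleast_2d(np.asarray(z_matrix, float))
    if candidates is None:
        candidates = np.arange(2, min(50, z.shape[0]) + 1)
    candidates = np.sort(np.asarray(candidates, int))
    counts = {}
    for m in candidates:
        counts[int(m)] = len(detect_sces(z, int(m), fs, min_duration,
                                         merge_gap, z_threshold))
    best = max(counts.values())
    if best == 0:
        raise ValueError("no SCEs detected at any candidate M")
    m_star = min(m for m, c in counts.items() if c == best)
    return m_star, counts


def sce_matrix(sces: list[SCE]) -> np.ndarray:
    """Stack SCE participation vectors into a binary (n_sces, n_neurons) matrix."""
    if not sces:
        raise ValueError("no SCEs to stack")
    return np.stack([s.participation for s in sces]).astype(float)


# ---------------------------------------------------------------------------
# Two-stage robust K-means and K selection
# ---------------------------------------------------------------------------

def robust_kmeans(X: np.ndarray, k: int, rng: np.random.Generator,
                  n_runs: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage robust K-means (Euclidean).

    Stage 1 runs `n_runs` conventional K-means with independent random-row
    initializations and pools their centers; stage 2 clusters the pooled
    centers with K-means, yielding stable centers.  Final labels assign each
    row of X to its nearest stable center.
    """
    X = np.asarray(X, float)
    if not 2 <= k <= 10:
        raise ValueError("K must lie in [2, 10]")
    if X.shape[0] < k:
        raise ValueError("fewer samples than clusters")
    seeds = rng.integers(0, 2**31 - 1, size=n_runs + 1)
    with warnings.catch_warnings():
        # probing K above the true structure duplicates centers; the empty-
        # cluster check below is the meaningful signal, not sklearn's warning
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        stage1 = np.concatenate([
            KMeans(n_clusters=k, init="random", n_init=1,
                   random_state=int(s)).fit(X).cluster_centers_
            for s in seeds[:-1]])
        stable = KMeans(n_clusters=k, n_init=10,
                        random_state=int(seeds[-1])).fit(stage1).cluster_centers_
    d = np.linalg.norm(X[:, None, :] - stable[None, :, :], axis=2)
    labels = d.argmin(axis=1)
    if len(np.unique(labels)) < k:
        raise ValueError(f"empty cluster at K={k}; use a smaller K")
    return stable, labels


def silhouette_mean(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (Euclidean); singleton clusters contribute 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(np.mean(silhouette_samples(np.asarray(X, float), labels)))


def select_k(X: np.ndarray, rng: np.random.Generator,
             k_range: tuple[int, int] = (2, 10),
             n_runs: int = 100) -> SCEClustering:
    """Run robust K-means for each candidate K and keep the best mean
    silhouette (smallest K on ties)."""
    X = np.asarray(X, float)
    if X.shape[0] < 3:
        raise ValueError("too few SCEs to cluster (need >= 3)")
    k_lo, k_hi = k_range
    if k_lo < 2 or k_hi > 10:
        raise ValueError("K range must lie within [2, 10]")
    results = {}
    sil = {}
    for k in range(k_lo, min(k_hi, X.shape[0] - 1) + 1):
        try:
            centers, labels = robust_kmeans(X, k, rng, n_runs=n_runs)
        except ValueError:
            continue
        results[k] = (centers, labels)
        sil[k] = silhouette_mean(X, labels)
    if not sil:
        raise ValueError("no candidate K produced a valid clustering")
    best = max(sil.values())
    k_star = min(k for k, v in sil.items() if v == best)
    centers, labels = results[k_star]
    return SCEClustering(k_star, labels, centers, sil)


# ---------------------------------------------------------------------------
# Assembly membership
# ---------------------------------------------------------------------------

def assign_assemblies(sce_mat: np.ndarray, labels: np.ndarray,
                      rng: np.random.Generator, n_perm: int = 1000,
                      percentile: float = 95.0,
                      region_labels: np.ndarray | None = None) -> list[Assembly]:
    """Permutation test of per-neuron activation rates within SCE clusters.

    A neuron's activation rate in cluster c is the fraction of cluster-c SCEs
    it participates in; the null permutes the cluster labels over SCEs.  The
    neuron joins the assembly of cluster c iff its observed rate strictly
    exceeds the null's `percentile`.  Neurons may join several assemblies or
    none.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sce_mat = np.asarray(sce_mat, float)
    labels = np.asarray(labels, int)
    n_sces, n_neurons = sce_mat.shape
    ks = np.unique(labels)
    onehot = (labels[:, None] == ks[None, :]).astype(float)
    sizes = onehot.sum(axis=0)
    obs = (onehot.T @ sce_mat) / sizes[:, None]          # (K, n_neurons)
    null = np.empty((n_perm, len(ks), n_neurons))
    for p in range(n_perm):
        perm = rng.permutation(n_sces)
        null[p] = (onehot[perm].T @ sce_mat) / sizes[:, None]
    thr = np.percentile(null, percentile, axis=0)        # (K, n_neurons)
    member = obs > thr
    assemblies = []
    for ci, c in enumerate(ks):
        members = np.nonzero(member[ci])[0]
        regions = (region_labels[members] if region_labels is not None
                   else np.repeat("", len(members)))
        assemblies.append(Assembly(int(ci), members, np.asarray(regions),
                                   int(c), thr[ci, members]))
    return assemblies


# ---------------------------------------------------------------------------
# Assembly characterization
# ---------------------------------------------------------------------------

def assembly_positions(assembly: Assembly, sces: list[SCE], labels: np.ndarray,
                       track: PositionTrack) -> dict:
    """Mouse positions at the onsets of the assembly's cluster's SCEs, plus a
    dispersion statistic (mean pairwise distance) quantifying location
    preference."""
    onsets = np.array([s.onset_s for s, l in zip(sces, labels)
                       if l == assembly.sce_cluster])
    inside = (onsets >= track.times[0]) & (onsets <= track.times[-1])
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} SCE onset(s) outside the tracked "
                      "period; excluded")
    onsets = onsets[inside]
    pos = track.interp(onsets)
    if len(pos) >= 2:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        dispersion = float(d[np.triu_indices(len(pos), 1)].mean())
    else:
        dispersion = np.nan
    return {"onsets": onsets, "positions": pos, "dispersion": dispersion}


def order_by_peak_time(assembly: Assembly, traces: TraceMatrix,
                       sces: list[SCE], labels: np.ndarray,
                       window: float = 10.0) -> dict:
    """Order assembly members by mean peak time in windows around their SCEs.

    For each member and each of the assembly's SCEs, take the trace within
    +-window s of the SCE onset and record the lag of its maximum; order
    members by mean lag ascending.  Members flat in every window are placed
    last and flagged.
    """
    fs = traces.sampling_rate
    half = int(round(window * fs))
    own = [s for s, l in zip(sces, labels) if l == assembly.sce_cluster]
    if not own:
        raise ValueError("assembly's cluster has no SCEs")
    members = assembly.members
    lags = np.full(len(members), np.nan)
    snippets = []
    for mi, nrn in enumerate(members):
        peaks, segs = [], []
        for s in own:
            a = max(s.onset_frame - half, 0)
            b = min(s.onset_frame + half, traces.n_frames)
            seg = traces.values[nrn, a:b]
            segs.append(seg)
            if np.ptp(seg) > 0:
                peaks.append((a + int(np.argmax(seg)) - s.onset_frame) / fs)
        snippets.append(np.concatenate(segs))
        if peaks:
            lags[mi] = float(np.mean(peaks))
    flat = np.isnan(lags)
    order = np.lexsort((members, np.where(flat, np.inf, lags)))
    return {"members": members, "mean_lag_s": lags, "order": order,
            "ordered_members": members[order], "flat_flags": flat,
            "snippets": snippets}
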