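"""Synthetic four-region calcium recordings with known ground truth.

Emulates the data a four-scope hippocampal experiment produces: place-field
modulated Poisson-like spiking along a simulated trajectory, a slow-indicator
calcium forward model, cross-region neuronal assemblies injected as timed
spike bursts, LFP with 1/f background plus ~180 Hz ripple bursts, and
stimulation epochs with a designated responsive subpopulation.  Every
component records its generating parameters so downstream detection stages
can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .config import SyntheticConfig
from .io import Arena, EventTable, LFPRecord, OpenField, PositionTrack, TMaze, TraceMatrix, arena_from_dict

__all__ = [
    "SyntheticGroundTruth", "SyntheticDataset",
    "simulate_trajectory", "simulate_spikes", "spikes_to_calcium",
    "inject_assembly_events", "simulate_lfp", "simulate_stim_experiment",
    "calcium_kernel", "generate_dataset",
]


@dataclass
class SyntheticGroundTruth:
    """Generating parameters recorded for parameter-recovery tests."""

    is_place_cell: np.ndarray
    place_field_centers: np.ndarray          # (n_neurons, 2); NaN for non-place cells
    assembly_membership: list                # list over assemblies of member index arrays
    assembly_event_times: list               # list over assemblies of event-time arrays
    assembly_lags: dict = field(default_factory=dict)   # neuron -> lag s
    ripple_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    responsive_neuron_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    spikes: np.ndarray | None = None         # (n_neurons, n_frames) counts

    def __post_init__(self) -> None:
        for m in self.assembly_membership:
            if len(m) < 2:
                raise ValueError("every assembly needs at least 2 members")


@dataclass
class SyntheticDataset:
    traces: TraceMatrix
    track: PositionTrack
    lfp: LFPRecord
    stim_events: EventTable
    truth: SyntheticGroundTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(arena: Arena, duration: float, fs: float,
                        rng: np.random.Generator,
                        mean_speed: float = 8.0) -> PositionTrack:
    """Simulate a foraging trajectory sampled at fs.

    Open field: smoothed random walk — velocity follows a mean-reverting
    (Ornstein-Uhlenbeck) process, reflecting at the walls.  T-maze:
    alternating trials from the start zone to a randomly chosen reward arm
    along the maze skeleton with speed jitter.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration*fs must give at least 2 samples")
    dt = 1.0 / fs
    times = np.arange(n) * dt
    if isinstance(arena, OpenField):
        theta = 1.0                      # 1/s velocity relaxation
        sigma_v = mean_speed             # stationary per-axis SD ~ mean_speed/sqrt(2)
        xy = np.empty((n, 2))
        xy[0] = (arena.width / 2, arena.height / 2)
        v = rng.normal(0, sigma_v / math.sqrt(2), 2)
        lo = np.zeros(2)
        hi = np.array([arena.width, arena.height])
        for i in range(1, n):
            v = v * (1 - theta * dt) + sigma_v * math.sqrt(dt) * rng.normal(0, 1, 2)
            p = xy[i - 1] + v * dt
            for k in range(2):           # reflect at walls
                if p[k] < lo[k]:
                    p[k] = 2 * lo[k] - p[k]
                    v[k] = -v[k]
                elif p[k] > hi[k]:
                    p[k] = 2 * hi[k] - p[k]
                    v[k] = -v[k]
            xy[i] = np.clip(p, lo, hi)
        return PositionTrack(times, xy, arena)
    if isinstance(arena, TMaze):
        return _tmaze_trajectory(arena, n, dt, rng, mean_speed)
    raise ValueError(f"unknown arena kind: {arena!r}")


def _tmaze_trajectory(arena: TMaze, n: int, dt: float,
                      rng: np.random.Generator, mean_speed: float) -> PositionTrack:
    start = np.array([0.0, 0.0])
    junction = np.array([0.0, arena.stem_length])
    ends = {1: np.array([arena.arm_length, arena.stem_length]),
            -1: np.array([-arena.arm_length, arena.stem_length])}
    xy = []
    pos = start.copy()
    while len(xy) < n:
        side = 1 if rng.random() < 0.5 else -1
        waypoints = [junction, ends[side], junction, start]
        for target in waypoints:
            while len(xy) < n:
                speed = mean_speed * (1.0 + 0.3 * rng.normal())
                speed = max(speed, 1.0)
                step = target - pos
                d = np.hypot(*step)
                if d <= speed * dt:
                    pos = target.copy()
                    xy.append(pos + _lateral_jitter(arena, rng))
                    break
                pos = pos + step / d * speed * dt
                xy.append(pos + _lateral_jitter(arena, rng))
            if len(xy) >= n:
                break
    xy = np.asarray(xy[:n])
    xy = np.where(arena.contains(xy)[:, None], xy, xy * 0.98)  # clamp rare jitter escapes
    return PositionTrack(np.arange(n) * dt, xy, arena, bounds_tol=1e-3)


def _lateral_jitter(arena: TMaze, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(-arena.width / 5, arena.width / 5, 2)


# ---------------------------------------------------------------------------
# Spiking
# ---------------------------------------------------------------------------

def place_field_rate(xy: np.ndarray, center: np.ndarray, sigma: float,
                     baseline: float, peak: float) -> np.ndarray:
    d2 = np.sum((np.asarray(xy) - np.asarray(center)) ** 2, axis=-1)
    return baseline + peak * np.exp(-d2 / (2 * sigma ** 2))


def simulate_spikes(track: PositionTrack, is_place_cell: np.ndarray,
                    centers: np.ndarray, rng: np.random.Generator,
                    sigma_cm: float = 8.0, peak_rate: float = 8.0,
                    baseline_rate: float = 0.1) -> np.ndarray:
    """Bernoulli-per-frame spiking: P(spike in frame) = rate(x, y)/fs.

    Valid for rates well below the frame rate; guarded by a precondition on
    peak+baseline.
    """
    fs = 1.0 / np.median(np.diff(track.times))
    if peak_rate + baseline_rate >= fs:
        raise ValueError("peak+baseline rate must be < sampling rate "
                         "(per-frame probability would reach 1)")
    n_neurons = len(is_place_cell)
    n = track.n_samples
    spikes = np.zeros((n_neurons, n), dtype=np.int8)
    u = rng.random((n_neurons, n))
    for i in range(n_neurons):
        if is_place_cell[i]:
            rate = place_field_rate(track.xy, centers[i], sigma_cm,
                                    baseline_rate, peak_rate)
        else:
            rate = np.full(n, baseline_rate)
        spikes[i] = u[i] < rate / fs
    return spikes


# ---------------------------------------------------------------------------
# Calcium forward model
# ---------------------------------------------------------------------------

def calcium_kernel(fs: float, rise: float = 0.1, decay: float = 1.5) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, peak-normalized to 1."""
    t = np.arange(0, decay * 8, 1.0 / fs)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def spikes_to_calcium(spikes: np.ndarray, fs: float, rng: np.random.Generator,
                      rise: float = 0.1, decay: float = 1.5,
                      noise_sd: float = 0.3,
                      clip_nonnegative: bool = False) -> np.ndarray:
    """Convolve spike counts with the indicator kernel and add white noise."""
    spikes = np.atleast_2d(np.asarray(spikes, float))
    kernel = calcium_kernel(fs, rise, decay)
    traces = signal.fftconvolve(spikes, kernel[None, :], axes=1)[:, :spikes.shape[1]]
    if noise_sd > 0:
        traces = traces + rng.normal(0, noise_sd, traces.shape)
    if clip_nonnegative:
        traces = np.clip(traces, 0, None)
    return traces


# ---------------------------------------------------------------------------
# Assemblies
# ---------------------------------------------------------------------------

def inject_assembly_events(spikes: np.ndarray, fs: float,
                           membership: Sequence[np.ndarray],
                           event_times: Sequence[np.ndarray],
                           lags: dict, rng: np.random.Generator,
                           jitter_s: float = 0.02,
                           burst_spikes: int = 5,
                           burst_span_s: float = 0.4) -> np.ndarray:
    """Superimpose assembly spike bursts on background rasters.

    At each scheduled event every member of the assembly fires a short burst,
    offset by its fixed per-neuron lag (creating a recoverable activation
    sequence) plus Gaussian jitter.  The burst layout keeps members co-active
    long enough for synchronous-event detection (>0.5 s once filtered through
    the slow calcium kernel).
    """
    out = spikes.copy()
    n_frames = spikes.shape[1]
    burst_offsets = np.linspace(0, burst_span_s, burst_spikes)
    for members, times in zip(membership, event_times):
        for t in times:
            for nrn in members:
                lag = lags.get(int(nrn), 0.0)
                jit = rng.normal(0, jitter_s) if jitter_s > 0 else 0.0
                for off in burst_offsets:
                    f = int(round((t + lag + jit + off) * fs))
                    if 0 <= f < n_frames:
                        out[nrn, f] += 1
    return out


def _schedule_events(n_events: int, duration: float, rng: np.random.Generator,
                     min_gap: float = 4.0, margin: float = 5.0,
                     track: PositionTrack | None = None,
                     gate=None) -> np.ndarray:
    """Random event times with a minimum separation, optionally gated to
    trajectory samples inside a spatial region (gate: callable xy -> bool)."""
    if gate is not None and track is not None:
        ok = gate(track.xy)
        candidates = track.times[ok]
        candidates = candidates[(candidates > margin) & (candidates < duration - margin)]
        times: list[float] = []
        for _ in range(20000):
            if len(times) == n_events:
                break
            t = rng.choice(candidates)
            if all(abs(t - s) >= min_gap for s in times):
                times.append(float(t))
        if len(times) < n_events:
            raise RuntimeError("could not schedule the requested events inside "
                               "the gate; lower the count or the minimum gap")
        return np.sort(times)
    # ungated: uniform spacings with the gap built in (always feasible if it fits)
    slack = duration - 2 * margin - (n_events - 1) * min_gap
    if slack <= 0:
        raise RuntimeError("could not schedule the requested events; "
                           "lower the count or the minimum gap")
    u = np.sort(rng.uniform(0, slack, n_events))
    return margin + u + min_gap * np.arange(n_events)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def one_over_f_noise(n: int, fs: float, rng: np.random.Generator,
                     exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    white = rng.normal(0, 1, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = f[1]
    spec *= f ** (-exponent / 2)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def simulate_lfp(duration: float, fs: float, rng: np.random.Generator,
                 n_ripples: int = 10, ripple_freq: float = 180.0,
                 ripple_duration: float = 0.06, snr: float = 5.0,
                 n_channels: int = 1,
                 channel_regions: Sequence[str] | None = None
                 ) -> tuple[LFPRecord, np.ndarray]:
    """1/f background with Hann-windowed ripple bursts injected.

    Ripple amplitude = snr x SD of the 150-250 Hz band-passed background, so
    `snr` is signal-to-noise within the detection band.  `ripple_duration` is
    the envelope's full width at half maximum (the duration a detector
    reports); the Hann window's total support is twice that.  Returns the
    record and the ripple center times (ground truth).
    """
    n = int(round(duration * fs))
    data = np.empty((n_channels, n))
    sos = signal.butter(4, [150, 250], btype="bandpass", fs=fs, output="sos")
    ripple_times = _schedule_events(n_ripples, duration, rng, min_gap=1.0,
                                    margin=1.0) if n_ripples else np.empty(0)
    n_rip = int(round(2 * ripple_duration * fs))
    window = signal.windows.hann(n_rip)
    t_rip = np.arange(n_rip) / fs
    for c in range(n_channels):
        bg = one_over_f_noise(n, fs, rng)
        band_sd = signal.sosfiltfilt(sos, bg).std()
        x = bg.copy()
        for t in ripple_times:
            phase = rng.uniform(0, 2 * np.pi)
            burst = snr * band_sd * window * np.sin(2 * np.pi * ripple_freq * t_rip + phase)
            start = int(round(t * fs)) - n_rip // 2
            sl = slice(max(start, 0), min(start + n_rip, n))
            x[sl] += burst[sl.start - start: sl.stop - start]
        data[c] = x
    if channel_regions is None:
        channel_regions = [f"ch{c}" for c in range(n_channels)]
    return LFPRecord(data, fs, np.asarray(channel_regions)), np.asarray(ripple_times)


# ---------------------------------------------------------------------------
# Stimulation
# ---------------------------------------------------------------------------

def stim_schedule(duration: float, period: float, start: float | None = None) -> np.ndarray:
    """Stimulation onsets: one event per period (default first at one period)."""
    if start is None:
        start = period / 2
    return np.arange(start, duration, period)


def simulate_stim_experiment(n_neurons: int, duration: float, fs: float,
                             rng: np.random.Generator,
                             period: float = 60.0,
                             responsive_ids: np.ndarray | None = None,
                             responsive_fraction: float = 0.1,
                             effect_noise_units: float = 5.0,
                             noise_sd: float = 0.3,
                             baseline_rate: float = 0.1,
                             regions: Sequence[str] = ("RiHP", "RdHP", "LdHP", "LiHP"),
                             sides: Sequence[str] | None = None,
                             ) -> tuple[TraceMatrix, EventTable, np.ndarray]:
    """Baseline activity plus an added calcium transient at each stimulation
    onset for the designated responsive neurons (amplitude = effect size in
    noise-SD units)."""
    import pandas as pd

    n_frames = int(round(duration * fs))
    onsets = stim_schedule(duration, period)
    if responsive_ids is None:
        n_resp = int(round(responsive_fraction * n_neurons))
        responsive_ids = rng.choice(n_neurons, size=n_resp, replace=False)
    responsive_ids = np.sort(np.asarray(responsive_ids, int))
    spikes = (rng.random((n_neurons, n_frames)) < baseline_rate / fs).astype(float)
    traces = spikes_to_calcium(spikes, fs, rng, noise_sd=noise_sd)
    kernel = calcium_kernel(fs)
    amp = effect_noise_units * noise_sd
    for t in onsets:
        f0 = int(round(t * fs))
        seg = kernel[: n_frames - f0]
        traces[responsive_ids, f0:f0 + len(seg)] += amp * seg
    labels = np.repeat(list(regions), int(np.ceil(n_neurons / len(regions))))[:n_neurons]
    tm = TraceMatrix(traces, np.arange(n_neurons), labels, fs)
    attrs = None
    if sides is not None:
        attrs = pd.DataFrame({"side": [sides[i % len(sides)] for i in range(len(onsets))]})
    events = EventTable(onsets, "stimulation", attrs)
    return tm, events, responsive_ids


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SyntheticConfig, rng: np.random.Generator) -> SyntheticDataset:
    """Compose trajectory, spiking, assemblies, calcium, LFP and stimulation
    into one time-consistent dataset with its ground truth."""
    arena = arena_from_dict(cfg.arena)
    track = simulate_trajectory(arena, cfg.duration, cfg.fs, rng)

    regions = list(cfg.regions)
    n_neurons = cfg.n_neurons_per_region * len(regions)
    region_labels = np.repeat(regions, cfg.n_neurons_per_region)

    is_place = np.zeros(n_neurons, bool)
    for r in range(len(regions)):
        block = np.arange(r * cfg.n_neurons_per_region, (r + 1) * cfg.n_neurons_per_region)
        chosen = rng.choice(block, size=int(round(cfg.fraction_place_cells
                                                  * cfg.n_neurons_per_region)),
                            replace=False)
        is_place[chosen] = True
    centers = np.full((n_neurons, 2), np.nan)
    centers[is_place] = _sample_field_centers(arena, int(is_place.sum()), rng)

    spikes = simulate_spikes(track, is_place, centers, rng,
                             sigma_cm=cfg.place_field_sigma_cm,
                             peak_rate=cfg.peak_rate_hz,
                             baseline_rate=cfg.baseline_rate_hz)

    membership: list[np.ndarray] = []
    event_times: list[np.ndarray] = []
    lags: dict[int, float] = {}
    if cfg.n_assemblies > 0:
        membership, lags = _draw_assemblies(cfg, regions, rng)
        gate = None
        if cfg.assembly_location_gated:
            x0, x1, y0, y1 = arena.bounds()
            def gate(xy, _b=(x0, x1, y0, y1)):  # lower-left quadrant of the arena
                return (xy[:, 0] < (_b[0] + _b[1]) / 2) & (xy[:, 1] < (_b[2] + _b[3]) / 2)
        # one joint schedule so events of different assemblies never overlap
        all_times = _schedule_events(cfg.events_per_assembly * cfg.n_assemblies,
                                     cfg.duration, rng,
                                     min_gap=cfg.assembly_min_gap_s,
                                     track=track, gate=gate)
        owner = rng.permutation(np.repeat(np.arange(cfg.n_assemblies),
                                          cfg.events_per_assembly))
        event_times = [np.sort(all_times[owner == a])
                       for a in range(cfg.n_assemblies)]
        spikes = inject_assembly_events(spikes, cfg.fs, membership, event_times,
                                        lags, rng, jitter_s=cfg.assembly_jitter_s,
                                        burst_spikes=cfg.assembly_burst_spikes,
                                        burst_span_s=cfg.assembly_burst_span_s)

    traces = spikes_to_calcium(spikes, cfg.fs, rng, rise=cfg.kernel_rise_s,
                               decay=cfg.kernel_decay_s, noise_sd=cfg.noise_sd,
                               clip_nonnegative=cfg.clip_nonnegative)

    onsets = stim_schedule(cfg.duration, cfg.stim_period_s)
    n_resp = int(round(cfg.responsive_fraction * n_neurons))
    responsive = np.sort(rng.choice(n_neurons, size=n_resp, replace=False)) \
        if n_resp else np.empty(0, int)
    kernel = calcium_kernel(cfg.fs, cfg.kernel_rise_s, cfg.kernel_decay_s)
    amp = cfg.stim_effect_noise_units * cfg.noise_sd
    n_frames = traces.shape[1]
    for t in onsets:
        f0 = int(round(t * cfg.fs))
        if f0 >= n_frames:
            continue
        seg = kernel[: n_frames - f0]
        traces[responsive, f0:f0 + len(seg)] += amp * seg

    tm = TraceMatrix(traces, np.arange(n_neurons), region_labels, cfg.fs)
    lfp, ripple_times = simulate_lfp(cfg.duration, cfg.lfp_fs, rng,
                                     n_ripples=cfg.n_ripples,
                                     ripple_freq=cfg.ripple_freq_hz,
                                     ripple_duration=cfg.ripple_duration_s,
                                     snr=cfg.ripple_snr)
    truth = SyntheticGroundTruth(
        is_place_cell=is_place, place_field_centers=centers,
        assembly_membership=membership, assembly_event_times=event_times,
        assembly_lags=lags, ripple_times=ripple_times,
        responsive_neuron_ids=responsive, spikes=spikes)
    return SyntheticDataset(tm, track, lfp, EventTable(onsets, "stimulation"),
                            truth, cfg)


def _sample_field_centers(arena: Arena, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(arena, OpenField):
        return np.column_stack([rng.uniform(0, arena.width, n),
                                rng.uniform(0, arena.height, n)])
    # T-maze: sample along the skeleton
    stem = arena.stem_length
    arm = arena.arm_length
    total = stem + 2 * arm
    s = rng.uniform(0, total, n)
    pts = np.empty((n, 2))
    on_stem = s < stem
    pts[on_stem] = np.column_stack([np.zeros(on_stem.sum()), s[on_stem]])
    rest = s[~on_stem] - stem
    pts[~on_stem] = np.column_stack([np.where(rest < arm, -rest, rest - arm),
                                     np.full((~on_stem).sum(), stem)])
    return pts


def _draw_assemblies(cfg: SyntheticConfig, regions: list,
                     rng: np.random.Generator) -> tuple[list[np.ndarray], dict]:
    """Disjoint assemblies whose members span all regions; fixed per-neuron
    lags spread over [0, assembly_max_lag_s] define a recoverable sequence."""
    per_region = cfg.n_neurons_per_region
    n_regions = len(regions)
    pools = [rng.permutation(np.arange(r * per_region, (r + 1) * per_region))
             for r in range(n_regions)]
    cursors = [0] * n_regions
    membership = []
    lags: dict[int, float] = {}
    for a in range(cfg.n_assemblies):
        members = []
        for j in range(cfg.assembly_size):
            # rotate the starting region per assembly so uneven sizes stay balanced
            r = (j + a) % n_regions
            if cursors[r] >= per_region:
                raise ValueError("not enough neurons per region for the requested assemblies")
            members.append(int(pools[r][cursors[r]]))
            cursors[r] += 1
        members = np.asarray(sorted(members))
        lag_values = np.linspace(0, cfg.assembly_max_lag_s, len(members))
        for nrn, lag in zip(members, rng.permutation(lag_values)):
            lags[int(nrn)] = float(lag)
        membership.append(members)
    return membership, lags
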