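"""Core data containers and file I/O.

Conventions used throughout the package: times are seconds from recording
start, positions are cm, all intervals are half-open ``[start, end)`` and
frame indices are 0-based.  Delimited tables are comma-separated UTF-8 with a
mandatory header row; scalar metadata travels in ``#``-prefixed key=value
lines before the header.  Matrices go to HDF5 with one group per region.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Arena",
    "OpenField",
    "TMaze",
    "TraceMatrix",
    "PositionTrack",
    "EventTable",
    "LFPRecord",
    "read_traces",
    "write_traces",
    "read_positions",
    "write_positions",
    "read_events",
    "write_events",
    "read_lfp",
    "write_lfp",
    "arena_from_dict",
]


# ---------------------------------------------------------------------------
# Arena geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpenField:
    """Rectangular open-field arena with corner at the origin (cm)."""

    width: float = 40.0
    height: float = 40.0
    kind: str = field(default="open_field", init=False)

    def contains(self, xy: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        xy = np.asarray(xy, float)
        return (
            (xy[..., 0] >= -tol)
            & (xy[..., 0] <= self.width + tol)
            & (xy[..., 1] >= -tol)
            & (xy[..., 1] <= self.height + tol)
        )

    def bounds(self) -> tuple[float, float, float, float]:
        return (0.0, self.width, 0.0, self.height)

    def to_dict(self) -> dict:
        return {"kind": "open_field", "width": self.width, "height": self.height}


@dataclass(frozen=True)
class TMaze:
    """T-shaped maze: a vertical stem from (0, 0) to (0, stem_length) joining
    a horizontal arm spanning (-arm_length, stem_length)..(arm_length,
    stem_length); corridors have the given width.  The start zone is the
    bottom of the stem."""

    stem_length: float = 40.0
    arm_length: float = 30.0
    width: float = 6.0

    kind: str = field(default="t_maze", init=False)

    def _dist_to_skeleton(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        x, y = xy[..., 0], xy[..., 1]
        # stem: segment x=0, y in [0, stem_length]
        d_stem = np.hypot(x, np.clip(y, 0.0, self.stem_length) - y)
        # arm: segment y=stem_length, x in [-arm_length, arm_length]
        d_arm = np.hypot(np.clip(x, -self.arm_length, self.arm_length) - x,
                         self.stem_length - y)
        return np.minimum(d_stem, d_arm)

    def contains(self, xy: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        return self._dist_to_skeleton(xy) <= self.width / 2 + tol

    def bounds(self) -> tuple[float, float, float, float]:
        w = self.width / 2
        return (-self.arm_length - w, self.arm_length + w, -w, self.stem_length + w)

    def to_dict(self) -> dict:
        return {
            "kind": "t_maze",
            "stem_length": self.stem_length,
            "arm_length": self.arm_length,
            "width": self.width,
        }


Arena = OpenField | TMaze


def arena_from_dict(d: dict) -> Arena:
    d = dict(d)
    kind = d.pop("kind")
    if kind == "open_field":
        return OpenField(**d)
    if kind == "t_maze":
        return TMaze(**d)
    raise ValueError(f"unknown arena kind: {kind!r}")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TraceMatrix:
    """Per-neuron fluorescence time series with region labels.

    values : (n_neurons, n_frames) float array, arbitrary fluorescence units
    region_labels : one label per neuron (e.g. RiHP/RdHP/LdHP/LiHP)
    sampling_rate : imaging frame rate, Hz
    t0 : time of frame 0, seconds
    """

    values: np.ndarray
    neuron_ids: np.ndarray
    region_labels: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.neuron_ids = np.asarray(self.neuron_ids)
        self.region_labels = np.asarray(self.region_labels)
        if self.values.shape[0] < 1:
            raise ValueError("TraceMatrix needs at least one neuron")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.region_labels) != self.values.shape[0]:
            raise ValueError("region_labels length must equal n_neurons")
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length must equal n_neurons")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(f"NaN in traces at neuron row {i}, frame {j}")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.sampling_rate

    def subset(self, idx: np.ndarray) -> "TraceMatrix":
        idx = np.asarray(idx)
        return TraceMatrix(self.values[idx], self.neuron_ids[idx],
                           self.region_labels[idx], self.sampling_rate, self.t0)


@dataclass
class PositionTrack:
    """Timestamped 2-D positions within an arena (times s, xy cm)."""

    times: np.ndarray
    xy: np.ndarray
    arena: Arena
    bounds_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.xy = np.asarray(self.xy, float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be (n_samples, 2)")
        if len(self.times) != len(self.xy):
            raise ValueError("times and xy length mismatch")
        bad = np.nonzero(np.diff(self.times) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"times must be strictly increasing; first violation at sample "
                f"{bad[0] + 1} (t={self.times[bad[0] + 1]!r} after t={self.times[bad[0]]!r})")
        inside = self.arena.contains(self.xy, tol=self.bounds_tol)
        if not inside.all():
            i = int(np.argmin(inside))
            raise ValueError(f"position sample {i} at {self.xy[i]} outside arena bounds")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of xy at times t (clipped to track range)."""
        t = np.asarray(t, float)
        x = np.interp(t, self.times, self.xy[:, 0])
        y = np.interp(t, self.times, self.xy[:, 1])
        return np.column_stack([x, y])


@dataclass
class EventTable:
    """Timestamped events of one kind with optional per-event attributes."""

    onset_times: np.ndarray
    kind: str = "stimulation"
    attributes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, float)
        if np.any(np.diff(self.onset_times) < 0):
            raise ValueError("onset_times must be sorted ascending")
        if self.attributes is not None and len(self.attributes) != len(self.onset_times):
            raise ValueError("attributes must have one row per event")

    @property
    def n_events(self) -> int:
        return len(self.onset_times)

    def select(self, column: str, value) -> "EventTable":
        if self.attributes is None or column not in self.attributes:
            raise KeyError(f"event attribute {column!r} missing")
        m = (self.attributes[column] == value).to_numpy()
        return EventTable(self.onset_times[m], self.kind,
                          self.attributes.loc[m].reset_index(drop=True))


@dataclass
class LFPRecord:
    """Multi-channel LFP (channels x samples, arbitrary reference)."""

    data: np.ndarray
    sampling_rate: float
    channel_regions: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        self.channel_regions = np.asarray(self.channel_regions)
        if self.sampling_rate < 600:
            raise ValueError("LFP sampling rate must be >= 600 Hz "
                             "(Nyquist margin above the 250 Hz ripple band)")
        if len(self.channel_regions) != self.data.shape[0]:
            raise ValueError("channel_regions length must equal n_channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


# ---------------------------------------------------------------------------
# Delimited-table metadata helpers
# ---------------------------------------------------------------------------

def _write_meta(fh, meta: dict) -> None:
    fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")


def _read_meta(path: Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        line = fh.readline()
    if not line.startswith("#"):
        return {}
    return json.loads(line[1:].strip())


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def write_traces(tm: TraceMatrix, path: str | Path, format: str = "csv") -> Path:
    path = Path(path)
    if format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _write_meta(fh, {"sampling_rate": tm.sampling_rate, "t0": tm.t0})
            df = pd.DataFrame(tm.values,
                              columns=[f"f{j}" for j in range(tm.n_frames)])
            df.insert(0, "neuron_id", tm.neuron_ids)
            df.insert(1, "region", tm.region_labels)
            # %.17g survives the text round trip bit-exactly
            df.to_csv(fh, index=False, float_format="%.17g")
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            for region in pd.unique(tm.region_labels):
                m = tm.region_labels == region
                g = f.create_group(str(region))
                g.create_dataset("traces", data=tm.values[m])
                g.create_dataset(
                    "neuron_ids",
                    data=np.asarray(tm.neuron_ids[m], dtype="S"))
                g.attrs["sampling_rate"] = tm.sampling_rate
                g.attrs["t0"] = tm.t0
    else:
        raise ValueError(f"unknown trace format {format!r}")
    return path


def read_traces(path: str | Path, format: str = "csv",
                nan_policy: str = "reject") -> TraceMatrix:
    """Load a TraceMatrix from CSV or HDF5.

    nan_policy: 'reject' raises naming the offending cell; 'interpolate'
    fills NaNs by per-neuron linear interpolation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        meta = _read_meta(path)
        df = pd.read_csv(path, comment="#")
        if "region" not in df.columns:
            raise ValueError("trace table is missing the 'region' label column")
        ids = df["neuron_id"].to_numpy()
        regions = df["region"].to_numpy()
        frame_cols = [c for c in df.columns if c.startswith("f")]
        vals = df[frame_cols].to_numpy(dtype=object)
        numeric = pd.DataFrame(df[frame_cols]).apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy() & ~pd.isna(vals.astype(object)))
        values = numeric.to_numpy(float)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-numeric cell in traces at row {i} ({ids[i]!r}), column {frame_cols[j]}")
        values = _apply_nan_policy(values, ids, nan_policy)
        return TraceMatrix(values, ids, regions,
                           float(meta.get("sampling_rate", 0.0)) or _require_fs(meta),
                           float(meta.get("t0", 0.0)))
    if format == "hdf5":
        blocks, ids, regions = [], [], []
        fs = t0 = None
        with h5py.File(path, "r") as f:
            for region in sorted(f.keys()):
                g = f[region]
                blocks.append(np.asarray(g["traces"]))
                ids.append(np.asarray(g["neuron_ids"]).astype(str))
                regions.append(np.repeat(region, blocks[-1].shape[0]))
                fs = float(g.attrs["sampling_rate"])
                t0 = float(g.attrs["t0"])
        values = _apply_nan_policy(np.vstack(blocks), np.concatenate(ids), nan_policy)
        return TraceMatrix(values, np.concatenate(ids), np.concatenate(regions), fs, t0)
    raise ValueError(f"unknown trace format {format!r}")


def _require_fs(meta: dict) -> float:
    raise ValueError("trace file metadata line lacks 'sampling_rate'")


def _apply_nan_policy(values: np.ndarray, ids: np.ndarray, policy: str) -> np.ndarray:
    nan = np.isnan(values)
    if not nan.any():
        return values
    if policy == "reject":
        i, j = np.argwhere(nan)[0]
        raise ValueError(f"NaN cell in traces at neuron {ids[i]!r} (row {i}), frame {j}")
    if policy == "interpolate":
        out = values.copy()
        x = np.arange(values.shape[1])
        for i in np.nonzero(nan.any(axis=1))[0]:
            good = ~nan[i]
            if not good.any():
                raise ValueError(f"neuron {ids[i]!r} is all-NaN; cannot interpolate")
            out[i, nan[i]] = np.interp(x[nan[i]], x[good], values[i, good])
        return out
    raise ValueError(f"unknown nan_policy {policy!r}")


# ---------------------------------------------------------------------------
# Positions
# ---------------------------------------------------------------------------

def write_positions(track: PositionTrack, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_meta(fh, {"arena": track.arena.to_dict()})
        pd.DataFrame({"time": track.times,
                      "x": track.xy[:, 0],
                      "y": track.xy[:, 1]}).to_csv(fh, index=False, float_format="%.12g")
    return path


def read_positions(path: str | Path, arena: Arena | None = None,
                   bounds_tol: float = 1e-6) -> PositionTrack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    for col in ("time", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"position table missing column {col!r}")
    if arena is None:
        if "arena" not in meta:
            raise ValueError("no arena metadata in file and none supplied")
        arena = arena_from_dict(meta["arena"])
    return PositionTrack(df["time"].to_numpy(float),
                         df[["x", "y"]].to_numpy(float), arena,
                         bounds_tol=bounds_tol)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_meta(fh, {"kind": events.kind})
        df = pd.DataFrame({"onset_time": events.onset_times})
        if events.attributes is not None:
            df = pd.concat([df, events.attributes.reset_index(drop=True)], axis=1)
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def read_events(path: str | Path) -> EventTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    if "onset_time" not in df.columns:
        raise ValueError("event table missing 'onset_time' column")
    attrs = df.drop(columns=["onset_time"])
    return EventTable(df["onset_time"].to_numpy(float),
                      str(meta.get("kind", "stimulation")),
                      attrs if len(attrs.columns) else None)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def write_lfp(lfp: LFPRecord, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=lfp.data)
        d.attrs["sampling_rate"] = lfp.sampling_rate
        d.attrs["t0"] = lfp.t0
        f.create_dataset("channel_regions",
                         data=np.asarray(lfp.channel_regions, dtype="S"))
    return path


def read_lfp(path: str | Path) -> LFPRecord:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        d = f["lfp"]
        return LFPRecord(np.asarray(d), float(d.attrs["sampling_rate"]),
                         np.asarray(f["channel_regions"]).astype(str),
                         float(d.attrs["t0"]))
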