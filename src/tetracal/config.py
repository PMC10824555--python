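"""Run configuration: every tunable of every pipeline stage, with defaults,
serializable to/from YAML or JSON.  Unknown keys are rejected so that typos in
config files fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SyntheticConfig", "PreprocessConfig", "TuningConfig", "SCEConfig",
    "DecodingConfig", "EphysConfig", "StimConfig", "RunConfig",
    "load_config", "save_config",
]


@dataclass
class SyntheticConfig:
    """Generator settings for four-region synthetic recordings.

    Rates in Hz, durations/times in s, distances in cm.  The calcium kernel
    defaults (0.1 s rise, 1.5 s decay) emulate the slow GCaMP6s indicator;
    noise_sd is relative to the unit-normalized single-transient amplitude.
    """

    duration: float = 1200.0
    fs: float = 20.0
    arena: dict = field(default_factory=lambda: {
        "kind": "open_field", "width": 40.0, "height": 40.0})
    regions: list = field(default_factory=lambda: ["RiHP", "RdHP", "LdHP", "LiHP"])
    n_neurons_per_region: int = 100
    fraction_place_cells: float = 0.3
    place_field_sigma_cm: float = 8.0
    peak_rate_hz: float = 8.0
    baseline_rate_hz: float = 0.1
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.5
    noise_sd: float = 0.3
    clip_nonnegative: bool = False
    # assemblies
    n_assemblies: int = 4
    assembly_size: int = 15
    events_per_assembly: int = 25
    assembly_max_lag_s: float = 0.45
    assembly_jitter_s: float = 0.02
    assembly_burst_spikes: int = 5
    assembly_burst_span_s: float = 0.4
    assembly_min_gap_s: float = 8.0
    assembly_location_gated: bool = False
    # LFP / ripples
    lfp_fs: float = 1000.0
    n_ripples: int = 10
    ripple_freq_hz: float = 180.0
    ripple_duration_s: float = 0.06
    ripple_snr: float = 5.0
    # stimulation
    stim_period_s: float = 60.0
    stim_duration_s: float = 1.0
    responsive_fraction: float = 0.1
    stim_effect_noise_units: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_place_cells <= 1:
            raise ValueError("fraction_place_cells must be in [0, 1]")
        if not 0 <= self.responsive_fraction <= 1:
            raise ValueError("responsive_fraction must be in [0, 1]")
        for name in ("peak_rate_hz", "baseline_rate_hz", "noise_sd",
                     "ripple_snr", "stim_period_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PreprocessConfig:
    bin_size_s: float = 0.1
    nan_policy: str = "reject"
    trim_threshold: float = 0.0
    trim_min_run_s: float = 5.0


@dataclass
class TuningConfig:
    spatial_bin_cm: float = 2.0
    smoothing_sigma_bins: float = 1.0
    min_occupancy_s: float = 0.2
    activity_z_threshold: float = 1.0
    n_shuffles: int = 1000
    min_shift_s: float = 20.0
    percentile: float = 95.0


@dataclass
class SCEConfig:
    z_threshold: float = 1.0
    min_duration_s: float = 0.5
    merge_gap_s: float = 0.5
    m_candidates_max: int = 50
    k_min: int = 2
    k_max: int = 10
    n_kmeans_runs: int = 100
    n_permutations: int = 1000
    participation_percentile: float = 95.0


@dataclass
class DecodingConfig:
    decoder: str = "ridge"         # ridge | mlp | lstm
    n_folds: int = 10
    window_bins: int = 5
    ridge_alpha: float = 1.0
    min_shift_bins: int = 2000
    n_chance_reps: int = 5


@dataclass
class EphysConfig:
    band_low_hz: float = 150.0
    band_high_hz: float = 250.0
    filter_order: int = 4
    envelope_smooth_s: float = 0.005
    z_on: float = 3.0
    z_peak: float = 5.0
    min_duration_s: float = 0.03
    max_duration_s: float = 0.2
    merge_gap_s: float = 0.01
    calcium_window_s: float = 2.0
    sync_z: float = 1.0
    sync_window_s: float = 0.5


@dataclass
class StimConfig:
    window_s: float = 2.0
    alpha: float = 0.05
    bh_correction: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    sce: SCEConfig = field(default_factory=SCEConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    ephys: EphysConfig = field(default_factory=EphysConfig)
    stim: StimConfig = field(default_factory=StimConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _build(cls, d, path="")


def _build(cls: type, d: dict, path: str) -> Any:
    """Instantiate a (possibly nested) config dataclass, rejecting unknown keys."""
    if not isinstance(d, dict):
        raise TypeError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) in {path or '<root>'}: "
                         f"{', '.join(sorted(unknown))}")
    kwargs = {}
    for name, value in d.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) or (
                isinstance(f.default_factory, type)
                and dataclasses.is_dataclass(f.default_factory)):
            kwargs[name] = _build(f.default_factory, value,
                                  path=f"{path}.{name}" if path else name)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text) or {}
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ValueError(f"config must be .yaml/.yml/.json, got {path.suffix!r}")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")
    elif path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True), encoding="utf-8")
    else:
        raise ValueError(f"config must be .yaml/.yml/.json, got {path.suffix!r}")
    return path
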