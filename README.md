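# tetracal

Downstream analysis for multi-region single-neuron calcium recordings —
the kind produced by implanting several miniature head-mounted microscopes
over different hippocampal subregions of a freely behaving mouse and
extracting one fluorescence trace per neuron. The package takes extracted
traces (neurons × frames, with a region label per neuron), the animal's
position track, stimulation event times and LFP channels, and provides the
standard population analyses for such experiments:

- **Spatial tuning** — plug-in mutual information
  `I(A;S) = Σ p(a,s) log₂ p(a,s)/(p(a)p(s))` between a neuron's binarized
  activity (z > 1) and the discretized position, tested against a circular
  time-shift null (≥ 20 s shifts, 95th-percentile criterion), plus
  occupancy-normalized, Gaussian-smoothed place-field rate maps.
- **Synchronous calcium events (SCEs) and assemblies** — an SCE is a run of
  frames with at least *M* co-active neurons (z > 1) lasting more than
  500 ms; *M* is chosen to maximize the number of detected SCEs (smallest
  *M* on ties). SCE participation vectors are clustered by two-stage robust
  K-means (100 independently seeded runs, then K-means over the pooled
  centers), with K ∈ [2, 10] selected by mean silhouette. A neuron joins the
  assembly of a cluster when its activation rate there exceeds the 95th
  percentile of a cluster-label permutation null. Assemblies are then
  characterized by the animal's position at their SCEs and by member
  activation order (mean peak lag in ±10 s windows).
- **Position decoding** — ridge regression (reference decoder; feedforward
  MLP and an LSTM variant available) on sliding windows of the previous
  N = 5 population activity bins (100-ms bins), 10-fold cross-validation
  over contiguous temporal blocks, with a chance level from re-fitting on
  time-flipped, cycle-shifted (≥ 2000 bins) positions, and per-region-subset
  comparisons (Mann-Whitney vs chance, Wilcoxon signed-rank between subsets).
- **Sharp-wave ripples** — zero-phase 150–250 Hz band-pass, smoothed Hilbert
  envelope, z-based onset/peak thresholds (3/5) with duration limits, and
  ripple-triggered calcium snippets with per-ripple synchronous neuron sets.
- **Stimulation responses** — noise-normalized, onset-centered trial
  snippets; paired Wilcoxon signed-rank tests of 2-s pre/post means per
  neuron (Benjamini-Hochberg corrected) and at the population level, with
  per-attribute splits (e.g. left vs right stimulation site).

Because public recordings of this kind are not available, the package ships
a first-class synthetic data generator (`tetracal.synthetic`) that emulates
four-region recordings with known ground truth: place-field-modulated
Bernoulli spiking along simulated open-field or T-maze trajectories, a
difference-of-exponentials calcium forward model (0.1 s rise / 1.5 s decay,
slow-indicator-like), cross-region assemblies injected as lagged spike
bursts, 1/f LFP with injected 180 Hz ripple bursts, and stimulation epochs
with a designated responsive subpopulation. Every analysis stage is tested
by recovering the generator's parameters.

## Worked example

```python
import numpy as np
import tetracal as tc
from tetracal.config import SyntheticConfig
from tetracal import decoding as dec

rng = np.random.default_rng(7)

# session A: synchronous-event / assembly analysis
cfg_a = SyntheticConfig(duration=600.0, n_neurons_per_region=12,
                        n_assemblies=3, assembly_size=16,
                        events_per_assembly=20, baseline_rate_hz=0.0,
                        fraction_place_cells=0.0, noise_sd=0.02)
ds_a = tc.generate_dataset(cfg_a, rng)
z = tc.zscore_traces(ds_a.traces)
m_star, _ = tc.select_m(z, ds_a.traces.sampling_rate)
sces = tc.detect_sces(z, m_star, ds_a.traces.sampling_rate)
print(f"M* = {m_star} -> {len(sces)} synchronous calcium events")
X = tc.sce_matrix(sces)
clustering = tc.select_k(X, rng)
assemblies = tc.assign_assemblies(X, clustering.labels, rng,
                                  region_labels=ds_a.traces.region_labels)
print(f"K* = {clustering.k} SCE clusters "
      f"(mean silhouette {clustering.silhouettes[clustering.k]:.2f})")

# session B: spatial tuning and position decoding
rng = np.random.default_rng(11)
cfg_b = SyntheticConfig(duration=600.0, n_neurons_per_region=40,
                        n_assemblies=0, n_ripples=0, responsive_fraction=0.0)
ds_b = tc.generate_dataset(cfg_b, rng)
z = tc.zscore_traces(ds_b.traces)
binned = tc.align_and_bin(ds_b.traces, ds_b.track, 0.1, activity=z)
tuning = tc.run_tuning(binned, ds_b.track.arena, rng, n_shuffles=300)
frac = tc.tuned_fractions(tuning.is_tuned.to_numpy(), tuning.region.to_numpy())
print("spatially tuned neurons per region:")
for _, row in frac.iterrows():
    print(f"  {row.region}: {row.n_tuned}/{row.n_total}")
Xw, y, _ = dec.build_windows(binned.binned_activity, binned.bin_positions,
                             5, binned.valid_mask)
res = dec.crossval_decode(Xw, y, "ridge", 10, rng)
chance = dec.chance_level(Xw, y, rng, n_reps=2)
print(f"decoding error {res.mean_of_medians:.2f} +/- {res.sem_of_medians:.2f} cm "
      f"(chance {chance.mean_of_medians:.2f} cm)")
```

This prints:

```
M* = 2 -> 60 synchronous calcium events
K* = 3 SCE clusters (mean silhouette 1.00)
spatially tuned neurons per region:
  RiHP: 12/40
  RdHP: 13/40
  LdHP: 13/40
  LiHP: 13/40
decoding error 5.78 +/- 0.17 cm (chance 18.47 cm)
```

The 60 injected assembly events are all detected, cluster into exactly the
3 generated assemblies (each with all 16 true members across the four
regions, Jaccard 1.0 against ground truth), roughly the generated 30% of
place cells are flagged spatially tuned, and the decoded position error sits
far below the shuffled chance level.

## Command line

```
tetracal simulate   --config cfg.yaml --seed 1 --out data/
tetracal tune       --config cfg.yaml --data data/ --out results/
tetracal assemblies --config cfg.yaml --data data/ --out results/
tetracal decode     --config cfg.yaml --data data/ --out results/
tetracal ripples    --config cfg.yaml --data data/ --out results/
tetracal stim       --config cfg.yaml --data data/ --out results/
tetracal all        --config cfg.yaml --seed 1 --out run/
```

All tunables live in one YAML/JSON config (unknown keys are rejected);
outputs are CSV tables plus HDF5 matrices, and are byte-identical across
runs with the same seed.

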