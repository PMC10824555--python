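# Methods

This note documents the models, defaults, and numerical choices behind each
pipeline stage, what the synthetic generator does and does not emulate, and
the known limitations.

## Conventions

Times are seconds from recording start; positions are cm; all intervals are
half-open `[start, end)`; frame indices are 0-based. One master seed drives
a NumPy `Generator` per stage; every stochastic operation takes its RNG
explicitly, which makes the full pipeline byte-reproducible.

## Preprocessing

**Noise level.** `estimate_noise_level` uses the robust first-difference
estimator `median(|x[t+1] − x[t]|) / (0.6745·√2)`. First differencing
removes the slow transient component; the MAD makes the estimate insensitive
to sparse large excursions. It is scale-equivariant and returns 0 for a
constant trace. A power-spectral high-band estimator would also work; the
difference-MAD form is simpler to test and adequate for sparse transients.

**z-scoring** is per neuron over the whole session (not sliding), so a
single "z > 1" threshold means the same thing for event detection, tuning
discretization and ripple-synchronous activity. Constant traces map to zeros
and are flagged.

**Alignment/binning.** Activity and positions are averaged in consecutive
100-ms bins (configurable) tiling the overlap of the trace and track time
ranges; bins with no position sample are masked. Bin assignment uses
epsilon-guarded floor arithmetic so frames sitting exactly on a bin edge are
deterministic.

**Silent-end trimming** automates the manual removal of inactive periods at
session boundaries: leading/trailing runs of bins (≥ 5 s) with
population-mean activity below a threshold (default 0) are dropped; interior
bins are never touched.

**Onset-centering.** Event-aligned snippets are divided by the neuron's
estimated noise level and shifted so the value at the onset frame is zero,
making pre/post comparisons invariant to per-neuron gain and offset.

## Spatial tuning

Activity is binarized at binned z > 1 (consistent with the synchronous-event
definition); positions are discretized to 2-cm bins (a standard choice for
mouse place fields at these arena sizes). The tuning statistic is plug-in
mutual information in bits; significance comes from circularly shifting the
activity relative to the trajectory by a random offset of at least 20 s
(1000 shuffles by default), which preserves both signals' autocorrelation
while destroying their relationship. A neuron is tuned when its MI exceeds
the null's 95th percentile — one-sided, uncorrected, mirroring the
assembly-participation criterion; a Benjamini-Hochberg variant is a config
flag away. Calibration on spatially untuned cells gives a type-I rate of
~0.05.

Rate maps are occupancy-normalized mean activity per 2-cm bin; bins visited
for less than 0.2 s are undefined. Smoothing (default σ = 2 bins) uses
normalized convolution so undefined bins neither leak nor shrink the map.
For the binary-activity MI null, a vectorized path computes all shuffles'
joint counts in one `bincount`, since only the active state's counts move
under a circular shift.

## Synchronous calcium events and assemblies

An SCE is a maximal run of frames with at least M neurons strictly above
z = 1 lasting strictly more than 500 ms (at 20 Hz: at least 11 frames). Runs
separated by less than 0.5 s are merged first: with a 1.5-s-decay indicator,
brief sub-threshold dropouts otherwise fragment one synchronous episode into
several, and fragmented background-coactivity runs inflate the SCE count at
small M, which the M-selection rule would then favor. Half the minimum event
duration is the natural bridging scale. Participation is "active at any
frame of the run".

M is selected by scanning candidates (2 … min(50, n_neurons)) and keeping
the count-maximizing value, smallest on ties (a small M gives longer but
fewer events). Clustering is two-stage robust K-means on the binary SCE ×
neuron matrix (Euclidean): stage 1 runs 100 K-means with independent
random-row initializations; stage 2 clusters the pooled 100·K centers with
K-means (seeded once from the master RNG), and rows are assigned to the
nearest stable center. K ∈ [2, 10] is chosen by mean silhouette (singleton
clusters contribute 0; smallest K on ties). An empty final cluster raises
rather than silently reducing K; the K-selection loop skips such candidates.

Assembly membership uses a permutation null: the activation rate r(n, c) =
fraction of cluster-c SCEs neuron n participates in, compared against the
95th percentile of r under 1000 random permutations of the cluster labels.
Membership requires strictly exceeding the percentile; neurons may join
several assemblies or none. On label-permuted data the per-(neuron, cluster)
membership rate calibrates to ≈ 0.04–0.05 (slightly below 0.05 because the
discrete null ties at the threshold are excluded).

Assemblies are characterized by the animal's position at their SCE onsets
(with mean pairwise distance as a dispersion statistic) and by member
activation order: mean peak lag across ±10-s windows around the cluster's
SCEs, flat members flagged and placed last.

## Position decoding

Each decoded sample holds the previous N = 5 bins of every neuron's activity
(flattened, time-major). Folds are contiguous temporal blocks — with slow
calcium, interleaved bins would leak training information into the test
fold. The reference decoder is ridge regression with intercept (α = 1),
solved by Cholesky on the normal equations; its per-fold factorization is
reused across the chance-level repetitions, where only the targets change.
A feedforward MLP (scikit-learn) is available; an LSTM decoder (200 units,
dropout 0.25, 10 epochs) is provided for parity but needs torch and is
excluded from reproducibility guarantees. The chance level flips the
position sequence in time and circularly shifts it by at least 2000 bins
(enforced), re-running the full cross-validation; 5 repetitions are pooled.
Region-subset comparisons report per-fold medians, Mann-Whitney tests
against each subset's chance level, and Wilcoxon signed-rank tests pairing
each subset's fold medians with the pooled set's.

Pooling all four regions reliably beats the best single region only when the
effective sample size supports the larger model: bins are autocorrelated
over the indicator timescale, so short sessions overfit the pooled design.
The decoding evaluation therefore uses 40-minute sessions (24 000 bins),
matching the scale of real recordings of this kind; the generator's default
session is 20 minutes as a runtime compromise.

## Ephys

Band-pass filtering is a 4th-order zero-phase Butterworth (150–250 Hz,
forward-backward). The ripple envelope is the Hilbert magnitude smoothed
with a 5-ms Gaussian; detection z-scores the envelope and requires: onset
threshold z > 3 sustained, peak z ≥ 5, duration 30–200 ms, events closer
than 10 ms merged. Detection is z-based and therefore invariant to
amplitude rescaling. The 30-ms minimum duration separates 60-ms ripples
(~50 ms above the onset threshold) from band-limited noise bursts, which
reach peak z ≥ 5 only for ≤ ~30 ms. The event midpoint (onset+offset)/2 is
the recommended event time for matching against references — the envelope
argmax wobbles by up to ~25 ms at moderate SNR. Spectrograms are Hann-window
short-time power densities (Parseval-consistent). Ripple-triggered calcium
returns onset-centered z-score snippets and, per ripple, the set of neurons
with z > 1 within 0.5 s of the ripple.

## Stimulation responses

Per trial, activity is averaged over `[onset − 2 s, onset)` and
`[onset, onset + 2 s)` on noise-normalized, onset-centered traces; windows
wider than the smallest inter-stimulus gap raise an error. Per-neuron tests
are paired Wilcoxon signed-rank with Benjamini-Hochberg correction (default
on; a flag disables it); a neuron is responsive when the adjusted p < 0.05
and its post-mean exceeds its pre-mean. The population test applies the same
paired Wilcoxon to per-trial means of the region-mean fluorescence. The
per-neuron test statistic was chosen to match the population-level test; the
pre/post windows follow the package's global half-open convention.

## Synthetic generator

The generator emulates what the pipeline needs to be testable, not the
imaging physics:

- **Trajectories**: open field — mean-reverting (OU) velocity with wall
  reflection; T-maze — alternating start → random reward arm trips along the
  maze skeleton with speed jitter. Default mean speed 8 cm/s.
- **Spiking**: Bernoulli per frame with p = rate/fs (valid for rates well
  below the 20 Hz frame rate; guarded). Place cells follow
  `rate = baseline + peak·exp(−d²/2σ²)` with σ = 8 cm, peak 8 Hz, baseline
  0.1 Hz, 30% place cells per region.
- **Calcium**: difference-of-exponentials kernel (0.1 s rise, 1.5 s decay),
  peak-normalized, plus i.i.d. Gaussian noise (SD 0.3 of the unit transient).
  The model is linear in spikes.
- **Assemblies**: disjoint member sets spanning all regions (per-assembly
  region rotation keeps uneven sizes balanced); events drawn on one joint
  schedule with a minimum gap (default 8 s) so events of different
  assemblies never overlap; each member fires a 5-spike burst at its fixed
  per-neuron lag (spread over 0–0.45 s) plus jitter, long enough for the
  >500-ms co-activity rule to fire.
- **LFP**: unit-variance 1/f Gaussian background; each ripple is a
  Hann-windowed 180 Hz burst whose stated 60-ms duration is the envelope
  FWHM (support 120 ms) — the duration a detector reports — with amplitude
  snr × the band-passed background SD.
- **Stimulation**: onsets every 60 s; responsive neurons receive an added
  unit-kernel transient of amplitude effect × noise SD at each onset.

**What it does not emulate** — and hence what passing tests do not show
about real data: motion artifacts and neuropil contamination, extraction
(CNMF-e) cross-talk and errors, temporally correlated noise, bursting
statistics beyond Bernoulli thinning, theta-paced spiking or phase
precession, behavioral state changes (immobility, grooming), and any
coupling between ripples and calcium events unless explicitly injected.

Two generator regimes matter for interpretation. Sparse, near-silent traces
put the z-score SD at the noise floor, so the z > 1 "active" state fires on
single noisy frames; dense background transients instead persist for seconds
(the 1.5-s decay) and create sustained spurious co-activity. Real denoised
traces sit between these extremes. The assembly-recovery tests therefore use
assembly-dominated sessions (members only, no background firing), which is
the regime where the SCE pipeline's assumptions hold; the calibration tests
use dense participation where the permutation null is informative.

## Known limitations

- **Rate-map peak localization is indicator-limited.** The calcium kernel's
  ~1.6-s mean lag blurs trace-based maps by (running speed × lag) ≈ 5–10 cm;
  in expectation the blur is symmetric and argmax-preserving for interior
  fields, but near walls it is asymmetric and displaces the argmax inward by
  about one 2-cm bin. Under the default generator physics the fraction of
  fields whose map argmax lands within one bin of the true center saturates
  around 0.65–0.85 depending on speed and session length (interior fields
  reach 1.0; wall-zone fields ~0.7). Spike deconvolution would remove the
  blur but is out of scope; onset-event maps and derivative weighting were
  evaluated and are worse (field-entry bias, noise amplification).
- The M-maximization rule inherits the background-coactivity structure: with
  dense spontaneous activity it selects an M inside the background
  fluctuation range and admits spurious events. This is a property of the
  procedure, not the implementation; the run-merge gap mitigates but does
  not remove it.
- The Bernoulli spiking model cannot represent refractory periods or bursts
  outside injected assembly events; firing-rate recovery tests are exact
  only in the low-rate regime the precondition enforces.
- T-maze decoding uses 2-D coordinates (errors in cm), not a linearized
  track coordinate.
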