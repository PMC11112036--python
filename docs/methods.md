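# Methods

This note documents the models, conventions and numerical choices behind
`stripmea`, the way the package itself would explain them to a careful
user. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and acquisition chain

A recording is a dense matrix of extracellular voltages in microvolts,
one row per electrode, sampled at a common rate (30 kHz throughout). The
canonical layout is 4 strips × 8 electrodes; electrodes are named E1..E32
consecutively across strips. The acquisition bandpass is a first-order
high-pass at 0.1 Hz followed by a third-order Butterworth low-pass at
5 kHz. Filtering is **causal** by default because the hardware filters in
real time and all timing conventions (cutout windows, burst intervals) are
defined on the filtered signal; zero-phase forward-backward filtering is
available for offline work where group delay matters. The first
`max(5/f_hp, 1 s)` of causal output (50 s at 0.1 Hz) is flagged as filter
transient, never removed — short synthetic recordings have no DC step, so
the flag matters mainly for real data with electrode offsets.

Filters are implemented as second-order sections (`scipy.signal`); the
passband and roll-off of the digital chain are validated against the
closed-form analog Butterworth magnitude response in the tests.

On disk a recording is a channel-interleaved flat binary file (float32
microvolts, or int16 with an explicit μV-per-count scale) plus a key-value
text sidecar. The format is deliberately minimal: byte-exact round trips,
no container dependency, trivially writable by other tools.

## Spike detection

Spikes are voltage excursions beyond `threshold_multiplier × σ_noise`
(default 6). Both polarities trigger by default: extracellular waveforms
in these tissues show both negative- and positive-dominant shapes. The
event time is the **first supra-threshold sample**; each event stores a
5 ms cutout beginning 1 ms before that sample, so the crossing sits at
sample 30 of 150 at 30 kHz. Events whose cutout would overrun a trace
edge are discarded. A 2 ms dead time suppresses re-triggering on the
later phases of one waveform; it also bounds how close two distinct
spikes on one electrode can be resolved.

Noise σ defaults to the plain standard deviation of the whole trace
(the hardware's definition). Dense, large spikes inflate that estimate,
so a median-absolute-deviation estimator (`mad`, MAD/0.6745) is provided
and is what the validation scripts use when firing is dense. SNR is
`peak-to-peak amplitude / σ_noise` per event, averaged per electrode;
with no events (or σ = 0) it is reported as missing, never 0. Two legacy
acquisition-software interval parameters (0.5/1.5 mV) are retained on
`DetectionParams` for config compatibility but enter no computation.

At 6σ on Gaussian noise the per-sample false-crossing probability is
2Φ(−6) ≈ 2×10⁻⁹, i.e. ≈0.1 expected false events in a 30-minute
30 kHz trace; the acceptance script measures this directly.

## Spike sorting

Features are PCA scores of the **1.4–2.4 ms segment** of each cutout —
samples [42, 72) at 30 kHz under round-half-even ms→sample conversion, a
half-open window of 30 samples. That segment covers the repolarization
tail, where units recorded on one electrode differ most; two components
are kept by default (the familiar two-dimensional point-cloud plot).

Before feature extraction, cutouts are re-aligned on their absolute
extremum with sub-sample precision (parabolic interpolation of the peak,
linear-interpolation shift). This matters: threshold-crossing timestamps
jitter by a few samples with noise, and without re-alignment that jitter
smears each unit along the waveform-derivative direction in PC space,
which a mixture model happily splits into spurious sub-clusters. Integer
re-alignment alone leaves the fractional phase as a residual spread with
the same failure mode. Alignment is a pre-sorting transform only — event
times remain threshold-crossing times.

Clustering is a full-covariance Gaussian mixture with k ∈ {1..3} chosen
by BIC (3 initialisations, fixed seed, `reg_covar` 10⁻⁶); k-means with a
fixed k is available as a fallback. Clusters smaller than 2 % of an
electrode's events are merged into their nearest neighbour. Electrodes
with fewer than `max(10, n_components+1)` events are unsortable and keep
all events in U1. Units are named U1..Uk by descending spike count.
By default every spike receives a unit; Mahalanobis outlier flagging
(events > n SD from their cluster centre labelled `noise`) is off unless
configured. PCA is fitted per electrode, not pooled across a strip.

Cross-session unit tracking pairs templates greedily by maximum Pearson
correlation (scale-invariant, so amplitude drift does not break pairing);
pairs under a 0.8 correlation floor stay unmatched.

## Burst and network-burst analysis

A burst is a **maximal** run of ≥3 consecutive spikes in which every
inter-spike interval is ≤50 ms. Runs extend past the 3-spike trigger —
with typical mean burst sizes of 7–9 spikes any non-maximal reading would
be inconsistent — and exactly-50 ms intervals qualify ("no more than").
Intra-burst rate is `n_spikes / duration` (not `n−1`); at the 0.1 s
durations typical here the printed precision cannot discriminate the two
conventions, so the choice is documented and configurable in one place.
Electrodes with zero bursts report rate 0.00 and 0.0 for every mean.
The implementation is verified by exact set equality against a
brute-force maximal-run enumerator on 10⁴ random trains.

No standard network-burst definition exists for 3D tissue, so the rule is
deliberately transparent: cut time into 25 ms bins; an electrode
participates in a bin when the bin overlaps one of its single-electrode
bursts or it fires in the bin; a network burst is a maximal run of bins
where ≥50 % of the *active* electrodes (≥1 spike in the frame)
participate. Both parameters are exposed. Under independent sparse
Poisson firing the rule produces essentially no events; under full
injected synchrony it recovers events spanning most of a strip.

Pattern labels use a simple rule whose thresholds are **heuristics**, not
published criteria: *Slow* below 0.1 Hz mean rate; otherwise *Bursting*
when ≥50 % of spikes fall inside bursts; otherwise *Irregular*. The
thresholds reproduce the obvious anchor cases (a 0.02 Hz unit is Slow, a
train that is all bursts is Bursting, 5 Hz Poisson is Irregular in ≥90 %
of seeded replicates) and are echoed in the run manifest so downstream
users see exactly what produced the labels.

Summary rows keep full-precision values internally; display rounding
(frequencies 1–2 decimals, burst rates 2, amplitudes 1) is applied only
when writing the summary CSV.

## Ground-truth simulator

The simulator emulates the documented signal regime of porous strip
arrays on mature 3D neural tissue, and is the source of truth for every
recovery test:

* **Templates** — difference of two Gaussian lobes, negative-first by
  default, zero-mean, dominant extremum pinned at the 1 ms mark so
  rendered spikes align with the cutout convention; peak-to-peak
  amplitude exact by construction, drawn uniformly from 50–100 μV.
  Same-electrode units use distinct second-lobe geometries (delay, width,
  relative size, polarity) so they differ inside the 1.4–2.4 ms window.
* **Noise** — white Gaussian, σ = 4 μV by default: the hardware quotes a
  ±10–15 μV peak-to-peak visual band, and ±3σ of a 4 μV Gaussian
  reproduces it. The noise is added to the rendered (already
  band-limited) trace. Note that the analysis chain then bandpasses the
  recording again, which removes the out-of-band two-thirds of white
  noise power and lowers the measured σ to ≈2.3 μV; simulated SNR values
  therefore run higher than the 7–10 typical of tissue recordings, whose
  noise is already band-limited and partly biological. Recovery results
  are insensitive to this, but absolute SNR columns from simulations
  should not be read as tissue-realistic.
* **Spike trains** — *irregular*: homogeneous Poisson (1–5 Hz drawn per
  unit); *slow*: Poisson at 0.05 Hz (capped at 0.1 Hz by contract);
  *bursting*: a two-state renewal process — Poisson burst onsets
  (2–12 min⁻¹ per unit), Poisson spikes-per-burst (mean 6–9, floored at
  3), intra-burst ISIs jittered around 10–18 ms and capped below 50 ms,
  plus a 0.2 Hz quiescent baseline. The generator is built to be
  detectable by the ISI criterion, not to model biophysics. A 2 ms
  within-unit refractory period keeps sorting ground truth well-defined;
  across units spikes superpose linearly (collisions are realistic and
  never an error).
* **Patterns mix** — units draw bursting/irregular/slow with weights
  0.6/0.3/0.1, matching the preponderance of bursting and irregular
  labels in published per-electrode tables for mature tissue.
* **Synchrony** — the unit with the most bursts serves as reference
  clock; for every other unit the configured fraction of its bursts is
  shifted so each onset lands on the nearest reference onset ± a uniform
  jitter (5 ms default). Spike counts are preserved. There is no
  quantitative published estimate of network-burst prevalence in this
  preparation, so `synchrony_fraction` defaults to 0 and is a free
  experimental knob rather than a calibrated one.

What the simulator does **not** model: electrode impedance and filtering
idiosyncrasies, spatially correlated noise, waveform drift within a
session, bursting non-stationarity, and true overlapping-spike waveform
shapes beyond linear superposition. Passing recovery tests therefore
demonstrate correctness of the analysis chain under the stated signal
regime, not performance on every real-tissue pathology.

## Problem sizes and determinism

Validation runs use deliberately desk-scale problems: end-to-end recovery
simulates the full 32-channel layout at 30 kHz but 60–120 s frames rather
than 30-minute sessions (≈10⁵ ground-truth spikes per run, ample for the
10 % rate and Poisson-CI burst checks); detection recall uses ~500 spikes
on one channel; the pure-noise false-positive check does use a full
30-minute single-channel trace because its expectation (~0.1 events) is
only meaningful at that length. Rate recovery is asserted per electrode
only where the ground truth has ≥50 spikes — below that, counting noise
exceeds the 10 % band by construction — and burst recovery compares
detected counts against the bursts detected on the ground-truth train
(the generator's realized burst rate) within a 95 % Poisson interval,
aggregated checks alongside per-electrode ones.

All randomness flows through `numpy.random.Generator` seeded from
explicit config fields; identical configs reproduce recordings, sidecars
and every output CSV byte for byte. GMM and k-means receive fixed
`random_state`s derived from the sorting seed.

## Known limitations

* The pattern classifier's thresholds are package conventions; labels on
  real data should be reviewed before scientific use.
* The network-burst rule is binned participation, not a point-process
  method; very short network events (< one bin) can be missed, and bin
  edges can split one event in two at low participation.
* Causal filtering delays waveforms by the filter group delay; cutout
  timing is defined post-filter, so comparisons with zero-phase analyses
  shift by a fraction of a millisecond.
* Sorting assumes stationary templates within a session; drift correction
  and overlapping-spike decomposition are out of scope.
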