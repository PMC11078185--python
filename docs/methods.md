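# Methods

This note documents the models, parameter choices and numerical
decisions behind `cordtrace`, and what the synthetic benchmarks do and
do not demonstrate about real recordings.

## Coordinate and unit conventions

Angles around the cord circumference are measured in degrees with 0° at
the dorsal midline, +90° at the animal's left lateral aspect (viewed
from rostral) and ±180° at the ventral midline; values live in
[−180, 180). Potentials are microvolts, times seconds, frequencies
hertz. Sample indices are 0-based; epochs are half-open `[start, end)`.
The evenly spaced layout constructor places one electrode exactly at 0°
(the dorsal-midline calibration electrode) and, at full coverage, spaces
the remaining electrodes at 360°/n (11.25° for the default n = 32).

## Synthetic-session model

The generator is the package's study-condition definition: every
recovery benchmark runs against it, so its defaults are fixed and are
not tuned per experiment.

**Evoked waveform.** An ECAP is modelled as a difference of two centred
Gaussians — a narrow positive core (σ = 10% of the 4-ms support) minus a
2.5×-wider surround whose truncated integral is balanced against the
core's, giving a zero-integral, positive-peaked biphasic pulse. The peak
is normalised to 1 and scaled to 50 µV at the hotspot. The conduction
delay from stimulation event to peak defaults to 1.5 ms. Per-event
amplitudes jitter uniformly by ±10%.

**Angular hotspot profiles.** Per-channel gain is a sum of von
Mises-shaped bumps `g(θ) ∝ Σ a_b·exp(κ(cos(θ−θ_b)−1))`, normalised so
the maximum over the whole circle is 1 (so rotating a source exactly
permutes the gains of a full-coverage layout). Defaults: somatosensory
sources one dorsal bump at ±20° (κ = 10); motor sources a ventrolateral
(±135°) plus weaker (0.8×) lateral (±90°) pair (κ = 12); tibial and
peroneal sub-sources at +15° and +45°. Right-side profiles are exact
mirrors of the left through 0°. A profile may carry a delayed secondary
component with its own hotspot, modelling activation that shifts sector
as later volleys arrive.

**Noise.** White Gaussian instrument noise at σ = 10 µV (peak SNR 5
against the 50-µV hotspot amplitude); an ECG-like Ricker transient train
(6 Hz, 20 µV, 5-ms width — a rat-scale heart rate, matched to the 5-ms
cardiac extraction scale); respiration drift (1 Hz sinusoid, 15 µV);
50-Hz line interference (5 µV); and a 0.5-ms biphasic stimulation
artifact (30 µV) at each event. ECG, respiration, line and stimulation
terms are common-source with equal gain on all channels, which is what
makes dormant-channel referencing cancel them; real arrays see
channel-dependent artifact gains, so referencing on real data removes
these terms only approximately.

**Schedule.** Events start 0.5 s into the session and repeat every 1 s,
cycling SSEP_L → MEP_L → SSEP_R → MEP_R; a 70-s session yields 70
events. Noise realisations are drawn from seed substreams independent of
the schedule, so the generator is additive in its events.

## Denoising and detection

The denoiser uses the stationary (undecimated) wavelet transform by
default: every coefficient band then has the signal's length, which is
what the per-band universal threshold `Th_l = σ_l·√(2 ln N)` assumes
here, and reconstruction is shift-invariant. A decimated variant
(`variant="dwt"`) is kept for comparison; its per-band N is the band
length. σ_l is estimated per level as `median(|c_l|)/0.6745`. Hard
thresholding keeps `|x| > Th` and zeroes the rest; exact equality maps
to 0 (a measure-zero case, resolved conservatively). The approximation
band is never thresholded. pywt's stationary transform uses periodic
convolution internally, so signals are symmetrically padded to a
multiple of 2^levels (plus one filter-support margin) and cropped after
reconstruction. With thresholds forced to zero the round trip is exact
to machine precision, and because σ and Th both scale linearly, the
denoiser is exactly scale-equivariant.

Detection runs on the denoised series. Its threshold is the universal
threshold computed from the series' own residual-noise SD, estimated by
MAD/0.6745 of the (median-centred) samples — evoked peaks occupy well
under 1% of the samples, so they do not move the median. Local maxima
strictly above threshold are accepted with a 4-ms refractory separation
(the larger of two competing peaks wins) and a 4-ms window centred on
each peak is cut; edge-clipped windows are zero-padded and flagged. Only
positive peaks are detected by default, matching the evoked-waveform
polarity; signed detection is available by config.

Cardiac extraction is a single-scale continuous wavelet transform with
the Ricker (Mexican-hat) kernel. pywt's `mexh` has its positive lobe on
|t| < 1 at scale 1, so a 5-ms QRS-like transient corresponds to a scale
of 2.5 ms in samples.

## Topographic mapping

Peak-amplitude maps hold, per event and channel, the largest detected
peak inside the post-stimulus window (0 when nothing was detected).
Frames interpolate a map row piecewise-linearly on the circle (wrapping
across ±180° only at full coverage); electrode values are reproduced
exactly and interpolation never overshoots the data. Linear
interpolation localises a hotspot to the nearest electrode, so angular
accuracy is limited by electrode spacing (≤ 5.625° worst case for 32
electrodes), not by the display grid. The dual-hotspot search returns
the best second local maximum at least 30° from the primary — roughly
the ventrolateral-to-lateral separation of the motor territories.
Temporal evolution averages selected epochs per channel and emits one
frame per time bin using the peak amplitude within the bin.

## Classification

Features are binarized strictly above each channel's mean peak amplitude
(ties map to 0). The supervised path is k-nearest neighbours with k = 1
under the city-block (L1) metric on a stratified 60/40 split — the split
is stratified to guarantee non-empty test classes at session scale.
Neighbour sets include every training point tied with the k-th distance,
so predictions do not depend on training-set ordering; vote ties break
by the smaller class-wise distance sum, then the lower class label. The
"unsupervised k = 2/4 grouping" is implemented as k-medoids under the
same L1 metric (exemplar-based, one deterministic maximin initialisation
plus seeded restarts, lowest within-cluster cost wins), with k-means as
an alternative; agreement against true labels is computed after optimal
one-to-one Hungarian matching. PCA (exact SVD) and optional UMAP
embeddings are provided for visualisation; classification operates on
the binary features directly.

## Closed-loop bypass

The bypass trigger fires at the first sample where the amplified
proximal signal crosses the threshold upward, then holds off for a
refractory period. The scenario model: before the injury time, each
stimulation event produces a distal response after the natural
conduction latency (1.5 ms default); after it, responses occur only via
trigger + loop delay (0.2 ms default). The distal trace is synthesised
as a Gaussian pulse per response and latencies are measured from its
peaks by search, not assumed. With the threshold on the rising edge
(half the nominal peak), triggering precedes the proximal peak, so the
loop beats natural conduction — the benchmark verifies this direction of
effect and the recovery of the configured pre-injury latency, not any
particular absolute latency value, since those depend on electrode
placement and hardware. The latency comparison defaults to a paired
two-tailed t test (unpaired available); zero-variance paired differences
are reported as degenerate rather than silently producing infinities.

## Morphometry

Circularity is `4π·area/perimeter²` on explicit simple polygons
(shoelace area, closed-edge perimeter, validity checked), invariant to
rigid motion and uniform scaling and ≤ 1 by the isoperimetric
inequality; a polygonised circle approaches 1 from below at O(1/n²), so
shape tests use ≥ 10³ vertices. Image segmentation is out of scope; a
marching-squares helper converts rasterised masks to outlines (on binary
masks the staircase contour inflates the perimeter — pass a smooth field
where accuracy matters). The group test takes the control reference mean
as an explicit argument.

## Benchmark problem sizes and what they show

Recovery benchmarks simulate at 10 kHz: all analysis bands (three detail
levels, the 50-Hz notch, 4-ms waveforms) sit far below Nyquist there,
and repeated-seed runs stay tractable on one core; the acquisition
default of 30 kHz remains in the config. Detection is scored over 20
seeds × 70 events at peak SNR 5: an event counts as detected when any
spike lands in its post-stimulus window, a spike is false when it lands
in none, and peak timing is measured on each event's hotspot channel.
Classification uses one 70-event session (≈ 17 events per class; 28 test
events) and a 50-permutation shuffled-label control. The bypass
benchmark pools 10 seeds of 30-s motor-only sessions at a reduced 2-µV
noise level (the trigger operates on the referenced raw signal, and the
scenario models a well-isolated proximal channel).

Passing these benchmarks shows the chain recovers what the generator
hides under its stated conditions. It does not show performance on real
recordings: real ECAP waveforms vary in shape and latency, artifact
gains differ across channels, electrode impedances drift, and real
hotspot profiles need not be von Mises — none of which the generator
emulates.

## Known limitations

- Dormant-channel referencing assumes the configured dormant set truly
  carries no evoked response; the default picks channels whose largest
  source gain stays below 0.15 (the ventral-midline electrodes and the
  trough between somatosensory and motor territories), trading a small
  evoked bleed-through for a lower-noise averaged reference. A
  mis-specified set leaks evoked signal into all channels.
- The universal threshold is conservative for long recordings (N is the
  full series length); very small or slow evoked components can fall
  below it.
- Peak-time accuracy at SNR 5 is noise-limited to about one sample at
  10 kHz; sub-sample timing would require template fitting, which is not
  implemented.
- The unsupervised grouping is one defensible reading of an
  exemplar-based "KNN-style" clustering; other readings (e.g. shared-
  neighbour graphs) exist.
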