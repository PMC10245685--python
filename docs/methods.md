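# Methods

This note documents the models, estimators and numerical choices behind
`songphys`: what each stage assumes, which parameters matter, and what the
synthetic-data generators do and do not emulate.

## Problem setting

Adult zebra finch song is produced by the premotor nucleus HVC and its
downstream motor nucleus RA. When HVC inhibition is chronically silenced,
song degrades and then recovers over weeks, and the recovery is
accompanied by changes in *offline* neural activity — large negative
voltage deflections (sharp-wave-like LFP events) during lights-off,
non-moving periods, with characteristic spectral content and spike-phase
relationships. `songphys` implements the analysis chain for both sides of
that experiment: bioacoustic quantification of song degradation/recovery,
and detection/characterization of the offline electrophysiological
events.

Because the original recordings are large and proprietary-format, the
package ships generators that produce audio, LFP, accelerometer and spike
data with exact ground truth, so every estimator is tested by parameter
recovery rather than by fixture files.

## Synthetic data generators (`songphys.synth`)

### LFP nights (`gen_lfp`)

The background is independent 1/f^α noise per channel (α = 1 by default,
a typical LFP spectral slope), generated by spectral shaping of white
Gaussian noise and normalized to `noise_sd` (μV). Deflection events are
inserted *coherently* on all channels — a field event is seen by every
nearby electrode — at homogeneous-Poisson times. The defaults encode the
study conditions used throughout the tests and the acceptance script: a
10-minute, 16-channel night at 30 kHz with events at 0.1 /s and a
signal-to-noise ratio (|amplitude| / broadband noise SD) of 10. Condition
presets: the degraded-song condition uses −530 μV, 50 ms events; the
control condition −140 μV, 96 ms events.

**Deflection waveform.** The event shape is a difference of Gaussians,

    w(t) = −A′ [ exp(−t²/2σ₁²) − r·exp(−t²/2(kσ₁)²) ],   k = 2, r = 1/2,

scaled so the signed minimum equals the `event_amplitude` parameter and
σ₁ solves for the requested full width at half magnitude (FWHM) of the
negative lobe. Two properties are deliberate:

* `r·k = 1` makes the waveform zero-mean (no DC), and
* `k = 2` keeps the side lobes narrow, which concentrates the spectrum
  above 1 Hz.

The second point matters: amplitude and duration are *measured* on the
1–40 Hz bandpassed trace (see below), and a wide pulse inherently carries
energy below 1 Hz that any 1 Hz highpass removes, shrinking the measured
minimum. With k = 2 the clean-waveform amplitude retention through the
measurement band is 99.4% at 50 ms and 95.9% at 96 ms (FWHM retention
99.6% / 97.7%); with a wider rebound (k = 5) the 96 ms retention drops to
~92%, an irreducible bias no filter sharpness recovers. The cost is a
positive rebound of ≈37% of the negative peak rather than a smaller one;
the biphasic character is preserved.

**Event placement.** Events avoid movement epochs and keep a minimum
spacing of 3.5 event durations (the stated lower bound is 2; 3.5 keeps
waveform tails, <0.5% of peak beyond 3.2 durations, from overlapping a
neighbor's negative lobe, so ground-truth amplitudes stay exact).
Placement is by rejection sampling of a Poisson-count draw; an
unsatisfiable rate raises immediately.

### Song (`gen_song`)

Syllables are harmonic stacks (1/h harmonic rolloff, randomized phases,
5 ms cosine onset/offset ramps) rendered from templates
(fundamental, harmonic count, duration, level, noise mix), arranged into
motifs and bouts separated by *exact* digital silence, so ground-truth
onsets/offsets are sample-accurate. The degradation model jitters the
fundamental multiplicatively, stretches durations lognormally (a ×10
stretch reproduces the abnormally long >800 ms vocalizations seen in
degraded song), and optionally fragments syllables with short internal
silences. The generator does not attempt realistic zebra finch timbre,
amplitude modulation, or motif syntax variability — only the statistical
structure the segmentation and featurization assume.

### Spikes and coupled oscillations

`gen_spikes` draws an inhomogeneous Poisson train whose rate is
von Mises-modulated by the Hilbert phase of a band-limited reference:
rate(t) = r₀·exp(κ·cos(θ(t) − θ₀))/I₀(κ), sampled by thinning. κ = 0
reduces exactly to homogeneous Poisson. `gen_pac_signal` sums a slow
sinusoid sin(φ), a carrier at the center of the fast band whose envelope
is 1 + depth·cos(φ − φ₀), and white noise; with this envelope the
phase-binned modulation index of the estimator equals `depth` exactly in
the noise-free limit.

## Phase convention

One convention everywhere: instantaneous phase is the Hilbert-transform
angle shifted so that **a positive peak of the oscillation is 90°**
(sine convention: sin(ωt) has phase ωt). The spike generator, the PAC
estimator and the spike-phase extractor all use
`preprocess.hilbert_phase_deg`, so locking parameters round-trip through
generation and estimation without offset.

## Signal conditioning (`songphys.preprocess`)

* All filters are 4th-order Butterworth, applied forward–backward
  (zero phase), as second-order sections.
* Resampling is polyphase with the rational rate approximation capped at
  denominator 1000; per-channel means are removed before and restored
  after resampling so non-zero-centered traces (accelerometers) do not
  ring at the edges.
* "Velocity" for movement detection is the magnitude of the 3-axis
  accelerometer after per-axis mean (gravity) removal — no integration;
  movement is where the 1 s moving SD of that magnitude exceeds a
  threshold, by default the 95th percentile of the night's moving-SD
  distribution (absolute overrides allowed per recording).
* Bad channels are those whose SD exceeds 10× the median channel SD.

## Sharp-wave detection (`songphys.sharpwave`)

Working representation: channel-average of the raw trace, resampled to
125 Hz, bandpassed 1–40 Hz. Detection is two-pass:

1. **Candidates** — samples in the most-negative 5% of non-movement
   values, in maximal runs of ≥ 10 ms, anchored at the run minimum;
   anchors closer than 80 ms resolved by keeping the deeper one
   (ties → earlier). The percentile is applied to the signed trace.
2. **Template matching** — the mean 80 ms candidate-centered window is
   cross-correlated with the whole trace (score aligned to the template
   center), z-scored with mean/SD from non-movement samples only, and
   peaks above a constant z = 4 are kept greedily in descending z with an
   80 ms exclusion zone. The z-threshold is deliberately not tuned per
   recording; z-scoring makes detection invariant to overall gain.

**Extraction and measurement.** Each event indexes the raw-rate channel
average: a 500 ms window is taken and recentered on the minimum of the
1–40 Hz trace within the central 100 ms. Amplitude is the signed minimum;
duration is the full width at half magnitude around it, with the
half-level crossings located by linear interpolation. Measurement runs on
the snippet resampled to 1 kHz before the 1–40 Hz bandpass: a 4th-order
bandpass with a 1 Hz edge at 30 kHz has normalized corner frequencies
~7·10⁻⁵ and is numerically fragile, while 1 kHz keeps 1 ms resolution
and is stable. Recentering uses the bandpassed trace rather than the raw
minimum because the broadband noise minimum of even a channel-averaged
raw trace jitters by several milliseconds.

Snippets whose 300–7000 Hz RMS exceeds 10× the night median are rejected
as electrical artifacts (an automated, counted proxy for the manual
curation such data normally receives). Matched non-event windows are
drawn uniformly from times free of movement and of detected events,
equal in number to the events by default, seeded.

Expected estimator behavior under the default conditions (from the
clean-waveform retention above plus the slight negative bias of a
minimum over noise): mean amplitudes within ~1% (50 ms events) and ~4%
(96 ms events) of ground truth, durations within ~3%. The tests assert
5%/10% envelopes end-to-end.

## MUA (`songphys.mua`)

Common-average-referenced channels are bandpassed 600–6000 Hz, upsampled
to 50 kHz, passed through the local (Teager) energy operator
ψ(x)[n] = x[n]² − x[n−1]x[n+1], clamped at zero, square-rooted, and
Gaussian-smoothed with σ = 0.4 ms (20 samples at 50 kHz; the σ unit is a
documented interpretation — milliseconds give a physiologically sensible
~1 ms kernel). The high-MUA mask thresholds the envelope at 5× the night
median (robust to rate differences across nights) and downsamples to
30 kHz by logical OR over each output sample's span so brief bursts
survive decimation. ψ can be negative on noise; clamping before the
square root is the standard remedy and is what the tests assert.

## Spectral analysis (`songphys.spectral`)

The CWT uses generalized Morse wavelets defined in the frequency domain,
Ψ(ω) ∝ ω^β exp(−ω^γ) with β = 20, γ = 3 (time–bandwidth ≈ 60, the
common analysis default). Filters are normalized to peak value 2 so the
transform magnitude of a pure cosine equals its amplitude at the tone
frequency. No installed wavelet library provides Morse wavelets, so the
filter bank is built directly; the tests check it against the analytic
tone response. Snippets are decimated to 1 kHz (configurable) before the
transform; 64 log-spaced frequencies span 1–200 Hz.

Event spectra are reported as percent increase over the non-event group
mean per frequency–time cell; band summaries average power over the
central 33 ms and the band, per event, and compare groups with a
two-sample t-test. A caveat the tests make explicit: on 500 ms snippets
the slowest wavelets (≲4 Hz) are longer than the snippet, so per-cell
null fluctuations are large at the band's bottom edge; group sizes in
the low bands need to be correspondingly larger.

Welch differences use Hann segments of a quarter snippet with 50%
overlap on the *averaged* event and non-event waveforms, integrated over
the band.

Phase–amplitude coupling bandpasses both bands (zero phase), takes the
Hilbert phase of the slow band and envelope of the fast band, and
collects the slow phase at fast-envelope peaks (at most one per fastest
slow cycle for continuous input; one per snippet for event input). The
coupling phase is the circular mean of those samples; modulation depth is
(max − min)/(max + min) of the 18-bin (20°) phase-binned mean envelope,
which equals the generator's `depth` parameter by construction. Segments
shorter than 3 slow-band cycles are skipped and counted. Both slow-band
presets used in practice — 1–10 Hz ("alpha") and 10–20 Hz — ship as named
bands; callers choose.

## Spike-phase statistics (`songphys.phaselock`)

Spikes are threshold crossings of the 300–7000 Hz common-average-
referenced trace: within each 2-minute window the threshold is
mean ± 9 SD of that window, applied to |x − mean| (a two-sided magnitude
criterion — extracellular spikes are predominantly but not exclusively
negative; a one-sided switch is provided), spike time at the excursion
extremum, 1 ms refractory. SD-relative thresholds make detection
invariant to gain and DC offset.

Spike phases are linearly interpolated on the unit circle (cos/sin
separately) to avoid wrap artifacts. Distributions use 18 bins of 20°.
Distribution comparisons use the two-sample Kolmogorov–Smirnov test on
the phase samples with the cut fixed at 0° (the KS statistic on circular
data depends on the cut; fixing it makes the test well-defined and
calibrated, which the suite verifies empirically). Firing-rate group
comparisons use the two-sided Wilcoxon rank-sum test with mid-ranks for
ties.

## Song featurization (`songphys.songfeat`, `songphys.summary`)

Spectrograms use 1024-sample Hann windows with a 44-sample hop — the
~1 ms feature cadence at 44.1 kHz. Per frame, over 0–11 kHz: spectral
centroid (mean frequency), total log power, Wiener entropy
(log geometric/arithmetic mean of the power spectrum), the maximum log
power in each 2.75 kHz quadrant, and cepstral pitch/goodness (peak of the
real cepstrum in the 350 Hz–2 kHz fundamental range, parabolic
sub-sample refinement; goodness is the peak height). Wiener entropy is
computed on a 9-bin smoothed spectrum: the raw periodogram's log carries
an Euler–Mascheroni bias (−0.577 for white noise) that smoothing removes,
restoring the analytic white-noise-≈0 / tone-≪0 limits.

Segmentation thresholds the 1 ms log-power trace; silences shorter than
15 ms between segments are merged first, then segments shorter than
20 ms are dropped (the order matters and is fixed; an exhaustive
run-length oracle pins the semantics). The threshold is per-corpus, as
manual per-bird thresholding is in practice; a helper expresses it as dB
above the bout's 10th-percentile frame power. For flat-envelope synthetic
syllables with 5 ms ramps, a threshold ~9 dB below the syllable plateau
is boundary-neutral under the 23 ms analysis window — the configuration
under which the ±3 ms onset/offset recovery test runs.

Per-segment summaries (7 dimensions: average mean frequency, average
pitch, max goodness, max log power, min entropy, entropy variance — over
the first 50 ms or the whole segment if shorter — plus duration) are
z-scored against a pre-perturbation baseline; PCA embeddings are fit on
the labeled reference set only (features standardized first; component
signs fixed by making the largest-magnitude loading positive) and other
segments projected in. Daily trends pool the 3 nearest recorded days and
report mean ± SE; missing days stay missing. Duration distributions use
5 ms bins over 0–1000 ms, column-normalized per day — wide enough to
resolve both <100 ms degraded vocalizations and >800 ms abnormal
syllables. Bout trajectories slide a 150 ms window in 3 ms steps,
describe each window by 20 ms moving averages every 5 ms of six features
(mean frequency, pitch, goodness, quadrant powers 4 and 2, total log
power; quadrants indexed low→high), and reduce to 30 principal
components fit across the sampled bouts.

## Problem sizes

The synthetic study conditions are 600 s nights (16 channels, 30 kHz)
for parameter-recovery runs; unit tests use 40–120 s nights at 2–8
channels, which leave the estimators' behavior unchanged and keep the
suite fast. Calibration checks use 200 null replicates; power and
sweep checks use 100 replicates or 4-point sweeps as appropriate.

## Known limitations

* The generators model statistical structure, not biophysics: no
  microcircuit dynamics, no seizure propagation, no HVC–RA interaction,
  no realistic song timbre. Passing recovery tests demonstrates estimator
  correctness under the stated noise model, not performance on arbitrary
  real recordings.
* The deflection waveform family is smooth and symmetric in its negative
  lobe; real sharp waves are skewed. FWHM and signed-minimum estimates
  are well-defined either way, but retention numbers quoted above are
  family-specific.
* Movement masking assumes accelerometer noise statistics differ between
  quiet and moving states by a clear margin; graded movement is not
  modeled.
* The chronic-recording PAC low band is configurable (1–10 Hz or
  10–20 Hz) because both conventions appear in practice; results depend
  on the choice and the configuration records it.
* Kilosort-style spike sorting is out of scope; the 9 SD threshold path
  is the supported spike source.
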