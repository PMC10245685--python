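"""Synthetic audio, LFP, accelerometer, and spike data with known ground truth.

Every generator draws all randomness from one ``numpy.random.default_rng``
seeded per call, so identical spec + seed gives bit-identical output.  The
generators emulate only the statistical structure the downstream estimators
assume: 1/f background LFP with embedded biphasic deflection events,
movement epochs with elevated accelerometer variance, harmonic-stack song
syllables with a controllable degradation model, von Mises phase-locked
spike trains, and phase-amplitude-coupled oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0

from .core import EventSet, SpikeTrain, TimeSeries
from .preprocess import bandpass, hilbert_phase_deg

__all__ = [
    "SynthLfpSpec",
    "SynthSongSpec",
    "SyllableTemplate",
    "SongDegradation",
    "SynthSpikeSpec",
    "SynthPacSpec",
    "deflection_waveform",
    "pink_noise",
    "gen_lfp",
    "gen_accelerometer",
    "gen_song",
    "gen_spikes",
    "gen_pac_signal",
    "tent_night_spec",
    "control_night_spec",
]

# Difference-of-Gaussians deflection shape: the wide Gaussian is K_SIGMA
# times the narrow one and carries R_REBOUND of its area.  The constraint
# R_REBOUND * K_SIGMA == 1 zeroes the waveform's DC, and keeping K_SIGMA
# small concentrates its spectrum above 1 Hz, so the 1-40 Hz band used for
# detection and measurement passes even a 96 ms-wide event with < 5%
# amplitude loss.  The positive rebound is ~37% of the negative peak.
K_SIGMA = 2.0
R_REBOUND = 0.5


def _dog_shape(u: np.ndarray | float) -> np.ndarray | float:
    """Unit shape f(u) = exp(-u^2/2) - r exp(-u^2/(2 k^2)); waveform = -A' f."""
    u2 = np.square(u)
    return np.exp(-u2 / 2.0) - R_REBOUND * np.exp(-u2 / (2.0 * K_SIGMA**2))


def _dog_fwhm_units() -> float:
    """Full width at half magnitude of the negative lobe, in units of sigma1."""
    peak = _dog_shape(0.0)
    half = brentq(lambda u: _dog_shape(u) - peak / 2.0, 1e-9, 3.0)
    return 2.0 * half


_FWHM_UNITS = _dog_fwhm_units()


def deflection_waveform(amplitude: float, duration_ms: float, fs: float) -> np.ndarray:
    """Biphasic sharp-wave-like deflection.

    Parameters
    ----------
    amplitude : float
        Signed minimum of the waveform, uV (must be <= 0).
    duration_ms : float
        Full width at half magnitude of the negative lobe, ms.
    fs : float
        Sampling rate, Hz.

    Returns
    -------
    ndarray of odd length; the minimum sits at the center sample and
    equals ``amplitude`` exactly.
    """
    if amplitude > 0:
        raise ValueError("deflection amplitude must be <= 0 (negative-going)")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    sigma1_s = (duration_ms / 1000.0) / _FWHM_UNITS
    half_support = int(round(4.0 * K_SIGMA * sigma1_s * fs))
    t = np.arange(-half_support, half_support + 1) / fs
    scale = -amplitude / (1.0 - R_REBOUND)
    return -scale * _dog_shape(t / sigma1_s)


def _pink_shaping(n: int, exponent: float) -> np.ndarray:
    """Spectral amplitude shaping |H(f)| ~ f^(-exponent/2), DC zeroed."""
    freqs = np.fft.rfftfreq(n).astype(np.float32)
    shaping = np.zeros(n // 2 + 1, dtype=np.float32)
    shaping[1:] = freqs[1:] ** np.float32(-exponent / 2.0)
    return shaping


def pink_noise(
    n: int,
    exponent: float,
    sd: float,
    rng: np.random.Generator,
    _shaping: np.ndarray | None = None,
) -> np.ndarray:
    """1/f^exponent noise of length n, normalized to the requested SD.

    Computed in single precision (the background is noise; float32 keeps
    long multichannel nights affordable in memory and FFT time).
    """
    from scipy import fft as sfft

    shaping = _pink_shaping(n, exponent) if _shaping is None else _shaping
    n_freq = n // 2 + 1
    spectrum = np.empty(n_freq, dtype=np.complex64)
    spectrum.real = rng.standard_normal(n_freq, dtype=np.float32) * shaping
    spectrum.imag = rng.standard_normal(n_freq, dtype=np.float32) * shaping
    x = sfft.irfft(spectrum, n=n)
    x *= np.float32(sd) / x.std()
    return x


@dataclass
class SynthLfpSpec:
    """Parameters of a synthetic overnight LFP recording.

    Defaults reflect a chronic 16-site implant sampled at 30 kHz with
    deflection events matching the degraded-song condition (about -530 uV,
    50 ms at half magnitude, at 0.1 events/s over a 10-minute night,
    signal-to-noise 10).
    """

    duration: float = 600.0
    fs: float = 30_000.0
    n_channels: int = 16
    noise_exponent: float = 1.0
    noise_sd: float = 53.0
    event_rate: float = 0.1
    event_amplitude: float = -530.0
    event_duration: float = 50.0
    event_jitter_frac: float = 0.0
    # minimum event spacing in units of event_duration.  3.5 keeps the
    # biphasic waveform tails (< 0.5% of peak beyond 3.2 durations) from
    # overlapping a neighbor's negative lobe; the floor is 2.
    spacing_duration_mult: float = 3.5
    movement_epochs: Sequence[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.event_amplitude > 0:
            raise ValueError("event_amplitude must be <= 0")
        if self.event_duration <= 0:
            raise ValueError("event_duration must be positive")
        for start, stop in self.movement_epochs:
            if not (0 <= start < stop <= self.duration):
                raise ValueError(f"movement epoch ({start}, {stop}) outside [0, duration]")


def tent_night_spec(**overrides) -> SynthLfpSpec:
    """Night emulating the silenced-interneuron condition at peak degradation."""
    params = dict(event_amplitude=-530.0, event_duration=50.0, noise_sd=53.0)
    params.update(overrides)
    return SynthLfpSpec(**params)


def control_night_spec(**overrides) -> SynthLfpSpec:
    """Night emulating the control condition (small, slow deflections)."""
    params = dict(event_amplitude=-140.0, event_duration=96.0, noise_sd=14.0)
    params.update(overrides)
    return SynthLfpSpec(**params)


def _draw_event_times(spec: SynthLfpSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson event times respecting spacing and movement-epoch exclusion."""
    n_events = rng.poisson(spec.event_rate * spec.duration)
    if n_events == 0:
        return np.empty(0)
    dur_s = spec.event_duration / 1000.0
    min_gap = max(spec.spacing_duration_mult, 2.0) * dur_s
    sigma1_s = dur_s / _FWHM_UNITS
    margin = 4.0 * K_SIGMA * sigma1_s  # full waveform support inside the record
    lo, hi = margin, spec.duration - margin
    if hi <= lo:
        raise ValueError("recording too short for the requested event duration")
    if n_events * min_gap > (hi - lo):
        raise ValueError(
            f"event_rate {spec.event_rate}/s unsatisfiable: {n_events} events need "
            f"{n_events * min_gap:.1f} s of spacing but only {hi - lo:.1f} s available"
        )
    times: list[float] = []
    attempts = 0
    max_attempts = 1000 * n_events
    while len(times) < n_events:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not place events: spacing/movement constraints unsatisfiable "
                f"at event_rate={spec.event_rate}/s"
            )
        t = rng.uniform(lo, hi)
        if any(abs(t - u) < min_gap for u in times):
            continue
        if any(t + dur_s > start and t - dur_s < stop for start, stop in spec.movement_epochs):
            continue
        times.append(t)
    return np.sort(np.asarray(times))


def gen_lfp(spec: SynthLfpSpec) -> tuple[TimeSeries, EventSet]:
    """Generate a synthetic multichannel LFP night.

    The background is independent 1/f noise per channel; deflection events
    are inserted coherently on every channel (a field deflection is seen by
    all nearby electrodes) at Poisson times that avoid movement epochs and
    keep at least twice the event duration between events.

    Returns the signal and a ground-truth :class:`EventSet` whose times are
    the exact sample times of each inserted waveform minimum.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    data = np.empty((spec.n_channels, n), dtype=np.float32)
    shaping = _pink_shaping(n, spec.noise_exponent)
    for ch in range(spec.n_channels):
        data[ch] = pink_noise(n, spec.noise_exponent, spec.noise_sd, rng, _shaping=shaping)

    times = _draw_event_times(spec, rng)
    amps = np.empty(times.size)
    durs = np.empty(times.size)
    snapped = np.empty(times.size)
    for i, t in enumerate(times):
        jitter_a = 1.0 + spec.event_jitter_frac * rng.standard_normal()
        jitter_d = 1.0 + spec.event_jitter_frac * rng.standard_normal()
        amps[i] = spec.event_amplitude * max(jitter_a, 0.1)
        durs[i] = spec.event_duration * max(jitter_d, 0.1)
        wave = deflection_waveform(amps[i], durs[i], spec.fs).astype(np.float32)
        center = int(round(t * spec.fs))
        half = wave.size // 2
        start, stop = center - half, center + half + 1
        data[:, max(start, 0):min(stop, n)] += wave[max(0, -start):wave.size - max(0, stop - n)]
        snapped[i] = center / spec.fs

    truth = EventSet(times=snapped, amplitude=amps, duration=durs, is_event=True)
    return TimeSeries(data, fs=spec.fs, units="uV"), truth


def gen_accelerometer(
    movement_epochs: Sequence[tuple[float, float]],
    duration: float,
    fs: float,
    quiet_sd: float,
    moving_sd: float,
    seed: int = 0,
    gravity_offset: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> TimeSeries:
    """3-axis accelerometer noise with elevated SD inside movement epochs.

    A constant per-axis gravity offset makes the traces non-zero-mean, as
    head-stage accelerometers are.
    """
    if not (moving_sd > quiet_sd > 0):
        raise ValueError("need moving_sd > quiet_sd > 0")
    for start, stop in movement_epochs:
        if not (0 <= start < stop <= duration):
            raise ValueError(f"movement epoch ({start}, {stop}) outside [0, {duration}]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    data = rng.standard_normal((3, n)) * quiet_sd
    for start, stop in movement_epochs:
        i0_, i1 = int(round(start * fs)), int(round(stop * fs))
        data[:, i0_:i1] = rng.standard_normal((3, i1 - i0_)) * moving_sd
    data += np.asarray(gravity_offset)[:, None]
    return TimeSeries(data, fs=fs, units="g")


# ---------------------------------------------------------------------------
# Song synthesis


@dataclass
class SyllableTemplate:
    """One harmonic-stack syllable type."""

    f0: float  # fundamental, Hz
    n_harmonics: int = 8
    duration_ms: float = 80.0
    amplitude_db: float = 0.0  # peak level re full scale
    entropy_target: float = 0.0  # 0 = pure harmonic stack, 1 = white noise

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("syllable duration must be positive")
        if self.f0 <= 0:
            raise ValueError("fundamental must be positive")


@dataclass
class SongDegradation:
    """Degradation model applied per rendered syllable.

    ``f0_jitter_frac`` is the SD of a multiplicative jitter on the
    fundamental; ``duration_scale`` is (median multiplier, log-SD) of a
    lognormal stretch of the syllable duration; ``fragmentation_prob``
    is the probability a syllable is broken by short internal silences.
    """

    f0_jitter_frac: float = 0.0
    duration_scale: tuple[float, float] = (1.0, 0.0)
    fragmentation_prob: float = 0.0
    frag_silence_ms: float = 10.0
    frag_piece_ms: float = 30.0


@dataclass
class SynthSongSpec:
    syllable_templates: Sequence[SyllableTemplate] = field(
        default_factory=lambda: [
            SyllableTemplate(f0=600.0, n_harmonics=10, duration_ms=90.0),
            SyllableTemplate(f0=900.0, n_harmonics=8, duration_ms=60.0),
            SyllableTemplate(f0=450.0, n_harmonics=12, duration_ms=120.0),
        ]
    )
    motif_order: Sequence[int] = (0, 1, 2)
    gap_ms: float = 40.0
    bout_gap_ms: float = 300.0
    n_bouts: int = 3
    degradation: SongDegradation = field(default_factory=SongDegradation)
    fs: float = 44_100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_ms < 0 or self.bout_gap_ms < 0:
            raise ValueError("gaps must be >= 0")
        for tpl in self.syllable_templates:
            if not (0 < tpl.f0 < self.fs / 2):
                raise ValueError("fundamental must lie in (0, fs/2)")


def _render_syllable(
    tpl: SyllableTemplate, duration_ms: float, f0: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    wave = np.zeros(n)
    for h in range(1, tpl.n_harmonics + 1):
        if h * f0 >= fs / 2:
            break
        wave += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
    wave /= np.max(np.abs(wave)) + 1e-12
    if tpl.entropy_target > 0:
        noise = rng.standard_normal(n)
        noise /= np.max(np.abs(noise)) + 1e-12
        wave = (1.0 - tpl.entropy_target) * wave + tpl.entropy_target * noise
    ramp = int(min(0.005 * fs, n // 4))
    if ramp > 0:
        env = np.ones(n)
        env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[-ramp:] = env[:ramp][::-1]
        wave *= env
    return wave * 10.0 ** (tpl.amplitude_db / 20.0)


def gen_song(spec: SynthSongSpec) -> tuple[TimeSeries, pd.DataFrame]:
    """Render bouts of harmonic-stack syllables separated by exact silences.

    Returns the audio (single channel, arbitrary units) and a ground-truth
    segment table with exact onsets/offsets (ms) and the generating
    parameters of every syllable.
    """
    rng = np.random.default_rng(spec.seed)
    deg = spec.degradation
    pieces: list[np.ndarray] = []
    rows: list[dict] = []
    cursor = 0  # samples

    def push_silence(ms: float) -> None:
        nonlocal cursor
        n = int(round(ms / 1000.0 * spec.fs))
        pieces.append(np.zeros(n))
        cursor += n

    for bout in range(spec.n_bouts):
        if bout > 0:
            push_silence(spec.bout_gap_ms)
        for k, idx in enumerate(spec.motif_order):
            if k > 0:
                push_silence(spec.gap_ms)
            tpl = spec.syllable_templates[idx]
            f0 = tpl.f0 * (1.0 + deg.f0_jitter_frac * rng.standard_normal())
            f0 = float(np.clip(f0, 50.0, spec.fs / 2 * 0.9))
            mu, sigma = deg.duration_scale
            scale = float(np.exp(np.log(mu) + sigma * rng.standard_normal())) if sigma > 0 else mu
            duration_ms = tpl.duration_ms * scale
            wave = _render_syllable(tpl, duration_ms, f0, spec.fs, rng)
            if deg.fragmentation_prob > 0 and rng.random() < deg.fragmentation_prob:
                piece = int(round(deg.frag_piece_ms / 1000.0 * spec.fs))
                gap = int(round(deg.frag_silence_ms / 1000.0 * spec.fs))
                pos = piece
                while pos + gap < wave.size:
                    wave[pos:pos + gap] = 0.0
                    pos += piece + gap
            onset_ms = cursor / spec.fs * 1000.0
            pieces.append(wave)
            cursor += wave.size
            offset_ms = cursor / spec.fs * 1000.0
            rows.append(
                {
                    "onset_ms": onset_ms,
                    "offset_ms": offset_ms,
                    "duration_ms": offset_ms - onset_ms,
                    "source_bout": bout,
                    "template_index": idx,
                    "f0_hz": f0,
                }
            )
    push_silence(spec.bout_gap_ms)
    audio = np.concatenate(pieces) if pieces else np.zeros(0)
    truth = pd.DataFrame(rows)
    return TimeSeries(audio, fs=spec.fs, units="au"), truth


# ---------------------------------------------------------------------------
# Phase-locked spikes and PAC signals


@dataclass
class SynthSpikeSpec:
    """von Mises phase-locked inhomogeneous Poisson spike train."""

    baseline_rate: float = 5.0  # Hz, time-averaged
    locking_phase_deg: float = 90.0
    concentration: float = 0.0  # von Mises kappa; 0 -> homogeneous Poisson
    band: tuple[float, float] = (1.0, 10.0)
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.concentration < 0:
            raise ValueError("rate and concentration must be >= 0")
        if not 0 <= self.locking_phase_deg < 360:
            raise ValueError("locking phase must be in [0, 360)")


def gen_spikes(spec: SynthSpikeSpec, reference: TimeSeries) -> SpikeTrain:
    """Spikes whose rate is von Mises-modulated by the phase of ``reference``.

    The reference (first channel) is bandpassed to ``spec.band``; the
    instantaneous rate is ``r0 * exp(kappa cos(theta - theta0)) / I0(kappa)``
    so the time-averaged rate stays ~r0 under a uniform phase distribution.
    Sampling is by thinning a homogeneous Poisson process at the rate maximum.
    """
    if reference.n_samples == 0:
        raise ValueError("empty reference signal")
    if reference.duration < spec.duration:
        raise ValueError("reference shorter than requested spike-train duration")
    rng = np.random.default_rng(spec.seed)
    if spec.baseline_rate == 0:
        return SpikeTrain(times=np.empty(0))
    n = int(round(spec.duration * reference.fs))
    ref = bandpass(reference.data[0, :n], reference.fs, spec.band)
    theta = np.radians(hilbert_phase_deg(ref))
    kappa = spec.concentration
    rate_max = spec.baseline_rate * np.exp(kappa) / i0(kappa)
    n_cand = rng.poisson(rate_max * spec.duration)
    cand = np.sort(rng.uniform(0, spec.duration, n_cand))
    idx = np.minimum((cand * reference.fs).astype(int), n - 1)
    rate = spec.baseline_rate * np.exp(
        kappa * np.cos(theta[idx] - np.radians(spec.locking_phase_deg))
    ) / i0(kappa)
    keep = rng.uniform(0, rate_max, n_cand) < rate
    return SpikeTrain(times=cand[keep])


@dataclass
class SynthPacSpec:
    """Slow oscillation plus a fast carrier whose envelope rides its phase."""

    carrier_band: tuple[float, float] = (30.0, 40.0)
    modulating_band: tuple[float, float] = (1.0, 10.0)
    coupling_phase_deg: float = 0.0
    modulation_depth: float = 1.0
    noise_sd: float = 0.0
    modulator_amplitude: float = 1.0
    carrier_amplitude: float = 0.5
    duration: float = 60.0
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.carrier_band[0] <= self.modulating_band[1]:
            raise ValueError("carrier band must lie above the modulating band")
        if not 0 <= self.modulation_depth <= 1:
            raise ValueError("modulation_depth must be in [0, 1]")


def gen_pac_signal(spec: SynthPacSpec) -> TimeSeries:
    """Phase-amplitude-coupled test signal.

    The slow component is ``sin(phi)`` (so its phase in the package
    convention equals phi in degrees); the carrier envelope is
    ``1 + depth*cos(phi - coupling_phase)``, which makes the binned-envelope
    modulation index equal to ``depth`` exactly in the noise-free limit.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    f_mod = float(np.sqrt(spec.modulating_band[0] * spec.modulating_band[1]))
    f_car = 0.5 * (spec.carrier_band[0] + spec.carrier_band[1])
    phi = 2 * np.pi * f_mod * t
    envelope = 1.0 + spec.modulation_depth * np.cos(phi - np.radians(spec.coupling_phase_deg))
    x = (
        spec.modulator_amplitude * np.sin(phi)
        + spec.carrier_amplitude * envelope * np.cos(2 * np.pi * f_car * t)
    )
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(n)
    return TimeSeries(x, fs=spec.fs, units="uV")
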