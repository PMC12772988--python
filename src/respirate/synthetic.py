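"""Synthetic breathing data: audio with annotated breath events, periodic
video grid features, boundary-probability series, and SNR-controlled mixing.

The generators emulate the study conditions the estimators target:

* **Audio** — alternating inspiration/expiration noise bursts (band-passed
  seeded noise under smooth raised-cosine envelopes) over low-level room
  tone.  Breath cycles are spaced ``60/true_rate`` seconds apart with
  Gaussian jitter; every segment is annotated.  Default expiration gain is
  +6 dB so the louder phase (the boundary-detection target) is expiration.
  The default room tone puts segment SNR near 26 dB, matching quiet indoor
  recordings.
* **Video features** — 84 grid channels at 29.9 frames/s in which a seeded
  subset carries a sinusoid at the breathing rate plus drift and noise, the
  rest drift and noise only.
* **Boundary probabilities** — a Gaussian-bump train at jittered breath
  times with additive clipped noise, mimicking the output of a trained
  framewise boundary detector without requiring one.

SNR here follows the segment convention: mean power of the two loudest
annotated segments over mean room-tone power between segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .dataio import AnnotationTrack, AudioClip, FrameFeatureMatrix

__all__ = [
    "SyntheticAudioSpec",
    "SyntheticVideoSpec",
    "synth_breath_audio",
    "synth_video_features",
    "synth_boundary_probs",
    "make_noise",
    "mix_at_snr",
    "measure_snr",
]


@dataclass
class SyntheticAudioSpec:
    duration: float = 60.0  # s
    true_rate: float = 20.0  # breaths/min
    interval_jitter_sd: float = 0.2  # s
    burst_duration: float = 0.8  # s per phase burst
    phase_gap: float = 0.0  # s pause between inspiration end and expiration start
    burst_band: tuple[float, float] = (200.0, 1800.0)  # Hz
    expiration_gain_db: float = 6.0  # expiration level relative to inspiration
    burst_rms: float = 0.2  # inspiration burst RMS amplitude
    room_tone_rms: float = 0.01  # room-tone RMS (~26 dB below default bursts)
    sample_rate: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 3 * 60.0 / self.true_rate:
            raise ValueError("duration must cover at least 3 breath intervals")
        if 2 * self.burst_duration + self.phase_gap >= 60.0 / self.true_rate:
            raise ValueError("breath bursts do not fit within one breath interval")


@dataclass
class SyntheticVideoSpec:
    duration: float = 60.0  # s
    true_rate: float = 20.0  # breaths/min
    n_channels: int = 84
    n_periodic: int = 8
    amplitude: float = 1.0
    drift_slope: float = 0.01  # intensity units per s
    noise_sd: float = 0.3
    frame_rate: float = 29.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_periodic <= self.n_channels:
            raise ValueError("n_periodic must be in [1, n_channels]")


def _burst(n: int, band: tuple[float, float], sr: int, rng: np.random.Generator
           ) -> np.ndarray:
    """Band-passed white noise under a raised-cosine (Hann) envelope, unit RMS."""
    x = rng.standard_normal(n + 2 * sr // 10)
    sos = butter(4, band, btype="bandpass", fs=sr, output="sos")
    x = sosfiltfilt(sos, x)[sr // 10: sr // 10 + n]
    env = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))
    x = x * env
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def synth_breath_audio(spec: SyntheticAudioSpec
                       ) -> tuple[AudioClip, AnnotationTrack]:
    """Deterministic (per seed) breathing clip with full phase annotations.

    Each cycle is an inspiration burst immediately followed (after a short
    ``phase_gap``) by an expiration burst, then a rest until the next cycle —
    the duty pattern of relaxed tidal breathing, where the intra-breath
    inspiration/expiration spacing is much shorter than the breath interval.
    Cycle starts are spaced ``60/true_rate + N(0, jitter^2)`` seconds apart.
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    n = int(round(spec.duration * sr))
    mean_iv = 60.0 / spec.true_rate
    x = spec.room_tone_rms * rng.standard_normal(n)
    exp_gain = 10.0 ** (spec.expiration_gain_db / 20.0)
    segments: list[tuple[str, float, float]] = []
    t = 0.3  # settle time before the first breath
    while t + mean_iv < spec.duration:
        interval = mean_iv + rng.normal(0.0, spec.interval_jitter_sd)
        interval = max(interval, 2.0 * spec.burst_duration + spec.phase_gap + 0.05)
        for phase, offset, gain in (
            ("inspiration", 0.0, 1.0),
            ("expiration", spec.burst_duration + spec.phase_gap, exp_gain),
        ):
            start = t + offset
            end = start + spec.burst_duration
            i0, i1 = int(round(start * sr)), int(round(end * sr))
            if i1 >= n:
                break
            burst = _burst(i1 - i0, spec.burst_band, sr, rng)
            x[i0:i1] += spec.burst_rms * gain * burst
            segments.append((phase, i0 / sr, i1 / sr))
        t += interval
    clip = AudioClip(x, sr)
    return clip, AnnotationTrack(segments)


def synth_video_features(spec: SyntheticVideoSpec
                         ) -> tuple[FrameFeatureMatrix, float]:
    """84-channel grid-feature matrix with a planted periodic subset.

    Returns the matrix and the true rate.  The planted channel indices are in
    the matrix's provenance only through the seed; recover them with
    ``np.random.default_rng(seed).choice`` if a test needs the ground truth
    (see :func:`planted_channels`).
    """
    rng = np.random.default_rng(spec.seed)
    T = int(round(spec.duration * spec.frame_rate))
    t = np.arange(T) / spec.frame_rate
    periodic = rng.choice(spec.n_channels, size=spec.n_periodic, replace=False)
    phases = rng.uniform(0.0, 2.0 * np.pi, spec.n_channels)
    drift = rng.uniform(-spec.drift_slope, spec.drift_slope, spec.n_channels)
    X = drift[:, None] * t[None, :]
    X += spec.noise_sd * rng.standard_normal((spec.n_channels, T))
    omega = 2.0 * np.pi * spec.true_rate / 60.0
    X[periodic] += spec.amplitude * np.sin(omega * t[None, :] + phases[periodic, None])
    return (FrameFeatureMatrix(X, frame_rate=spec.frame_rate, modality="video"),
            spec.true_rate)


def planted_channels(spec: SyntheticVideoSpec) -> np.ndarray:
    """Indices of the periodic channels planted by :func:`synth_video_features`."""
    rng = np.random.default_rng(spec.seed)
    return np.sort(rng.choice(spec.n_channels, size=spec.n_periodic, replace=False))


def synth_boundary_probs(
    true_rate: float,
    duration: float = 60.0,
    frame_rate: float = 8000.0 / 267.0,
    interval_jitter_sd: float = 0.2,
    bump_sd_s: float = 0.14,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary-probability series emulating a trained detector's output.

    Gaussian bumps (sd ``bump_sd_s`` seconds, peak 1) at jittered breath
    times, plus clipped Gaussian noise.  Returns (p1, breath_frames).
    """
    rng = np.random.default_rng(seed)
    T = int(round(duration * frame_rate))
    t = np.arange(T) / frame_rate
    mean_iv = 60.0 / true_rate
    times = []
    tt = 0.5 + rng.uniform(0.0, mean_iv)
    while tt < duration - 0.2:
        times.append(tt)
        tt += max(mean_iv + rng.normal(0.0, interval_jitter_sd), 0.3)
    p = np.zeros(T)
    for bt in times:
        p += np.exp(-0.5 * ((t - bt) / bump_sd_s) ** 2)
    p += noise_sd * rng.standard_normal(T)
    p = np.clip(p, 0.0, 1.0)
    breath_frames = np.round(np.asarray(times) * frame_rate).astype(int)
    return p, breath_frames


def make_noise(kind: str, n: int, sample_rate: int, seed: int = 0) -> AudioClip:
    """Seeded noise generators for robustness sweeps.

    ``white`` — flat spectrum; ``pink`` — 1/f power via FFT shaping;
    ``babble`` — sum of 40 random tones with slowly varying amplitudes,
    a crude stand-in for background chatter.  All unit RMS.
    """
    rng = np.random.default_rng(seed)
    if kind == "white":
        x = rng.standard_normal(n)
    elif kind == "pink":
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
        f[0] = f[1] if n > 1 else 1.0
        spec = spec / np.sqrt(f)
        x = np.fft.irfft(spec, n=n)
    elif kind == "babble":
        t = np.arange(n) / sample_rate
        x = np.zeros(n)
        for _ in range(40):
            f0 = rng.uniform(100.0, 1000.0)
            am = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.2, 2.0) * t
                                    + rng.uniform(0, 2 * np.pi))
            x += am * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    return AudioClip(x / np.sqrt(np.mean(x ** 2)), sample_rate)


def mix_at_snr(signal: AudioClip, noise: AudioClip, target_db: float | None,
               seed: int = 0) -> AudioClip:
    """Add noise scaled so the full-clip power ratio equals ``target_db``.

    ``target_db=None`` means clean: the signal is returned unchanged.  Noise
    shorter than the signal is tiled with a seeded random circular offset.
    """
    if target_db is None:
        return AudioClip(signal.samples.copy(), signal.sample_rate)
    if signal.sample_rate != noise.sample_rate:
        raise ValueError("sample rates must match")
    n = len(signal.samples)
    nz = noise.samples
    if len(nz) < n:
        reps = int(np.ceil(n / len(nz))) + 1
        nz = np.tile(nz, reps)
    offset = np.random.default_rng(seed).integers(0, max(len(nz) - n, 1))
    nz = nz[offset: offset + n]
    p_sig = np.mean(signal.samples ** 2)
    p_noise = np.mean(nz ** 2)
    if p_sig <= 0 or p_noise <= 0:
        raise ValueError("signal and noise must have nonzero power")
    # scale noise: 10*log10(p_sig / (a^2 p_noise)) == target_db
    a = np.sqrt(p_sig / (p_noise * 10.0 ** (target_db / 10.0)))
    return AudioClip(signal.samples + a * nz, signal.sample_rate)


def measure_snr(clip: AudioClip, ann: AnnotationTrack) -> float:
    """Segment SNR in dB: average power of the two loudest annotated segments
    over the power of the room tone in the gaps between segments."""
    if len(ann) < 1:
        raise ValueError("need at least one annotated segment")
    sr = clip.sample_rate
    powers = []
    spans = []
    for _, a, b in ann.segments:
        i0 = min(int(round(a * sr)), len(clip.samples))
        i1 = min(int(round(b * sr)), len(clip.samples))
        spans.append((i0, i1))
        seg = clip.samples[i0:i1]
        if len(seg):
            powers.append(float(np.mean(seg ** 2)))
    if not powers:
        raise ValueError("no annotated segment overlaps the clip")
    if len(powers) < 2:
        warnings.warn("only one annotated segment; using it alone for the "
                      "numerator", stacklevel=2)
        top = powers
    else:
        top = sorted(powers, reverse=True)[:2]
    spans.sort()
    gap_samples = []
    for (_, e0), (s1, _) in zip(spans, spans[1:]):
        if s1 > e0:
            gap_samples.append(clip.samples[e0:s1])
    if not gap_samples:
        raise ValueError("no inter-segment gaps to measure room tone")
    gap = np.concatenate(gap_samples)
    p_room = float(np.mean(gap ** 2))
    return 10.0 * np.log10(np.mean(top) / p_room)
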