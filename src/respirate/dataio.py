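"""Audio, annotation and feature-matrix I/O.

The canonical in-memory containers are three small dataclasses:

``AudioClip``
    a mono float waveform with its sample rate;
``AnnotationTrack``
    labelled inspiration/expiration segments in seconds (the dialect of an
    ELAN export flattened to ``label,start,end`` CSV rows);
``FrameFeatureMatrix``
    a channels x frames matrix with its frame rate and modality tag
    (80 log-Mel channels for audio, 84 grid channels for video, 164 fused).

Feature matrices are serialised as a raw little-endian float64 binary plus a
JSON sidecar describing shape, frame rate and modality, so they round-trip
losslessly at 64-bit precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioClip",
    "AnnotationTrack",
    "FrameFeatureMatrix",
    "PHASES",
    "read_wav",
    "write_wav",
    "resample",
    "read_annotations",
    "write_annotations",
    "convert_elan_export",
    "align_modalities",
    "write_features",
    "read_features",
]

PHASES = ("inspiration", "expiration")

#: frame-rate difference (frames/s) below which two streams count as synchronized
FRAME_RATE_TOL = 0.1


class FormatError(ValueError):
    """Raised for unreadable or malformed input files."""


@dataclass
class AudioClip:
    """Mono waveform. ``samples`` are dimensionless floats, ideally in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be 1-D (mono)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return len(self.samples) / self.sample_rate


@dataclass
class AnnotationTrack:
    """Sorted inspiration/expiration segments, each ``(phase, start_s, end_s)``."""

    segments: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = [(str(p), float(a), float(b)) for p, a, b in self.segments]
        for p, a, b in segs:
            if p not in PHASES:
                raise ValueError(f"unknown phase label {p!r}")
            if not a < b:
                raise ValueError(f"segment start must precede end: ({p}, {a}, {b})")
        segs.sort(key=lambda s: (s[1], s[2]))
        for phase in PHASES:
            same = [s for s in segs if s[0] == phase]
            for (_, _, e0), (_, s1, _) in zip(same, same[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping {phase} segments")
        self.segments = segs

    def phase_segments(self, phase: str) -> list[tuple[float, float]]:
        return [(a, b) for p, a, b in self.segments if p == phase]

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class FrameFeatureMatrix:
    """channels x frames feature array sampled at ``frame_rate`` frames/s."""

    values: np.ndarray
    frame_rate: float
    modality: str = "audio"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.modality not in ("audio", "video", "fused"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM WAV file as floats in [-1, 1] at its native rate.

    Integer PCM (16/24/32-bit) is scaled by the full-scale value of its bit
    depth; float WAV passes through.  Stereo is down-mixed to mono by channel
    mean (the modelled case is a single lavalier microphone).
    """
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:
        raise FormatError(f"unsupported WAV sample format {data.dtype}")
    if x.ndim == 2:
        x = x.mean(axis=1)
    return AudioClip(samples=np.asarray(x, dtype=np.float64), sample_rate=int(rate))


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV (values clipped to [-1, 1])."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(clip.sample_rate), pcm)


def resample(clip: AudioClip, target_hz: int) -> AudioClip:
    """Polyphase resampling (``scipy.signal.resample_poly``, default Kaiser
    window with beta=5.0) to ``target_hz``.  Identity when rates match."""
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if target_hz == clip.sample_rate:
        return AudioClip(clip.samples.copy(), clip.sample_rate)
    frac = Fraction(int(target_hz), int(clip.sample_rate))
    y = resample_poly(clip.samples, frac.numerator, frac.denominator)
    return AudioClip(y, int(target_hz))


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read a ``label,start,end`` CSV of breath-phase segments (seconds)."""
    df = pd.read_csv(path)
    expected = ["label", "start", "end"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"annotation CSV must have columns {expected}, got {list(df.columns)}")
    segments = [
        (str(row.label).strip().lower(), float(row.start), float(row.end))
        for row in df.itertuples()
    ]
    return AnnotationTrack(segments)


def write_annotations(path: str | Path, track: AnnotationTrack) -> None:
    df = pd.DataFrame(track.segments, columns=["label", "start", "end"])
    df.to_csv(path, index=False)


def convert_elan_export(src: str | Path, dst: str | Path) -> None:
    """Flatten a raw ELAN tab-export (tier, start, end, label per row, no
    header) into the canonical ``label,start,end`` dialect."""
    rows = []
    for line in Path(src).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"malformed ELAN row: {line!r}")
        _tier, start, end, label = parts[0], parts[1], parts[2], parts[-1]
        rows.append((label.strip().lower(), float(start), float(end)))
    pd.DataFrame(rows, columns=["label", "start", "end"]).to_csv(dst, index=False)


def align_modalities(a: FrameFeatureMatrix, v: FrameFeatureMatrix) -> FrameFeatureMatrix:
    """Concatenate audio and video features channel-wise into a fused matrix.

    The streams are assumed to share t=0; frame rates must agree within
    0.1 frames/s and the longer stream is truncated to the shorter one.
    Audio channels come first.
    """
    if abs(a.frame_rate - v.frame_rate) > FRAME_RATE_TOL:
        raise ValueError(
            f"frame rates differ by more than {FRAME_RATE_TOL} frames/s: "
            f"{a.frame_rate} vs {v.frame_rate}"
        )
    n = min(a.n_frames, v.n_frames)
    fused = np.vstack([a.values[:, :n], v.values[:, :n]])
    return FrameFeatureMatrix(fused, frame_rate=a.frame_rate, modality="fused")


def write_features(prefix: str | Path, X: FrameFeatureMatrix) -> None:
    """Serialise as ``<prefix>.bin`` (raw C-order little-endian float64) plus
    ``<prefix>.json`` sidecar with shape/rate/modality metadata."""
    prefix = Path(prefix)
    vals = np.ascontiguousarray(X.values, dtype="<f8")
    vals.tofile(prefix.with_suffix(".bin"))
    meta = {
        "format_version": 1,
        "channels": X.n_channels,
        "frames": X.n_frames,
        "frame_rate": X.frame_rate,
        "modality": X.modality,
        "dtype": "<f8",
        "order": "C",
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_features(prefix: str | Path) -> FrameFeatureMatrix:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    vals = np.fromfile(prefix.with_suffix(".bin"), dtype=meta["dtype"])
    vals = vals.reshape(meta["channels"], meta["frames"])
    return FrameFeatureMatrix(vals, frame_rate=meta["frame_rate"], modality=meta["modality"])
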