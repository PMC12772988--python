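"""Feature extraction: 84-channel video grid means and 80-band log-Mel audio.

Video: each (optionally ROI-cropped) frame is converted to grayscale
(ITU-R BT.601 luma), resized to 350x600 with bilinear interpolation, and
divided into a 7x12 grid of 50x50-pixel cells; the feature value of a cell is
its mean intensity.  Chest motion modulates these means periodically at the
breathing rate.

Audio: waveform at 8 kHz, Hann window of 512 samples, hop 267 samples
(chosen so the spectral frame rate, 8000/267 = 29.96 frames/s, matches the
29.9 frames/s video rate), 80 HTK-style Mel bands over 0-4000 Hz, natural log
with an additive floor.  Frames are centred via reflect padding, so a clip of
N samples yields 1 + floor(N/hop) frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann
from skimage.transform import resize as _sk_resize

from .dataio import AudioClip, FrameFeatureMatrix

__all__ = [
    "VideoFeatureConfig",
    "AudioFeatureConfig",
    "video_grid_features",
    "log_mel_spectrogram",
    "mel_filterbank",
]

# ITU-R BT.601 luma weights for RGB -> grayscale
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass
class VideoFeatureConfig:
    roi: tuple[int, int, int, int] | str = "full"  # (x0, y0, x1, y1) pixel box
    target_size: tuple[int, int] = (350, 600)  # (height, width)
    window: tuple[int, int] = (50, 50)
    grid: tuple[int, int] = (7, 12)

    def __post_init__(self) -> None:
        th, tw = self.target_size
        wh, ww = self.window
        if th % wh or tw % ww:
            raise ValueError("target_size must be divisible by window size")
        if (th // wh, tw // ww) != tuple(self.grid):
            raise ValueError("grid must equal target_size / window elementwise")


@dataclass
class AudioFeatureConfig:
    sample_rate: int = 8000
    win_length: int = 512
    hop_length: int = 267
    n_mels: int = 80
    log_floor: float = 1e-10
    fmin: float = 0.0
    fmax: float | None = None  # defaults to Nyquist

    def __post_init__(self) -> None:
        if not 0 < self.hop_length < self.win_length:
            raise ValueError("require 0 < hop_length < win_length")
        if self.n_mels <= 0:
            raise ValueError("n_mels must be positive")

    @property
    def frame_rate(self) -> float:
        return self.sample_rate / self.hop_length


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3 and frame.shape[2] == 3:
        return np.asarray(frame, dtype=np.float64) @ _BT601
    raise ValueError(f"frame must be HxW or HxWx3, got shape {frame.shape}")


def video_grid_features(
    frames,
    cfg: VideoFeatureConfig | None = None,
    frame_rate: float = 29.9,
) -> FrameFeatureMatrix:
    """Mean-intensity grid features, one channel per 50x50 cell.

    Channels are ordered row-major over the 7x12 grid (channel 0 is the
    top-left cell, channel ``r*12 + c`` is grid cell (r, c)).
    """
    cfg = cfg or VideoFeatureConfig()
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    shape0 = frames[0].shape
    th, tw = cfg.target_size
    gr, gc = cfg.grid
    wh, ww = cfg.window
    out = np.empty((gr * gc, len(frames)))
    for t, frame in enumerate(frames):
        if frame.shape != shape0:
            raise ValueError("all frames must have the same shape")
        img = _to_gray(frame)
        if cfg.roi != "full":
            x0, y0, x1, y1 = cfg.roi
            img = img[y0:y1, x0:x1]
            if img.size == 0:
                raise ValueError("ROI crop is empty")
        if img.shape != (th, tw):
            img = _sk_resize(img, (th, tw), order=1, anti_aliasing=False,
                             preserve_range=True)
        cells = img.reshape(gr, wh, gc, ww).mean(axis=(1, 3))
        out[:, t] = cells.reshape(-1)
    return FrameFeatureMatrix(out, frame_rate=frame_rate, modality="video")


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sr: int, n_fft: int, n_mels: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular HTK-style Mel filterbank, shape (n_mels, n_fft//2 + 1).

    Band edges are spaced uniformly on the Mel scale between ``fmin`` and
    ``fmax`` (Nyquist by default); each triangle peaks at 1.
    """
    fmax = sr / 2 if fmax is None else fmax
    fft_freqs = np.linspace(0.0, sr / 2, n_fft // 2 + 1)
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def log_mel_spectrogram(clip: AudioClip, cfg: AudioFeatureConfig | None = None
                        ) -> FrameFeatureMatrix:
    """80 x T log-Mel power spectrogram at ~29.96 frames/s.

    Power spectrogram (|STFT|^2 with a periodic Hann window), Mel projection,
    then ``log(mel_power + log_floor)``.
    """
    cfg = cfg or AudioFeatureConfig()
    if clip.sample_rate != cfg.sample_rate:
        raise ValueError(
            f"clip rate {clip.sample_rate} != config rate {cfg.sample_rate}; resample first"
        )
    x = clip.samples
    if len(x) < cfg.win_length:
        raise ValueError("clip shorter than one analysis window")
    half = cfg.win_length // 2
    xp = np.pad(x, half, mode="reflect")
    n_frames = 1 + len(x) // cfg.hop_length
    frames = sliding_window_view(xp, cfg.win_length)[:: cfg.hop_length][:n_frames]
    win = hann(cfg.win_length, sym=False)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    fb = mel_filterbank(cfg.sample_rate, cfg.win_length, cfg.n_mels, cfg.fmin, cfg.fmax)
    mel = spec @ fb.T
    out = np.log(mel.T + cfg.log_floor)
    return FrameFeatureMatrix(out, frame_rate=cfg.frame_rate, modality="audio")
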