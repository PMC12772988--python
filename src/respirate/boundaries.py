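"""Breathing-boundary detection: widened framewise labels, frequency
permutation, a BLSTM framewise classifier, and RR from predicted boundaries.

A *breathing boundary* is the start frame of the louder of the two breath
phases (inspiration or expiration) for the recording at hand.  Boundary
frames are vastly outnumbered by non-boundary frames, so each boundary is
widened to a block of ``widen_width`` class-1 frames (default 10, window
``[b-5, b+4]``) to keep the classifier from collapsing to all-zeros.

*Frequency permutation* shuffles the spectrogram channel order; temporal
periodicity survives the shuffle, so it works as a train-time augmentation
that discourages overfitting to specific Mel bands.

RR from the detector's framewise probability series reuses the
autocorrelation estimator with the series as a single channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autocorr
from .dataio import AnnotationTrack, AudioClip, FrameFeatureMatrix
from .hsmm import BoundaryProbSeries
from .nn import Adam, BLSTMClassifier

__all__ = [
    "BoundaryLabelSeries",
    "BoundaryModelConfig",
    "choose_louder_phase",
    "boundary_frames_from_annotations",
    "make_boundary_labels",
    "frequency_permute",
    "train_boundary_model",
    "predict_boundaries",
    "rr_from_boundaries",
]


@dataclass
class BoundaryLabelSeries:
    labels: np.ndarray  # per-frame class in {0, 1}
    boundary_frames: np.ndarray
    widen_width: int = 10

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.boundary_frames = np.asarray(self.boundary_frames, dtype=np.int64)


@dataclass
class BoundaryModelConfig:
    """Architecture and training hyperparameters for the boundary detector.

    Defaults are the full-size model (two BLSTM layers of 128 units per
    direction, FC 256 -> 2); tests and the synthetic study use a reduced
    ``hidden``/``fc_hidden`` since the synthetic task is much easier than
    real lung sounds.
    """

    n_input: int = 80
    n_blstm_layers: int = 2
    hidden: int = 128
    fc_hidden: int = 256
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    dev_fraction: float = 0.1
    patience: int = 5  # early-stopping patience on dev loss
    class_weighting: bool = True  # inverse-frequency class weights
    freq_permute: bool = True  # train-time augmentation (never at predict time)
    seed: int = 0


def choose_louder_phase(clip: AudioClip, ann: AnnotationTrack) -> str:
    """Phase with the greater mean per-segment average power; ties (and
    single-phase tracks trivially) go to inspiration."""
    if len(ann) == 0:
        raise ValueError("empty annotation track")
    sr = clip.sample_rate
    means = {}
    for phase in ("inspiration", "expiration"):
        seg_powers = []
        for a, b in ann.phase_segments(phase):
            seg = clip.samples[int(round(a * sr)): int(round(b * sr))]
            if len(seg):
                seg_powers.append(np.mean(seg ** 2))
        if seg_powers:
            means[phase] = float(np.mean(seg_powers))
    if len(means) == 1:
        return next(iter(means))
    return "expiration" if means["expiration"] > means["inspiration"] else "inspiration"


def boundary_frames_from_annotations(ann: AnnotationTrack, phase: str,
                                     frame_rate: float, n_frames: int) -> np.ndarray:
    """Start frames of every segment of ``phase``, clipped to the series."""
    starts = [a for a, _ in ann.phase_segments(phase)]
    frames = np.round(np.asarray(starts) * frame_rate).astype(int)
    return frames[(frames >= 0) & (frames < n_frames)]


def make_boundary_labels(boundaries, n_frames: int,
                         widen_width: int = 10) -> BoundaryLabelSeries:
    """Widened binary labels: class 1 on ``[b - w//2, b + w - w//2 - 1]`` for
    each boundary ``b`` (so ``[b-5, b+4]`` at the default width 10), clipped
    to the series; overlapping windows take their union."""
    boundaries = np.asarray(boundaries, dtype=int)
    if np.any((boundaries < 0) | (boundaries >= n_frames)):
        raise ValueError("boundary frame out of range")
    labels = np.zeros(n_frames, dtype=np.int64)
    left = widen_width // 2
    for b in boundaries:
        labels[max(b - left, 0): min(b + widen_width - left, n_frames)] = 1
    return BoundaryLabelSeries(labels=labels, boundary_frames=np.sort(boundaries),
                               widen_width=widen_width)


def frequency_permute(X: FrameFeatureMatrix, seed: int | np.random.Generator = 0
                      ) -> FrameFeatureMatrix:
    """Shuffle spectrogram rows with a seeded uniform random permutation."""
    if X.modality != "audio":
        raise ValueError("frequency permutation applies to audio features")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(X.n_channels)
    return FrameFeatureMatrix(X.values[perm], X.frame_rate, X.modality)


def _zscore_clip(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def train_boundary_model(dataset, cfg: BoundaryModelConfig | None = None
                         ) -> tuple[BLSTMClassifier, dict]:
    """Train the framewise boundary classifier.

    ``dataset`` is a list of ``(FrameFeatureMatrix, BoundaryLabelSeries)``
    pairs (audio modality, equal frame counts).  Each clip is z-scored per
    channel; frequency permutation is re-drawn per clip per epoch when
    enabled.  Training is deterministic given ``cfg.seed``.  Returns the
    model and a history dict with per-epoch train/dev losses.
    """
    cfg = cfg or BoundaryModelConfig()
    if not dataset:
        raise ValueError("empty dataset")
    for X, y in dataset:
        if X.modality != "audio":
            raise ValueError("boundary detector expects audio-modality features")
        if X.n_channels != cfg.n_input:
            raise ValueError(f"expected {cfg.n_input} channels, got {X.n_channels}")
        if len(y.labels) != X.n_frames:
            raise ValueError("label series length must match feature frames")
    lengths = {X.n_frames for X, _ in dataset}
    if len(lengths) != 1:
        raise ValueError("all clips must have equal frame counts for batching")

    rng = np.random.default_rng(cfg.seed)
    feats = np.stack([_zscore_clip(X.values).T for X, _ in dataset])  # (N, T, D)
    labels = np.stack([y.labels for _, y in dataset])  # (N, T)
    n = len(dataset)
    n_dev = 0
    if cfg.dev_fraction > 0 and n > 1:
        n_dev = max(1, int(round(cfg.dev_fraction * n)))
    order = rng.permutation(n)
    dev_idx, train_idx = order[:n_dev], order[n_dev:]
    if len(train_idx) == 0:
        train_idx, dev_idx = order, order[:0]

    if cfg.class_weighting:
        counts = np.bincount(labels[train_idx].ravel(), minlength=2).astype(float)
        counts[counts == 0] = 1.0
        weights = counts.sum() / (2.0 * counts)
    else:
        weights = np.ones(2)

    net = BLSTMClassifier(n_input=cfg.n_input, hidden=cfg.hidden,
                          fc_hidden=cfg.fc_hidden, n_layers=cfg.n_blstm_layers,
                          seed=cfg.seed)
    opt = Adam(net.params, lr=cfg.lr)
    history = {"train_loss": [], "dev_loss": []}
    best_dev = np.inf
    best_params = {k: v.copy() for k, v in net.params.items()}
    stale = 0
    for _epoch in range(cfg.epochs):
        ep_order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(ep_order), cfg.batch_size):
            idx = ep_order[start: start + cfg.batch_size]
            xb = feats[idx]
            if cfg.freq_permute:
                xb = xb.copy()
                for r in range(len(idx)):
                    xb[r] = xb[r][:, rng.permutation(cfg.n_input)]
            loss, grads = net.loss_and_grads(xb, labels[idx], class_weights=weights)
            opt.step(net.params, grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if len(dev_idx):
            from .nn import weighted_ce_loss
            logits = net.forward(feats[dev_idx])
            dev_loss, _ = weighted_ce_loss(logits, labels[dev_idx], weights)
            history["dev_loss"].append(dev_loss)
            if dev_loss < best_dev - 1e-5:
                best_dev = dev_loss
                best_params = {k: v.copy() for k, v in net.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if len(dev_idx):
        net.params = best_params
    return net, history


def predict_boundaries(model: BLSTMClassifier, X: FrameFeatureMatrix
                       ) -> BoundaryProbSeries:
    """Framewise boundary probability p(class 1) for an 80-channel log-Mel
    matrix (z-scored per channel, no permutation at prediction time)."""
    if X.n_channels != model.n_input:
        raise ValueError(f"expected {model.n_input} channels, got {X.n_channels}")
    x = _zscore_clip(X.values).T[None]  # (1, T, D)
    probs = model.predict_proba(x)[0]
    return BoundaryProbSeries(p1=np.clip(probs[:, 1].astype(np.float64), 0.0, 1.0),
                              frame_rate=X.frame_rate)


def rr_from_boundaries(p: BoundaryProbSeries,
                       prior: autocorr.BIPF | None = None,
                       min_lag_s: float = autocorr.DEFAULT_MIN_LAG_S,
                       max_lag_s: float = autocorr.DEFAULT_MAX_LAG_S,
                       **kwargs) -> autocorr.RREstimate:
    """Autocorrelation RR estimate with the probability series as the single
    feature channel (k = 1)."""
    X = FrameFeatureMatrix(p.p1[None, :], frame_rate=p.frame_rate, modality="audio")
    est = autocorr.estimate_rr_autocorr(
        X, k=1, prior=prior, min_lag_s=min_lag_s, max_lag_s=max_lag_s,
        standardize=False, **kwargs)
    return replace(est, method="bb-autocorr")
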