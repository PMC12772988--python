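import numpy as np
import pytest

from respirate import boundaries, features, synthetic

FRAME_RATE = 8000.0 / 267.0


@pytest.fixture(scope="session")
def breath_clip_20bpm():
    """A 60 s synthetic breathing clip at 20 breaths/min with annotations."""
    spec = synthetic.SyntheticAudioSpec(true_rate=20.0, seed=11)
    return synthetic.synth_breath_audio(spec)


@pytest.fixture(scope="session")
def logmel_20bpm(breath_clip_20bpm):
    clip, _ = breath_clip_20bpm
    return features.log_mel_spectrogram(clip)


def make_boundary_dataset(n_clips, duration=20.0, seed0=0, rates=(15, 20, 24)):
    """Small audio feature/label pairs for boundary-detector tests."""
    out = []
    for s in range(n_clips):
        rate = rates[s % len(rates)]
        spec = synthetic.SyntheticAudioSpec(duration=duration, true_rate=rate,
                                            seed=seed0 + s)
        clip, ann = synthetic.synth_breath_audio(spec)
        X = features.log_mel_spectrogram(clip)
        phase = boundaries.choose_louder_phase(clip, ann)
        bf = boundaries.boundary_frames_from_annotations(ann, phase, X.frame_rate,
                                                         X.n_frames)
        out.append((rate, X, boundaries.make_boundary_labels(bf, X.n_frames)))
    return out


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A very small detector memorising 6 short clips; reused across tests."""
    data = make_boundary_dataset(6, duration=20.0, seed0=50)
    cfg = boundaries.BoundaryModelConfig(hidden=16, fc_hidden=32, epochs=6,
                                         batch_size=6, dev_fraction=0.0,
                                         patience=10, seed=3)
    net, history = boundaries.train_boundary_model([(X, y) for _, X, y in data], cfg)
    return net, history, data
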