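"""Evaluation metrics and the noise-robustness sweep harness.

Provides MAE, error SD, Bland-Altman agreement statistics (mean difference
and mean +/- 1.96 SD limits), a Welch two-sample two-tailed t-test on
absolute errors for method comparison, and an SNR sweep that degrades
seeded synthetic breathing clips with noise and reports MAE per SNR level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SyntheticAudioSpec, make_noise, mix_at_snr, synth_breath_audio

__all__ = ["mae", "error_sd", "bland_altman", "welch_ttest", "noise_sweep", "EvalReport"]


@dataclass
class EvalReport:
    truth: np.ndarray
    estimate: np.ndarray
    method: str

    @property
    def mae(self) -> float:
        return mae(self.truth, self.estimate)

    @property
    def error_sd(self) -> float:
        return error_sd(self.truth, self.estimate)

    def bland_altman(self):
        return bland_altman(self.truth, self.estimate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"truth": self.truth, "estimate": self.estimate,
                             "method": self.method})


def _check_pair(truth, est):
    truth = np.asarray(truth, dtype=np.float64)
    est = np.asarray(est, dtype=np.float64)
    if truth.shape != est.shape or truth.ndim != 1 or len(truth) == 0:
        raise ValueError("truth and estimate must be equal-length nonempty 1-D arrays")
    return truth, est


def mae(truth, est) -> float:
    """Mean absolute error, breaths/min."""
    truth, est = _check_pair(truth, est)
    return float(np.mean(np.abs(est - truth)))


def error_sd(truth, est) -> float:
    """Sample (n-1) standard deviation of the signed errors."""
    truth, est = _check_pair(truth, est)
    if len(truth) < 2:
        raise ValueError("need at least 2 pairs")
    return float(np.std(est - truth, ddof=1))


def bland_altman(truth, est) -> tuple[float, float, float]:
    """(mean difference, lower, upper) with limits at mean +/- 1.96 sample SD
    of the differences ``est - truth``."""
    truth, est = _check_pair(truth, est)
    if len(truth) < 2:
        raise ValueError("need at least 2 pairs")
    d = est - truth
    m = float(np.mean(d))
    s = float(np.std(d, ddof=1))
    return m, m - 1.96 * s, m + 1.96 * s


def welch_ttest(truth_a, est_a, truth_b, est_b) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test on the absolute errors of two
    methods; returns (t, p).  Reporting utility only."""
    ta, ea = _check_pair(truth_a, est_a)
    tb, eb = _check_pair(truth_b, est_b)
    res = stats.ttest_ind(np.abs(ea - ta), np.abs(eb - tb), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def noise_sweep(estimator, base_spec: SyntheticAudioSpec, snr_levels,
                n_per_level: int = 10, seed: int = 0,
                noise_kind: str = "pink",
                rates=(12.0, 15.0, 20.0, 24.0, 30.0)) -> pd.DataFrame:
    """MAE of ``estimator`` across SNR levels on seeded synthetic clips.

    ``estimator(clip) -> rate`` is called on each degraded clip.  The same
    clip seeds are reused at every level (including the clean row, SNR
    ``None``), so rows are directly comparable.  Rates cycle through
    ``rates``.  Returns a tidy frame with columns (snr_db, mae, n).
    """
    snr_levels = list(snr_levels)
    if not snr_levels:
        raise ValueError("snr_levels must be nonempty")
    if None not in snr_levels:
        snr_levels = [None] + snr_levels
    clips = []
    for i in range(n_per_level):
        spec = replace(base_spec, true_rate=rates[i % len(rates)], seed=seed + i)
        clip, _ = synth_breath_audio(spec)
        clips.append((spec.true_rate, clip))
    rows = []
    for level in snr_levels:
        truths, ests = [], []
        for i, (rate, clip) in enumerate(clips):
            noise = make_noise(noise_kind, len(clip.samples), clip.sample_rate,
                               seed=seed + 10_000 + i)
            degraded = mix_at_snr(clip, noise, level, seed=seed + 20_000 + i)
            truths.append(rate)
            ests.append(float(estimator(degraded)))
        rows.append({"snr_db": np.inf if level is None else level,
                     "mae": mae(truths, ests), "n": len(clips)})
    return pd.DataFrame(rows)
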