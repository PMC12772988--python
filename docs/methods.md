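# Methods

This note documents the models implemented in `respirate`, the defaults and
why they were chosen, the numerical decisions that make results
reproducible, what the synthetic generators do and do not emulate, and known
limitations.

## Feature extraction

**Video.** Each grayscale frame (ITU-R BT.601 luma if RGB; bilinear resize)
is cropped to a region of interest — supplied by the caller, default the
full frame; automatic chest localisation by a pose model is deliberately out
of scope — resized to 350×600 pixels and divided into a 7×12 grid of 50×50
cells; one channel per cell carries the cell's mean intensity over time.
Chest motion modulates these means at the breathing rate. Channel ordering
is row-major from the top-left cell; the mean over the 84 channels equals
the frame mean exactly (mass conservation), which the tests pin.

**Audio.** Waveforms are polyphase-resampled to 8 kHz
(`scipy.signal.resample_poly`, Kaiser β=5). The log-Mel spectrogram uses a
periodic Hann window of 512 samples, hop 267 samples — chosen so the frame
rate 8000/267 ≈ 29.96 frames/s matches the 29.9 frames/s video within
0.1 frames/s, letting audio and video features be concatenated frame by
frame — 80 HTK-style Mel triangles over 0–4000 Hz, power spectrogram, and
`log(· + 1e-10)`. Frames are centred via reflect padding, so N samples give
`1 + floor(N/267)` frames. All of these conventions are pinned by tests so
frame counts and values are reproducible.

Streams are assumed to share t = 0; fusion truncates to the shorter stream
and concatenates channels (audio first).

## Autocorrelation estimator

Periodicity `P[i, l]` is the mean-centred lagged product with per-lag
normalisation `1/(M − l + 1)`; lags are integer frames internally (the sum
is only well defined that way) and are converted to seconds for reporting.
After computing `P`, a zero-phase moving average of ≈0.25 s of lag
(nearest-edge padding) removes micro-structure; channel variance (the
biased 1/N form) ranks channels, ties broken toward the lower index. The
top-k rows are summed, multiplied by the interval prior, and the first
local maximum `curve[l−1] < curve[l] ≥ curve[l+1]` in a 1–10 s lag window
(60 down to 6 breaths/min) gives `l_max`; `R = 60/l_max`.

Numerical decisions worth knowing:

* **Peak positivity.** A local maximum at a *negative* summed periodicity
  value is residual anti-correlation, not a breath interval, and the
  varying per-lag normalisation produces micro-kinks in the flat part of
  the curve that would otherwise satisfy the peak definition; peaks are
  therefore required to be positive. If no admissible peak exists the
  estimator either raises or (default) falls back to the global maximum of
  the weighted curve and flags the estimate in its diagnostics.
* **Interval prior (BIPF).** Log-normal-shaped weight, mode 3.0 s
  (a typical adult resting breath), log-spread σ_log = 0.8, normalised to
  max 1; a flat prior is available. The spread matters more than it looks:
  because the interval is picked at the *first* local maximum of the
  weighted curve, a prior that rises faster below its mode than the
  periodicity curve can fall fabricates a spurious early peak. The prior's
  log-slope at lag l is `ln(mode/l)/(σ_log² l)`; at the 1 s search boundary
  a 12 breaths/min sinusoid descends at ≈3.8/s, so σ_log must keep the
  prior's rise below that — 0.8 gives 1.7/s, while 0.5 would give 4.4/s and
  systematically mis-locks slow breathers.
* **Per-channel standardisation** (z-score before computing P) is applied
  automatically in fusion mode: scaling a channel by c scales its P row by
  c² and its ranking variance by c⁴, so ranking raw log-Mel values against
  raw pixel means would compare units, not periodicity. With
  standardisation on, the estimate is invariant to per-channel affine
  rescaling; single-modality estimates keep raw scales by default.
* Defaults k = 30 (video) and k = 60 (audio) select the most periodic
  channels while leaving noise-dominated ones out.

The whole pipeline with k = all channels and a flat prior is verified
against an independent loop-level transcription on small matrices.

## Boundary detector

A breathing boundary is the start frame of the louder breath phase
(chosen by comparing mean per-segment power; ties go to inspiration).
Boundary frames are widened to 10 class-1 frames (`[b−5, b+4]`, clipped at
clip edges, overlaps unioned) so the classifier does not collapse to the
majority class.

The classifier is two bidirectional LSTM layers (default 128 units per
direction; tests and the synthetic study use 32 — the synthetic task is far
easier than real lung sounds) followed by fully-connected layers 256→2 and
a framewise softmax. It is implemented directly in numpy with hand-derived
backpropagation through time (verified against central finite differences
to ~1e-9) and Adam (lr 1e-3). Inputs are z-scored per channel per clip;
inverse-frequency class weights balance the loss; frequency permutation —
shuffling the 80 spectrogram rows, which preserves temporal periodicity —
is applied as train-time augmentation, re-drawn per clip per epoch, never
at prediction time. Training holds out 10% of clips for early stopping
(patience 5, ≤50 epochs) and is bit-deterministic given the seed.
Checkpoints are single versioned `.npz` files.

RR from the detector treats the probability series as a one-channel feature
matrix and reuses the autocorrelation estimator with k = 1.

## HSMM

States are pairs of adjacent breath times; gaps are constrained to
`[F_Bmax, F_Bmin]` frames, the frame counts at the fastest/slowest
admissible rates (defaults 60 and 6 breaths/min — deliberately wide; the
decoder, unlike the BIPF route, has no preference inside the band). The
initial law is uniform jointly over admissible gaps and first-breath
positions within one maximal interval (the position rule is ours; only the
gap law is forced by the model). Transitions are a Gaussian in the new gap,
mean the previous gap, σ = 0.5 s expressed in frames, **renormalised over
each state's admissible successors** — required for probabilistic
coherence; near the series end it slightly favours states with fewer
successors, which is harmless under informative emissions. Emissions are
`BB(i)·BB(j)`; interior breath times are counted by two consecutive states,
a property of the model kept as specified. Decoding is max-product in log
space over states with admissible gaps only (≈ T·(F_Bmin−F_Bmax+1) states,
not T²), with −inf for zero probabilities.

**Depth selection.** The trellis depth Q (number of states; Q+1 breaths) is
a free parameter of the model. `Q="auto"` runs one incremental pass to the
largest feasible depth and keeps the depth with the best per-state
normalised log score (`score/Q`, ties to the smaller depth). Normalisation
is what lets depths compete — raw log scores only decrease with more states
— and scanning *all* depths matters: any small candidate set around a
duration-based guess cannot represent rates far from the band midpoint and
intermittently halves fast rates (an alignment that skips every other
breath is also locally consistent).

**Tie-break.** Among equal-score alignments: smallest final state `(i, j)`
lexicographically, then recursively the smallest predecessor breath time.
The brute-force enumeration oracle implements the same scoring with the
same floating-point grouping, so Viterbi agrees with it exactly (path and
log score) on random instances, not merely to tolerance.

The rate is 60 over the mean inter-breath interval in seconds.

## Synthetic data

The generators define the study conditions; their defaults are fixed and
seeded:

* **Audio** (60 s, 8 kHz): each breath cycle is an inspiration burst
  (band-passed 200–1800 Hz noise under a raised-cosine envelope, 0.8 s,
  RMS 0.2) immediately followed by an expiration burst (+6 dB), then rest —
  the duty pattern of relaxed tidal breathing, where the two phases form
  one sustained sound and the intra-breath spacing is much shorter than the
  breath interval. Cycle starts are spaced `60/rate + N(0, 0.2² s²)`;
  room tone RMS 0.01 puts segment SNR near 26 dB (a quiet indoor
  recording). Every segment is annotated, so the SNR measurement
  (mean power of the two loudest segments over inter-segment room tone) can
  be checked against construction.
* **Video** (84 channels, 29.9 frames/s): 8 randomly chosen channels carry
  a unit-amplitude sinusoid at the breathing rate with random phase; all
  channels get linear drift (slope ≤ 0.01/s) and Gaussian noise
  (sd 0.3).
* **Boundary series**: Gaussian bumps (sd 0.14 s ≈ the 10-frame widened
  supervision target) at jittered breath times plus clipped noise
  (sd 0.05) — the shape a well-trained detector produces, without needing
  one.
* **Noise**: seeded pink (default for sweeps), white, and babble-like
  (sum of amplitude-modulated random tones); mixing rescales the noise so
  the full-clip power ratio hits the target SNR exactly.

What the synthetic experiments **do not** show: real lung-sound spectra
(wheezes, crackles, cough), patient movement and camera shake, annotation
error, room reverberation, or domain shift between recording conditions.
Synthetic bursts are band-limited and stationary, so pink noise that
swamps the full-clip SNR still leaves the upper Mel bands comparatively
clean — noise robustness numbers here are upper bounds on what the same
pipeline achieves on clinical audio. Passing tests demonstrate correctness
of the algorithms and their qualitative behaviour (degradation order across
SNR levels, the high-rate advantage of the HSMM over the prior-biased
autocorrelation route), not clinical accuracy.

## Problem sizes in the shipped experiments

The test suite and `scripts/acceptance.py` use 60 s clips for rate
recovery (10 and 6 seeds per rate over {12, 15, 20, 24, 30} breaths/min
respectively), 200 training + 20 held-out 30 s clips at reduced model size
(hidden 32) for the boundary detector, 15 clips per SNR level for the noise
sweep, and 30 s boundary series at 15 frames/s for the HSMM studies —
sizes chosen so the full suite replays in a few minutes while keeping every
comparison statistically meaningful at the effect sizes involved.

## Known limitations

* The first-local-maximum rule inherits the resolution of one frame of lag
  and, on plateau-shaped peaks (ideal impulse trains), the per-lag
  normalisation tilts the plateau so the pick lands up to a smoothing
  halfwidth (≈0.12 s) late.
* The HSMM emission double-counts interior breaths by construction; scores
  are comparable between paths of the same depth, and across depths only
  after per-state normalisation.
* Fusion assumes the modalities are already synchronised at t = 0 and
  frame-rate matched within 0.1 frames/s; no cross-modal alignment is
  attempted.
* `measure_snr` needs at least one inter-segment gap; with a single
  measurable segment it warns and uses that segment alone.
* Training the detector on real corpora (e.g. lung-sound datasets with
  inspiration/expiration annotations) is supported through the same
  WAV + CSV interface but no downloader or fold protocol is bundled.
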