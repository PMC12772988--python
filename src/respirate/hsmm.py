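"""Hidden semi-Markov model over adjacent-breath alignments.

A state is a pair ``(i, j)`` of timesteps of two adjacent breaths, so
inter-breath durations are explicit.  With ``F_B`` the number of frames per
breath at rate ``B`` breaths/min:

* initial probability: uniform over admissible gaps
  ``j - i in [F_Bmax, F_Bmin]`` (and uniform over admissible first-breath
  positions ``i < F_Bmin``), zero otherwise;
* transition ``(i, j) -> (j, k)``: a discretised Gaussian in the new gap
  ``k - j`` with mean equal to the previous gap ``j - i`` and variance
  ``sigma^2`` (frames^2), renormalised over the admissible successors of
  ``j`` — breathing rate changes slowly, so consecutive gaps are similar;
* emission of state ``(i, j)``: ``BB(i) * BB(j)``, the product of the
  boundary-detector probabilities at both breath times.

Viterbi decoding over a fixed number of breaths ``Q`` (the trellis depth,
``Q`` states = ``Q + 1`` breath times) maximises
``pi * prod(a) * prod(b)`` in log space; only admissible-gap states are
instantiated, so the state count is about ``T * (F_Bmin - F_Bmax + 1)``
rather than ``T^2``.  The respiratory rate is ``60 / mean inter-breath
interval``.

Tie-break: among equal-score alignments the decoder returns the one whose
final state ``(i, j)`` is smallest lexicographically, then recursively the
smallest predecessor breath time — matched exactly by the brute-force
enumeration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .autocorr import RREstimate

__all__ = [
    "HSMMParams",
    "AlignmentState",
    "BreathAlignment",
    "BoundaryProbSeries",
    "initial_prob",
    "transition_prob",
    "emission_prob",
    "viterbi_decode",
    "brute_force_decode",
    "rr_from_alignment",
]


@dataclass
class BoundaryProbSeries:
    """Framewise probability of a breathing boundary."""

    p1: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=np.float64).ravel()
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if np.any((self.p1 < 0) | (self.p1 > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.p1)


@dataclass
class HSMMParams:
    """Rate band, frame rate and transition spread of the breath HSMM.

    ``sigma_s`` is the transition standard deviation in seconds; internally
    the Gaussian operates on frame counts with ``sigma2 = (sigma_s *
    frame_rate)^2``.
    """

    frame_rate: float
    b_min: float = 6.0  # breaths/min, slowest admissible rate
    b_max: float = 60.0  # breaths/min, fastest admissible rate
    sigma_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.b_min < self.b_max:
            raise ValueError("require 0 < b_min < b_max")
        if self.sigma_s <= 0 or self.frame_rate <= 0:
            raise ValueError("sigma_s and frame_rate must be positive")
        if self.gap_min >= self.gap_max:
            raise ValueError("rate band too narrow at this frame rate")

    @property
    def gap_min(self) -> int:
        """F at b_max: fewest frames per breath."""
        return int(round(self.frame_rate * 60.0 / self.b_max))

    @property
    def gap_max(self) -> int:
        """F at b_min: most frames per breath."""
        return int(round(self.frame_rate * 60.0 / self.b_min))

    @property
    def sigma2(self) -> float:
        """Transition variance in frames^2."""
        return (self.sigma_s * self.frame_rate) ** 2

    @property
    def n_gaps(self) -> int:
        return self.gap_max - self.gap_min + 1


@dataclass(frozen=True)
class AlignmentState:
    i: int
    j: int

    def __post_init__(self) -> None:
        if not 0 <= self.i < self.j:
            raise ValueError("require 0 <= i < j")

    @property
    def gap(self) -> int:
        return self.j - self.i


@dataclass
class BreathAlignment:
    breath_times: np.ndarray  # frame indices, strictly increasing
    score: float  # log joint probability of the decoded path

    def __post_init__(self) -> None:
        self.breath_times = np.asarray(self.breath_times, dtype=int)
        if np.any(np.diff(self.breath_times) <= 0):
            raise ValueError("breath times must be strictly increasing")


def _admissible_initial(p: HSMMParams, n_frames: int) -> list[tuple[int, int]]:
    """All admissible first states: first breath within one maximal interval."""
    out = []
    for i in range(min(p.gap_max, n_frames)):
        for g in range(p.gap_min, p.gap_max + 1):
            if i + g <= n_frames - 1:
                out.append((i, i + g))
    return out


def initial_prob(state: AlignmentState, p: HSMMParams, n_frames: int) -> float:
    """Jointly normalised uniform initial probability.

    The gap term is uniform over ``[gap_min, gap_max]`` and the first-breath
    position is uniform over ``i < gap_max``; both are zero elsewhere, and
    the product is normalised so the probabilities of all admissible initial
    states sum to one.
    """
    adm = _admissible_initial(p, n_frames)
    if not adm:
        return 0.0
    if (state.i, state.j) in set(adm):
        return 1.0 / len(adm)
    return 0.0


def gap_prior(gap: int, p: HSMMParams) -> float:
    """The gap factor of the initial distribution: uniform over admissible
    inter-breath gaps, ``1 / (gap_max - gap_min + 1)``."""
    if p.gap_min <= gap <= p.gap_max:
        return 1.0 / p.n_gaps
    return 0.0


def _log_kernel(p: HSMMParams) -> np.ndarray:
    """Unnormalised log transition kernel LK[g_prev, g_new] (gaps in frames)."""
    gaps = np.arange(p.gap_min, p.gap_max + 1, dtype=np.float64)
    diff = gaps[None, :] - gaps[:, None]
    return -0.5 * diff ** 2 / p.sigma2


def transition_prob(prev: AlignmentState, nxt: AlignmentState, p: HSMMParams,
                    n_frames: int | None = None) -> float:
    """Renormalised Gaussian transition probability ``(i,j) -> (j,k)``.

    Raises if the states do not share the middle breath.  When ``n_frames``
    is given, normalisation runs over successors that fit before the end of
    the series (states are truncated there), otherwise over all admissible
    gaps.
    """
    if prev.j != nxt.i:
        raise ValueError("states must share the middle breath time")
    g_new = nxt.gap
    if not p.gap_min <= g_new <= p.gap_max or not p.gap_min <= prev.gap <= p.gap_max:
        return 0.0
    if n_frames is not None and nxt.j > n_frames - 1:
        return 0.0
    hi = p.gap_max
    if n_frames is not None:
        hi = min(hi, n_frames - 1 - prev.j)
        if hi < p.gap_min:
            return 0.0
    gaps = np.arange(p.gap_min, hi + 1, dtype=np.float64)
    logw = -0.5 * (gaps - prev.gap) ** 2 / p.sigma2
    return float(np.exp(-0.5 * (g_new - prev.gap) ** 2 / p.sigma2 - logsumexp(logw)))


def emission_prob(state: AlignmentState, bb: BoundaryProbSeries) -> float:
    """``BB(i) * BB(j)``."""
    if state.j >= len(bb):
        raise IndexError("state index beyond series length")
    return float(bb.p1[state.i] * bb.p1[state.j])


def _viterbi_scan(bb: BoundaryProbSeries, p: HSMMParams, q_max: int):
    """One incremental Viterbi pass to depth ``q_max``.

    Returns ``(per_depth, bps)`` where ``per_depth[q-1]`` is
    ``(score, (k, gi))`` — the best depth-q log score and its final state
    with the tie-break applied (smallest ``(i, j)``) — or ``None`` when no
    depth-q path exists, and ``bps`` holds the backpointer arrays.
    """
    T = len(bb)
    G = p.n_gaps
    g0 = p.gap_min
    with np.errstate(divide="ignore"):
        logbb = np.log(bb.p1)
    LK = _log_kernel(p)
    adm = _admissible_initial(p, T)
    if not adm:
        return [], []
    lp0 = -np.log(len(adm))

    # D[k, gi]: best log score of a depth-q path ending in state (k-g, k)
    D = np.full((T, G), -np.inf)
    for i, j in adm:
        D[j, j - i - g0] = lp0 + logbb[i] + logbb[j]

    # per-j truncated-normaliser table: Zc[c, g'] = logsumexp(LK[g', :c])
    Zc = np.full((G + 1, G), -np.inf)
    for c in range(1, G + 1):
        Zc[c] = logsumexp(LK[:, :c], axis=1)
    n_adm_gaps = np.clip(T - 1 - np.arange(T) - g0 + 1, 0, G)  # per j

    def summarise(D):
        if not np.isfinite(D).any():
            return None
        m = D.max()
        cand = np.argwhere(D == m)  # tie-break: smallest (i, j)
        ks, gis = cand[:, 0], cand[:, 1]
        pick = np.lexsort((ks, ks - (g0 + gis)))[0]
        return float(m), (int(ks[pick]), int(gis[pick]))

    per_depth = [summarise(D)]
    bps = []
    for _ in range(2, q_max + 1):
        if per_depth[-1] is None:
            per_depth.append(None)
            bps.append(None)
            continue
        Z = Zc[n_adm_gaps, :]  # (T, G)
        with np.errstate(invalid="ignore"):
            Mp = np.where(np.isfinite(D) & np.isfinite(Z), D - Z, -np.inf)
        # max-plus over previous gap, ties -> largest g' (smallest i)
        Mp_rev = Mp[:, ::-1]
        LK_rev = LK[::-1, :]
        best = np.full((T, G), -np.inf)
        bp = np.zeros((T, G), dtype=np.int16)
        for gi in range(G):
            tmp = Mp_rev + LK_rev[:, gi][None, :]
            am = np.argmax(tmp, axis=1)
            best[:, gi] = tmp[np.arange(T), am]
            bp[:, gi] = (G - 1 - am).astype(np.int16)
        D_new = np.full((T, G), -np.inf)
        bp_store = np.zeros((T, G), dtype=np.int16)
        for gi in range(G):
            g = g0 + gi
            ks = np.arange(g, T)
            vals = best[ks - g, gi] + logbb[ks - g] + logbb[ks]
            D_new[ks, gi] = vals
            bp_store[ks, gi] = bp[ks - g, gi]
        D = D_new
        bps.append(bp_store)
        per_depth.append(summarise(D))
    return per_depth, bps


def _backtrack(final, bps, gap_min: int) -> np.ndarray:
    k, gi = final
    times = [k - (gap_min + gi), k]
    for bp_store in reversed(bps):
        gi_prev = int(bp_store[k, gi])
        k = times[0]
        gi = gi_prev
        times.insert(0, k - (gap_min + gi))
    return np.array(times)


def viterbi_decode(bb: BoundaryProbSeries, p: HSMMParams,
                   Q: int | str = "auto", max_depth: int | None = None
                   ) -> BreathAlignment:
    """Most likely breath alignment by max-product dynamic programming.

    ``Q`` is the trellis depth (number of states; the alignment has ``Q + 1``
    breath times).  ``Q="auto"`` scans every feasible depth up to
    ``floor((T-1)/gap_min)`` (or ``max_depth``) in a single incremental pass
    and keeps the depth with the best per-state normalised log score
    (``score / Q``, ties to the smaller depth).  Normalisation is what lets
    depths compete: raw log scores only ever decrease with more states, and
    a fixed small depth cannot distinguish a breath-per-interval alignment
    from one that skips every other breath.
    """
    T = len(bb)
    if T < p.gap_min + 1:
        raise ValueError("series shorter than one minimal breath interval")
    if Q == "auto":
        q_hi = max(1, (T - 1) // p.gap_min)
        if max_depth is not None:
            q_hi = min(q_hi, max_depth)
        per_depth, bps = _viterbi_scan(bb, p, q_hi)
        results = [
            (s[0] / (q + 1), -(q + 1), q, s[1])
            for q, s in enumerate(per_depth) if s is not None
        ]
        if not results:
            raise RuntimeError("no admissible breath sequence at any depth")
        _, _, qi, final = max(results, key=lambda r: (r[0], r[1]))
        score = per_depth[qi][0]
        times = _backtrack(final, bps[:qi], p.gap_min)
        return BreathAlignment(breath_times=times, score=score)
    if int(Q) < 1:
        raise ValueError("Q must be >= 1")
    Q = int(Q)
    per_depth, bps = _viterbi_scan(bb, p, Q)
    if len(per_depth) < Q or per_depth[Q - 1] is None:
        raise RuntimeError(f"no admissible breath sequence of depth {Q} in {T} frames")
    score, final = per_depth[Q - 1]
    times = _backtrack(final, bps[: Q - 1], p.gap_min)
    return BreathAlignment(breath_times=times, score=score)


def brute_force_decode(bb: BoundaryProbSeries, p: HSMMParams, Q: int
                       ) -> BreathAlignment:
    """Exact argmax by enumerating every admissible breath sequence.

    Test oracle only; guarded to ``T <= 25`` and ``Q <= 4``.  Uses the same
    scoring (joint-uniform initial, truncation-renormalised transitions,
    product emissions) and the same tie-break as :func:`viterbi_decode`.
    """
    T = len(bb)
    if T > 25 or Q > 4:
        raise ValueError("brute force guarded to T <= 25, Q <= 4")
    with np.errstate(divide="ignore"):
        logbb = np.log(bb.p1)
    adm = _admissible_initial(p, T)
    if not adm:
        raise RuntimeError("no admissible initial state")
    lp0 = -np.log(len(adm))
    g0 = p.gap_min
    G = p.n_gaps
    LK = _log_kernel(p)
    Zc = np.full((G + 1, G), -np.inf)
    for c in range(1, G + 1):
        Zc[c] = logsumexp(LK[:, :c], axis=1)

    best: tuple | None = None

    def extend(times: list[int], score: float, depth: int) -> None:
        nonlocal best
        if depth == Q:
            key = (times[-2], times[-1]) + tuple(reversed(times[:-2]))
            if best is None or score > best[0] or (
                    score == best[0] and key < best[1]):
                best = (score, key, list(times))
            return
        j = times[-1]
        g_prev = j - times[-2]
        c = int(np.clip(T - 1 - j - g0 + 1, 0, G))
        if c == 0 or not np.isfinite(score):
            return
        z = Zc[c, g_prev - g0]
        for g in range(g0, p.gap_max + 1):
            k = j + g
            if k > T - 1:
                continue
            # grouping mirrors the vectorised DP so scores match bit-exactly
            s = (((score - z) + LK[g_prev - g0, g - g0]) + logbb[j]) + logbb[k]
            extend(times + [k], s, depth + 1)

    for i, j in adm:
        extend([i, j], lp0 + logbb[i] + logbb[j], 1)
    if best is None or not np.isfinite(best[0]):
        # all paths have -inf score (some BB value is exactly zero on every
        # path); fall back to plain enumeration order for a deterministic
        # answer, mirroring the DP's -inf handling
        raise RuntimeError("no finite-score breath sequence")
    return BreathAlignment(breath_times=np.array(best[2]), score=float(best[0]))


def rr_from_alignment(a: BreathAlignment, frame_rate: float) -> RREstimate:
    """Rate = 60 / mean inter-breath interval (s)."""
    if len(a.breath_times) < 2:
        raise ValueError("need at least two breath times")
    mean_gap_s = float(np.mean(np.diff(a.breath_times))) / frame_rate
    return RREstimate(
        rate=60.0 / mean_gap_s,
        method="bb-hsmm",
        l_max_s=mean_gap_s,
        diagnostics={"breath_times": a.breath_times.tolist(), "score": a.score},
    )
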