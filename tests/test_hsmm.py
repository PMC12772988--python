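import numpy as np
import pytest

from respirate import hsmm, synthetic
from respirate.hsmm import AlignmentState, BoundaryProbSeries, HSMMParams


@pytest.fixture()
def gaps_2_to_6():
    """Frame gaps 2..6: one frame per second, rates 10-30 breaths/min."""
    return HSMMParams(frame_rate=1.0, b_min=10.0, b_max=30.0)


def _random_series(seed, T=20):
    rng = np.random.default_rng(seed)
    return BoundaryProbSeries(rng.uniform(0.01, 1.0, T), 1.0)


def _unnormalised_path_score(times, bb, sigma2):
    """Independent scorer: uniform gap prior, raw Gaussian kernel, product
    emissions (each boundary probability counted as the model counts it)."""
    lp = np.log(bb.p1[times[0]]) + np.log(bb.p1[times[1]])
    for q in range(2, len(times)):
        g_prev = times[q - 1] - times[q - 2]
        g_new = times[q] - times[q - 1]
        lp += -0.5 * (g_new - g_prev) ** 2 / sigma2
        lp += np.log(bb.p1[times[q - 1]]) + np.log(bb.p1[times[q]])
    return lp


def _normalised_path_score(times, bb, p):
    """Score an arbitrary breath sequence under the normalised model via the
    public probability API (independent of the DP internals)."""
    T = len(bb)
    lp = np.log(hsmm.initial_prob(AlignmentState(times[0], times[1]), p, T))
    lp += np.log(bb.p1[times[0]]) + np.log(bb.p1[times[1]])
    for q in range(2, len(times)):
        a = hsmm.transition_prob(AlignmentState(times[q - 2], times[q - 1]),
                                 AlignmentState(times[q - 1], times[q]), p,
                                 n_frames=T)
        lp += np.log(a) + np.log(bb.p1[times[q - 1]]) + np.log(bb.p1[times[q]])
    return lp


class TestParams:
    def test_frame_counts_at_extreme_rates(self, gaps_2_to_6):
        assert gaps_2_to_6.gap_min == 2
        assert gaps_2_to_6.gap_max == 6
        assert gaps_2_to_6.n_gaps == 5

    def test_gap_prior_value(self, gaps_2_to_6):
        assert hsmm.gap_prior(4, gaps_2_to_6) == pytest.approx(1.0 / 5.0)
        assert hsmm.gap_prior(7, gaps_2_to_6) == 0.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            HSMMParams(frame_rate=1.0, b_min=30.0, b_max=10.0)


class TestInitialProb:
    def test_inadmissible_gap_is_zero(self, gaps_2_to_6):
        assert hsmm.initial_prob(AlignmentState(0, 8), gaps_2_to_6, 20) == 0.0

    def test_sums_to_one_over_enumerated_states(self, gaps_2_to_6):
        total = sum(hsmm.initial_prob(AlignmentState(i, j), gaps_2_to_6, 20)
                    for i in range(20) for j in range(i + 1, 20))
        assert total == pytest.approx(1.0)

    def test_uniform_over_admissible(self, gaps_2_to_6):
        a = hsmm.initial_prob(AlignmentState(0, 3), gaps_2_to_6, 20)
        b = hsmm.initial_prob(AlignmentState(4, 9), gaps_2_to_6, 20)
        assert a == b > 0


class TestTransitionProb:
    def test_mode_at_equal_gap(self, gaps_2_to_6):
        probs = {k: hsmm.transition_prob(AlignmentState(0, 4),
                                         AlignmentState(4, 4 + k), gaps_2_to_6)
                 for k in range(2, 7)}
        assert max(probs, key=probs.get) == 4

    def test_symmetry_about_previous_gap(self, gaps_2_to_6):
        lo = hsmm.transition_prob(AlignmentState(0, 4), AlignmentState(4, 7),
                                  gaps_2_to_6)
        hi = hsmm.transition_prob(AlignmentState(0, 4), AlignmentState(4, 9),
                                  gaps_2_to_6)
        assert lo == pytest.approx(hi)

    def test_row_sums_to_one(self, gaps_2_to_6):
        total = sum(hsmm.transition_prob(AlignmentState(0, 4),
                                         AlignmentState(4, 4 + k), gaps_2_to_6)
                    for k in range(2, 7))
        assert total == pytest.approx(1.0)

    def test_small_sigma_concentrates(self):
        p = HSMMParams(frame_rate=1.0, b_min=10.0, b_max=30.0, sigma_s=0.1)
        a = hsmm.transition_prob(AlignmentState(0, 4), AlignmentState(4, 8), p)
        assert a >= 0.99

    def test_mismatched_middle_rejected(self, gaps_2_to_6):
        with pytest.raises(ValueError):
            hsmm.transition_prob(AlignmentState(0, 4), AlignmentState(5, 9),
                                 gaps_2_to_6)


class TestEmissionProb:
    def test_product_rule(self, gaps_2_to_6):
        bb = BoundaryProbSeries([1.0, 0.5, 0.0, 0.2, 1.0], 1.0)
        assert hsmm.emission_prob(AlignmentState(0, 4), bb) == 1.0
        assert hsmm.emission_prob(AlignmentState(2, 4), bb) == 0.0
        assert hsmm.emission_prob(AlignmentState(1, 3), bb) == pytest.approx(0.1)

    def test_out_of_range_rejected(self, gaps_2_to_6):
        bb = BoundaryProbSeries([0.5, 0.5], 1.0)
        with pytest.raises(IndexError):
            hsmm.emission_prob(AlignmentState(0, 5), bb)


class TestViterbi:
    def test_depth_one_is_argmax_of_initial_times_emission(self, gaps_2_to_6):
        bb = _random_series(1)
        a = hsmm.viterbi_decode(bb, gaps_2_to_6, Q=1)
        best, best_score = None, -np.inf
        for i in range(20):
            for g in range(2, 7):
                j = i + g
                if j > 19 or i > gaps_2_to_6.gap_max - 1:
                    continue
                s = (np.log(hsmm.initial_prob(AlignmentState(i, j), gaps_2_to_6, 20))
                     + np.log(bb.p1[i]) + np.log(bb.p1[j]))
                if s > best_score:
                    best, best_score = [i, j], s
        assert list(a.breath_times) == best
        assert a.score == pytest.approx(best_score)

    def test_impulse_train_recovered(self, gaps_2_to_6):
        p1 = np.full(12, 1e-3)
        p1[[2, 5, 8, 11]] = 0.95
        a = hsmm.viterbi_decode(BoundaryProbSeries(p1, 1.0), gaps_2_to_6, Q=3)
        assert list(a.breath_times) == [2, 5, 8, 11]

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence_on_random_series(self, gaps_2_to_6, seed):
        bb = _random_series(seed)
        v = hsmm.viterbi_decode(bb, gaps_2_to_6, Q=3)
        b = hsmm.brute_force_decode(bb, gaps_2_to_6, Q=3)
        assert np.array_equal(v.breath_times, b.breath_times)
        assert v.score == b.score

    def test_score_ties_resolve_identically(self, gaps_2_to_6):
        bb = BoundaryProbSeries(np.full(20, 0.5), 1.0)
        p = HSMMParams(frame_rate=1.0, b_min=10.0, b_max=30.0, sigma_s=100.0)
        v = hsmm.viterbi_decode(bb, p, Q=3)
        b = hsmm.brute_force_decode(bb, p, Q=3)
        assert np.array_equal(v.breath_times, b.breath_times)
        assert v.score == b.score

    def test_enlarged_band_only_grows_the_admissible_optimum(self):
        """Monotone pruning safety on the band's *search space*: the best
        achievable unnormalised alignment score never decreases when the
        rate band is enlarged (normalisation constants shrink with the band,
        so the normalised scores themselves are not comparable)."""
        narrow = HSMMParams(frame_rate=1.0, b_min=12.0, b_max=25.0)
        wide = HSMMParams(frame_rate=1.0, b_min=8.0, b_max=35.0)

        def best_unnormalised(bb, p, Q=3):
            best = -np.inf

            def rec(times):
                nonlocal best
                if len(times) == Q + 1:
                    best = max(best, _unnormalised_path_score(times, bb, p.sigma2))
                    return
                for g in range(p.gap_min, p.gap_max + 1):
                    if times[-1] + g <= len(bb) - 1:
                        rec(times + [times[-1] + g])

            for i in range(min(p.gap_max, len(bb))):
                for g in range(p.gap_min, p.gap_max + 1):
                    if i + g <= len(bb) - 1:
                        rec([i, i + g])
            return best

        for seed in range(5):
            bb = _random_series(seed, T=22)
            assert best_unnormalised(bb, wide) >= best_unnormalised(bb, narrow) - 1e-12

    def test_viterbi_beats_any_rescored_competitor_path(self):
        """DP optimality under the normalised model: the decoded path scores
        at least as high as the optimum of a smaller admissible band when
        both are rescored through the public probability API."""
        narrow = HSMMParams(frame_rate=1.0, b_min=12.0, b_max=25.0)
        wide = HSMMParams(frame_rate=1.0, b_min=8.0, b_max=35.0)
        for seed in range(8):
            bb = _random_series(seed, T=22)
            a_n = hsmm.viterbi_decode(bb, narrow, Q=3)
            a_w = hsmm.viterbi_decode(bb, wide, Q=3)
            s_own = _normalised_path_score(a_w.breath_times, bb, wide)
            s_comp = _normalised_path_score(a_n.breath_times, bb, wide)
            assert s_own == pytest.approx(a_w.score, abs=1e-9)
            assert s_own >= s_comp - 1e-9

    def test_infeasible_depth_rejected(self, gaps_2_to_6):
        bb = _random_series(0, T=8)
        with pytest.raises(RuntimeError):
            hsmm.viterbi_decode(bb, gaps_2_to_6, Q=4)

    def test_brute_force_guard(self, gaps_2_to_6):
        with pytest.raises(ValueError):
            hsmm.brute_force_decode(_random_series(0, T=26), gaps_2_to_6, Q=3)
        with pytest.raises(ValueError):
            hsmm.brute_force_decode(_random_series(0, T=20), gaps_2_to_6, Q=5)

    def test_parameter_recovery_with_jitter_and_noise(self):
        fr = 12.0
        params = HSMMParams(frame_rate=fr)
        for rate in (12.0, 20.0, 30.0):
            errs = []
            for seed in range(8):
                p1, _ = synthetic.synth_boundary_probs(
                    rate, duration=25.0, frame_rate=fr, seed=seed)
                bb = BoundaryProbSeries(p1, fr)
                est = hsmm.rr_from_alignment(hsmm.viterbi_decode(bb, params), fr)
                errs.append(abs(est.rate - rate))
            assert np.median(errs) <= 1.5

    def test_high_rate_beats_low_rate_biased_autocorr(self):
        """A strongly low-rate-favouring interval prior drags the
        boundary-autocorrelation estimate below fast true rates; the HSMM,
        whose gap prior is uniform over the admissible band, is unaffected."""
        from respirate import autocorr, boundaries

        fr = 15.0
        strong_prior = autocorr.BIPF(mode_s=3.0, sigma_log=0.4)
        params = HSMMParams(frame_rate=fr)
        ac_err, hs_err, ac_signed = [], [], []
        for seed in range(12):
            rate = 32.0 + seed % 4
            p1, _ = synthetic.synth_boundary_probs(
                rate, duration=30.0, frame_rate=fr, seed=200 + seed)
            bb = BoundaryProbSeries(p1, fr)
            ac = boundaries.rr_from_boundaries(bb, prior=strong_prior)
            hs = hsmm.rr_from_alignment(hsmm.viterbi_decode(bb, params), fr)
            ac_err.append(abs(ac.rate - rate))
            hs_err.append(abs(hs.rate - rate))
            ac_signed.append(ac.rate - rate)
        assert np.median(hs_err) < np.median(ac_err)
        assert np.median(ac_signed) < 0  # the bias is an under-estimate


class TestRRFromAlignment:
    def test_mean_interval_rate(self):
        a = hsmm.BreathAlignment(np.array([0, 3, 6, 9]), score=0.0)
        assert hsmm.rr_from_alignment(a, 1.0).rate == pytest.approx(20.0)

    def test_two_breaths(self):
        a = hsmm.BreathAlignment(np.array([0, 2]), score=0.0)
        assert hsmm.rr_from_alignment(a, 1.0).rate == pytest.approx(30.0)

    def test_jittered_gaps_use_mean(self):
        a = hsmm.BreathAlignment(np.array([0, 25, 55, 90]), score=0.0)
        assert hsmm.rr_from_alignment(a, 10.0).rate == pytest.approx(20.0)

    def test_single_breath_rejected(self):
        a = hsmm.BreathAlignment(np.array([5]), score=0.0)
        with pytest.raises(ValueError):
            hsmm.rr_from_alignment(a, 1.0)
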