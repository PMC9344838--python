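import math

import numpy as np
import pytest

import splicewarp as sw
from splicewarp.dtw import flat_normal_logpdf
from splicewarp.inference import auto_siq_threshold
from splicewarp.pore_model import CandidateSquiggle


class TestSegment:
    def test_hand_computable_medians(self):
        A = np.array([[0, 0, 1, 1, 2]])
        x = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        s = sw.segment(x, A, min_len=1)
        assert s.bounds == ((0, 2), (2, 4), (4, 5))
        np.testing.assert_array_equal(s.y, [2.0, 6.0, 9.0])
        np.testing.assert_array_equal(s.state_indices, [[0, 1, 2]])

    def test_any_row_change_splits(self):
        A = np.array([[0, 0, 1], [0, 1, 1]])
        s = sw.segment(np.array([1.0, 2.0, 3.0]), A, min_len=1)
        assert s.N == 3
        assert all(e - b == 1 for b, e in s.bounds)

    def test_matches_adjacent_column_scan_oracle(self):
        """Random A and x: segments equal a brute-force scan comparing
        adjacent columns; medians equal a sort-based median."""
        rng = np.random.default_rng(5)
        for _ in range(15):
            M, K = int(rng.integers(1, 4)), int(rng.integers(3, 40))
            A = np.maximum.accumulate(rng.integers(0, 3, size=(M, K)), axis=1)
            x = rng.normal(size=K)
            s = sw.segment(x, A, min_len=1, max_len=K)
            bounds = []
            start = 0
            for k in range(1, K):
                if any(A[m, k] != A[m, k - 1] for m in range(M)):
                    bounds.append((start, k))
                    start = k
            bounds.append((start, K))
            assert s.bounds == tuple(bounds)
            for (b, e), y in zip(bounds, s.y):
                vals = sorted(x[b:e])
                n = len(vals)
                med = (
                    vals[n // 2]
                    if n % 2
                    else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
                )
                assert y == pytest.approx(med)

    def test_min_length_filter_drops_short_segments(self):
        A = np.array([[0, 0, 1, 2, 2, 2]])
        x = np.arange(6.0)
        s = sw.segment(x, A, min_len=2)
        assert s.bounds == ((0, 2), (3, 6))
        assert s.n_dropped == 1

    def test_all_filtered_raises(self):
        A = np.array([[0, 1, 2]])
        with pytest.raises(ValueError, match="no usable segments"):
            sw.segment(np.arange(3.0), A, min_len=2)

    def test_max_length_filter(self):
        A = np.array([[0] * 30 + [1, 2, 3]])
        x = np.arange(33.0)
        s = sw.segment(x, A, min_len=1, max_len=10)
        assert (0, 30) not in s.bounds
        assert s.N == 3


class TestCandidateLoglik:
    def cand(self):
        return CandidateSquiggle(
            "AAAA", np.array([0.0, 1.0, 2.0, 3.0]), np.full(4, 0.5)
        )

    def summary(self, y, states):
        return sw.SegmentedSummary(
            y=np.asarray(y, float),
            bounds=tuple((i, i + 1) for i in range(len(y))),
            state_indices=np.asarray(states),
        )

    def test_density_at_the_mean(self):
        cand = self.cand()
        s = self.summary([0.0, 1.0, 2.0], [[0, 1, 2]])
        got = sw.candidate_loglik(s, cand, 0)
        assert got == pytest.approx(3 * math.log(1 / (0.5 * math.sqrt(2 * math.pi))))

    def test_flat_tail_floor(self):
        cand = self.cand()
        far = sw.candidate_loglik(self.summary([0.0 + 100 * 0.5], [[0]]), cand, 0)
        at3 = sw.candidate_loglik(self.summary([0.0 + 3 * 0.5], [[0]]), cand, 0)
        assert far == pytest.approx(at3)

    def test_order_independent_sum(self):
        rng = np.random.default_rng(7)
        cand = self.cand()
        y = rng.normal(size=40)
        states = rng.integers(0, 4, size=40)
        fwd = sw.candidate_loglik(self.summary(y, [states]), cand, 0)
        rev = sw.candidate_loglik(self.summary(y[::-1], [states[::-1]]), cand, 0)
        assert fwd == pytest.approx(rev, abs=1e-9)


class TestAssignmentProbabilities:
    def test_symmetry(self):
        np.testing.assert_allclose(
            sw.assignment_probabilities([-5.0, -5.0]), [0.5, 0.5]
        )

    def test_hand_computed_softmax(self):
        probs = sw.assignment_probabilities([0.0, -math.log(2), -math.log(2)])
        np.testing.assert_allclose(probs, [0.5, 0.25, 0.25], atol=1e-12)

    def test_prior_passes_through_on_ties(self):
        probs = sw.assignment_probabilities([-3.0, -3.0], priors=[0.9, 0.1])
        np.testing.assert_allclose(probs, [0.9, 0.1], atol=1e-12)

    def test_shift_invariance_and_normalization(self):
        rng = np.random.default_rng(11)
        ll = rng.normal(size=6) * 50
        a = sw.assignment_probabilities(ll)
        b = sw.assignment_probabilities(ll + 1234.5)
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert abs(a.sum() - 1.0) < 1e-9

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        ll = rng.normal(size=5)
        perm = rng.permutation(5)
        a = sw.assignment_probabilities(ll)
        b = sw.assignment_probabilities(ll[perm])
        np.testing.assert_allclose(a[perm], b, atol=1e-12)

    def test_all_minus_inf_rejected(self):
        with pytest.raises(ValueError, match="no candidate"):
            sw.assignment_probabilities([-np.inf, -np.inf])


class TestSiq:
    def res(self, loglik):
        return sw.AlignmentResult(
            path=np.zeros(1, dtype=int), path_loglik=loglik, start_state=0, end_state=0
        )

    def cand(self, n, buf=0):
        return CandidateSquiggle(
            "A" * (n + 2 * buf),
            np.zeros(n + 2 * buf),
            np.ones(n + 2 * buf),
            buf,
            buf,
        )

    def test_single_ratio(self):
        assert sw.compute_siq([self.res(-5.0)], [self.cand(10)]) == pytest.approx(-0.5)

    def test_max_across_candidates(self):
        got = sw.compute_siq(
            [self.res(-5.0), self.res(-20.0)], [self.cand(10), self.cand(10)]
        )
        assert got == pytest.approx(-0.5)

    def test_buffer_excluded_from_denominator(self):
        got = sw.compute_siq([self.res(-5.0)], [self.cand(10, buf=5)])
        assert got == pytest.approx(-0.5)

    def test_no_valid_alignment_gives_minus_inf(self):
        got = sw.compute_siq(
            [sw.AlignmentResult.unalignable()], [self.cand(4)]
        )
        assert got == -np.inf

    def test_auto_threshold_floor_and_outliers(self):
        bulk = list(np.linspace(-0.5, -0.1, 50))
        assert auto_siq_threshold(bulk) == pytest.approx(-0.8)  # floored
        tight = list(np.linspace(0.5, 0.7, 50))
        thr = auto_siq_threshold(tight)
        assert thr > -0.8  # Q1 - 3*IQR of a tight high bulk sits above the floor
        assert auto_siq_threshold([]) == pytest.approx(-0.8)


class TestCallJunction:
    def test_clear_call_passes(self, model6, two_candidate_locus):
        loc = two_candidate_locus
        cs = sw.build_junction_motifs([loc["true"], loc["alt"]], loc["ref"])
        x = loc["simulate_x"](np.random.default_rng(1), noise_scale=0.5)
        call = sw.call_junction(cs, x, model6)
        assert call.passed_filters
        assert call.best == 0
        assert call.best_junction == loc["true"]
        assert call.probs[0] > 0.8
        assert abs(call.probs.sum() - 1.0) < 1e-9

    def test_identical_candidates_give_uniform_posteriors(self, model6, two_candidate_locus):
        loc = two_candidate_locus
        cs_one = sw.build_junction_motifs([loc["true"]], loc["ref"])
        cs = sw.CandidateSet(
            junctions=(loc["true"], loc["true"]),
            motifs=(cs_one.motifs[0], cs_one.motifs[0]),
            sources=("mapped", "mapped"),
            prior_weights=np.array([0.5, 0.5]),
            buffer_head=cs_one.buffer_head,
            buffer_tail=cs_one.buffer_tail,
            common_start=cs_one.common_start,
            common_end=cs_one.common_end,
        )
        x = loc["simulate_x"](np.random.default_rng(2), noise_scale=0.5)
        call = sw.call_junction(cs, x, model6)
        np.testing.assert_allclose(call.probs, [0.5, 0.5], atol=1e-12)
        assert not call.passed_filters
        assert call.reason == "failed_prob"

    def test_offtarget_squiggle_fails_siq(self, model6, two_candidate_locus):
        loc = two_candidate_locus
        cs = sw.build_junction_motifs([loc["true"], loc["alt"]], loc["ref"])
        rng = np.random.default_rng(3)
        motif = "".join(rng.choice(list("ACGT"), 52))
        cfg = sw.SimulationConfig(seed=0, dwell_mean=8.0, noise_scale=0.5)
        sig, _ = sw.simulate_squiggle(motif, model6, cfg, rng)
        call = sw.call_junction(cs, sw.JunctionSquiggle(sig), model6)
        assert not call.passed_filters
        assert call.reason == "failed_siq"
        assert call.siq <= -0.8

    def test_unalignable_when_squiggle_too_short(self, model6, two_candidate_locus):
        loc = two_candidate_locus
        cs = sw.build_junction_motifs([loc["true"], loc["alt"]], loc["ref"])
        call = sw.call_junction(
            cs, sw.JunctionSquiggle(np.array([0.1, 0.2])), model6
        )
        assert call.reason == "unalignable"
        assert np.all(call.probs == 0)

    def test_permuting_candidates_permutes_probs(self, model6, two_candidate_locus):
        loc = two_candidate_locus
        a = sw.build_junction_motifs([loc["true"], loc["alt"]], loc["ref"])
        b = sw.build_junction_motifs([loc["alt"], loc["true"]], loc["ref"])
        x = loc["simulate_x"](np.random.default_rng(4))
        ca = sw.call_junction(a, x, model6)
        cb = sw.call_junction(b, x, model6)
        np.testing.assert_allclose(ca.probs, cb.probs[::-1], atol=1e-9)
        assert ca.best_junction == cb.best_junction

    def test_apply_thresholds_reclassifies(self, model6, two_candidate_locus):
        loc = two_candidate_locus
        cs = sw.build_junction_motifs([loc["true"], loc["alt"]], loc["ref"])
        x = loc["simulate_x"](np.random.default_rng(5), noise_scale=0.5)
        call = sw.call_junction(cs, x, model6)
        assert call.passed_filters
        stricter = sw.apply_thresholds(call, siq_threshold=call.siq + 1.0)
        assert not stricter.passed_filters
        assert stricter.reason == "failed_siq"
        relaxed = sw.apply_thresholds(stricter, siq_threshold=-100.0)
        assert relaxed.passed_filters


def test_spike_robustness_small(model6, two_candidate_locus):
    """5% +/-10 sigma spikes move the max assignment probability < 0.1 in
    nearly all replicates (flat tails + median summaries)."""
    loc = two_candidate_locus
    cs = sw.build_junction_motifs([loc["true"], loc["alt"]], loc["ref"])
    rng = np.random.default_rng(21)
    n, ok = 50, 0
    for _ in range(n):
        seed_rng = np.random.default_rng(rng.integers(2**31))
        state = seed_rng.bit_generator.state
        clean = loc["simulate_x"](seed_rng)
        seed_rng.bit_generator.state = state
        spiked = loc["simulate_x"](seed_rng, spike_rate=0.05)
        p0 = sw.call_junction(cs, clean, model6).probs.max()
        p1 = sw.call_junction(cs, spiked, model6).probs.max()
        ok += abs(p0 - p1) < 0.1
    assert ok >= 0.9 * n
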