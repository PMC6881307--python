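"""Sample entropy, state thresholding, run detection, and the adaptive
threshold search — each checked against an independent naive oracle."""

import math

import numpy as np
import pytest

import emgtcd as E
from emgtcd.errors import ParameterError, SegmentationFailure

from conftest import naive_runs, naive_sample_entropy


class TestSumChannels:
    def test_zero(self):
        rec = E.EmgRecording(samples=np.zeros((9, 100)))
        s = E.sum_channels(rec)
        assert s.shape == (100,) and np.all(s == 0)

    def test_single_active_channel_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        samples = np.zeros((9, 50))
        samples[0] = x
        assert np.array_equal(E.sum_channels(E.EmgRecording(samples=samples)), x)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((9, 30))
        b = rng.standard_normal((9, 30))
        lhs = E.sum_channels(E.EmgRecording(samples=a + b))
        rhs = (E.sum_channels(E.EmgRecording(samples=a))
               + E.sum_channels(E.EmgRecording(samples=b)))
        assert np.allclose(lhs, rhs)


class TestSampleEntropy:
    def test_periodic_window_is_zero(self):
        # every m-match extends to an (m+1)-match, so A == B
        window = np.tile([1.0, 2.0], 256)
        params = E.SampEnParams(sigma=window.std())
        assert E.sample_entropy(window, params) == 0.0

    def test_constant_window_undefined(self):
        window = np.full(512, 3.3)
        params = E.SampEnParams(sigma=0.0)
        assert math.isnan(E.sample_entropy(window, params))

    def test_too_short_window(self):
        with pytest.raises(ParameterError):
            E.sample_entropy(np.zeros(3), E.SampEnParams(sigma=1.0))

    @pytest.mark.parametrize("length", [64, 128, 512])
    def test_matches_naive_oracle(self, length):
        """Implementation equals the O(M^2) double-loop oracle."""
        rng = np.random.default_rng(17)
        for _ in range(6):
            w = rng.standard_normal(length)
            params = E.SampEnParams(sigma=w.std())
            got = E.sample_entropy(w, params)
            want = naive_sample_entropy(w, params.m, params.r)
            assert got == pytest.approx(want, abs=1e-10)

    def test_scale_invariance(self):
        """SampEn(c*x) with r scaled by |c| equals SampEn(x)."""
        rng = np.random.default_rng(21)
        w = rng.standard_normal(256)
        base = E.sample_entropy(w, E.SampEnParams(sigma=w.std()))
        for c in (-3.0, 0.5, 40.0):
            scaled = E.sample_entropy(
                c * w, E.SampEnParams(sigma=abs(c) * w.std())
            )
            assert scaled == pytest.approx(base, abs=1e-12)


class TestStateFunction:
    def test_threshold_applied(self):
        s = E.state_function(np.array([0.1, 0.9, 0.5]), 0.5)
        assert list(s.states) == [0, 1, 1]

    def test_zero_threshold_activates_defined(self):
        s = E.state_function(np.array([0.0, 1.2, np.nan]), 0.0)
        assert list(s.states) == [1, 1, 0]

    def test_all_undefined(self):
        s = E.state_function(np.array([np.nan, np.nan]), 0.3)
        assert list(s.states) == [0, 0]

    def test_active_count_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        sampen = rng.uniform(0, 2, size=200)
        counts = [E.state_function(sampen, th).states.sum()
                  for th in np.linspace(0, 2, 41)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDetectSegments:
    def test_single_run(self):
        states = np.zeros(60, dtype=int)
        states[10:40] = 1
        segs = E.detect_segments(states, L0=12)
        assert len(segs) == 1
        assert (segs[0].l1, segs[0].l2, segs[0].L) == (10, 40, 30)

    def test_short_run_is_noise(self):
        states = np.zeros(30, dtype=int)
        states[5:10] = 1
        assert E.detect_segments(states, L0=12) == []

    def test_matches_run_scan_oracle(self):
        rng = np.random.default_rng(33)
        states = (rng.random(500) < 0.5).astype(int)
        for L0 in (1, 3, 10):
            got = [(s.l1, s.l2) for s in E.detect_segments(states, L0)]
            want = [r for r in naive_runs(states) if r[1] - r[0] >= L0]
            assert got == want

    def test_accepted_plus_rejected_reconstruct_all_runs(self):
        rng = np.random.default_rng(34)
        states = (rng.random(300) < 0.4).astype(int)
        L0 = 4
        accepted = [(s.l1, s.l2) for s in E.detect_segments(states, L0)]
        all_runs = [(s.l1, s.l2) for s in E.detect_segments(states, 1)]
        rejected = [r for r in all_runs if r[1] - r[0] < L0]
        assert sorted(accepted + rejected) == all_runs
        # disjoint and ordered
        for (a1, a2), (b1, b2) in zip(accepted, accepted[1:]):
            assert a2 <= b1


def plateau_series(n_plateaus=5, width=20, gap=15, base=0.2, high=1.5):
    vals = [base] * gap
    for _ in range(n_plateaus):
        vals += [high] * width + [base] * gap
    return np.array(vals)


class TestThresholdSearch:
    def test_recovers_constructed_plateaus(self):
        sampen = plateau_series()
        res = E.optimal_threshold_search(sampen, n0=5)
        assert res.n == 5
        expected = [(15 + i * 35, 35 + i * 35) for i in range(5)]
        assert [(s.l1, s.l2) for s in res.segments] == expected
        assert 0.2 < res.threshold <= 1.5

    def test_constant_series_fails(self):
        with pytest.raises(SegmentationFailure, match="closest"):
            E.optimal_threshold_search(np.full(200, 0.7), n0=5)

    def test_failure_reports_closest_count(self):
        sampen = plateau_series(n_plateaus=3)
        with pytest.raises(SegmentationFailure) as err:
            E.optimal_threshold_search(sampen, n0=7)
        assert err.value.closest_n == 3

    def test_longest_objective_prefers_low_threshold(self):
        """The longest-segment objective maximizes total active length, so
        its threshold is never above the stability choice and its
        segments are at least as long."""
        sampen = plateau_series()
        stable = E.optimal_threshold_search(sampen, n0=5, objective="stability")
        longest = E.optimal_threshold_search(sampen, n0=5, objective="longest")
        assert longest.n == stable.n == 5
        assert longest.threshold <= stable.threshold
        assert (sum(s.L for s in longest.segments)
                >= sum(s.L for s in stable.segments))

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            E.optimal_threshold_search(np.zeros(10), n0=0)
        with pytest.raises(ParameterError):
            E.optimal_threshold_search(np.zeros(10), n0=5, th_grid_step=0.5)


class TestFullDetector:
    def test_recovers_bursts_on_synthetic_trial(self, se_denoised):
        rec, truth = se_denoised
        res, sampen = E.segment_recording(rec)
        assert res.n == 5
        wspec = E.WindowSpec()
        for seg, (b0, b1) in zip(res.segments, truth.burst_intervals):
            t0, t1 = seg.to_seconds(wspec, rec.fs)
            overlap = min(t1, b1) - max(t0, b0)
            assert overlap / (b1 - b0) >= 0.9
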