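"""HMM fitting, decoding and RoH calling, against independent oracles."""

import numpy as np
import pytest

from rohscan.hmm import (WindowHMM, _forward, _log_gaussian, _viterbi,
                         baseline_threshold_caller, call_roh, decode_states,
                         fit_baum_welch, kmeans3_init, roh_to_regions)
from rohscan.windows import synthetic_track
from oracles import brute_force_viterbi

from scipy.special import logsumexp


def random_params(rng, K=3):
    means = np.sort(rng.uniform(0, 5e-4, K))
    variances = rng.uniform(1e-9, 5e-9, K)
    start = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K), size=K)
    return means, variances, start, trans


def background_track(rng, n=40, low_at=None, n_low=3):
    """Synthetic noisy background track with an optional low-het run."""
    ratios = rng.normal(2.5e-4, 3e-5, n).clip(min=5e-5)
    if low_at is not None:
        ratios[low_at:low_at + n_low] = 1e-6
    return synthetic_track(ratios)


class TestKmeansInit:
    def test_perfectly_separated_clusters_recovered_exactly(self):
        ratios = np.array([1e-4] * 10 + [3e-4] * 10 + [9e-4] * 10)
        means, variances, weights = kmeans3_init(ratios, seed=0)
        assert np.allclose(means, [1e-4, 3e-4, 9e-4])
        assert np.allclose(weights, [1 / 3] * 3)
        assert np.all(variances >= 1e-12)

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans3_init(np.full(20, 2e-4), seed=0)

    def test_mixture_means_recovered_within_5_percent(self):
        rng = np.random.default_rng(12)
        truth = np.array([1e-5, 2.5e-4, 6e-4])
        x = np.concatenate([rng.normal(m, m / 10, 1000) for m in truth])
        means, _, weights = kmeans3_init(x, seed=0)
        assert np.allclose(means, truth, rtol=0.05)
        assert np.allclose(weights, 1 / 3, atol=0.02)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5e-4, 200)
        a = kmeans3_init(x, seed=9)
        b = kmeans3_init(x, seed=9)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)


class TestBaumWelch:
    def test_loglik_monotone_and_fit_beats_init(self):
        rng = np.random.default_rng(21)
        track = background_track(rng, n=60, low_at=20, n_low=10)
        model = WindowHMM(track)
        res = model.fit(seed=5)
        diffs = np.diff(res.loglik_history)
        assert np.all(diffs >= -1e-8 * (1 + np.abs(res.loglik_history[:-1])))
        assert res.log_likelihood >= res.loglik_history[0]

    def test_constant_regime_mean_converges(self):
        rng = np.random.default_rng(8)
        ratios = np.full(30, 2.0e-4) + rng.normal(0, 1e-9, 30)
        track = synthetic_track(ratios)
        init = (np.array([1e-4, 2e-4, 4e-4]), np.full(3, 1e-9), np.full(3, 1 / 3))
        res = fit_baum_welch(track, init, seed=1, max_iter=200)
        # ratios quantize to k/150000; the occupied state's mean matches them
        target = track.windows["het_ratio"].mean()
        occupied = np.argmin(np.abs(res.means - target))
        assert res.means[occupied] == pytest.approx(target, rel=1e-3)

    def test_two_regime_roh_mean_recovered(self):
        rng = np.random.default_rng(30)
        ratios = rng.normal(2.5e-4, 2e-5, 200).clip(min=1e-5)
        inside = slice(60, 120)
        ratios[inside] = rng.normal(1e-5, 3e-6, 60).clip(min=0)
        res = WindowHMM(synthetic_track(ratios)).fit(seed=2)
        assert res.means[res.roh_state] == pytest.approx(1e-5, rel=0.20)

    def test_variance_floor_enforced(self):
        rng = np.random.default_rng(13)
        track = background_track(rng, n=50, low_at=10, n_low=15)
        res = WindowHMM(track).fit(seed=3)
        assert np.all(res.variances >= 1e-12)
        assert np.allclose(res.transition.sum(axis=1), 1.0, atol=1e-9)

    def test_forward_loglik_matches_hmmlearn(self):
        from hmmlearn.hmm import GaussianHMM

        rng = np.random.default_rng(17)
        means, variances, start, trans = random_params(rng)
        obs = rng.uniform(0, 5e-4, 25)
        log_obs = _log_gaussian(obs, means, variances)
        ours = logsumexp(_forward(log_obs, np.log(start), np.log(trans))[-1])
        gh = GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        gh.startprob_, gh.transmat_ = start, trans
        gh.means_ = means.reshape(-1, 1)
        gh.covars_ = variances.reshape(-1, 1)
        theirs = gh.score(obs.reshape(-1, 1))
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_too_few_windows_rejected(self):
        track = synthetic_track([1e-4, 2e-4, 3e-4, 4e-4, 5e-4])
        with pytest.raises(ValueError, match="decodable"):
            WindowHMM(track).fit(seed=0)

    def test_posterior_columns_sum_to_one(self):
        from rohscan.hmm import _backward

        rng = np.random.default_rng(40)
        means, variances, start, trans = random_params(rng)
        obs = rng.uniform(0, 5e-4, 30)
        log_obs = _log_gaussian(obs, means, variances)
        alpha = _forward(log_obs, np.log(start), np.log(trans))
        beta = _backward(log_obs, np.log(trans))
        post = np.exp(alpha + beta - logsumexp(alpha[-1]))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(55)
        for _ in range(60):
            T = int(rng.integers(2, 13))
            means, variances, start, trans = random_params(rng)
            obs = rng.uniform(0, 6e-4, T)
            log_obs = _log_gaussian(obs, means, variances)
            ours = _viterbi(log_obs, np.log(start), np.log(trans))
            brute, _ = brute_force_viterbi(log_obs, np.log(start), np.log(trans))
            assert np.array_equal(ours, brute)

    def test_all_windows_at_roh_mean_decode_to_roh_state(self):
        from rohscan.hmm import WindowHMM, WindowHMMResults

        ratios = np.full(20, 1e-5)
        track = synthetic_track(ratios)
        res = WindowHMMResults(
            model=WindowHMM(track),
            means=np.array([1.33e-5, 2.5e-4, 5e-4]),  # track quantizes 1e-5 -> 2/150000
            variances=np.full(3, 1e-10), weights=np.full(3, 1 / 3),
            transition=np.full((3, 3), 1 / 3), start_probs=np.full(3, 1 / 3),
            log_likelihood=0.0, n_iterations=0, seed=0)
        path = decode_states(track, res)
        assert np.all(path == res.roh_state)

    def test_undecodable_windows_break_paths(self):
        ratios = np.array([1e-5] * 5 + [np.nan] + [1e-5] * 5 + [2.5e-4] * 10)
        track = synthetic_track(ratios)
        init = (np.array([1e-5, 1e-4, 2.5e-4]), np.full(3, 1e-10), np.full(3, 1 / 3))
        res = fit_baum_welch(track, init, seed=0, max_iter=5)
        path = decode_states(track, res)
        assert path[5] == -1


class TestCallRoh:
    def _decoded(self, flags):
        """Track + path where flags mark RoH-state windows."""
        ratios = np.where(flags, 0.0, 2.5e-4)
        track = synthetic_track(ratios)
        path = np.where(flags, 0, 2).astype(np.int8)
        return track, path

    def test_three_window_run_gives_minimum_length_segment(self):
        flags = np.zeros(20, dtype=bool)
        flags[5:8] = True
        track, path = self._decoded(flags)
        segs = call_roh(path, track, min_windows=3)
        assert len(segs) == 1
        assert segs["length"].iloc[0] == 150_001
        assert segs["n_windows"].iloc[0] == 3

    def test_two_window_run_emits_nothing(self):
        flags = np.zeros(20, dtype=bool)
        flags[5:7] = True
        track, path = self._decoded(flags)
        assert len(call_roh(path, track, min_windows=3)) == 0

    def test_five_window_run_length(self):
        flags = np.zeros(20, dtype=bool)
        flags[2:7] = True
        track, path = self._decoded(flags)
        segs = call_roh(path, track)
        assert segs["length"].iloc[0] == 250_001

    def test_run_reaching_scaffold_end_truncated(self):
        # with the default geometry a segment can never overrun the
        # scaffold; use a step larger than the trailing-window span so
        # the clamp at the scaffold end is exercised
        from rohscan.io import CallabilityMask, GenomeIndex
        from rohscan.windows import build_window_track

        index = GenomeIndex({"s1": 350_000})
        mask = CallabilityMask({"s1": np.array([[1, 350_000]])})
        track = build_window_track({"s1": np.array([], dtype=np.int64)}, mask, index,
                                   sample="S", width=100_000, overlap=20_000)
        assert track.windows["start"].tolist() == [1, 80_001, 160_001, 240_001, 320_001]
        path = np.zeros(len(track.windows), dtype=np.int8)
        segs = call_roh(path, track, min_windows=3)
        assert segs["end"].iloc[0] == 350_000
        assert segs["length"].iloc[0] == 350_000

    def test_no_segment_shorter_than_convention_minimum(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            flags = rng.random(50) < 0.4
            track, path = self._decoded(flags)
            segs = call_roh(path, track, min_windows=3)
            if len(segs):
                assert segs["length"].min() >= 3 * track.step + 1

    def test_label_permutation_leaves_roh_calls_unchanged(self):
        rng = np.random.default_rng(31)
        ratios = rng.normal(2.5e-4, 2e-5, 120).clip(min=1e-5)
        ratios[40:70] = rng.normal(1e-5, 3e-6, 30).clip(min=0)
        track = synthetic_track(ratios)
        means = np.array([1e-5, 1.5e-4, 2.5e-4])
        variances = np.full(3, 1e-9)
        weights = np.array([0.3, 0.2, 0.5])
        base = fit_baum_welch(track, (means, variances, weights), seed=4)
        perm = np.array([2, 0, 1])
        permuted = fit_baum_welch(
            track, (means[perm], variances[perm], weights[perm]), seed=4,
            transition=None, start_probs=weights[perm])
        a = base.call_roh(track)
        b = permuted.call_roh(track)
        assert a[["scaffold", "start", "end"]].equals(b[["scaffold", "start", "end"]])


class TestBaselineCaller:
    def test_track_above_cutoff_empty(self):
        track = synthetic_track(np.full(20, 2.5e-4))
        assert len(baseline_threshold_caller(track, ratio_cutoff=1e-4)) == 0

    def test_single_dip_gives_minimum_segment(self):
        ratios = np.full(20, 2.5e-4)
        ratios[8:11] = 1e-5
        track = synthetic_track(ratios)
        segs = baseline_threshold_caller(track, ratio_cutoff=1e-4)
        assert len(segs) == 1 and segs["length"].iloc[0] == 150_001

    def test_agrees_with_hmm_caller_on_planted_tracts(self):
        # per-sample RoH fractions from the two callers correlate strongly
        rng = np.random.default_rng(101)
        frac_hmm, frac_base = [], []
        for _ in range(12):
            n = 300
            ratios = rng.normal(2.5e-4, 2e-5, n).clip(min=1e-5)
            target = rng.uniform(0.05, 0.45)
            pos = 0
            while pos < n * target:
                start = int(rng.integers(0, n - 12))
                ln = int(rng.integers(8, 13))
                ratios[start:start + ln] = rng.normal(1e-5, 3e-6, ln).clip(min=0)
                pos += ln
            track = synthetic_track(ratios)
            res = WindowHMM(track).fit(seed=7)
            genome = int(track.windows["end"].max())
            frac_hmm.append(res.call_roh(track)["length"].sum() / genome)
            frac_base.append(
                baseline_threshold_caller(track, 1e-4)["length"].sum() / genome)
        r = np.corrcoef(frac_hmm, frac_base)[0, 1]
        assert r > 0.9


def test_roh_to_regions_merges_overlaps():
    import pandas as pd

    segs = pd.DataFrame({"scaffold": ["s1", "s1"], "start": [1, 100_000],
                         "end": [200_000, 300_000]})
    regions = roh_to_regions(segs)
    assert regions["s1"].tolist() == [[1, 300_000]]
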