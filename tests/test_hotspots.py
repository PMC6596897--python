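import itertools

import numpy as np
import pandas as pd
import pytest

from equivnet import hotspots as H


def brute_force_viterbi(rates, params):
    """Independent oracle: enumerate all 2^n state paths."""
    best_ll, best_path = -np.inf, None
    for path in itertools.product((0, 1), repeat=len(rates)):
        ll = H.path_loglik(np.asarray(rates), np.asarray(path), params)
        if ll > best_ll:
            best_ll, best_path = ll, path
    return np.asarray(best_path)


def random_params(rng):
    mean_cold = rng.uniform(0.1, 1.0)
    mean_hot = mean_cold * rng.uniform(2.0, 30.0)
    a, b = rng.uniform(0.5, 0.99, 2)
    return H.HMM2Params(mean_hot, mean_cold, np.array([[a, 1 - a], [1 - b, b]]))


class TestViterbi:
    def test_all_zero_rates_decode_cold(self):
        params = H.HMM2Params(10.0, 0.1, np.full((2, 2), 0.5))
        states = H.viterbi(np.zeros(20), params)
        assert (states == H.COLD).all()

    def test_single_hot_window(self):
        # one observation at the hot mean, uniform transitions:
        # log f(x; hot) = -log(10.5) - 1 beats log f(x; cold) = -log(0.5) - 21
        params = H.HMM2Params(10.5, 0.5, np.full((2, 2), 0.5))
        assert H.viterbi(np.array([10.5]), params)[0] == H.HOT

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(50):
            params = random_params(rng)
            n = int(rng.integers(2, 13))
            rates = rng.exponential(rng.uniform(0.2, 10.0), n)
            dp = H.viterbi(rates, params)
            oracle = brute_force_viterbi(rates, params)
            assert H.path_loglik(rates, dp, params) >= H.path_loglik(rates, oracle, params) - 1e-9
            assert np.array_equal(dp, oracle)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            H.viterbi(np.array([]), H.HMM2Params(2.0, 1.0, np.full((2, 2), 0.5)))


class TestViterbiTraining:
    def test_parameter_recovery(self, rng):
        true = H.HMM2Params(10.5, 0.5, np.array([[0.99, 0.01], [0.01, 0.99]]))
        track, _ = H.simulate_rate_track(true, 10_000, rng=np.random.default_rng(42))
        init = H.HMM2Params(5.0, 1.0, np.array([[0.9, 0.1], [0.1, 0.9]]))
        fitted = H.viterbi_train(track["rate"].to_numpy(), init)
        assert abs(fitted.mean_hot - 10.5) / 10.5 < 0.10
        assert abs(fitted.mean_cold - 0.5) / 0.5 < 0.10
        assert abs(fitted.transitions[0, 0] - 0.99) < 0.02
        assert abs(fitted.transitions[1, 1] - 0.99) < 0.02

    def test_training_monotone_in_joint_likelihood(self, rng):
        true = H.HMM2Params(8.0, 0.4, np.array([[0.95, 0.05], [0.05, 0.95]]))
        track, _ = H.simulate_rate_track(true, 2000, rng=np.random.default_rng(3))
        rates = np.maximum(track["rate"].to_numpy(), H.RATE_FLOOR)
        params = H.HMM2Params(3.0, 1.0, np.array([[0.8, 0.2], [0.2, 0.8]]))
        prev = -np.inf
        for _ in range(10):
            path = H.viterbi(rates, params)
            ll = H.path_loglik(rates, path, params)
            assert ll >= prev - 1e-9
            prev = ll
            params = H.viterbi_train(rates, params, max_iter=1)

    def test_single_state_track(self):
        rates = np.full(200, 0.3)
        init = H.HMM2Params(5.0, 0.4, np.array([[0.9, 0.1], [0.1, 0.9]]))
        with pytest.warns(UserWarning):  # hot state receives zero windows
            fitted = H.viterbi_train(rates, init)
        path = H.viterbi(rates, fitted)
        assert len(np.unique(path)) == 1
        assert np.isclose(fitted.mean_cold, 0.3)

    def test_true_parameters_near_fixed_point(self):
        true = H.HMM2Params(10.5, 0.5, np.array([[0.99, 0.01], [0.01, 0.99]]))
        track, _ = H.simulate_rate_track(true, 10_000, rng=np.random.default_rng(9))
        one_step = H.viterbi_train(track["rate"].to_numpy(), true, max_iter=1)
        assert abs(one_step.mean_hot - true.mean_hot) / true.mean_hot < 0.05
        assert abs(one_step.mean_cold - true.mean_cold) / true.mean_cold < 0.05
        assert np.abs(one_step.transitions - true.transitions).max() < 0.01

    def test_estimator_facade(self):
        true = H.HMM2Params(10.5, 0.5, np.array([[0.99, 0.01], [0.01, 0.99]]))
        track, states = H.simulate_rate_track(true, 5000, rng=np.random.default_rng(5))
        seg = H.ExponentialHMMSegmenter(mean_hot=5.0, mean_cold=1.0, self_transition=0.9)
        seg.fit(track["rate"])
        assert seg.mean_hot_ > seg.mean_cold_
        decoded = seg.predict(track["rate"])
        assert (decoded == states).mean() > 0.95


class TestSegmentsToSequences:
    def make_track(self, n, chrom="chr1", w=1000):
        return pd.DataFrame(
            {"chrom": chrom, "start": np.arange(n) * w, "end": (np.arange(n) + 1) * w,
             "rate": np.ones(n)}
        )

    def test_call_hotspots_merges_runs(self):
        track = self.make_track(6)
        states = np.array([1, 0, 0, 1, 0, 1])
        iv = H.call_hotspots(states, track)
        assert list(iv["start"]) == [1000, 4000]
        assert list(iv["end"]) == [3000, 5000]

    def test_alternating_states_one_interval_each(self):
        track = self.make_track(6)
        iv = H.call_hotspots(np.array([0, 1, 0, 1, 0, 1]), track)
        assert len(iv) == 3
        assert ((iv["end"] - iv["start"]) == 1000).all()

    def test_all_cold_empty(self):
        assert len(H.call_hotspots(np.ones(5, dtype=int), self.make_track(5))) == 0

    def test_extract_center_rules(self, rng):
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 12_000))
        genome = {"chr1": contig}
        intervals = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [2000, 5000],
                "end": [4000, 10_500],  # 2 kb kept, 5.5 kb discarded
                "mean_rate": [5.0, 5.0],
            }
        )
        out = H.extract_center(intervals, genome)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"]) == (2500, 3500)
        assert row["seq"] == contig[2500:3500]

    def test_extract_center_drops_n_and_contig_overruns(self):
        genome = {"chr1": "A" * 1500 + "N" + "A" * 1500}
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2000], "mean_rate": [1.0]})
        assert len(H.extract_center(iv, genome)) == 0  # center window hits the N
        iv2 = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [400], "mean_rate": [1.0]})
        with pytest.warns(UserWarning):
            assert len(H.extract_center(iv2, genome)) == 0  # window past contig start


class TestGcContent:
    def test_values(self):
        assert H.gc_content("ATGC") == 0.5
        assert H.gc_content("GGGG") == 1.0

    def test_rc_invariant(self, rng):
        from equivnet.sequences import rc_seq

        for _ in range(20):
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            assert H.gc_content(s) == H.gc_content(rc_seq(s))

    def test_errors(self):
        with pytest.raises(ValueError):
            H.gc_content("")
        with pytest.raises(ValueError):
            H.gc_content("ACGN")


class TestColdspotMatching:
    def toy(self, rng, n_kb=40):
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, n_kb * 1000))
        track = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n_kb) * 1000,
                "end": (np.arange(n_kb) + 1) * 1000,
                "rate": np.zeros(n_kb),
            }
        )
        return {"chr1": contig}, track

    def test_adjacent_identical_gc_window_chosen(self):
        genome = {"chr1": "ACGT" * 1000}
        track = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [4000], "rate": [0.0]}
        )
        hit = H.match_coldspot(("chr1", 1000, 2000), genome, track)
        assert hit is not None
        chrom, s, e, seq = hit
        assert (s, e) == (2000, 3000)  # first candidate to the right

    def test_rate_ceiling_blocks_all(self, rng):
        genome, track = self.toy(rng)
        track["rate"] = 5.0
        assert H.match_coldspot(("chr1", 10_000, 11_000), genome, track) is None

    def test_matches_never_overlap_hotspots(self, rng):
        for trial in range(100):
            local = np.random.default_rng(trial)
            genome, track = self.toy(local, n_kb=30)
            hot = pd.DataFrame(
                {"chrom": "chr1", "start": [5000, 12_000], "end": [6000, 13_000]}
            )
            cold = H.match_coldspots(hot, genome, track, search_radius=20_000)
            for row in cold.itertuples():
                for hs, he in ((5000, 6000), (12_000, 13_000)):
                    assert row.end <= hs or row.start >= he
            # chosen coldspots are pairwise disjoint
            spans = sorted((r.start, r.end) for r in cold.itertuples())
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_emitted_pairs_satisfy_constraints(self, rng):
        genome, track = self.toy(rng)
        hot = pd.DataFrame({"chrom": ["chr1"], "start": [20_000], "end": [21_000]})
        cold = H.match_coldspots(hot, genome, track, gc_tol=0.05, rate_max=0.5)
        for row in cold.itertuples():
            gc_h = H.gc_content(genome["chr1"][row.hot_start : row.hot_end])
            assert abs(H.gc_content(row.seq) - gc_h) <= 0.05
            assert H._TrackIndex(track).mean_rate("chr1", row.start, row.end) < 0.5

    def test_relative_gc_tolerance_mode(self, rng):
        genome, track = self.toy(rng)
        hit = H.match_coldspot(("chr1", 20_000, 21_000), genome, track, relative_gc=True, gc_tol=0.10)
        if hit is not None:
            gc_h = H.gc_content(genome["chr1"][20_000:21_000])
            assert abs(H.gc_content(hit[3]) - gc_h) <= 0.10 * gc_h


class TestTrackSimulation:
    def test_absorbing_hot_state(self):
        params = H.HMM2Params(5.0, 0.5, np.array([[1.0, 0.0], [0.0, 1.0]]),
                              initial=np.array([1.0, 0.0]))
        _, states = H.simulate_rate_track(params, 100, rng=np.random.default_rng(1))
        assert (states == H.HOT).all()

    def test_hot_state_rate_mean(self):
        params = H.HMM2Params(10.5, 0.5, np.array([[0.9, 0.1], [0.1, 0.9]]))
        track, states = H.simulate_rate_track(params, 20_000, rng=np.random.default_rng(2))
        hot_rates = track["rate"].to_numpy()[states == H.HOT]
        se = 10.5 / np.sqrt(hot_rates.size)
        assert abs(hot_rates.mean() - 10.5) < 3 * se

    def test_seed_determinism(self):
        params = H.HMM2Params(2.0, 0.2, np.full((2, 2), 0.5))
        t1, s1 = H.simulate_rate_track(params, 50, rng=np.random.default_rng(7))
        t2, s2 = H.simulate_rate_track(params, 50, rng=np.random.default_rng(7))
        assert t1.equals(t2) and np.array_equal(s1, s2)

    def test_track_io_round_trip(self, tmp_path):
        params = H.HMM2Params(2.0, 0.2, np.full((2, 2), 0.5))
        track, _ = H.simulate_rate_track(params, 20, rng=np.random.default_rng(1))
        path = tmp_path / "track.tsv"
        H.write_rate_track(str(path), track)
        back = H.read_rate_track(str(path))
        assert np.allclose(back["rate"], track["rate"])
        assert list(back["start"]) == list(track["start"])
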