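import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mea3d.geometry import ElectrodeAddress, SpikeTrain
from mea3d.synchrony import (
    SynchronyMatrix,
    SynchronyParams,
    pairwise_matrix,
    spike_distance,
    surrogate_distance,
    synchrony,
    synchrony_timecourse,
)

from conftest import make_recording
from spike_oracle import grid_spike_distance


def train(times, duration=30.0, e=1):
    return SpikeTrain(ElectrodeAddress(1, 1, e), np.asarray(times, float), duration)


class TestSpikeDistance:
    def test_identical_trains_have_zero_distance(self):
        a = train([3.0, 7.5, 12.0, 20.0])
        assert spike_distance(a, a) == 0.0

    def test_symmetry_is_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = train(np.sort(rng.uniform(0, 30, 15)))
            b = train(np.sort(rng.uniform(0, 30, 25)), e=2)
            assert spike_distance(a, b) == spike_distance(b, a)

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            na, nb = rng.integers(1, 60, size=2)
            ta = np.sort(rng.uniform(0, 30, na))
            tb = np.sort(rng.uniform(0, 30, nb))
            exact = spike_distance(train(ta), train(tb, e=2))
            approx = grid_spike_distance(ta, tb, 30.0)
            assert exact == pytest.approx(approx, abs=1e-3)

    def test_single_spike_trains_match_oracle(self):
        a, b = train([10.0]), train([20.0], e=2)
        assert spike_distance(a, b) == pytest.approx(
            grid_spike_distance([10.0], [20.0], 30.0), abs=1e-3
        )

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_time_rescaling_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        ta = np.sort(rng.uniform(0, 30, rng.integers(2, 40)))
        tb = np.sort(rng.uniform(0, 30, rng.integers(2, 40)))
        d1 = spike_distance(train(ta), train(tb, e=2))
        d2 = spike_distance(
            SpikeTrain(ElectrodeAddress(1, 1, 1), c * ta, 30.0 * c),
            SpikeTrain(ElectrodeAddress(1, 1, 2), c * tb, 30.0 * c),
        )
        assert d2 == pytest.approx(d1, abs=1e-9)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            ta = np.sort(rng.uniform(0, 30, rng.integers(1, 80)))
            tb = np.sort(rng.uniform(0, 30, rng.integers(1, 80)))
            d = spike_distance(train(ta), train(tb, e=2))
            assert 0.0 <= d <= 1.0

    def test_empty_train_and_duration_mismatch_error(self):
        with pytest.raises(ValueError):
            spike_distance(train([]), train([1.0], e=2))
        with pytest.raises(ValueError):
            spike_distance(train([1.0]), train([1.0], duration=20.0, e=2))


class TestSynchronyScore:
    def test_identical_trains_score_one_with_and_without_normalization(self):
        a = train(np.linspace(1, 29, 50))
        assert synchrony(a, a, SynchronyParams(normalize=False)) == 1.0
        assert synchrony(a, a, SynchronyParams(normalize=True)) == 1.0

    def test_pair_at_surrogate_level_scores_zero(self):
        # construct the score from its definition: D == D_rand -> 1 - D/D_rand = 0
        params = SynchronyParams(seed=3)
        rng = np.random.default_rng(4)
        a = train(np.sort(rng.uniform(0, 30, 40)))
        b = train(np.sort(rng.uniform(0, 30, 40)), e=2)
        d = spike_distance(a, b)
        d_rand = surrogate_distance(40, 40, 30.0, params, entropy=(0,))
        score = synchrony(a, b, params, _entropy=(0,))
        assert score == pytest.approx(max(0.0, 1.0 - d / d_rand))

    def test_independent_poisson_pairs_score_near_zero_on_average(self):
        params = SynchronyParams(n_surrogates=10, seed=5)
        rng = np.random.default_rng(6)
        scores = []
        for k in range(40):
            a = train(np.sort(rng.uniform(0, 60, 80)), duration=60.0)
            b = train(np.sort(rng.uniform(0, 60, 80)), duration=60.0, e=2)
            d = spike_distance(a, b)
            d_rand = surrogate_distance(80, 80, 60.0, params, entropy=(k,))
            scores.append(1.0 - d / d_rand)  # unclipped, sign-preserving
        scores = np.asarray(scores)
        se = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean()) < 3.0 * se + 1e-12

    def test_similarity_normalization_variant(self):
        params = SynchronyParams(method="similarity", seed=7)
        a = train(np.linspace(1, 29, 30))
        assert synchrony(a, a, params) == 1.0


class TestPairwiseMatrix:
    def test_cofiring_array_blocks_are_one(self, layout):
        times = np.linspace(1.0, 58.0, 40)
        rec = make_recording(layout, lambda a: times, duration=60.0)
        m = pairwise_matrix(rec, SynchronyParams(normalize=False))
        blocks = m.section_block_means()
        np.testing.assert_allclose(blocks.to_numpy(dtype=float), 1.0)

    def test_all_silent_array_is_fully_missing(self, layout):
        rec = make_recording(layout, lambda a: [1.0], duration=60.0)
        m = pairwise_matrix(rec, SynchronyParams(normalize=False))
        assert np.isnan(m.scores).all()

    def test_matrix_symmetric_with_nan_diagonal(self, layout):
        rng = np.random.default_rng(8)
        rec = make_recording(
            layout, lambda a: np.sort(rng.uniform(0, 60, 30)), duration=60.0
        )
        m = pairwise_matrix(rec, SynchronyParams(normalize=False))
        np.testing.assert_array_equal(m.scores, m.scores.T)
        assert np.isnan(np.diag(m.scores)).all()

    def test_within_coupling_only_separates_blocks(self, layout):
        from mea3d.synthetic import CultureConfig, simulate_recording

        cfg = CultureConfig(between_coupling=0.0)
        rec = simulate_recording(cfg, div=45, seed=9, duration=200.0,
                                 layout=layout)
        blocks = pairwise_matrix(
            rec, SynchronyParams(normalize=False)
        ).section_block_means().to_numpy(dtype=float)
        within = np.diag(blocks).mean()
        between = blocks[~np.eye(4, dtype=bool)].mean()
        assert within > between


class TestTimecourse:
    def test_stationary_cofiring_profile_is_flat_at_one(self, layout):
        times = np.arange(0.5, 120.0, 1.5)
        rec = make_recording(layout, lambda a: times, duration=120.0)
        prof = synchrony_timecourse(rec, window=30.0,
                                    params=SynchronyParams(normalize=False))
        assert prof.shape[0] == 4
        np.testing.assert_allclose(prof.to_numpy(dtype=float), 1.0)

    def test_second_half_coupling_raises_second_half_profile(self, layout):
        rng = np.random.default_rng(10)
        shared = np.sort(rng.uniform(60.0, 120.0, 60))

        def times_fn(a):
            own = np.sort(rng.uniform(0.0, 60.0, 60))
            return np.sort(np.concatenate([own, shared]))

        rec = make_recording(layout, times_fn, duration=120.0)
        prof = synchrony_timecourse(rec, window=60.0,
                                    params=SynchronyParams(normalize=False))
        for sec in prof.columns:
            assert prof[sec].iloc[1] > prof[sec].iloc[0]

    def test_silent_section_profile_missing(self, layout):
        def times_fn(a):
            return [] if a.section == "top" else np.arange(0.5, 60.0, 1.0)

        rec = make_recording(layout, times_fn, duration=60.0)
        prof = synchrony_timecourse(rec, window=60.0,
                                    params=SynchronyParams(normalize=False))
        assert np.isnan(prof["top"]).all()
        assert prof.shape[0] == 1  # window longer than recording -> single window

    def test_nonpositive_window_rejected(self, uniform_recording):
        with pytest.raises(ValueError):
            synchrony_timecourse(uniform_recording, window=0.0)
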