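"""Map combination: iteration, sum/max baselines, clustered strategy."""

import numpy as np
import pytest

from v1sal.combination import (
    CombineParams,
    combine,
    combine_clustered,
    combine_iterate,
    combine_max,
    combine_sum,
    iterate_map,
)


@pytest.fixture
def params():
    return CombineParams(seed=3)


def impulse_stack(seed=42, n_maps=6, shape=(48, 48), peak=(24, 24)):
    """One informative impulse map among weak-noise maps."""
    rng = np.random.default_rng(seed)
    maps = 0.05 * rng.random((n_maps,) + shape)
    maps[0][peak] = 1.0
    return maps


class TestIterateMap:
    def test_peak_to_background_ratio_grows(self, params):
        rng = np.random.default_rng(31)
        s = 0.1 * rng.random((64, 64))
        s[32, 32] = 1.0
        before = s[32, 32] / np.median(s[s > 0])
        out = iterate_map(s, params)
        bg = np.median(out[out > 0]) if (out > 0).sum() > 1 else 1e-12
        assert out[32, 32] / bg > before

    def test_zero_map_stays_zero(self, params):
        out = iterate_map(np.zeros((32, 32)), params)
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_when_dog_and_bias_vanish(self, rng):
        p = CombineParams(c_ex=0.0, c_inh=0.0, c_inh_const=0.0, n_iterations=4)
        s = rng.random((20, 20))
        np.testing.assert_array_equal(iterate_map(s, p), s)

    def test_nonfinite_rejected(self, params):
        s = np.zeros((10, 10))
        s[0, 0] = np.nan
        with pytest.raises(ValueError):
            iterate_map(s, params)


class TestSumMax:
    def test_single_map_normalized(self, rng):
        m = 2.0 * rng.random((16, 16))
        out = combine_sum(m[None])
        np.testing.assert_allclose(out.s, m / m.max())
        out2 = combine_max(m[None])
        np.testing.assert_allclose(out2.s, m / m.max())

    def test_two_identical_maps_sum_doubles(self, rng):
        m = rng.random((16, 16))
        out = combine_sum(np.stack([m, m]))
        np.testing.assert_allclose(out.s, 2 * m / m.max())

    def test_max_dominates_inputs(self, rng):
        maps = rng.random((4, 12, 12))
        out = combine_max(maps)
        for m in maps:
            assert (out.s >= m / m.max() - 1e-12).all()

    def test_against_pixel_loop_oracle(self, rng):
        maps = rng.random((3, 9, 9))
        norm = np.stack([m / m.max() for m in maps])
        s_sum = combine_sum(maps).s
        s_max = combine_max(maps).s
        for i in range(9):
            for j in range(9):
                assert s_sum[i, j] == pytest.approx(norm[:, i, j].sum(), abs=1e-12)
                assert s_max[i, j] == pytest.approx(norm[:, i, j].max(), abs=1e-12)

    def test_reordering_invariance(self, rng):
        maps = rng.random((5, 10, 10))
        perm = [3, 1, 4, 0, 2]
        np.testing.assert_allclose(combine_sum(maps).s, combine_sum(maps[perm]).s)
        np.testing.assert_allclose(combine_max(maps).s, combine_max(maps[perm]).s)


class TestIterateStrategy:
    def test_informative_impulse_wins(self, params):
        maps = impulse_stack()
        out = combine_iterate(maps, params)
        assert out.argmax() == (24, 24)

    def test_single_map_equals_iterate_map(self, params, rng):
        m = rng.random((24, 24))
        out = combine_iterate(m[None], params)
        np.testing.assert_allclose(out.s, iterate_map(m / m.max(), params))

    def test_empty_stack_rejected(self, params):
        with pytest.raises(ValueError):
            combine_iterate(np.empty((0, 8, 8)), params)


class TestClustered:
    def test_cluster_count_equal_stack_size_matches_iterate(self, rng):
        maps = rng.random((4, 20, 20)) + np.linspace(0, 3, 4)[:, None, None]
        p = CombineParams(n_clusters=4, seed=0)
        out = combine_clustered(maps, p)
        ref = combine_iterate(maps, p)
        np.testing.assert_allclose(out.s, ref.s, atol=1e-10)

    def test_recovers_duplicated_groups(self, rng):
        """Two groups of duplicated maps: the best 2-partition is the
        group structure (oracle: exhaustive check over partitions)."""
        a = rng.random((24, 24))
        b = rng.random((24, 24)) ** 3
        maps = np.stack([a, a * 1.9, a * 0.6, b, b * 1.5, b * 0.8])
        p = CombineParams(n_clusters=2, subsample_factor=1, seed=0)
        out = combine_clustered(maps, p)
        labels = np.asarray(out.provenance["labels"])
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            combine_clustered(rng.random((3, 8, 8)), CombineParams(n_clusters=5))

    def test_deterministic_under_seed(self, rng):
        maps = rng.random((12, 16, 16))
        p = CombineParams(n_clusters=3, seed=42)
        out1 = combine_clustered(maps, p)
        out2 = combine_clustered(maps, p)
        np.testing.assert_array_equal(out1.s, out2.s)


class TestDispatch:
    def test_small_stack_iterates(self, params):
        maps = impulse_stack(n_maps=4)
        out = combine(maps, params)
        assert out.provenance["strategy"] == "iterate"

    def test_large_stack_clusters(self, rng):
        maps = rng.random((12, 16, 16))
        out = combine(maps, CombineParams(n_clusters=3, seed=0))
        assert out.provenance["strategy"] == "cluster_iterate"

    def test_unknown_strategy_rejected(self, rng):
        with pytest.raises(ValueError):
            combine(rng.random((2, 8, 8)), CombineParams(strategy="banana"))


def test_iterate_sparser_than_sum():
    """The iteration strategy concentrates mass compared with plain
    normalized summing on a one-informative-map stack."""
    maps = impulse_stack(n_maps=10, shape=(64, 64), peak=(30, 33))
    p = CombineParams(seed=0)
    s_it = combine_iterate(maps, p).s
    s_sum = combine_sum(maps).s
    frac = lambda s: np.mean(s > 0.1 * s.max())
    assert frac(s_it) < frac(s_sum)
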