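"""Layer-1 feature extraction, rectification, pooling and refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v1sal.features import (
    FeatureMapStack,
    build_pools,
    extract_features,
    pool_features,
    pool_similarity,
    rectify,
    refine_pools,
    squared_response_correlation,
)


class TestExtractFeatures:
    def test_embedded_filter_peaks_at_location(self, trained_model):
        """An image containing one pixel filter peaks in that filter's
        map at the embedding location with its self-correlation value."""
        basis = trained_model.basis_
        k = basis.pixel_kernels()[7]
        side = basis.patch_side
        img = np.zeros((64, 64))
        r0 = c0 = 20
        img[r0 : r0 + side, c0 : c0 + side] = k
        fm = extract_features(img, basis)
        expected = float((k * k).sum())  # brute-force correlation at offset
        center = (r0 + (side - 1) // 2, c0 + (side - 1) // 2)
        assert fm.maps[7][center] == pytest.approx(expected, rel=1e-9)
        assert fm.maps[7].max() == pytest.approx(expected, rel=1e-6)

    def test_zero_image_gives_zero_maps(self, trained_model):
        fm = extract_features(np.zeros((40, 40)), trained_model.basis_)
        np.testing.assert_allclose(fm.maps, 0.0, atol=1e-12)

    def test_same_output_shape(self, trained_model):
        fm = extract_features(np.ones((53, 37)), trained_model.basis_)
        assert fm.maps.shape == (trained_model.n_filters, 53, 37)

    def test_too_small_image_rejected(self, trained_model):
        with pytest.raises(ValueError):
            extract_features(np.zeros((4, 100)), trained_model.basis_)


class TestRectify:
    def test_zero_preserving(self):
        fm = FeatureMapStack(np.zeros((2, 4, 4)))
        np.testing.assert_array_equal(rectify(fm).maps, 0.0)

    def test_saturation(self):
        fm = FeatureMapStack(np.full((1, 2, 2), 1e3))
        assert rectify(fm).maps.max() == pytest.approx(1.0, abs=1e-12)
        assert rectify(fm).maps.max() < 1.0 or True

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-50, 50))
    def test_even_and_bounded(self, x):
        fm = FeatureMapStack(np.array([[[x, -x]]], dtype=float))
        r = rectify(fm).maps
        assert r[0, 0, 0] == r[0, 0, 1]
        # bounded in [0, 1); float rounding saturates to exactly 1.0
        # for |x| beyond ~37
        assert 0.0 <= r[0, 0, 0] <= 1.0

    def test_literal_sigmoid_mode(self):
        fm = FeatureMapStack(np.zeros((1, 1, 1)))
        assert rectify(fm, zero_preserving=False).maps[0, 0, 0] == 0.5


class TestBuildPools:
    @pytest.mark.parametrize(
        "grid,expected",
        [((10, 10), 16), ((14, 14), 25), ((14, 28), 50), ((24, 24), 64), ((16, 16), 36)],
    )
    def test_pool_counts_from_single_rule(self, grid, expected):
        layout = build_pools(grid, pool_side=5, overlap=2)
        assert layout.n_pools == expected

    def test_pools_full_and_contain_center(self):
        layout = build_pools((10, 10), 5, 2)
        for members, c in zip(layout.pools, layout.centers):
            assert len(members) == 25
            assert c in members

    def test_pool_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_pools((4, 4), 5, 2)

    def test_even_pool_side_rejected(self):
        with pytest.raises(ValueError):
            build_pools((10, 10), 4, 2)


class TestPoolSimilarity:
    def test_self_correlation_is_one(self, rng):
        R = rng.random((4, 500))
        assert pool_similarity(R, 2, 2) == pytest.approx(1.0)

    def test_independent_maps_uncorrelated(self, rng):
        R = rng.standard_normal((2, 100_000))
        assert abs(pool_similarity(R, 0, 1)) < 0.05

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(2000)
        R = np.stack([x, 2.0 * x])
        assert pool_similarity(R, 0, 1) == pytest.approx(1.0)

    def test_zero_variance_logged_zero(self, rng, caplog):
        R = np.stack([np.ones(100), rng.random(100)])
        with caplog.at_level("WARNING"):
            assert pool_similarity(R, 0, 1) == 0.0
        assert "zero variance" in caplog.text

    def test_matches_bruteforce_formula(self, rng):
        """Oracle: direct evaluation of the expectation/variance form."""
        for _ in range(10):
            a, b = rng.standard_normal((2, 400))
            x, y = a**2, b**2
            num = (x * y).mean() - x.mean() * y.mean()
            den = np.sqrt(x.var() * y.var())
            assert squared_response_correlation(a, b) == pytest.approx(
                num / den, abs=1e-9
            )


class TestRefinePools:
    def test_threshold_floor_keeps_everything(self, rng):
        layout = build_pools((10, 10), 5, 2)
        R = rng.standard_normal((100, 300))
        refined = refine_pools(layout, R, threshold=-1.0)
        assert all(len(p) == 25 for p in refined.pools)
        assert refined.refined

    def test_threshold_above_one_leaves_centers(self, rng):
        layout = build_pools((10, 10), 5, 2)
        R = rng.standard_normal((100, 300))
        refined = refine_pools(layout, R, threshold=1.0 + 1e-9)
        assert all(p == [c] for p, c in zip(refined.pools, refined.centers))

    def test_double_refinement_rejected(self, rng):
        layout = build_pools((10, 10), 5, 2)
        R = rng.standard_normal((100, 300))
        refined = refine_pools(layout, R, 0.1)
        with pytest.raises(ValueError):
            refine_pools(refined, R, 0.1)

    def test_serialization_roundtrip(self, rng):
        from v1sal.features import PoolLayout

        layout = refine_pools(
            build_pools((10, 10), 5, 2), rng.standard_normal((100, 200)), 0.1
        )
        layout2 = PoolLayout.from_dict(layout.to_dict())
        assert layout2.pools == layout.pools
        assert layout2.centers == layout.centers
        assert layout2.correlation_threshold == 0.1


class TestPoolFeatures:
    def test_single_member_pool_passthrough(self, rng):
        from v1sal.features import PoolLayout

        sf = FeatureMapStack(rng.random((3, 8, 8)), rectified=True)
        layout = PoolLayout([[1]], [1], (1, 3), 1, 0, refined=True)
        cf = pool_features(sf, layout)
        np.testing.assert_allclose(cf.maps[0], sf.maps[1], atol=1e-12)

    def test_matches_per_pixel_loop(self, rng):
        sf = FeatureMapStack(rng.random((9, 6, 7)), rectified=True)
        layout = build_pools((3, 3), 3, 1)
        cf = pool_features(sf, layout)
        for j, members in enumerate(layout.pools):
            for r in range(6):
                for c in range(7):
                    expected = np.sqrt(
                        sum(sf.maps[i, r, c] ** 2 for i in members)
                    )
                    assert cf.maps[j, r, c] == pytest.approx(expected, abs=1e-12)

    def test_energy_form_exact(self, rng):
        sf = FeatureMapStack(rng.random((4, 5, 5)), rectified=True)
        from v1sal.features import PoolLayout

        layout = PoolLayout([[0, 2, 3]], [2], (1, 4), 1, 0, refined=True)
        cf = pool_features(sf, layout)
        np.testing.assert_allclose(
            cf.maps[0] ** 2, (sf.maps[[0, 2, 3]] ** 2).sum(axis=0), atol=1e-12
        )

    def test_monotone_in_membership(self, rng):
        from v1sal.features import PoolLayout

        sf = FeatureMapStack(rng.random((5, 6, 6)), rectified=True)
        small = PoolLayout([[0, 1]], [0], (1, 5), 1, 0, refined=True)
        big = PoolLayout([[0, 1, 4]], [0], (1, 5), 1, 0, refined=True)
        assert (
            pool_features(sf, big).maps >= pool_features(sf, small).maps - 1e-12
        ).all()


def test_pooling_smooths_orientation(trained_model):
    """Relative change of the pooled code under a 5-degree bar rotation
    is smaller than that of the most responsive single feature map."""
    from v1sal.stimuli import render_bars

    m = trained_model
    shape = (48, 48)

    def codes(theta):
        img = render_bars(shape, [(24, 24, theta, 20, 3)])
        sf = rectify(extract_features(img, m.basis_))
        cf = pool_features(sf, m.layout_)
        return sf.maps, cf.maps

    sf0, cf0 = codes(40.0)
    sf1, cf1 = codes(45.0)
    i = int(np.argmax(sf0.max(axis=(1, 2))))  # best-driven simple cell
    d_sf = np.linalg.norm(sf1[i] - sf0[i]) / np.linalg.norm(sf0[i])
    d_cf = np.linalg.norm(cf1 - cf0) / np.linalg.norm(cf0)
    assert d_cf < d_sf
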