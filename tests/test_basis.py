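"""Topographic basis learning: initialization, training, torus layout,
back-projection."""

import numpy as np
import pytest

from v1sal.basis import (
    LearningConfig,
    TopographicBasisLearner,
    TopographicBasisSet,
    backproject_filters,
    init_basis,
    learn_basis,
    neighborhood_matrix,
    torus_distance,
)
from v1sal.preprocessing import PatchSet, fit_whitening, sample_patches, whiten


def small_config(**kw):
    base = dict(
        n_filters=16,
        grid_shape=(4, 4),
        neighborhood_side=3,
        n_iterations=50,
        batch_size=200,
        seed=5,
    )
    base.update(kw)
    return LearningConfig(**base)


class TestTorus:
    def test_wraparound_adjacency(self):
        # bottom row filter is adjacent to the top row filter
        assert torus_distance(0, 12, (4, 4)) == 1  # (0,0) vs (3,0)
        assert torus_distance(0, 3, (4, 4)) == 1  # (0,0) vs (0,3)
        assert torus_distance(0, 10, (4, 4)) == 2  # (0,0) vs (2,2)

    def test_neighborhood_matrix_properties(self):
        H = neighborhood_matrix((5, 5), 3)
        assert H.shape == (25, 25)
        np.testing.assert_array_equal(H, H.T)
        np.testing.assert_array_equal(H.sum(axis=1), 9)
        assert (np.diag(H) == 1).all()


class TestInitBasis:
    def test_complete_case_orthonormal(self):
        b = init_basis(small_config(), d_red=16)
        np.testing.assert_allclose(b.filters @ b.filters.T, np.eye(16), atol=1e-8)

    def test_overcomplete_unit_rows(self):
        b = init_basis(small_config(n_filters=32, grid_shape=(4, 8)), d_red=16)
        assert b.filters.shape == (32, 16)
        np.testing.assert_allclose(
            np.linalg.norm(b.filters, axis=1), 1.0, atol=1e-8
        )

    def test_deterministic_under_seed(self):
        a = init_basis(small_config(), 16)
        b = init_basis(small_config(), 16)
        np.testing.assert_array_equal(a.filters, b.filters)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LearningConfig(n_filters=0, grid_shape=(0, 1))
        with pytest.raises(ValueError):
            LearningConfig(n_filters=16, grid_shape=(4, 4), neighborhood_side=4)


@pytest.fixture(scope="module")
def whitened_textures(texture_images):
    raw = sample_patches(texture_images, patch_side=8, n_patches=4000, seed=2)
    tf = fit_whitening(raw, 16)
    return whiten(raw, tf), tf


class TestLearnBasis:
    def test_zero_iterations_returns_init(self, whitened_textures):
        zw, _ = whitened_textures
        cfg = small_config(n_iterations=0)
        b = learn_basis(zw, cfg)
        np.testing.assert_array_equal(b.filters, init_basis(cfg, 16).filters)

    def test_gaussian_noise_converges(self, rng):
        z = PatchSet(rng.standard_normal((16, 3000)), 8, whitened=True)
        b = learn_basis(z, small_config(n_iterations=100))
        assert np.isfinite(b.provenance["loss"]).all()
        np.testing.assert_allclose(b.filters @ b.filters.T, np.eye(16), atol=1e-8)

    def test_objective_decreases_on_textures(self, whitened_textures):
        zw, _ = whitened_textures
        b = learn_basis(zw, small_config(n_iterations=400, step_size=1.0))
        loss = b.provenance["loss"]
        assert np.mean(loss[-40:]) < np.mean(loss[:40])

    def test_orthonormal_after_training(self, whitened_textures):
        zw, _ = whitened_textures
        b = learn_basis(zw, small_config(n_iterations=30))
        np.testing.assert_allclose(b.filters @ b.filters.T, np.eye(16), atol=1e-8)


class TestBackprojection:
    def test_identity_whitening_reshapes_filters(self, rng):
        from v1sal.preprocessing import WhiteningTransform

        d = 16
        tf = WhiteningTransform(
            mean_patch=np.zeros(d),
            whitening_matrix=np.eye(d),
            dewhitening_matrix=np.eye(d),
            retained_dim=d,
            eigenvalues=np.ones(d),
            eigenvectors=np.eye(d),
            patch_side=4,
        )
        b = init_basis(small_config(), d)
        bp = backproject_filters(b, tf)
        np.testing.assert_array_equal(bp.pixel_filters, b.filters)

    def test_response_roundtrip_oracle(self, whitened_textures, rng):
        """Pixel-filter response to a raw patch equals the whitened-space
        inner product (brute-force over 100 random patches)."""
        zw, tf = whitened_textures
        b = learn_basis(zw, small_config(n_iterations=20))
        bp = backproject_filters(b, tf)
        X = rng.standard_normal((64, 100))
        lhs = bp.pixel_filters @ X
        rhs = b.filters @ (tf.whitening_matrix @ X)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_dimension_mismatch_rejected(self, whitened_textures):
        zw, tf = whitened_textures
        b = init_basis(small_config(), 12)
        with pytest.raises(ValueError):
            backproject_filters(b, tf)


def test_topography_emerges_on_trained_model(trained_model):
    """After training on oriented textures, squared-response correlation
    between grid-adjacent filters exceeds that of torus-distant pairs."""
    from v1sal.features import squared_response_correlation
    from v1sal.stimuli import oriented_texture

    m = trained_model
    imgs = [oriented_texture(seed=9000 + k) for k in range(8)]
    raw = sample_patches(imgs, m.patch_side, 4000, seed=77)
    U = m.basis_.filters @ whiten(raw, m.whitening_).data
    adj, far = [], []
    n = m.n_filters
    for i in range(n):
        for j in range(i + 1, n):
            d = torus_distance(i, j, m.basis_.grid_shape)
            c = squared_response_correlation(U[i], U[j])
            if d == 1:
                adj.append(c)
            elif d >= 3:
                far.append(c)
    assert np.mean(adj) > np.mean(far)


def test_basis_io_roundtrip(tmp_path, whitened_textures):
    zw, tf = whitened_textures
    b = backproject_filters(learn_basis(zw, small_config(n_iterations=10)), tf)
    path = tmp_path / "basis.npz"
    b.save(path)
    b2 = TopographicBasisSet.load(path)
    np.testing.assert_array_equal(b.filters, b2.filters)
    np.testing.assert_array_equal(b.pixel_filters, b2.pixel_filters)
    assert b2.grid_shape == (4, 4) and b2.torus
    np.testing.assert_array_equal(
        b.whitening.whitening_matrix, b2.whitening.whitening_matrix
    )


def test_learner_sklearn_api(whitened_textures):
    from sklearn.base import clone

    zw, _ = whitened_textures
    est = TopographicBasisLearner(
        n_filters=16, grid_shape=(4, 4), neighborhood_side=3,
        n_iterations=25, batch_size=100, seed=0,
    )
    est = clone(est)
    est.fit(zw.data.T)
    assert est.components_.shape == (16, 16)
    assert len(est.loss_curve_) == 25
    R = est.transform(zw.data.T[:10])
    np.testing.assert_allclose(R, zw.data.T[:10] @ est.components_.T)
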