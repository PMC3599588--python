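"""Learning an (over)complete topographic basis from whitened patches.

The first layer of the model is a set of Gabor-like filters arranged on
a 2-D torus grid so that neighbouring filters have similar orientation,
frequency and position tuning.  Training maximises a topographic
energy objective

    sum_pools G( sum_{i in pool} (phi_i^T z)^2 ),   G(u) = -sqrt(u + eps)

over torus neighbourhoods by stochastic gradient ascent with symmetric
orthogonalization after each step (the standard topographic-ICA family
of energy models; pairwise-cumulant variants converge to the same
filter/topography structure).  For overcomplete sets (more filters than
whitened dimensions) exact orthogonalization is impossible and the
quasi-orthogonalization  Phi <- 1.5 Phi - 0.5 Phi Phi^T Phi  with row
renormalization is used instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .preprocessing import PatchSet, WhiteningTransform

logger = logging.getLogger(__name__)

__all__ = [
    "TopographicBasisSet",
    "LearningConfig",
    "TopographicBasisLearner",
    "init_basis",
    "learn_basis",
    "backproject_filters",
    "torus_distance",
    "neighborhood_matrix",
]


def torus_distance(a, b, grid_shape) -> int:
    """Chebyshev distance between grid positions on the torus."""
    ra, ca = divmod(a, grid_shape[1])
    rb, cb = divmod(b, grid_shape[1])
    dr = abs(ra - rb)
    dc = abs(ca - cb)
    dr = min(dr, grid_shape[0] - dr)
    dc = min(dc, grid_shape[1] - dc)
    return max(dr, dc)


def neighborhood_matrix(grid_shape, side: int) -> np.ndarray:
    """Binary (n, n) matrix: H[j, i] = 1 iff filter i lies in the
    ``side`` x ``side`` torus neighbourhood centred on filter j."""
    if side % 2 != 1:
        raise ValueError("neighbourhood side must be odd")
    rows, cols = grid_shape
    n = rows * cols
    h = side // 2
    H = np.zeros((n, n), dtype=np.float64)
    for j in range(n):
        rj, cj = divmod(j, cols)
        for dr in range(-h, h + 1):
            for dc in range(-h, h + 1):
                i = ((rj + dr) % rows) * cols + (cj + dc) % cols
                H[j, i] = 1.0
    return H


@dataclass
class TopographicBasisSet:
    """Learned layer-1 filters on a torus grid.

    ``filters`` lives in whitened space (n_filters x d_red); when a
    whitening transform is attached, ``pixel_filters`` (n_filters x
    d_raw) holds the back-projection used for image convolution.
    """

    filters: np.ndarray
    grid_shape: tuple
    patch_side: int
    torus: bool = True
    pixel_filters: np.ndarray | None = None
    whitening: WhiteningTransform | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=np.float64)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if self.grid_shape[0] * self.grid_shape[1] != self.filters.shape[0]:
            raise ValueError("grid_shape does not match number of filters")
        norms = np.linalg.norm(self.filters, axis=1)
        if not np.all(np.isfinite(self.filters)) or np.any(norms == 0):
            raise ValueError("filters must be finite with non-zero norm")

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def d_red(self) -> int:
        return self.filters.shape[1]

    def pixel_kernels(self) -> np.ndarray:
        """Unit-norm convolution kernels, shape (n, side, side)."""
        if self.pixel_filters is None:
            raise ValueError("basis has no pixel filters; call backproject_filters")
        k = self.pixel_filters / np.linalg.norm(
            self.pixel_filters, axis=1, keepdims=True
        )
        return k.reshape(self.n_filters, self.patch_side, self.patch_side)

    def save(self, path) -> None:
        arrays = dict(
            filters=self.filters,
            grid_shape=np.asarray(self.grid_shape),
            patch_side=self.patch_side,
            torus=self.torus,
            provenance=json.dumps(self.provenance, sort_keys=True),
        )
        if self.pixel_filters is not None:
            arrays["pixel_filters"] = self.pixel_filters
        if self.whitening is not None:
            tf = self.whitening
            arrays.update(
                w_mean=tf.mean_patch,
                w_matrix=tf.whitening_matrix,
                w_dematrix=tf.dewhitening_matrix,
                w_evals=tf.eigenvalues,
                w_evecs=tf.eigenvectors,
            )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TopographicBasisSet":
        with np.load(path, allow_pickle=False) as z:
            tf = None
            if "w_matrix" in z:
                tf = WhiteningTransform(
                    mean_patch=z["w_mean"],
                    whitening_matrix=z["w_matrix"],
                    dewhitening_matrix=z["w_dematrix"],
                    retained_dim=z["w_matrix"].shape[0],
                    eigenvalues=z["w_evals"],
                    eigenvectors=z["w_evecs"],
                    patch_side=int(z["patch_side"]),
                )
            return cls(
                filters=z["filters"],
                grid_shape=tuple(z["grid_shape"]),
                patch_side=int(z["patch_side"]),
                torus=bool(z["torus"]),
                pixel_filters=z["pixel_filters"] if "pixel_filters" in z else None,
                whitening=tf,
                provenance=json.loads(str(z["provenance"])),
            )


@dataclass
class LearningConfig:
    """Hyper-parameters of the topographic learning run."""

    n_filters: int = 196
    grid_shape: tuple = (14, 14)
    neighborhood_side: int = 5
    step_size: float = 0.1
    n_iterations: int = 500
    batch_size: int = 1000
    seed: int = 0
    eps: float = 1e-3
    decay_every: int = 100
    decay_factor: float = 0.5

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if self.grid_shape[0] * self.grid_shape[1] != self.n_filters:
            raise ValueError("grid_shape inconsistent with n_filters")
        if self.neighborhood_side % 2 != 1:
            raise ValueError("neighborhood_side must be odd")
        if self.neighborhood_side > min(self.grid_shape):
            raise ValueError("neighborhood_side exceeds grid dimension")


def _symmetric_orthogonalize(Phi: np.ndarray) -> np.ndarray:
    """Phi <- (Phi Phi^T)^(-1/2) Phi (complete / undercomplete case)."""
    U, _, Vt = np.linalg.svd(Phi, full_matrices=False)
    return U @ Vt


def _quasi_orthogonalize(Phi: np.ndarray) -> np.ndarray:
    """Overcomplete surrogate: one step of 1.5*Phi - 0.5*Phi Phi^T Phi,
    then row renormalization."""
    Phi = 1.5 * Phi - 0.5 * (Phi @ Phi.T) @ Phi
    return Phi / np.linalg.norm(Phi, axis=1, keepdims=True)


def _orthogonalize(Phi: np.ndarray) -> np.ndarray:
    if Phi.shape[0] <= Phi.shape[1]:
        return _symmetric_orthogonalize(Phi)
    return _quasi_orthogonalize(Phi)


def init_basis(config: LearningConfig, d_red: int) -> TopographicBasisSet:
    """Random orthogonalized starting basis, deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    Phi = rng.standard_normal((config.n_filters, d_red))
    Phi = _orthogonalize(Phi)
    return TopographicBasisSet(
        filters=Phi,
        grid_shape=config.grid_shape,
        patch_side=0,
        provenance={"stage": "init", "seed": config.seed},
    )


def learn_basis(
    patches: PatchSet,
    config: LearningConfig,
    callback=None,
) -> TopographicBasisSet:
    """Run the topographic energy learning on whitened patches.

    Returns the trained basis; per-iteration objective values are stored
    in ``provenance['loss']`` (negated objective, so lower is better).
    """
    if not patches.whitened:
        logger.warning("learn_basis called on patches not marked whitened")
    Z = patches.data  # (d_red, n)
    d_red, n = Z.shape
    basis = init_basis(config, d_red)
    Phi = basis.filters.copy()
    H = neighborhood_matrix(config.grid_shape, config.neighborhood_side)
    rng = np.random.default_rng(config.seed + 1)
    eta = config.step_size
    losses = []
    for it in range(config.n_iterations):
        if config.decay_every and it > 0 and it % config.decay_every == 0:
            eta *= config.decay_factor
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        Zb = Z[:, idx]  # (d, b)
        U = Phi @ Zb  # (n_filters, b)
        E = U**2
        pooled = H @ E + config.eps  # (n_filters pools, b)
        loss = float(np.mean(np.sqrt(pooled).sum(axis=0)))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged (non-finite objective) at iteration {it}"
            )
        losses.append(loss)
        g = -0.5 / np.sqrt(pooled)  # G'(pooled energy)
        R = H.T @ g  # (n_filters, b): sum over pools containing i
        grad = ((U * R) @ Zb.T) / Zb.shape[1]
        Phi = Phi + eta * grad
        Phi = _orthogonalize(Phi)
        if callback is not None:
            callback(it, loss, Phi)
    return TopographicBasisSet(
        filters=Phi,
        grid_shape=config.grid_shape,
        patch_side=patches.patch_side,
        provenance={
            "stage": "trained",
            "seed": config.seed,
            "n_iterations": config.n_iterations,
            "loss": losses,
            "data_hash": hashlib.sha256(
                np.ascontiguousarray(Z[:, : min(n, 100)])
            ).hexdigest()[:16],
        },
    )


def backproject_filters(
    basis: TopographicBasisSet, tf: WhiteningTransform
) -> TopographicBasisSet:
    """Compose whitened-space filters with the whitening matrix so they
    can be applied to raw pixel patches: pixel_phi = Phi @ W.

    The inner product of ``pixel_phi`` with a raw patch equals the
    whitened-space inner product of ``Phi`` with the whitened patch (up
    to the constant mean offset, which DC-centred filters ignore).
    """
    if basis.d_red != tf.retained_dim:
        raise ValueError(
            f"basis dimension {basis.d_red} != whitening retained_dim "
            f"{tf.retained_dim}"
        )
    pix = basis.filters @ tf.whitening_matrix
    return TopographicBasisSet(
        filters=basis.filters,
        grid_shape=basis.grid_shape,
        patch_side=tf.patch_side,
        torus=basis.torus,
        pixel_filters=pix,
        whitening=tf,
        provenance=dict(basis.provenance),
    )


class TopographicBasisLearner(BaseEstimator):
    """sklearn-style decomposition estimator for the topographic basis.

    ``fit(X)`` expects whitened patches with one sample per row
    (``n_samples x d_red``).  Fitted attributes: ``components_``
    (n_filters x d_red), ``basis_`` (the TopographicBasisSet) and
    ``loss_curve_``.
    """

    def __init__(
        self,
        n_filters: int = 196,
        grid_shape: tuple = (14, 14),
        neighborhood_side: int = 5,
        step_size: float = 0.1,
        n_iterations: int = 500,
        batch_size: int = 1000,
        seed: int = 0,
    ):
        self.n_filters = n_filters
        self.grid_shape = grid_shape
        self.neighborhood_side = neighborhood_side
        self.step_size = step_size
        self.n_iterations = n_iterations
        self.batch_size = batch_size
        self.seed = seed

    def _config(self) -> LearningConfig:
        return LearningConfig(
            n_filters=self.n_filters,
            grid_shape=tuple(self.grid_shape),
            neighborhood_side=self.neighborhood_side,
            step_size=self.step_size,
            n_iterations=self.n_iterations,
            batch_size=self.batch_size,
            seed=self.seed,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        side = int(round(np.sqrt(X.shape[1])))
        ps = PatchSet(X.T, side, whitened=True)
        self.basis_ = learn_basis(ps, self._config())
        self.components_ = self.basis_.filters
        self.loss_curve_ = list(self.basis_.provenance.get("loss", []))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Filter responses of whitened patches, (n_samples, n_filters)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "components_")
        return np.asarray(X, dtype=np.float64) @ self.components_.T
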