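"""Patch sampling, PCA dimension reduction and whitening.

Training images are cut into small square patches which are DC-centred,
reduced by PCA and whitened so that the retained components have unit
covariance.  The whitening transform is the fixed "retina" of the model:
every later stage (basis learning, feature extraction) lives in the
whitened space it defines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "PatchSet",
    "WhiteningTransform",
    "PatchWhitener",
    "sample_patches",
    "fit_whitening",
    "whiten",
    "dewhiten",
]


@dataclass
class PatchSet:
    """A matrix of column patches.

    ``data`` has shape ``(d, n_patches)`` — one column per patch, in the
    convention of the patch matrix the whitening acts on.  ``patch_side``
    is the side of the square patch in pixels (``d == patch_side**2`` for
    raw patches; whitened patches have ``d == retained_dim``).
    """

    data: np.ndarray
    patch_side: int
    whitened: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("PatchSet.data must be 2-D (d x n_patches)")
        if self.data.shape[1] < 1:
            raise ValueError("PatchSet needs at least one patch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("PatchSet contains non-finite values")
        if not self.whitened and self.data.shape[0] != self.patch_side**2:
            raise ValueError(
                f"raw patch dimension {self.data.shape[0]} != patch_side**2 "
                f"= {self.patch_side ** 2}"
            )

    @property
    def n_patches(self) -> int:
        return self.data.shape[1]

    @property
    def dim(self) -> int:
        return self.data.shape[0]


def sample_patches(
    images,
    patch_side: int = 16,
    n_patches: int = 50_000,
    seed: int = 0,
    remove_dc: bool = True,
) -> PatchSet:
    """Sample square patches uniformly at random from a list of images.

    Sampling is with replacement, uniform first over the usable images
    and then over valid top-left positions.  Each patch has its own mean
    (DC component) removed by default.  Images smaller than
    ``patch_side`` in either dimension are rejected with a warning.
    """
    rng = np.random.default_rng(seed)
    usable = []
    for k, img in enumerate(images):
        arr = np.asarray(img, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"image {k} is not 2-D grayscale")
        if arr.shape[0] < patch_side or arr.shape[1] < patch_side:
            logger.warning(
                "image %d (%dx%d) smaller than patch_side=%d; skipped",
                k, arr.shape[0], arr.shape[1], patch_side,
            )
            continue
        usable.append(arr)
    if not usable:
        raise ValueError("no image large enough to sample patches from")

    d = patch_side**2
    out = np.empty((d, n_patches), dtype=np.float64)
    img_idx = rng.integers(0, len(usable), size=n_patches)
    for j in range(n_patches):
        arr = usable[img_idx[j]]
        r = rng.integers(0, arr.shape[0] - patch_side + 1)
        c = rng.integers(0, arr.shape[1] - patch_side + 1)
        out[:, j] = arr[r : r + patch_side, c : c + patch_side].ravel()
    if remove_dc:
        out -= out.mean(axis=0, keepdims=True)
    return PatchSet(out, patch_side)


@dataclass
class WhiteningTransform:
    """PCA whitening restricted to the leading principal components.

    ``whitening_matrix`` W has shape ``(d_red, d_raw)``; applying it to
    mean-centred patches gives unit covariance on the retained
    components.  ``dewhitening_matrix`` maps whitened coordinates back
    to pixel space (the PCA reconstruction).
    """

    mean_patch: np.ndarray
    whitening_matrix: np.ndarray
    dewhitening_matrix: np.ndarray
    retained_dim: int
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    patch_side: int = 0
    seed: int | None = None

    @property
    def d_raw(self) -> int:
        return self.whitening_matrix.shape[1]

    def save(self, path) -> None:
        np.savez(
            path,
            mean_patch=self.mean_patch,
            whitening_matrix=self.whitening_matrix,
            dewhitening_matrix=self.dewhitening_matrix,
            retained_dim=self.retained_dim,
            eigenvalues=self.eigenvalues,
            eigenvectors=self.eigenvectors,
            patch_side=self.patch_side,
            seed=-1 if self.seed is None else self.seed,
        )

    @classmethod
    def load(cls, path) -> "WhiteningTransform":
        with np.load(path) as z:
            seed = int(z["seed"])
            return cls(
                mean_patch=z["mean_patch"],
                whitening_matrix=z["whitening_matrix"],
                dewhitening_matrix=z["dewhitening_matrix"],
                retained_dim=int(z["retained_dim"]),
                eigenvalues=z["eigenvalues"],
                eigenvectors=z["eigenvectors"],
                patch_side=int(z["patch_side"]),
                seed=None if seed < 0 else seed,
            )


# Relative eigenvalue floor guarding U^(-1/2) against numerically zero modes.
EIG_FLOOR = 1e-10


def fit_whitening(patches: PatchSet, retained_dim: int) -> WhiteningTransform:
    """Fit the PCA whitening transform on a training PatchSet.

    The covariance eigendecomposition C = V U V^T gives
    W = U_k^(-1/2) V_k^T on the ``retained_dim`` leading components.
    Eigenvalues below ``EIG_FLOOR`` times the largest are considered
    zero; if fewer than ``retained_dim`` components survive, the
    achievable rank is reported in the error.
    """
    X = patches.data
    d = X.shape[0]
    if retained_dim > d:
        raise ValueError(f"retained_dim {retained_dim} > patch dimension {d}")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    C = (Xc @ Xc.T) / X.shape[1]
    evals, evecs = np.linalg.eigh(C)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    # deterministic sign convention: largest-magnitude entry positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip

    floor = EIG_FLOOR * max(evals[0], 0.0)
    rank = int(np.sum(evals > floor))
    if rank < retained_dim:
        raise ValueError(
            f"covariance rank {rank} below requested retained_dim "
            f"{retained_dim}; reduce retained_dim"
        )
    lam = evals[:retained_dim]
    Vk = evecs[:, :retained_dim]
    W = (lam**-0.5)[:, None] * Vk.T
    Wd = Vk * (lam**0.5)[None, :]
    return WhiteningTransform(
        mean_patch=mean,
        whitening_matrix=W,
        dewhitening_matrix=Wd,
        retained_dim=retained_dim,
        eigenvalues=evals,
        eigenvectors=evecs,
        patch_side=patches.patch_side,
    )


def whiten(patches: PatchSet, tf: WhiteningTransform) -> PatchSet:
    """Apply the whitening transform: Z = W (X - mean)."""
    if patches.data.shape[0] != tf.d_raw:
        raise ValueError(
            f"patch dimension {patches.data.shape[0]} != transform input "
            f"dimension {tf.d_raw}"
        )
    Z = tf.whitening_matrix @ (patches.data - tf.mean_patch[:, None])
    return PatchSet(Z, patches.patch_side, whitened=True)


def dewhiten(patches: PatchSet, tf: WhiteningTransform) -> PatchSet:
    """Map whitened patches back to pixel space (PCA reconstruction)."""
    if patches.data.shape[0] != tf.retained_dim:
        raise ValueError("whitened dimension mismatch")
    X = tf.dewhitening_matrix @ patches.data + tf.mean_patch[:, None]
    return PatchSet(X, patches.patch_side)


class PatchWhitener(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`fit_whitening`.

    Follows the sklearn sample convention: ``X`` is ``(n_samples,
    n_features)`` with one patch per row.

    Parameters
    ----------
    retained_dim : int or None
        Number of principal components kept; ``None`` keeps all.

    Attributes
    ----------
    transform_ : WhiteningTransform
        The fitted whitening transform (column-patch convention).
    """

    def __init__(self, retained_dim: int | None = None, patch_side: int = 0):
        self.retained_dim = retained_dim
        self.patch_side = patch_side

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        k = X.shape[1] if self.retained_dim is None else self.retained_dim
        side = self.patch_side or int(round(np.sqrt(X.shape[1])))
        ps = PatchSet(X.T, side, whitened=side**2 != X.shape[1])
        self.transform_ = fit_whitening(ps, k)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "transform_")
        X = np.asarray(X, dtype=np.float64)
        tf = self.transform_
        return (tf.whitening_matrix @ (X.T - tf.mean_patch[:, None])).T

    def inverse_transform(self, Z):
        check_is_fitted(self, "transform_")
        tf = self.transform_
        Z = np.asarray(Z, dtype=np.float64)
        return (tf.dewhitening_matrix @ Z.T + tf.mean_patch[:, None]).T
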