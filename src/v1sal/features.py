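"""Layers 1–2: convolutional feature maps, rectification and invariant
pooling over topographic neighbourhoods.

Layer 1 convolves the image with each unit-norm pixel filter (simple
cells); a zero-preserving sigmoid of the absolute response bounds the
maps in [0, 1).  Layer 2 pools squared responses over 2-D torus
neighbourhoods of the filter grid and takes the square root — the
energy model of complex cells.  Pool membership can be refined by the
squared-response correlation between each member and the pool centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .basis import TopographicBasisSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMapStack",
    "PoolLayout",
    "extract_features",
    "rectify",
    "build_pools",
    "pool_similarity",
    "squared_response_correlation",
    "refine_pools",
    "pool_features",
]


@dataclass
class FeatureMapStack:
    """Per-filter response volume, shape (n_filters, H, W)."""

    maps: np.ndarray
    rectified: bool = False

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("FeatureMapStack.maps must be 3-D (n, H, W)")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def source_shape(self) -> tuple:
        return self.maps.shape[1:]


def _reflect_conv_same(image: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Correlate ``image`` (H, W) with a bank of kernels (n, k, k),
    reflect padding, 'same' output.  Returns (n, H, W)."""
    k = kernels.shape[-1]
    ph, pw = (k - 1) // 2, k // 2
    padded = np.pad(image, ((ph, pw), (ph, pw)), mode="reflect")
    # correlation = convolution with flipped kernel
    flipped = kernels[:, ::-1, ::-1]
    out = fftconvolve(padded[None, :, :], flipped, mode="valid", axes=(1, 2))
    return out


def extract_features(
    image: np.ndarray, basis: TopographicBasisSet
) -> FeatureMapStack:
    """Layer-1 responses: convolve the image with every unit-normalized
    pixel filter ('same' size, reflect padding).  Not yet rectified."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    side = basis.patch_side
    if image.shape[0] < side or image.shape[1] < side:
        raise ValueError(
            f"image {image.shape} smaller than filter size {side}x{side}"
        )
    kernels = basis.pixel_kernels()
    return FeatureMapStack(_reflect_conv_same(image, kernels))


def rectify(stack: FeatureMapStack, zero_preserving: bool = True) -> FeatureMapStack:
    """Bound responses to [0, 1) by a sigmoid of the absolute value.

    Default is the zero-preserving form r(x) = 2/(1+exp(-|x|)) - 1, so a
    zero response stays zero; ``zero_preserving=False`` gives the
    literal logistic sigmoid(|x|) in [0.5, 1).
    """
    a = np.abs(stack.maps)
    if zero_preserving:
        r = 2.0 / (1.0 + np.exp(-a)) - 1.0
    else:
        r = 1.0 / (1.0 + np.exp(-a))
    return FeatureMapStack(r, rectified=True)


@dataclass
class PoolLayout:
    """Layer-2 neighbourhoods Omega_j over the filter grid.

    ``pools`` is a list of filter-index lists; ``centers`` holds the
    central filter index of each pool.
    """

    pools: list
    centers: list
    grid_shape: tuple
    pool_side: int
    overlap: int
    refined: bool = False
    correlation_threshold: float | None = None

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def to_dict(self) -> dict:
        return {
            "pools": [list(map(int, p)) for p in self.pools],
            "centers": list(map(int, self.centers)),
            "grid_shape": list(self.grid_shape),
            "pool_side": self.pool_side,
            "overlap": self.overlap,
            "refined": self.refined,
            "correlation_threshold": self.correlation_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoolLayout":
        return cls(
            pools=[list(p) for p in d["pools"]],
            centers=list(d["centers"]),
            grid_shape=tuple(d["grid_shape"]),
            pool_side=int(d["pool_side"]),
            overlap=int(d["overlap"]),
            refined=bool(d["refined"]),
            correlation_threshold=d.get("correlation_threshold"),
        )


def build_pools(
    basis_or_grid, pool_side: int = 5, overlap: int = 2
) -> PoolLayout:
    """Tile the torus grid with pool_side x pool_side neighbourhoods.

    Consecutive pools overlap by ``overlap`` filters along each axis
    (stride = pool_side - overlap, starting at grid position 0), so a
    grid axis of length L yields ceil(L / stride) pools along that axis
    — e.g. a 10x10 grid with 5x5 pools overlapping by 2 gives 16 pools.
    """
    if isinstance(basis_or_grid, TopographicBasisSet):
        grid_shape = basis_or_grid.grid_shape
    else:
        grid_shape = tuple(int(g) for g in basis_or_grid)
    rows, cols = grid_shape
    if pool_side % 2 != 1:
        raise ValueError("pool_side must be odd")
    if not 0 <= overlap < pool_side:
        raise ValueError("overlap must satisfy 0 <= overlap < pool_side")
    if pool_side > rows or pool_side > cols:
        raise ValueError(
            f"pool_side {pool_side} exceeds grid dimension {grid_shape}"
        )
    stride = pool_side - overlap
    h = pool_side // 2
    pools, centers = [], []
    for r0 in range(0, rows, stride):
        for c0 in range(0, cols, stride):
            members = [
                ((r0 + dr) % rows) * cols + (c0 + dc) % cols
                for dr in range(pool_side)
                for dc in range(pool_side)
            ]
            center = ((r0 + h) % rows) * cols + (c0 + h) % cols
            pools.append(members)
            centers.append(center)
    return PoolLayout(
        pools=pools,
        centers=centers,
        grid_shape=grid_shape,
        pool_side=pool_side,
        overlap=overlap,
    )


def _as_response_matrix(responses) -> np.ndarray:
    """Accept a FeatureMapStack or an (n_filters, n_samples) matrix."""
    if isinstance(responses, FeatureMapStack):
        return responses.maps.reshape(responses.n_maps, -1)
    arr = np.asarray(responses, dtype=np.float64)
    if arr.ndim == 3:
        return arr.reshape(arr.shape[0], -1)
    return arr


def squared_response_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """corr(a^2, b^2): the high-order similarity between two response
    ensembles,
        [E(a^2 b^2) - E(a^2) E(b^2)] / sqrt(D(a^2) D(b^2)).
    Returns 0 with a warning if either squared ensemble has zero
    variance."""
    x = np.ravel(a) ** 2
    y = np.ravel(b) ** 2
    mx, my = x.mean(), y.mean()
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    if vx == 0.0 or vy == 0.0:
        logger.warning("zero variance in squared responses; correlation := 0")
        return 0.0
    cov = np.mean(x * y) - mx * my
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def pool_similarity(responses, i: int, c: int) -> float:
    """Similarity of filter ``i`` to pool-centre filter ``c`` over a
    response ensemble (a FeatureMapStack or response matrix)."""
    R = _as_response_matrix(responses)
    return squared_response_correlation(R[i], R[c])


def refine_pools(
    layout: PoolLayout, responses, threshold: float = 0.1
) -> PoolLayout:
    """Keep, in every pool, the centre filter plus the members whose
    squared-response correlation with the centre is >= threshold."""
    if layout.refined:
        raise ValueError("layout already refined")
    R = _as_response_matrix(responses)
    sq = R**2
    mean = sq.mean(axis=1)
    var = sq.var(axis=1)
    new_pools = []
    for members, c in zip(layout.pools, layout.centers):
        kept = []
        for i in members:
            if i == c:
                kept.append(i)
                continue
            if var[i] == 0.0 or var[c] == 0.0:
                rho = 0.0
            else:
                cov = np.mean(sq[i] * sq[c]) - mean[i] * mean[c]
                rho = cov / np.sqrt(var[i] * var[c])
            if rho >= threshold:
                kept.append(i)
        new_pools.append(kept)
    return PoolLayout(
        pools=new_pools,
        centers=list(layout.centers),
        grid_shape=layout.grid_shape,
        pool_side=layout.pool_side,
        overlap=layout.overlap,
        refined=True,
        correlation_threshold=threshold,
    )


@dataclass
class InvariantMapStack:
    """Layer-2 invariant feature maps CF, shape (n_pools, H, W)."""

    maps: np.ndarray
    pooling_exponent: float = 2.0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("InvariantMapStack.maps must be 3-D")

    @property
    def n_pools(self) -> int:
        return self.maps.shape[0]


def pool_features(stack: FeatureMapStack, layout: PoolLayout) -> InvariantMapStack:
    """Energy pooling: CF_j(x, y) = sqrt( sum_{i in Omega_j} SF_i(x, y)^2 ),
    computed pixelwise (no spatial pooling)."""
    if not stack.rectified:
        logger.warning("pooling un-rectified feature maps")
    sq = stack.maps**2
    out = np.empty((layout.n_pools,) + stack.source_shape, dtype=np.float64)
    for j, members in enumerate(layout.pools):
        out[j] = np.sqrt(sq[list(members)].sum(axis=0))
    return InvariantMapStack(out)
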