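"""Combining conspicuity maps into one saliency map.

The main strategy is iterative within-map competition

    s <- | s + s (*) DoG - C_inh |_{>=0}

(an excitatory centre / broad inhibitory surround update that amplifies
the global maximum and crushes diffuse activity), followed by summing
the iterated maps.  When many maps must be combined, maps are first
clustered by their pairwise squared-response correlation (K-means on
rows of the similarity matrix), averaged within clusters, and the N
cluster maps are iterated and summed.  Plain normalized-sum and
pixelwise-max baselines are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans

from .features import squared_response_correlation
from .suppression import ConspicuityStack

__all__ = [
    "CombineParams",
    "SaliencyMap",
    "iterate_map",
    "combine_sum",
    "combine_max",
    "combine_iterate",
    "combine_clustered",
    "combine",
]


@dataclass
class CombineParams:
    """Parameters of the iteration DoG and the clustered combination.

    The iteration DoG is the amplitude-weighted form
    ``c_ex * G(sigma_ex) - c_inh * G(sigma_inh)`` with sigmas given as
    fractions of the image width; ``c_inh_const`` is the constant
    inhibitory bias C_inh.  Maps are max-normalized to [0, 1] before
    iterating.
    """

    n_iterations: int = 5
    c_ex: float = 0.5
    sigma_ex_frac: float = 0.02
    c_inh: float = 1.5
    sigma_inh_frac: float = 0.25
    c_inh_const: float = 0.02
    n_clusters: int = 8
    subsample_factor: int = 4
    cluster_threshold: int = 10
    strategy: str = "auto"
    boundary: str = "reflect"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.c_inh_const < 0:
            raise ValueError("C_inh must be >= 0")


@dataclass
class SaliencyMap:
    """Final (or per-strategy) saliency map with provenance."""

    s: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        if self.s.ndim != 2:
            raise ValueError("SaliencyMap must be 2-D")
        if np.any(self.s < 0):
            raise ValueError("SaliencyMap must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.s.shape

    def argmax(self) -> tuple:
        return tuple(np.unravel_index(int(np.argmax(self.s)), self.s.shape))


def _norm01(m: np.ndarray) -> np.ndarray:
    mx = m.max()
    return m / mx if mx > 0 else m.copy()


def iterate_map(s: np.ndarray, params: CombineParams) -> np.ndarray:
    """Apply s <- |s + s(*)DoG - C_inh|_{>=0} ``n_iterations`` times.

    The DoG convolution is computed with two separable Gaussian filters
    (reflect boundary), which is exact for the Gaussian-difference
    kernel and much faster than an explicit 2-D kernel.
    """
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite values in map passed to iterate_map")
    width = s.shape[1]
    sig_ex = params.sigma_ex_frac * width
    sig_inh = params.sigma_inh_frac * width
    for _ in range(params.n_iterations):
        ex = (
            params.c_ex * gaussian_filter(s, sig_ex, mode=params.boundary, truncate=3.0)
            if params.c_ex and sig_ex > 0
            else 0.0
        )
        inh = (
            params.c_inh * gaussian_filter(s, sig_inh, mode=params.boundary, truncate=3.0)
            if params.c_inh and sig_inh > 0
            else 0.0
        )
        s = np.maximum(s + ex - inh - params.c_inh_const, 0.0)
    return s


def _stack_maps(stack) -> np.ndarray:
    maps = stack.maps if isinstance(stack, ConspicuityStack) else np.asarray(stack)
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim != 3 or maps.shape[0] < 1:
        raise ValueError("need a non-empty stack of 2-D maps")
    return maps


def combine_sum(stack) -> SaliencyMap:
    """Max-normalize each map to [0, 1], then sum pixelwise."""
    maps = _stack_maps(stack)
    out = np.zeros(maps.shape[1:], dtype=np.float64)
    for m in maps:
        out += _norm01(m)
    return SaliencyMap(out, {"strategy": "sum", "n_maps": maps.shape[0]})


def combine_max(stack) -> SaliencyMap:
    """Pixelwise maximum over max-normalized maps."""
    maps = _stack_maps(stack)
    out = _norm01(maps[0])
    for m in maps[1:]:
        out = np.maximum(out, _norm01(m))
    return SaliencyMap(out, {"strategy": "max", "n_maps": maps.shape[0]})


def combine_iterate(stack, params: CombineParams | None = None) -> SaliencyMap:
    """Iterate each (normalized) map, then sum the results."""
    params = params or CombineParams()
    maps = _stack_maps(stack)
    out = np.zeros(maps.shape[1:], dtype=np.float64)
    for m in maps:
        out += iterate_map(_norm01(m), params)
    return SaliencyMap(out, {"strategy": "iterate", "n_maps": maps.shape[0]})


def _similarity_matrix(maps: np.ndarray, subsample: int) -> np.ndarray:
    sub = maps[:, ::subsample, ::subsample] if subsample > 1 else maps
    n = maps.shape[0]
    S = np.eye(n)
    flat = sub.reshape(n, -1)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = squared_response_correlation(flat[i], flat[j])
    return S


def combine_clustered(stack, params: CombineParams | None = None) -> SaliencyMap:
    """Cluster maps by pairwise similarity (K-means on similarity-matrix
    rows), average within clusters, iterate the N cluster maps, sum."""
    params = params or CombineParams()
    maps = _stack_maps(stack)
    n = maps.shape[0]
    if params.n_clusters > n:
        raise ValueError(
            f"n_clusters {params.n_clusters} exceeds stack size {n}"
        )
    S = _similarity_matrix(maps, params.subsample_factor)
    km = KMeans(
        n_clusters=params.n_clusters,
        n_init=10,
        random_state=params.seed % (2**31),
    )
    labels = km.fit_predict(S)
    out = np.zeros(maps.shape[1:], dtype=np.float64)
    for k in range(params.n_clusters):
        members = np.flatnonzero(labels == k)
        if members.size == 0:  # empty cluster after k-means: skip
            continue
        avg = maps[members].mean(axis=0)
        out += iterate_map(_norm01(avg), params)
    return SaliencyMap(
        out,
        {
            "strategy": "cluster_iterate",
            "n_maps": n,
            "n_clusters": params.n_clusters,
            "labels": labels.tolist(),
        },
    )


def combine(stack, params: CombineParams | None = None) -> SaliencyMap:
    """Dispatch on ``params.strategy``; ``"auto"`` iterates directly for
    fewer than ``cluster_threshold`` maps and clusters otherwise."""
    params = params or CombineParams()
    maps = _stack_maps(stack)
    strategy = params.strategy
    if strategy == "auto":
        strategy = (
            "iterate" if maps.shape[0] < params.cluster_threshold else "cluster_iterate"
        )
        if strategy == "cluster_iterate" and maps.shape[0] < params.n_clusters:
            strategy = "iterate"
    if strategy == "sum":
        return combine_sum(maps)
    if strategy == "max":
        return combine_max(maps)
    if strategy == "iterate":
        return combine_iterate(maps, params)
    if strategy == "cluster_iterate":
        return combine_clustered(maps, params)
    raise ValueError(f"unknown combination strategy {strategy!r}")
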