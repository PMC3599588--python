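"""The full two-layer attention model and its comparison variants.

``SaliencyModel`` is a sklearn-style estimator: ``fit`` learns the
whitening and the topographic basis from training images (or from the
package's own oriented-texture generator when none are given) and
prepares the layer-2 pool layout; ``transform`` maps grayscale images
to saliency maps.

Variants sharing the same trained layers:

* ``invariant`` — the full pipeline (pool -> suppress -> combine);
* ``no_invariance`` — suppression applied directly to each rectified
  layer-1 map (layer-2 RF of 1);
* ``fully_connected`` — all filters pooled into a single map, which is
  suppressed and returned (no combination stage);
* ``randomly_connected`` — pools are random filter sets of fixed size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .basis import (
    LearningConfig,
    TopographicBasisSet,
    backproject_filters,
    learn_basis,
)
from .combination import CombineParams, SaliencyMap, combine
from .features import (
    PoolLayout,
    build_pools,
    extract_features,
    pool_features,
    rectify,
    refine_pools,
)
from .preprocessing import fit_whitening, sample_patches, whiten
from .suppression import SuppressionParams, conspicuity_stack, suppress
from .stimuli import oriented_texture

logger = logging.getLogger(__name__)

__all__ = ["VariantSpec", "run_variant", "SaliencyModel", "random_pool_layout"]

VARIANTS = ("invariant", "no_invariance", "fully_connected", "randomly_connected")


@dataclass
class VariantSpec:
    kind: str = "invariant"
    random_group_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in VARIANTS:
            raise ValueError(f"unknown variant kind {self.kind!r}")


def random_pool_layout(
    n_filters: int, n_groups: int, group_size: int, seed: int
) -> PoolLayout:
    """Random filter groups of fixed size (sampled without replacement
    within a group; groups may overlap)."""
    if group_size > n_filters:
        raise ValueError("random_group_size exceeds number of filters")
    rng = np.random.default_rng(seed)
    pools = [
        sorted(int(i) for i in rng.choice(n_filters, size=group_size, replace=False))
        for _ in range(n_groups)
    ]
    return PoolLayout(
        pools=pools,
        centers=[p[0] for p in pools],
        grid_shape=(1, n_filters),
        pool_side=1,
        overlap=0,
        refined=True,
    )


def run_variant(
    image: np.ndarray,
    basis: TopographicBasisSet,
    spec: VariantSpec,
    sup: SuppressionParams,
    comb: CombineParams,
    layout: PoolLayout | None = None,
) -> SaliencyMap:
    """Run one of the four architectures on a single image."""
    image = np.asarray(image, dtype=np.float64)
    sup_px = sup.resolve(rf_size=basis.patch_side, image_shape=image.shape)
    sf = rectify(extract_features(image, basis))

    kind = spec.kind
    if (
        kind == "randomly_connected"
        and (spec.random_group_size or 0) >= basis.n_filters
    ):
        # a random group spanning the whole first layer IS the fully
        # connected network
        kind = "fully_connected"

    if kind == "invariant":
        if layout is None:
            raise ValueError("invariant variant needs a pool layout")
        cf = pool_features(sf, layout)
        cs = conspicuity_stack(cf, sup_px)
        out = combine(cs, comb)
    elif kind == "no_invariance":
        cs = conspicuity_stack(sf.maps, sup_px)
        out = combine(cs, comb)
    elif kind == "fully_connected":
        pooled = np.sqrt((sf.maps**2).sum(axis=0))
        s = suppress(pooled, sup_px)
        out = SaliencyMap(s, {"strategy": "fully_connected"})
    else:  # randomly_connected
        n_groups = layout.n_pools if layout is not None else basis.n_filters
        gsize = spec.random_group_size or (
            layout.pool_side**2 if layout is not None else basis.n_filters
        )
        rlayout = random_pool_layout(basis.n_filters, n_groups, gsize, spec.seed)
        cf = pool_features(sf, rlayout)
        cs = conspicuity_stack(cf, sup_px)
        out = combine(cs, comb)
    out.provenance.update(variant=spec.kind, alpha=sup_px.alpha)
    return out


class SaliencyModel(BaseEstimator):
    """Two-layer bottom-up saliency model as a fit/transform estimator.

    Parameters mirror the stages: layer-1 patch/filter geometry and
    training budget, layer-2 pooling and refinement, surround
    suppression, and the combination strategy.  ``retained_dim=None``
    keeps min(n_filters, ~77% of the raw patch dimension) principal
    components, i.e. a complete basis up to the 256 -> 196 reduction
    point and an overcomplete one beyond it.

    Attributes (after ``fit``)
    --------------------------
    basis_ : TopographicBasisSet  (with pixel filters and whitening)
    layout_ : PoolLayout          (refined when refine_mode='train')
    whitening_ : WhiteningTransform
    """

    def __init__(
        self,
        variant: str = "invariant",
        patch_side: int = 16,
        n_filters: int = 49,
        grid_shape: tuple = (7, 7),
        retained_dim: int | None = None,
        neighborhood_side: int = 3,
        pool_side: int = 3,
        overlap: int = 1,
        refine_threshold: float = 0.1,
        refine_mode: str = "train",
        n_patches: int = 20_000,
        n_iterations: int = 3000,
        batch_size: int = 500,
        step_size: float = 1.0,
        alpha: float = 1.8,
        sigma_ex: float = 2.0,
        sigma_unit: str = "rf",
        sigma_ratio: float = 4.0,
        annulus: bool = False,
        boundary: str = "reflect",
        combine_strategy: str = "auto",
        combine_iterations: int = 10,
        n_clusters: int = 8,
        random_group_size: int | None = None,
        n_train_images: int = 40,
        seed: int = 0,
    ):
        self.variant = variant
        self.patch_side = patch_side
        self.n_filters = n_filters
        self.grid_shape = grid_shape
        self.retained_dim = retained_dim
        self.neighborhood_side = neighborhood_side
        self.pool_side = pool_side
        self.overlap = overlap
        self.refine_threshold = refine_threshold
        self.refine_mode = refine_mode
        self.n_patches = n_patches
        self.n_iterations = n_iterations
        self.batch_size = batch_size
        self.step_size = step_size
        self.alpha = alpha
        self.sigma_ex = sigma_ex
        self.sigma_unit = sigma_unit
        self.sigma_ratio = sigma_ratio
        self.annulus = annulus
        self.boundary = boundary
        self.combine_strategy = combine_strategy
        self.combine_iterations = combine_iterations
        self.n_clusters = n_clusters
        self.random_group_size = random_group_size
        self.n_train_images = n_train_images
        self.seed = seed

    # -- parameter bundles -------------------------------------------------

    def suppression_params(self) -> SuppressionParams:
        return SuppressionParams(
            sigma_ex=self.sigma_ex,
            sigma_unit=self.sigma_unit,
            sigma_ratio=self.sigma_ratio,
            alpha=self.alpha,
            annulus=self.annulus,
            boundary=self.boundary,
        )

    def combine_params(self) -> CombineParams:
        return CombineParams(
            n_iterations=self.combine_iterations,
            n_clusters=self.n_clusters,
            strategy=self.combine_strategy,
            boundary=self.boundary,
            seed=self.seed,
        )

    def variant_spec(self) -> VariantSpec:
        return VariantSpec(
            kind=self.variant,
            random_group_size=self.random_group_size,
            seed=self.seed,
        )

    # -- fitting -----------------------------------------------------------

    def _training_images(self):
        return [
            oriented_texture(seed=self.seed * 1000 + k)
            for k in range(self.n_train_images)
        ]

    def fit(self, X=None, y=None):
        """Learn whitening + basis from images (default: generated
        oriented textures) and prepare the pool layout."""
        images = list(X) if X is not None else self._training_images()
        raw = sample_patches(
            images, self.patch_side, self.n_patches, seed=self.seed
        )
        d_raw = self.patch_side**2
        k = self.retained_dim
        if k is None:
            # complete regime below ~77% of the raw dimension (the
            # 256 -> 196 reduction), overcomplete above it
            k = min(self.n_filters, int(round(0.766 * d_raw)))
            k = max(1, min(k, d_raw))
        self.whitening_ = fit_whitening(raw, k)
        zw = whiten(raw, self.whitening_)
        cfg = LearningConfig(
            n_filters=self.n_filters,
            grid_shape=tuple(self.grid_shape),
            neighborhood_side=self.neighborhood_side,
            step_size=self.step_size,
            n_iterations=self.n_iterations,
            batch_size=self.batch_size,
            seed=self.seed,
        )
        basis = learn_basis(zw, cfg)
        self.basis_ = backproject_filters(basis, self.whitening_)
        self.loss_curve_ = list(basis.provenance.get("loss", []))

        layout = build_pools(self.basis_, self.pool_side, self.overlap)
        if self.refine_mode == "train":
            # refinement ensemble: filter responses to the training patches
            responses = self.basis_.filters @ zw.data
            layout = refine_pools(layout, responses, self.refine_threshold)
        self.layout_ = layout
        return self

    def set_basis(self, basis: TopographicBasisSet) -> "SaliencyModel":
        """Adopt a previously trained basis (with attached whitening)
        instead of fitting; prepares an unrefined pool layout."""
        if basis.pixel_filters is None:
            raise ValueError("basis must carry pixel filters")
        self.basis_ = basis
        self.whitening_ = basis.whitening
        self.layout_ = build_pools(basis, self.pool_side, self.overlap)
        return self

    # -- inference ---------------------------------------------------------

    def saliency(self, image: np.ndarray) -> SaliencyMap:
        check_is_fitted(self, "basis_")
        layout = self.layout_
        if self.refine_mode == "image" and self.variant == "invariant":
            sf = rectify(extract_features(np.asarray(image, float), self.basis_))
            base = build_pools(self.basis_, self.pool_side, self.overlap)
            layout = refine_pools(base, sf, self.refine_threshold)
        return run_variant(
            image,
            self.basis_,
            self.variant_spec(),
            self.suppression_params(),
            self.combine_params(),
            layout=layout,
        )

    def transform(self, X):
        """Saliency maps for a list of images (or a single 2-D image)."""
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return self.saliency(X)
        return [self.saliency(img) for img in X]

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X).transform(X)

    @property
    def detect_tolerance(self) -> int:
        """Default localization tolerance: half the layer-1 RF side."""
        return max(1, self.patch_side // 2)
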