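"""Within-feature competition: non-classical receptive-field surround
suppression by a difference-of-Gaussians operator.

Each invariant feature map CF_j competes with itself spatially:

    s_j = | CF_j - alpha * (CF_j (*) omega) |_{>=0}

where omega is the half-rectified DoG kernel normalized by the L1 norm
of the full DoG, and |.|_{>=0} zeroes negatives.  Homogeneous texture
(near-constant CF) is suppressed when alpha * sum(omega) >= 1, while an
isolated peak survives — the mechanism behind pop-out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "SuppressionParams",
    "dog_kernel",
    "inhibition_weights",
    "suppress",
    "conspicuity_stack",
    "ConspicuityStack",
]


@dataclass
class SuppressionParams:
    """Surround-suppression parameters.

    ``sigma_ex`` is interpreted according to ``sigma_unit``:
    ``"px"`` (pixels), ``"rf"`` (multiples of the layer-1 RF side) or
    ``"image_frac"`` (fraction of max(H, W)).  ``sigma_inh`` defaults to
    ``sigma_ratio * sigma_ex``.  ``annulus=True`` switches to the
    surround-minus-centre convention (keeps the negative lobe instead).
    """

    sigma_ex: float = 2.0
    sigma_unit: str = "rf"
    sigma_ratio: float = 4.0
    sigma_inh: float | None = None
    alpha: float = 1.8
    kernel_radius: int | None = None
    annulus: bool = False
    boundary: str = "reflect"

    def resolve(self, rf_size: int | None = None, image_shape=None) -> "SuppressionParams":
        """Return a copy with sigmas in pixels."""
        if self.sigma_unit == "px":
            s_ex = float(self.sigma_ex)
        elif self.sigma_unit == "rf":
            if rf_size is None:
                raise ValueError("rf_size needed to resolve sigma in RF units")
            s_ex = float(self.sigma_ex) * rf_size
        elif self.sigma_unit == "image_frac":
            if image_shape is None:
                raise ValueError("image_shape needed for image_frac units")
            s_ex = float(self.sigma_ex) * max(image_shape)
        else:
            raise ValueError(f"unknown sigma_unit {self.sigma_unit!r}")
        s_inh = (
            self.sigma_ratio * s_ex
            if self.sigma_inh is None
            else float(self.sigma_inh) * (s_ex / self.sigma_ex)
        )
        return replace(
            self, sigma_ex=s_ex, sigma_inh=s_inh, sigma_unit="px"
        )

    def validate(self) -> None:
        s_inh = self.sigma_inh if self.sigma_inh is not None else self.sigma_ratio * self.sigma_ex
        if not (s_inh > self.sigma_ex > 0):
            raise ValueError(
                f"need sigma_inh ({s_inh}) > sigma_ex ({self.sigma_ex}) > 0"
            )
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def _pixel_sigmas(params: SuppressionParams) -> tuple:
    if params.sigma_unit != "px":
        raise ValueError(
            "params must be resolved to pixel units first (params.resolve)"
        )
    s_ex = float(params.sigma_ex)
    s_inh = float(
        params.sigma_inh if params.sigma_inh is not None else params.sigma_ratio * s_ex
    )
    if not (s_inh > s_ex > 0):
        raise ValueError(f"need sigma_inh ({s_inh}) > sigma_ex ({s_ex}) > 0")
    return s_ex, s_inh


def dog_kernel(params: SuppressionParams) -> np.ndarray:
    """Discrete DoG on a (2r+1)^2 grid, r = kernel_radius (default
    ceil(3 * sigma_inh)).  Both Gaussian terms have unit continuous
    integral, so the discrete kernel sums to ~0."""
    s_ex, s_inh = _pixel_sigmas(params)
    r = params.kernel_radius or int(np.ceil(3.0 * s_inh))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    rr = x**2 + y**2
    g_ex = np.exp(-rr / (2 * s_ex**2)) / (2 * np.pi * s_ex**2)
    g_inh = np.exp(-rr / (2 * s_inh**2)) / (2 * np.pi * s_inh**2)
    return g_ex - g_inh


def inhibition_weights(params: SuppressionParams) -> np.ndarray:
    """omega = half-rectified DoG / L1 norm of the DoG.

    With ``annulus=True`` the negative (surround) lobe is kept instead,
    sign-flipped — the surround-minus-centre convention used in the
    contour-saliency literature.
    """
    dog = dog_kernel(params)
    l1 = np.abs(dog).sum()
    if l1 == 0:
        raise ValueError("degenerate DoG kernel (all zero)")
    if params.annulus:
        w = np.maximum(-dog, 0.0) / l1
    else:
        w = np.maximum(dog, 0.0) / l1
    return w


def _crop_support(kernel: np.ndarray) -> np.ndarray:
    """Crop a centred kernel to the symmetric bounding box of its
    non-zero support (pure speed-up; convolution result unchanged)."""
    nz = np.argwhere(kernel > 0)
    if nz.size == 0:
        return kernel
    r = kernel.shape[0] // 2
    ext = int(np.max(np.abs(nz - r)))
    return kernel[r - ext : r + ext + 1, r - ext : r + ext + 1]


def _padded_conv2d_same(
    arr: np.ndarray, kernel: np.ndarray, boundary: str = "reflect"
) -> np.ndarray:
    """'same' convolution with reflect or wrap (toroidal) padding.

    Wrap treats the map as periodic — the natural boundary for tiled
    psychophysical displays, where it emulates an infinite array and
    avoids spurious conspicuity at the display edge.
    """
    k = kernel.shape[0]
    h = k // 2
    if boundary not in ("reflect", "wrap"):
        raise ValueError(f"unknown boundary {boundary!r}")
    if h >= min(arr.shape):  # padding cannot exceed array size: stage it
        padded = arr
        rem = h
        while rem > 0:
            step = min(rem, min(padded.shape) - 1)
            padded = np.pad(padded, step, mode=boundary)
            rem -= step
    else:
        padded = np.pad(arr, h, mode=boundary)
    return fftconvolve(padded, kernel, mode="valid")


def suppress(cf: np.ndarray, params: SuppressionParams) -> np.ndarray:
    """s = | CF - alpha * (CF (*) omega) |_{>=0}; 'same' convolution
    with the boundary handling chosen in params."""
    cf = np.asarray(cf, dtype=np.float64)
    if cf.ndim != 2:
        raise ValueError("conspicuity input must be a 2-D map")
    w = _crop_support(inhibition_weights(params))
    inhib = _padded_conv2d_same(cf, w, params.boundary)
    return np.maximum(cf - params.alpha * inhib, 0.0)


@dataclass
class ConspicuityStack:
    """Per-pool conspicuity maps s_j, shape (n_pools, H, W), >= 0."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("ConspicuityStack.maps must be 3-D")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


def conspicuity_stack(inv, params: SuppressionParams) -> ConspicuityStack:
    """Apply :func:`suppress` to every invariant map independently."""
    maps = inv.maps if hasattr(inv, "maps") else np.asarray(inv, dtype=np.float64)
    w = _crop_support(inhibition_weights(params))
    out = np.empty_like(maps)
    for j in range(maps.shape[0]):
        inhib = _padded_conv2d_same(maps[j], w, params.boundary)
        out[j] = np.maximum(maps[j] - params.alpha * inhib, 0.0)
    return ConspicuityStack(out)
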