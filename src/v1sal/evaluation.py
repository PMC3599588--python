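"""Evaluation metrics for the saliency model.

* correct-detection rate on search arrays (saliency argmax on target);
* the top-m segment rule for object-in-texture scenes: a detection is
  correct when at least 70% of the m most salient segments are object
  segments, with a closed-form chance level;
* ROC area against human-fixation maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.ndimage import binary_dilation
from sklearn.metrics import roc_auc_score

from .combination import SaliencyMap

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionResult",
    "detect_target",
    "detection_rate",
    "topm_detection",
    "random_detection_probability",
    "chance_topm_probability",
    "roc_area",
]


@dataclass
class DetectionResult:
    hit: bool
    argmax_location: tuple
    flagged: bool = False


def _disk(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), dtype=bool)
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return x**2 + y**2 <= radius**2


def detect_target(
    smap, scene, tolerance: int = 4
) -> DetectionResult:
    """Hit iff the saliency argmax lies within the target mask dilated
    by ``tolerance`` pixels (default: half a typical layer-1 RF).

    Ties in the map resolve to the first maximum in row-major order
    (with a warning); an all-zero map counts as a flagged miss.
    """
    s = smap.s if isinstance(smap, SaliencyMap) else np.asarray(smap, dtype=float)
    mask = scene.target_mask if hasattr(scene, "target_mask") else np.asarray(scene)
    if not mask.any():
        raise ValueError("scene has an empty target mask")
    if s.shape != mask.shape:
        raise ValueError(f"map shape {s.shape} != mask shape {mask.shape}")
    mx = s.max()
    flagged = False
    if mx == 0:
        logger.warning("all-zero saliency map: counted as a miss")
        return DetectionResult(False, (0, 0), flagged=True)
    if np.count_nonzero(s == mx) > 1:
        logger.warning("tied saliency maxima; using first in row-major order")
        flagged = True
    loc = np.unravel_index(int(np.argmax(s)), s.shape)
    dilated = binary_dilation(mask, structure=_disk(tolerance)) if tolerance else mask
    return DetectionResult(bool(dilated[loc]), tuple(int(v) for v in loc), flagged)


def detection_rate(runner, scenes, tolerance: int = 4):
    """Average hit rate of ``runner(scene) -> SaliencyMap`` over scenes.

    Returns (rate, records).
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("no scenes supplied")
    records = [detect_target(runner(sc), sc, tolerance=tolerance) for sc in scenes]
    rate = sum(r.hit for r in records) / len(records)
    return rate, records


def topm_detection(
    smap,
    scene,
    fraction_required: float = 0.7,
    score: str = "max",
) -> bool:
    """Top-m rule: score every labelled segment by its max (or mean)
    saliency, rank all m+n segments, and call the detection correct
    when at least ceil(fraction_required * m) of the top-m are object
    segments."""
    s = smap.s if isinstance(smap, SaliencyMap) else np.asarray(smap, dtype=float)
    lab = scene.segment_labels
    flags = scene.object_flags
    m = int(np.sum(flags))
    if m == 0:
        raise ValueError("scene has no object segments")
    n_seg = len(flags)
    scores = np.full(n_seg, -np.inf)
    for k in range(n_seg):
        pix = lab == k + 1
        if pix.any():
            scores[k] = s[pix].max() if score == "max" else s[pix].mean()
    order = np.argsort(-scores, kind="stable")
    top = order[:m]
    hits = int(np.sum(flags[top]))
    return hits >= int(np.ceil(fraction_required * m))


def random_detection_probability(m: int, n: int) -> float:
    """Chance level printed for the top-m rule: the binomial term
    C(10,7) * (m/(m+n))^7 * (n/(m+n))^3 — the probability that exactly
    7 of 10 segments drawn with replacement are object segments."""
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    p = m / (m + n)
    return comb(10, 7) * p**7 * (1 - p) ** 3


def chance_topm_probability(m: int, n: int, draw: int = 10, need: int = 7) -> float:
    """Exact chance that >= ``need`` of the top-``draw`` segments are
    object segments under a uniform random ranking (hypergeometric tail
    — sampling without replacement, the process the top-m rule actually
    performs)."""
    from scipy.stats import hypergeom

    return float(hypergeom.sf(need - 1, m + n, m, draw))


def roc_area(smap, fixation_map, density_percentile: float = 95.0) -> float:
    """AUC for classifying fixated vs non-fixated pixels by saliency.

    ``fixation_map`` may be boolean or a nonnegative density; densities
    are binarized at ``density_percentile``.
    """
    s = smap.s if isinstance(smap, SaliencyMap) else np.asarray(smap, dtype=float)
    fx = np.asarray(fixation_map)
    if fx.shape != s.shape:
        raise ValueError("fixation map shape mismatch")
    if fx.dtype != bool:
        thr = np.percentile(fx, density_percentile)
        fx = fx > thr
    y = fx.ravel().astype(int)
    if y.min() == y.max():
        raise ValueError("fixation map must contain both classes")
    return float(roc_auc_score(y, s.ravel()))
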