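"""Synthetic psychophysical stimuli with machine-readable ground truth.

Four scene families cover the model's experiment classes:

* orientation-singleton search arrays (one bar orthogonal to jittered
  distractors) — the classic pop-out task;
* composite-element arrays (multi-bar elements, one deviant);
* global-structure scenes (a solid S-curve, an illusory S made of
  collinear fragments, and a noisy version with random background bars);
* object-in-texture edge images (a closed fruit-like contour of ~30
  short segments inserted into a procedural texture edge field at a
  controlled object:background segment ratio, the "SNR").

All bars are rendered anti-aliased on a black [0, 1] background; every
generator is a pure function of its parameters and seed.  A separate
``oriented_texture`` generator produces naturalistic training images
(dense random-orientation bar fields) for basis learning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticScene",
    "render_bars",
    "gen_orientation_array",
    "gen_composite_array",
    "gen_contour_scene",
    "gen_object_in_texture",
    "make_object_segments",
    "make_texture_segments",
    "oriented_texture",
    "OBJECT_KINDS",
    "TEXTURE_KINDS",
]


@dataclass
class SyntheticScene:
    """Stimulus image plus ground truth.

    ``segment_labels`` assigns integer ids (0 = empty background) to
    pixels; ``object_flags[k]`` says whether segment id ``k+1`` belongs
    to the object/target.  ``m``/``n`` are object/background segment
    counts where the scene family defines them.
    """

    image: np.ndarray
    target_mask: np.ndarray
    segment_labels: np.ndarray
    object_flags: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return int(np.sum(self.object_flags))

    @property
    def n(self) -> int:
        return int(np.sum(~self.object_flags))

    def save(self, prefix) -> None:
        from .imageio import write_image

        write_image(f"{prefix}.png", self.image)
        write_image(f"{prefix}_mask.png", self.target_mask.astype(float))
        np.savez(
            f"{prefix}_truth.npz",
            target_mask=self.target_mask,
            segment_labels=self.segment_labels,
            object_flags=self.object_flags,
        )
        with open(f"{prefix}.json", "w") as fh:
            json.dump(self.params, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# rendering primitives


def _bar_alpha_patch(theta_deg: float, length: float, width: float):
    """Anti-aliased coverage patch of a rotated bar centred at origin.

    Returns (alpha, half) where alpha is a (2*half+1)^2 patch.
    """
    th = np.deg2rad(theta_deg)
    half = int(np.ceil(0.5 * (abs(length * np.cos(th)) + abs(width * np.sin(th))))) + 2
    halfv = int(np.ceil(0.5 * (abs(length * np.sin(th)) + abs(width * np.cos(th))))) + 2
    half = max(half, halfv)
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    # local frame: u along the bar, v across
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    d = np.maximum(np.abs(u) - length / 2.0, np.abs(v) - width / 2.0)
    return np.clip(0.5 - d, 0.0, 1.0), half


def render_bars(shape, bars, labels=False):
    """Composite anti-aliased bars onto a zero canvas.

    ``bars`` is a sequence of (cx, cy, theta_deg, length, width) with
    (cx, cy) = (col, row) centre.  Returns the image, or (image,
    label_map) when ``labels`` — the label map holds 1-based bar
    indices where each bar's coverage exceeds 0.5 (later bars win
    ties).
    """
    img = np.zeros(shape, dtype=np.float64)
    lab = np.zeros(shape, dtype=np.int32) if labels else None
    H, W = shape
    for k, (cx, cy, th, length, width) in enumerate(bars, start=1):
        alpha, half = _bar_alpha_patch(th, length, width)
        r0, c0 = int(round(cy)) - half, int(round(cx)) - half
        fy = cy - round(cy)
        fx = cx - round(cx)
        # sub-pixel offsets are folded into the distance field centre
        if fx or fy:
            alpha, half2 = _bar_alpha_patch_offset(th, length, width, fx, fy, half)
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1 = min(r0 + alpha.shape[0], H)
        cc1 = min(c0 + alpha.shape[1], W)
        if rr1 <= rr0 or cc1 <= cc0:
            continue
        a = alpha[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        img[rr0:rr1, cc0:cc1] = np.maximum(img[rr0:rr1, cc0:cc1], a)
        if labels:
            sel = a > 0.5
            lab[rr0:rr1, cc0:cc1][sel] = k
    return (img, lab) if labels else img


def _bar_alpha_patch_offset(theta_deg, length, width, fx, fy, half):
    th = np.deg2rad(theta_deg)
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    x = x - fx
    y = y - fy
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    d = np.maximum(np.abs(u) - length / 2.0, np.abs(v) - width / 2.0)
    return np.clip(0.5 - d, 0.0, 1.0), half


# ---------------------------------------------------------------------------
# orientation-singleton search arrays


def gen_orientation_array(
    grid=(10, 10),
    bar_length: float = 16.0,
    bar_width: float = 3.0,
    spacing: float = 24.0,
    noise_halfwidth: float = 0.0,
    seed: int = 0,
    jitter: float | None = None,
    margin: float | None = None,
) -> SyntheticScene:
    """One randomly oriented target bar among distractors orthogonal to
    it, with distractor orientations perturbed by U(-dtheta, +dtheta).

    ``noise_halfwidth`` (degrees) must not exceed 45 — beyond that the
    distractor band reaches the target orientation.  Element positions
    are jittered inside their cells without letting bars overlap, and a
    blank ``margin`` (default: half a cell) frames the array so no bar
    is clipped by the canvas edge.
    """
    if noise_halfwidth > 45.0:
        raise ValueError("orientation noise half-width must not exceed 45 deg")
    rng = np.random.default_rng(seed)
    rows, cols = grid
    if margin is None:
        margin = spacing / 2.0
    H = int(round(rows * spacing + 2 * margin))
    W = int(round(cols * spacing + 2 * margin))
    diag = np.hypot(bar_length, bar_width)
    max_jitter = (spacing - diag) / 2.0 - 1.0 if jitter is None else jitter
    if max_jitter < 0:
        raise ValueError(
            f"bars of diagonal {diag:.1f}px overlap at spacing {spacing}px"
        )
    target_cell = int(rng.integers(0, rows * cols))
    theta_t = float(rng.uniform(0.0, 180.0))
    bars = []
    for cell in range(rows * cols):
        r, c = divmod(cell, cols)
        cy = margin + (r + 0.5) * spacing + rng.uniform(-max_jitter, max_jitter)
        cx = margin + (c + 0.5) * spacing + rng.uniform(-max_jitter, max_jitter)
        if cell == target_cell:
            th = theta_t
        else:
            th = theta_t + 90.0 + rng.uniform(-noise_halfwidth, noise_halfwidth)
        bars.append((cx, cy, th, bar_length, bar_width))
    img, lab = render_bars((H, W), bars, labels=True)
    flags = np.zeros(len(bars), dtype=bool)
    flags[target_cell] = True
    mask = lab == target_cell + 1
    return SyntheticScene(
        image=img,
        target_mask=mask,
        segment_labels=lab,
        object_flags=flags,
        params={
            "kind": "orientation_array",
            "grid": list(grid),
            "bar_length": bar_length,
            "bar_width": bar_width,
            "spacing": spacing,
            "noise_halfwidth": noise_halfwidth,
            "margin": margin,
            "seed": seed,
            "target_cell": target_cell,
            "target_theta": theta_t,
        },
    )


# ---------------------------------------------------------------------------
# composite-element arrays

# default element templates: bars given as (du, dv, rel_angle, length, width)
# in element-local units before global rotation
_BASE_TEMPLATE = [(-4.0, 0.0, 0.0, 14.0, 2.5), (4.0, 0.0, 90.0, 14.0, 2.5)]
_DEVIANT_TEMPLATE = [(-4.0, 0.0, 0.0, 14.0, 2.5), (4.0, 0.0, 0.0, 14.0, 2.5)]


def gen_composite_array(
    grid=(6, 6),
    spacing: float = 40.0,
    base_template=None,
    deviant_template=None,
    n_deviants: int = 1,
    orientation: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Array of identical multi-bar composite elements with
    ``n_deviants`` elements drawn from a deviant internal configuration
    (default: an L-junction pair among parallel pairs)."""
    base_template = base_template or _BASE_TEMPLATE
    deviant_template = deviant_template or _DEVIANT_TEMPLATE
    rng = np.random.default_rng(seed)
    rows, cols = grid
    H, W = int(rows * spacing), int(cols * spacing)
    cells = rng.permutation(rows * cols)
    deviant_cells = set(int(c) for c in cells[:n_deviants])
    bars, owner = [], []
    th0 = np.deg2rad(orientation)
    for cell in range(rows * cols):
        r, c = divmod(cell, cols)
        cy = (r + 0.5) * spacing
        cx = (c + 0.5) * spacing
        tpl = deviant_template if cell in deviant_cells else base_template
        for du, dv, rel, length, width in tpl:
            dx = du * np.cos(th0) - dv * np.sin(th0)
            dy = du * np.sin(th0) + dv * np.cos(th0)
            bars.append((cx + dx, cy + dy, orientation + rel, length, width))
            owner.append(cell)
    img, lab = render_bars((H, W), bars, labels=True)
    owner = np.asarray(owner)
    flags = np.array([owner[k] in deviant_cells for k in range(len(bars))])
    mask = np.isin(lab, np.flatnonzero(flags) + 1)
    # collapse per-bar labels to per-element labels
    elem_lab = np.where(lab > 0, owner[np.maximum(lab - 1, 0)] + 1, 0)
    elem_flags = np.array([c in deviant_cells for c in range(rows * cols)])
    return SyntheticScene(
        image=img,
        target_mask=mask,
        segment_labels=elem_lab.astype(np.int32),
        object_flags=elem_flags,
        params={
            "kind": "composite_array",
            "grid": list(grid),
            "spacing": spacing,
            "n_deviants": n_deviants,
            "deviant_cells": sorted(deviant_cells),
            "seed": seed,
            "empty_target": n_deviants == 0,
        },
    )


# ---------------------------------------------------------------------------
# global-structure (S-curve) scenes


def _s_path(t: np.ndarray, shape, amplitude: float = 0.28, margin: float = 0.12):
    """Parametric S-curve through the canvas; returns (x, y, tangent_deg)."""
    H, W = shape
    y = (margin + (1 - 2 * margin) * t) * H
    x = W / 2.0 + amplitude * W * np.sin(2 * np.pi * t)
    dy = (1 - 2 * margin) * H
    dx = amplitude * W * 2 * np.pi * np.cos(2 * np.pi * t)
    ang = np.rad2deg(np.arctan2(dy, dx))
    return x, y, ang


def gen_contour_scene(
    kind: str = "illusory_s",
    shape=(256, 256),
    n_elements: int = 24,
    element_length: float = 12.0,
    element_width: float = 2.5,
    gap: float = 6.0,
    background_density: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """An S-shaped contour: solid curve, collinear fragments with gaps
    ('illusory'), or fragments plus ``background_density`` (elements per
    1000 px^2) randomly placed and oriented background bars ('noisy')."""
    if kind not in ("solid_s", "illusory_s", "noisy_s"):
        raise ValueError(f"unknown contour kind {kind!r}")
    rng = np.random.default_rng(seed)
    H, W = shape
    bars = []
    if kind == "solid_s":
        t = np.linspace(0.0, 1.0, 400)
        x, y, ang = _s_path(t, shape)
        for xi, yi, ai in zip(x, y, ang):
            bars.append((xi, yi, ai, 3.0, element_width))
        n_obj = len(bars)
    else:
        t = np.linspace(0.0, 1.0, n_elements)
        x, y, ang = _s_path(t, shape)
        for xi, yi, ai in zip(x, y, ang):
            bars.append((xi, yi, ai, element_length, element_width))
        n_obj = n_elements
    n_bg = 0
    if kind == "noisy_s":
        n_bg = int(round(background_density * H * W / 1000.0))
        margin = element_length
        for _ in range(n_bg):
            bars.append(
                (
                    rng.uniform(margin, W - margin),
                    rng.uniform(margin, H - margin),
                    rng.uniform(0.0, 180.0),
                    element_length,
                    element_width,
                )
            )
    img, lab = render_bars((H, W), bars, labels=True)
    flags = np.zeros(len(bars), dtype=bool)
    flags[:n_obj] = True
    mask = (lab > 0) & (lab <= n_obj)
    if kind == "solid_s":
        # the whole curve is one object segment
        lab = np.where(mask, 1, np.where(lab > 0, lab - n_obj + 1, 0)).astype(np.int32)
        flags = np.concatenate([[True], np.zeros(n_bg, dtype=bool)])
    return SyntheticScene(
        image=img,
        target_mask=mask,
        segment_labels=lab,
        object_flags=flags,
        params={
            "kind": kind,
            "shape": list(shape),
            "n_elements": n_elements,
            "gap": gap,
            "background_density": background_density,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# object-in-texture edge images

OBJECT_KINDS = ("pear", "banana", "onion")
TEXTURE_KINDS = ("brick", "wave", "grain", "brick_fine", "wave_fine", "grain_fine")


def make_object_segments(kind: str = "pear", n_segments: int = 30, seed: int = 0):
    """Closed fruit-like contour sampled into short edge segments.

    Returns an (n_segments, 4) array of (x0, y0, x1, y1) in a local
    frame centred at (0, 0), fitting inside a 32x32 box.  These are
    procedural stand-ins for object edge maps.
    """
    rng = np.random.default_rng(seed)
    phases = {"pear": (0.25, 2, 0.0), "banana": (0.45, 1, 1.2), "onion": (0.18, 3, 0.6)}
    if kind not in phases:
        raise ValueError(f"unknown object kind {kind!r}")
    amp, lobe, ph = phases[kind]
    phi = np.linspace(0.0, 2 * np.pi, n_segments, endpoint=False)
    phi = phi + rng.uniform(0, 2 * np.pi / n_segments)
    r = 13.0 * (1.0 + amp * np.sin(lobe * phi + ph))
    r = np.clip(r, 5.0, 15.5)
    x = r * np.cos(phi)
    y = 0.9 * r * np.sin(phi)
    # contiguous chords partition the closed contour, the way an edge
    # detector breaks a silhouette into touching segments
    segs = np.empty((n_segments, 4))
    for k in range(n_segments):
        k2 = (k + 1) % n_segments
        segs[k] = (x[k], y[k], x[k2], y[k2])
    return segs


def make_texture_segments(kind: str = "brick", shape=(64, 64), seed: int = 0):
    """Procedural texture edge field covering the canvas.

    'brick' = staggered horizontal/vertical wall joints, 'wave' =
    tangent segments along sinusoidal rows, 'grain' = an orientation-
    coherent random field.  '*_fine' variants halve the spatial scale.
    Returns an (N, 4) segment array (several hundred segments).
    """
    base = kind.replace("_fine", "")
    fine = kind.endswith("_fine")
    if base not in ("brick", "wave", "grain"):
        raise ValueError(f"unknown texture kind {kind!r}")
    rng = np.random.default_rng(seed)
    H, W = shape
    segs = []
    if base == "brick":
        bh, bw = (4, 8) if fine else (5, 10)
        for i, y in enumerate(range(0, H + bh, bh)):
            off = (i % 2) * bw // 2
            piece = 3
            for x in range(-off, W + bw, bw):
                # bed joints broken into ~3 px pieces, like detector output
                x0 = x + 0.5
                while x0 < x + bw - 0.5:
                    x1 = min(x0 + piece, x + bw - 0.5)
                    segs.append((x0, y, x1, y))
                    x0 = x1 + 0.6
                segs.append((x, y + 0.5, x, y + min(piece, bh) - 0.5))  # head joint
    elif base == "wave":
        period = 16 if fine else 24
        rows = range(2, H, 4 if fine else 6)
        step = 3 if fine else 4
        for y0 in rows:
            ph = rng.uniform(0, 2 * np.pi)
            for x in range(0, W - step, step):
                y1 = y0 + 1.6 * np.sin(2 * np.pi * x / period + ph)
                y2 = y0 + 1.6 * np.sin(2 * np.pi * (x + step) / period + ph)
                segs.append((x, y1, x + step, y2))
    else:  # grain
        cell = 4 if fine else 5
        length = 3.0 if fine else 3.0
        # slowly varying orientation field
        gx = rng.uniform(0, 2 * np.pi)
        gy = rng.uniform(0, 2 * np.pi)
        for y in range(cell // 2, H, cell):
            for x in range(cell // 2, W, cell):
                th = (
                    90.0 * np.sin(2 * np.pi * x / 48.0 + gx)
                    + 90.0 * np.sin(2 * np.pi * y / 56.0 + gy)
                    + rng.uniform(-15, 15)
                )
                thr = np.deg2rad(th)
                dx, dy = 0.5 * length * np.cos(thr), 0.5 * length * np.sin(thr)
                jx, jy = rng.uniform(-1, 1, 2)
                segs.append((x + jx - dx, y + jy - dy, x + jx + dx, y + jy + dy))
    return np.asarray(segs, dtype=np.float64)


def _segments_to_bars(segs: np.ndarray, width: float = 1.2):
    bars = []
    for x0, y0, x1, y1 in segs:
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        length = float(np.hypot(x1 - x0, y1 - y0))
        ang = float(np.rad2deg(np.arctan2(y1 - y0, x1 - x0)))
        bars.append((cx, cy, ang, max(length, 1.0), width))
    return bars


def gen_object_in_texture(
    object_segments: np.ndarray | str = "pear",
    texture_segments: np.ndarray | str = "brick",
    snr=(1, 3),
    canvas=(64, 64),
    seed: int = 0,
    scale: int = 1,
) -> SyntheticScene:
    """Insert an object edge image into the centre of a texture edge
    image at an object:background segment ratio ``snr`` = (m_units,
    n_units); with m object segments the background keeps
    n = round(m * n_units / m_units) segments, subsampled at random.

    ``scale`` > 1 renders the same layout on a proportionally larger
    canvas (segment coordinates are scaled), which keeps segment counts
    fixed while giving the model more pixels to work with.
    """
    rng = np.random.default_rng(seed)
    if isinstance(object_segments, str):
        object_segments = make_object_segments(object_segments, seed=seed)
    if isinstance(texture_segments, str):
        texture_segments = make_texture_segments(texture_segments, canvas, seed=seed + 1)
    m = len(object_segments)
    n = int(round(m * snr[1] / snr[0]))
    H, W = canvas
    obj = np.asarray(object_segments, dtype=np.float64).copy()
    span = max(
        obj[:, [0, 2]].max() - obj[:, [0, 2]].min(),
        obj[:, [1, 3]].max() - obj[:, [1, 3]].min(),
    )
    if span > min(H, W) / 2:
        raise ValueError("object does not fit in the centre region")
    obj[:, [0, 2]] += W / 2.0
    obj[:, [1, 3]] += H / 2.0

    tex = np.asarray(texture_segments, dtype=np.float64)
    # drop texture segments whose midpoint falls inside the object box
    mid = np.c_[tex[:, [0, 2]].mean(1), tex[:, [1, 3]].mean(1)]
    ox0, ox1 = obj[:, [0, 2]].min() - 1, obj[:, [0, 2]].max() + 1
    oy0, oy1 = obj[:, [1, 3]].min() - 1, obj[:, [1, 3]].max() + 1
    outside = ~(
        (mid[:, 0] > ox0) & (mid[:, 0] < ox1) & (mid[:, 1] > oy0) & (mid[:, 1] < oy1)
    )
    tex = tex[outside]
    if n > len(tex):
        raise ValueError(
            f"requested {n} background segments but texture offers {len(tex)}"
        )
    keep = rng.choice(len(tex), size=n, replace=False)
    tex = tex[np.sort(keep)]

    all_segs = np.vstack([obj, tex]) * float(scale)
    shape = (H * scale, W * scale)
    img, lab = render_bars(
        shape, _segments_to_bars(all_segs, width=1.2 * scale), labels=True
    )
    flags = np.zeros(len(all_segs), dtype=bool)
    flags[:m] = True
    mask = (lab > 0) & (lab <= m)
    return SyntheticScene(
        image=img,
        target_mask=mask,
        segment_labels=lab,
        object_flags=flags,
        params={
            "kind": "object_in_texture",
            "snr": list(snr),
            "m": m,
            "n": n,
            "canvas": list(canvas),
            "scale": scale,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# training textures


def oriented_texture(
    shape=(128, 128),
    n_bars: int = 120,
    bar_length=(8.0, 22.0),
    bar_width=(1.5, 3.5),
    seed: int = 0,
) -> np.ndarray:
    """Naturalistic training texture: a dense field of anti-aliased bars
    at uniformly random orientations and positions.  Basis learning on
    patches from such images yields oriented, localized filters."""
    rng = np.random.default_rng(seed)
    H, W = shape
    bars = []
    for _ in range(n_bars):
        bars.append(
            (
                rng.uniform(0, W),
                rng.uniform(0, H),
                rng.uniform(0.0, 180.0),
                rng.uniform(*bar_length),
                rng.uniform(*bar_width),
            )
        )
    return render_bars(shape, bars)
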