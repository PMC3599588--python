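"""Experiment drivers reproducing the study protocols on synthetic
stimuli: pop-out sweeps over orientation noise, the contour suite, the
SNR curve for object-in-texture scenes, and the combination-strategy
comparison.  Each driver returns plain records (list of dicts) so the
CLI can dump CSV/JSON and tests can assert on them directly.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from .combination import combine_iterate, combine_max, combine_sum
from .evaluation import detect_target, topm_detection
from .features import pool_features, rectify, extract_features
from .model import SaliencyModel, VariantSpec, run_variant
from .stimuli import (
    OBJECT_KINDS,
    TEXTURE_KINDS,
    gen_contour_scene,
    gen_object_in_texture,
    gen_orientation_array,
)
from .suppression import conspicuity_stack

logger = logging.getLogger(__name__)

__all__ = [
    "popout_sweep",
    "contour_suite",
    "snr_curve",
    "combine_compare",
    "run_experiment",
    "EXPERIMENTS",
]

ALL_VARIANTS = ("invariant", "no_invariance", "fully_connected", "randomly_connected")


def _variant_map(model: SaliencyModel, scene, kind: str, group_seed: int | None = None):
    # random groups are resampled per scene so the randomly connected
    # network's rate reflects its average over group draws
    spec = VariantSpec(
        kind=kind,
        random_group_size=model.random_group_size,
        seed=model.seed if group_seed is None else group_seed,
    )
    return run_variant(
        scene.image,
        model.basis_,
        spec,
        model.suppression_params(),
        model.combine_params(),
        layout=model.layout_,
    )


def popout_sweep(
    model: SaliencyModel,
    deltas=(0.0, 10.0, 20.0, 30.0, 45.0),
    n_scenes: int = 20,
    variants=ALL_VARIANTS,
    seed: int = 0,
    scene_kw: dict | None = None,
):
    """Correct-detection rate of each variant on orientation-singleton
    arrays as the distractor orientation noise grows."""
    scene_kw = scene_kw or {}
    records = []
    for dth in deltas:
        scenes = [
            gen_orientation_array(
                noise_halfwidth=dth, seed=seed * 100_000 + int(dth * 100) + k,
                **scene_kw,
            )
            for k in range(n_scenes)
        ]
        for kind in variants:
            hits = 0
            for ks, sc in enumerate(scenes):
                smap = _variant_map(model, sc, kind, group_seed=seed * 977 + ks)
                hits += detect_target(
                    smap, sc, tolerance=model.detect_tolerance
                ).hit
            records.append(
                {
                    "delta_theta": dth,
                    "variant": kind,
                    "n_scenes": n_scenes,
                    "rate": hits / n_scenes,
                }
            )
            logger.info("popout d=%g %s rate=%.2f", dth, kind, hits / n_scenes)
    return records


def contour_suite(model: SaliencyModel, seed: int = 0, background_density: float = 0.5):
    """Saliency of the S-contour versus background for the three global-
    structure scenes; reports the contour/background saliency contrast."""
    records = []
    for kind in ("solid_s", "illusory_s", "noisy_s"):
        sc = gen_contour_scene(
            kind=kind,
            seed=seed,
            background_density=background_density if kind == "noisy_s" else 0.0,
        )
        smap = _variant_map(model, sc, "invariant")
        on = smap.s[sc.target_mask]
        off = smap.s[~sc.target_mask]
        contrast = float(on.mean() / (off.mean() + 1e-12))
        records.append(
            {
                "kind": kind,
                "contour_mean": float(on.mean()),
                "background_mean": float(off.mean()),
                "contrast": contrast,
                "argmax_on_contour": bool(
                    detect_target(smap, sc, tolerance=model.detect_tolerance).hit
                ),
            }
        )
    return records


SNR_GRID = ((1, 2), (1, 2.5), (1, 3), (1, 3.5), (1, 4))


def snr_curve(
    model: SaliencyModel,
    snrs=SNR_GRID,
    objects=OBJECT_KINDS,
    textures=TEXTURE_KINDS,
    seed: int = 0,
    scale: int = 1,
):
    """Top-m detection rate of the invariant model on object-in-texture
    scenes across SNRs; each SNR gets one scene per (object, texture)
    pair (3 x 6 = 18 scenes)."""
    records = []
    for snr in snrs:
        correct = 0
        total = 0
        for oi, obj in enumerate(objects):
            for ti, tex in enumerate(textures):
                sc = gen_object_in_texture(
                    obj, tex, snr=snr, seed=seed + 97 * oi + 13 * ti, scale=scale
                )
                smap = _variant_map(model, sc, "invariant")
                correct += topm_detection(smap, sc)
                total += 1
        records.append(
            {
                "snr": f"{snr[0]}:{snr[1]}",
                "snr_value": snr[0] / snr[1],
                "n_scenes": total,
                "rate": correct / total,
            }
        )
        logger.info("snr %s rate=%.2f", records[-1]["snr"], correct / total)
    return records


def combine_compare(model: SaliencyModel, seed: int = 0, n_scenes: int = 5):
    """Sparsity and argmax behaviour of the sum / max / iterate
    combination strategies on pop-out arrays."""
    records = []
    for k in range(n_scenes):
        sc = gen_orientation_array(noise_halfwidth=30.0, seed=seed * 1000 + k)
        sf = rectify(extract_features(sc.image, model.basis_))
        cf = pool_features(sf, model.layout_)
        sup = model.suppression_params().resolve(
            rf_size=model.basis_.patch_side, image_shape=sc.image.shape
        )
        cs = conspicuity_stack(cf, sup)
        for name, fn in (
            ("sum", combine_sum),
            ("max", combine_max),
            ("iterate", lambda s: combine_iterate(s, model.combine_params())),
        ):
            smap = fn(cs)
            frac = float(np.mean(smap.s > 0.1 * smap.s.max())) if smap.s.max() > 0 else 0.0
            records.append(
                {
                    "scene": k,
                    "strategy": name,
                    "active_fraction": frac,
                    "hit": detect_target(
                        smap, sc, tolerance=model.detect_tolerance
                    ).hit,
                }
            )
    return records


EXPERIMENTS = {
    "popout_sweep": popout_sweep,
    "contour_suite": contour_suite,
    "snr_curve": snr_curve,
    "combine_compare": combine_compare,
}


def run_experiment(
    name: str, model: SaliencyModel, outdir, seed: int = 0, plot: bool = True, **kw
):
    """Drive a named experiment, writing CSV + JSON (and a PNG plot for
    the rate curves) into ``outdir``.  Returns the records."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = EXPERIMENTS[name](model, seed=seed, **kw)
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(records, fh, indent=2)
    if records:
        with open(outdir / f"{name}.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(records[0].keys()))
            w.writeheader()
            w.writerows(records)
    if plot and name in ("popout_sweep", "snr_curve"):
        _plot_rates(name, records, outdir / f"{name}.png")
    return records


def _plot_rates(name, records, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    if name == "popout_sweep":
        variants = sorted({r["variant"] for r in records})
        for v in variants:
            pts = [(r["delta_theta"], r["rate"]) for r in records if r["variant"] == v]
            ax.plot(*zip(*pts), marker="o", label=v)
        ax.set_xlabel("orientation noise half-width (deg)")
        ax.legend(fontsize=7)
    else:
        pts = [(r["snr_value"], r["rate"]) for r in records]
        ax.plot(*zip(*pts), marker="o")
        ax.set_xlabel("SNR (m/n)")
    ax.set_ylabel("correct detection rate")
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
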