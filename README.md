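# v1sal

A two-layer, biologically constrained model of **bottom-up visual
saliency**, for researchers studying how the primary visual cortex
(V1) could encode a saliency map — and for anyone who wants a small,
fully seeded test bed of the classic pop-out, contour and
object-in-texture psychophysics that such models are judged on.

Instead of hand-built Gabor pyramids, layer 1 is an (over)complete set
of filters **learned from images** and arranged on a topographic torus
grid, so that neighbouring filters share orientation and frequency
tuning (simple cells).  Layer 2 pools squared responses over torus
neighbourhoods Ω_j,

    CF_j(x,y) = sqrt( Σ_{i∈Ω_j} SF_i(x,y)² ),

the energy model of complex cells, which buys invariance to phase and
small orientation changes.  Each invariant map then competes with
itself through non-classical-receptive-field surround suppression,

    s_j = | CF_j − α (CF_j ⊛ ω) |_{≥0},   ω = |DoG|_{≥0} / ‖DoG‖₁,

and the conspicuity maps s_j are fused by iterating
`s ← |s + s⊛DoG − C_inh|_{≥0}` and summing (with K-means clustering of
similar maps when there are many).  Comparison architectures — no
invariant pooling, fully connected, randomly connected — share the
same trained filters, so ablation experiments isolate what invariant
and overcomplete coding contribute.  Everything is organised as
sklearn-style estimators (`fit` learns the filters, `transform` maps
images to saliency maps) with plain functions underneath.

## Worked example

```python
import numpy as np
from v1sal import SaliencyModel, gen_orientation_array, detect_target

model = SaliencyModel(seed=1)        # 49 filters, 16x16 px, 7x7 torus
model.fit(None)                      # trains on built-in oriented textures

scene = gen_orientation_array(noise_halfwidth=30.0, seed=7)
smap = model.saliency(scene.image)

res = detect_target(smap, scene, tolerance=model.detect_tolerance)
ty, tx = np.argwhere(scene.target_mask).mean(axis=0).astype(int)
print("target bar at ", (ty, tx))
print("saliency argmax", res.argmax_location, "hit:", res.hit)
```

```
target bar at  (np.int64(241), np.int64(118))
saliency argmax (238, 118) hit: True
```

The scene is a 10×10 array of bars; every distractor is orthogonal to
the target ±30° of uniform orientation noise, yet the argmax of the
combined saliency map lands on the target bar — the pop-out that the
invariant pooling is responsible for (set `variant="no_invariance"`
or `"fully_connected"` on the model to watch it degrade).

The same model drives the experiment protocols:

```bash
v1sal train --n-filters 49 --seed 1 --out basis.npz
v1sal gen orientation --noise 30 --seed 7 --out scene
v1sal saliency scene.png --basis basis.npz --out smap
v1sal experiment popout_sweep --basis basis.npz --seed 1 --out results/
```

`experiment` writes per-condition CSV/JSON (and a rate-curve PNG) for
`popout_sweep`, `contour_suite`, `snr_curve` and `combine_compare`.

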