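# facetfit

Reconstruction and tracking of 3D polyhedral crystal shapes from
single-view transmission-microscopy keypoints.

Faceted crystals grown in a temperature-controlled cell are imaged from a
single overhead camera.  Because the crystal is transparent, its *back*
edges are visible through the *front* faces — displaced by refraction —
and the junctions where projected edges meet form distinctive 2D
*keypoints*.  `facetfit` turns those keypoints back into 3D shape: it
models a crystal habit as `m` bounding lattice planes at center-to-plane
distances `D = {d_i}` with pose `(P, R)` and refractive index `eta`,
projects the posed polyhedron to a refraction-aware 2D wireframe, and
recovers the `m + 6` shape-and-pose parameters by gradient descent on

```
L_ref = w_K sinkhorn(K, K_obs) + w_z (min_z V)^2 + w_R (R_x^2 + R_y^2)
        + w_o mean_i max(0, d_i - dbar_i)^2
```

where `sinkhorn` is an entropic optimal-transport divergence between the
projected and observed keypoint sets, the `z` term keeps the crystal on
the glass, the rotation term encodes that sedimented crystals lie nearly
flat, and the overgrowth term holds vanished faces at their threshold of
appearance.  A growth *sequence* is fitted by a small feed-forward network
mapping normalized time to the face distances, trained through the same
projection losses with an adaptive frame sampler and a penalty on negative
face growth.  Everything runs on NumPy/SciPy; gradients come from a
frozen-combinatorics finite-difference path combined with exact envelope
gradients of the transport term.

The package is aimed at crystallization researchers who want facet-level
growth kinetics (per-face distances, areas, volume over time) from
inexpensive single-view microscopy, and ships an alpha-form L-glutamic
acid (alpha-LGA) habit plus cubic and octahedral test habits.

## Worked example

```python
import numpy as np
from facetfit.io import load_bundled_habit, load_prior, bundled_habit_path
from facetfit.projector import ImageGeometry, project_wireframe
from facetfit.habit import build_polyhedron, canonicalize, config_metrics
from facetfit.fitloss import LossWeights
from facetfit.refine import (OptimizerSettings, PerturbationSpec,
                             perturb_config, refine_frame, _snap_to_substrate)
from facetfit.sampler import sample_configuration

habit = load_bundled_habit("alpha_lga")
prior = load_prior(bundled_habit_path("alpha_lga"))
geom = ImageGeometry(width=400, height=400, scale=100.0)  # px, px/mm
rng = np.random.default_rng(0)

truth = _snap_to_substrate(sample_configuration(habit, prior, geom, rng))
K_obs = project_wireframe(build_polyhedron(habit, truth),
                          truth.refractive_index, geom).keypoints

# initialization with 5% distance noise, as a one-shot predictor would give
init = perturb_config(truth, PerturbationSpec(distance_sigma=0.05), rng)
fit = refine_frame(init, K_obs, LossWeights(),
                   OptimizerSettings(iterations=300), geom)

m0 = config_metrics(canonicalize(_snap_to_substrate(init)), canonicalize(truth))
m1 = config_metrics(fit.final, canonicalize(truth))
print(f"E_d: {m0.E_d:.4f} -> {m1.E_d:.4f} mm")
print(f"E_v: {m0.E_v:.4f} -> {m1.E_v:.4f} mm")
```

prints (seed 0)

```
E_d: 0.0147 -> 0.0003 mm
E_v: 0.0512 -> 0.0021 mm
```

i.e. the mean center-to-plane distance error drops from 15 um to 0.3 um
and the bidirectional nearest-neighbor vertex error from 51 um to 2 um
after 300 refinement iterations against the crystal's own projected
keypoints — the refinement recovers the generating shape almost exactly.

The same machinery is available from the shell:

```
facetfit simulate --habit src/facetfit/data/alpha_lga.yaml --out runs/sim --seed 1
facetfit fit-frame --habit ... --keypoints kp.csv --init init.json --out fit.json
facetfit fit-sequence --habit ... --obs-dir runs/sim --init-dir runs/sim/truth --out runs/fit
facetfit perturb-study --habit ... --config ref.json --rotation-deg 10 --out study.csv
facetfit metrics --habit ... --pred fit.json --target manual.json
```

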