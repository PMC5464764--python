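# rootshape

Three-dimensional statistical shape analysis of maxillary incisor roots.

Root morphology — how long, wide, tapered, blunted or bent an incisor root
is — matters clinically because it modulates the risk of external apical
root resorption during orthodontic treatment. `rootshape` turns a cohort of
segmented single-tooth surfaces (from CBCT label maps or meshes) into a
quantitative morphometric analysis:

1. **Correspondence** — each watertight genus-0 tooth surface is mapped to
   the unit sphere (harmonic latitude/longitude with area equalization),
   expanded in real spherical harmonics (SPHARM, degree *L* = 12 by
   default), canonicalized by its first-order ellipsoid and anatomical
   axes, and resampled at the vertices of a subdivided icosahedron. At
   level 10 this yields **1002 homologous surface points** per tooth:
   point *k* denotes the same anatomical location on every tooth.
2. **Alignment** — rigid (6-DOF, never scaled) superimposition of the
   cohort: generalized Procrustes initialization, then robust
   closest-point refinement against the cohort's median shape.
3. **Averaging and signed distances** — pointwise mean shape
   x̄ₖ = (1/n) Σᵢ xᵢₖ and per-tooth signed surface distances
   sₖ = ‖dₖ‖·sign(dₖ·n̂ₖ), negative where the individual lies inside the
   reference (blue), positive outside (red), with standardized color
   scales (±1.5 mm central, ±3 mm lateral incisors).
4. **Classification** — regional summaries of the root (apical length
   change, cervical width change, mid/apical circumference change, lateral
   apex deviation from the root's own axis) drive a deterministic decision
   tree into the subgroups *neutral, blunt, long, conical, short* and
   *mesial / distal / lingual dilaceration*.
5. **Statistics** — at each of the 1002 points, subgroups are compared to
   the neutral group with the two-sample Hotelling T²

   T² = (n₁n₂/(n₁+n₂)) (x̄₁−x̄₂)ᵀ S⁻¹ (x̄₁−x̄₂),

   significance assessed by permuting whole-tooth group labels
   (exhaustively when feasible), and the 1002 raw p-values corrected with
   Benjamini–Hochberg FDR at q = 0.05.

Because clinical CBCT cohorts cannot be redistributed, the package ships a
first-class synthetic generator (`rootshape.synthetic`) producing
watertight incisor surfaces with controllable subgroup deformations,
inter-subject anatomical variation and segmentation-like noise, plus
"second-rater" perturbations for reproducibility studies. Every stage of
the pipeline is exercised end-to-end on these cohorts.

## Worked example

```python
import numpy as np
from rootshape import (CohortSpec, PipelineConfig, generate_cohort, run_pipeline)

teeth = []  # exchangeable cohorts: surface noise only, no anatomical jitter
for mesh, label, _ in generate_cohort(CohortSpec("neutral", n=10, seed=1, anatomical_scale=0.0)):
    teeth.append((f"neutral_{len(teeth)}", mesh))
for mesh, label, _ in generate_cohort(CohortSpec("long", n=8, seed=2, anatomical_scale=0.0)):
    teeth.append((f"long_{len(teeth)}", mesh))

result = run_pipeline(PipelineConfig(seed=1, n_permutations=2000), teeth, "results/")
print(result["distribution"])
res = result["stats"]["long"]
print(int(res.mask.sum()), "points significant after FDR")
```

prints (seed 1):

```
            subgroup  n  percent
             neutral 10     55.6
               blunt  0      0.0
                long  8     44.4
             conical  0      0.0
               short  0      0.0
 mesial_dilaceration  0      0.0
 distal_dilaceration  0      0.0
lingual_dilaceration  0      0.0
1002 points significant after FDR
```

All 18 teeth are classified into their generating subgroup. With surface
noise as the only within-group variation, every one of the 1002 points
separates the groups after FDR (the homologous sampling itself shifts
slightly when the root grows); with realistic inter-subject anatomy
(`anatomical_scale=1`, the default) the significant region shrinks to the
root, where the long phenotype actually differs — `rootshape demo` shows
that case. The run writes signed-distance overlays
(`overlays/*.vtp`, channels `signed_distance` and `rgb`), per-point
statistics tables and a run log under `results/`.

The same stages are available from the shell:

```bash
rootshape simulate --subgroup long --n 8 --seed 2 --out sim/
rootshape correspond sim/long_000.ply long_000.pdm --level 10 --degree 12
rootshape run sim/*.ply --out results/
rootshape demo --seed 1
```

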