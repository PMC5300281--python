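# hippomesh

Mesh-based comparison of 3D segmentations of small brain structures.

When two segmentations of the same structure — say the hippocampus from a
pair of back-to-back MRI scans, outlined manually or by FSL-FIRST or
FreeSurfer — are compared voxelwise, every resampling step injects
interpolation error that is large relative to a structure only a few
centimetres across. `hippomesh` avoids that by moving the comparison to
surfaces: label volumes are converted once to watertight triangulated
meshes in native world coordinates (marching cubes at iso-level 0.5), rigid
registration matrices are applied to mesh vertices exactly, and all
volumes and overlaps are measured by counting the points of a fine regular
grid that fall inside each surface.

The toolkit computes:

* **Global overlap** — the Jaccard index of a surface pair (A, B),
  `Jacc(A, B) = |A ∩ B| / |A ∪ B| ≈ N(A ∩ B) / N(A ∪ B)`, where `N(V)` is
  the number of shared-grid points inside surface `V`.
* **Regional overlap and volumes** — the same quantities with both
  surfaces constrained to a region of interest,
  `Jacc_ROI = N((A ∩ B) ∩ ROI) / N((A ∩ ROI) ∪ (B ∩ ROI))`. A template
  mask is split into anterior (35%), middle (45%) and posterior (20%)
  regions along its long axis (first principal axis of the mask voxels,
  cuts at volume quantiles) and mapped to subject space by an affine.
* **Registration quality control (full-circle method)** — multiplying the
  rigid transforms around a closed cycle of scans gives a residual matrix
  `RM` that would be the identity for perfect registrations. It is
  summarised by `TranslationTotal = ‖trans(RM)‖`,
  `RotationTotal = arccos((trace(R_RM) − 1)/2)`, and
  `Consistency = Jacc(S, RM(S))` for a structure surface `S`;
  `1 − Consistency` is the registration error.
* **Mixed-model analysis** — regional volumes `V` (or Jaccard indices
  transformed to `J = Jacc⁹` to make their errors approximately Gaussian)
  are modelled as `V ~ M + G + H + T + R + interactions + (1|subject)`
  with treatment-coded fixed effects for method, group, hemisphere,
  time-point and region and a random intercept per subject, fitted by
  maximum likelihood. Backward elimination repeatedly drops the least
  significant term (Satterthwaite F tests) while the AIC does not
  increase, and the selected model predicts cell means.

Everything is exercised end-to-end on synthetic phantoms (spheres,
ellipsoids, bent tubes, factorial observation tables) whose ground truth
is known in closed form; no scan data is required.

## Worked example

Two spheres of radius 10 mm whose centres are 10 mm apart overlap in a
lens of volume `π(4r + d)(2r − d)²/12`, giving an exact Jaccard index of
5/27 ≈ 0.18519. The full pipeline — rasterize at 1 mm, extract surfaces,
count on a 0.25 mm grid — reproduces it:

```python
import numpy as np
from hippomesh import (ShapeSpec, make_pair, extract_surface,
                       build_grid, jaccard, RigidTransform)

shape = ShapeSpec(kind="sphere", radii=(10, 10, 10))
va, vb, truth = make_pair(shape, RigidTransform.from_translation((10, 0, 0)),
                          dims=(48, 34, 34), voxel_size=1.0)
a, b = extract_surface(va, 1), extract_surface(vb, 1)
grid = build_grid([a, b], spacing=0.25, margin=2.0)
print(f"Jaccard {jaccard(a, b, grid):.5f}  vs analytic {5/27:.5f}")
```

```
Jaccard 0.18420  vs analytic 0.18519
```

The 0.5% gap is the discretization error of the 1 mm voxelization plus the
0.25 mm counting grid. The same objects drive model selection:

```python
from hippomesh import DesignSpec, simulate_observations, ModelSpec, backward_select
from hippomesh.mixedmodel import parse_terms, VOLUME_FULL_TERMS

design = DesignSpec(n_subjects_per_group=20, sd_subject=0.15, sd_residual=0.1,
                    seed=7, coefficients={"intercept": 1.2,
                                          "M": {"Manual": 0.3, "FreeSurfer": -0.35},
                                          "R": {"Middle": 0.4, "Posterior": -0.3}})
sel = backward_select(simulate_observations(design), ModelSpec(fixed_terms=VOLUME_FULL_TERMS))
print(sel.selected.formula)
```

```
response ~ G + M + T + R + G:M + G:R + M:R + T:R + G:M:R + (1|subject)
```

Only M and R carry true effects here; the draw above keeps several null
terms, a visible instance of AIC's known per-term retention probability
(a null term with q coefficients survives with chance 1 − P(χ²_q ≤ 2q);
see `docs/methods.md` for the quantitative account).

A command-line interface mirrors the library —
`hippomesh phantom | extract | regions | compare | circleqc | fitmodel` —
chaining NIfTI label maps, FLIRT-style 4×4 ASCII transforms, PLY meshes
and CSV tables. Run `hippomesh --help` for the options.

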