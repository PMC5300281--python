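# Methods

## Surfaces from label volumes

A segmentation is an integer label map plus a voxel-index-to-world-mm
affine. The surface of one label is the marching-cubes iso-surface at
level 0.5 of the binary indicator, with trilinear interpolation between
the binary values — the standard convention that places the surface
halfway between a foreground and a background voxel centre and is
symmetric between the two phases. The volume is zero-padded by one voxel
before extraction so the surface always closes, vertices are mapped to
world coordinates through the affine (0-based indices, no axis
reorientation — the affine is trusted as given), and duplicated vertices
are merged. A segmentation with several connected components yields one
multi-component surface; its total enclosed volume is used.

Closure is validated as *even edge incidence*: every edge must border an
even number of triangles. Manifold edges have two; marching cubes on noisy
labels can also emit pinch edges with four, where two sheets touch
diagonally. Those are legitimate closed surfaces for a parity inside test
and for the divergence-theorem volume, so they are accepted; an edge with
odd incidence is a genuine hole and is reported with the offending vertex
pair. Faces are wound so the total signed volume is positive; transforms
with negative determinant flip the winding to keep normals outward.

Mesh volume is the divergence-theorem sum of signed tetrahedra against the
origin, `Σ det(v0, v1, v2)/6`. It is exact for the polyhedron and serves as
the cross-check for the grid-count estimator below.

## Point-in-surface counting

All overlap metrics reduce to counting lattice points inside surfaces. The
sample grid is a regular isotropic lattice covering the union bounding box
of the compared surfaces plus a margin (defaults: 0.5 mm spacing, 2 mm
margin — submillimetre sampling at roughly one tenth of the structures'
diameter; 0.25 mm is used where 1%-level volume accuracy is asserted).
The grid origin is pushed outward by an extra irrational fraction of one
spacing, a different constant per axis (frac(√2)/2, frac(√3)/2,
frac(√5)/2): voxelized meshes have large exactly axis-aligned facets, and
a lattice aligned with them would place entire point layers exactly on
the boundary, visibly biasing counts for sub-voxel-shifted surface pairs.
The offsets must differ between axes — with equal offsets the lattice
coordinates cancel on the 45-degree projected edges marching cubes emits,
leaving edge-function values at rounding noise where the exact-zero
tie-break cannot engage. The offsets are fixed constants, so grids remain
deterministic.

A point is inside iff a ray from it crosses the surface an odd number of
times (parity over all components, so nested components form cavities).
Rays are cast along +x; every point of one (y, z) column shares a line, so
that line's crossings are computed once and the whole column is classified
by binary search. A KD-tree over projected triangle bounding boxes
prefilters the candidate triangles per column. The brute-force path — the
same predicate against every triangle — is retained as the oracle; the
prefilter provably returns a superset of the triangles any column can hit,
so the two paths agree flag-for-flag, which the test suite asserts on
every phantom family.

Degeneracies (a ray exactly through a vertex or edge, a triangle parallel
to the ray) are resolved exactly, not by tolerance: point-in-triangle is
evaluated in the projected (y, z) plane with a lexicographic half-open
rule equivalent to perturbing every query point by (+ε, +ε²) for an
infinitesimal ε. Each edge is evaluated through a canonical edge function
(endpoints ordered lexicographically), so the two triangles flanking an
edge see bit-identical values with opposite signs and make exactly one
claim between them; fold edges make zero or two claims, which is also
parity-correct. Triangles with zero projected area cannot be hit by a
perturbed ray and are skipped. Along the ray the same limit applies:
crossings strictly beyond the point's x count, so a point exactly on a
surface plane is classified as the limit from −x (lower faces closed,
upper faces open — the same half-open convention as voxel-centre
rasterization, chosen over an "on-surface means inside" rule because the
latter double-counts aligned boundary layers and biases volumes).

Convergence behaviour: the half-open count is unbiased, so its error
against 4/3·π·r³ for a sphere phantom rasterized at 0.5 mm is
boundary-layer quantization noise with RMS ≈ h²·√(S/12) for surface area
S — about 1 mm³ (0.03%) at 1.0 and 0.5 mm spacing and ≈0.2 mm³ at
0.25 mm, each well inside its envelope — and the 0.25 mm estimate agrees
with the divergence-theorem mesh volume to well under 1%. Because the
sequence is noise- rather than bias-dominated, convergence checks compare
each refinement against the coarser error or its own noise floor rather
than demanding strict monotonicity of three tiny numbers. The phantom
voxel size
matters for such comparisons: a 1 mm voxelization of a 10 mm sphere is
itself ≈0.4% off the analytic ball, a rasterization bias no grid
refinement can remove, which is why the convergence check rasterizes at
0.5 mm.

## Overlap metrics

For a pair (A, B) on one shared grid, `Jacc = N(A∩B)/N(A∪B)` from the two
boolean occupancy arrays; the regional variant constrains both to an ROI,
`N((A∩B)∩ROI) / N((A∩ROI)∪(B∩ROI))`. A regional Jaccard whose denominator
is zero is *missing* (None), not 0 — a region the structure never enters
carries no reproducibility information, and the mixed model drops missing
cells listwise. All metrics of one comparison share a single grid so the
counts form valid ratios; reported volumes use grid counting, with the
mesh volume carried alongside as a discretization cross-check.

## Long-axis regions

The template mask's long axis is the first principal component of its
voxels' world coordinates (deterministic sign: largest-magnitude component
positive; a warning is issued when the first two eigenvalues are within a
factor 1.2, where "long axis" is ill-defined but still resolved
deterministically). The two cut planes are perpendicular to the axis and
placed at the *volume* quantiles matching the requested fractions
(default 35/45/20), cutting *between* adjacent voxel slabs at the count
closest to each target so a whole slab is never over-swept; realised
fractions are within half a slab (well under 2 percentage points for the
phantoms used). Anterior/posterior orientation is a convention fixed by an
explicit hint vector; an affine carries the regions to subject space, with
the cut planes transformed as planes (inverse-transpose normals).

Grid-point region membership is defined as (inside the whole-template
surface) AND (axis projection vs the cut positions). This makes the three
regions an exact pointwise partition of the template occupancy on any
grid. The alternative — meshing the three masked voxel subsets
independently and testing each mesh — does *not* partition exactly: at the
rim where a cut plane meets the outer surface, the independently
interpolated sub-surfaces pinch and leave thin gap lenses (if two adjacent
regions hold indicator fractions f1 and f2, points with f1+f2 > 0.5 but
max(f1, f2) < 0.5 belong to the whole mask but to neither region).
Sub-mask meshes are still extracted for export and for mesh-ROI
operations, where exact additivity is not claimed.

## Full-circle registration QC

Rigid transforms are validated 4×4 homogeneous matrices (orthonormal
rotation block, det +1, within 1e-6). Composing a closed cycle of
registrations gives the residual RM; its summaries are the translation
norm and the rotation angle from the trace of the rotation block,
arccos((trace−1)/2), evaluated as atan2(‖skew(R)‖, (trace−1)/2) because
plain arccos next to 1 amplifies rounding to a ~1e-6-degree floor while
the atan2 form resolves the ~1e-16 residuals of exactly consistent chains.
The Jaccard between a surface and its RM-image gives the consistency
index; 1 − consistency is the registration error. Two caveats are
inherent to the definition: rotations about a symmetry axis of the chosen
surface are invisible (a perfect sphere scores 1 under any central
rotation — use an elongated structure), and at fixed grid spacing the
error for sub-voxel perturbations includes a quantization component, which
the de-aligned grid origin keeps small. On the bent-tube phantom,
1 − consistency grows strictly monotonically for perturbations from
0.1 to 5 mm. The four standard circles of a BL/M12 back-to-back session
are provided as a preset; arbitrary chains compose, and a stored transform
is inverted automatically when only the opposite direction is on file.

## Phantoms

Three analytic shapes with closed-form volumes: spheres, axis-aligned
ellipsoids, and a bent tube — a sphere of radius r swept along a circular
arc (volume πr²·Rφ + 4/3·πr³ by Pappus), an asymmetric elongated stand-in
for a hippocampus with a well-defined long axis. Rasterization labels a
voxel iff its centre lies strictly inside the shape (binary labels, as
segmentation tools emit; no partial volume). Back-to-back pairs rasterize
the same shape after a known rigid transform on the same grid, then flip
boundary voxels (those with an opposite-valued 6-neighbour) independently
at a chosen rate — outline variability concentrated at the boundary, not
salt-and-pepper noise. What the phantoms do not emulate: MRI intensities,
bias fields, anisotropic voxels, partial-volume effects, or anatomically
realistic shape variation; passing tests demonstrate the correctness of
the measurement machinery, not segmentation quality on real scans.

Observation tables are drawn from the mixed model itself: a full factorial
of group (4 levels) × method (3) × hemisphere (2) × time-point (2) ×
region (3) with chosen cell-offset coefficients, a N(0, σ_s²) intercept
per subject and N(0, σ_e²) residuals, reproducible under a seed.
Simulation conditions used in the recovery studies: 20 subjects per group
(80 total, the study size this design models), σ_e = 0.1 on a ~1.2
response scale, σ_s = 0.15, and true effects of at least 3σ_e.

## Mixed models and backward elimination

Whole-structure and regional Jaccard responses are transformed to J⁹
before modelling (a fixed exponent; strictly monotone on [0, 1], so method
rankings are preserved when distributions do not cross). Models are
Gaussian LMMs with treatment-coded fixed effects (alphabetically first
level as reference, so predicted-cell tables reconstruct by adding single
fitted offsets) and a subject random intercept, estimated by maximum
likelihood — not REML, because AIC comparisons across different
fixed-effect structures are only valid under ML.

With a single variance ratio θ = σ_s²/σ_e², the likelihood is profiled:
for fixed θ each subject's rows are whitened by shrinking their subject
mean (factor 1 − 1/√(1+n_iθ)), β and σ_e² drop out in closed form, and a
bounded 1-D search over log θ (plus the θ = 0 boundary) gives the MLE
deterministically. This profile fit agrees with statsmodels MixedLM (ML)
to ~1e-14 in coefficients and ~1e-6 in log-likelihood on test tables, runs
two orders of magnitude faster on the balanced designs used here, and is
exact at the σ → 0 boundary, where noiseless-recovery checks require
coefficients to 1e-8. AIC counts k = p + 2 parameters (fixed effects plus
two variances).

Per-term significance uses marginal F tests on the term's coefficient
block with Satterthwaite denominator degrees of freedom: the asymptotic
covariance of (σ_s², σ_e²) comes from the finite-difference Hessian of the
profile deviance, each contrast's df from the delta method, and multi-df
terms combine eigencontrast dfs as in the lmerTest algorithm. On a
deterministic fixture the whole table (F, dfs, p, log-likelihood, AIC,
variance components) matches R's lmerTest (ML fit) to the printed
precision. If the variance Hessian is not positive definite (variance on
the boundary), likelihood-ratio p-values are substituted and the method is
recorded per fit in the selection trace.

Backward elimination: among droppable terms not contained in any retained
interaction, refit without the one with the highest p-value (ties: higher
order first, then alphabetically); keep the drop if AIC does not increase,
else stop. The trace records every attempted drop with p-value, df method
and AIC before/after. Selection is invariant to row order, and with large
effects the true structure is never touched.

A quantitative caveat on *exact* recovery rates: a null term with q
coefficients survives elimination when its likelihood-ratio statistic
exceeds 2q, which for central χ²_q has probability 1 − P(χ²_q ≤ 2q) — about
0.14 for q = 2 down to 0.02 for q = 12. Eliminating from the 13-term full
volume model with 6 null terms therefore yields the exactly-true model in
about Π P(χ²_q ≤ 2q) ≈ 57% of replicates, and an all-null simulation ends
with every droppable term removed in only ≈23% — the empirical rates from
`scripts/acceptance.py` (0.56 and 0.16 at seed 1) match. This is a
property of AIC-driven selection itself (its fixed penalty of 2 per
parameter trades overfitting for power), not of the implementation;
per-term retention behaves exactly as theory predicts.

## Numerical choices and degenerate inputs

* Rigid validation tolerance 1e-6 on orthonormality and determinant;
  FLIRT-style files are world-mm matrices (no scaled-voxel
  reinterpretation), and the last row must be (0, 0, 0, 1) within 1e-6.
* Label values within 1e-6 of integers are rounded on NIfTI input;
  anything else is rejected.
* Zero-noise tables drive the profile fit to a zero residual variance;
  coefficients remain exact (GLS at the boundary) and the reported
  log-likelihood is floored rather than infinite.
* Masks with fewer than 10 voxels have no defined long axis and are
  rejected; near-isotropic masks are split deterministically with a
  warning.
* An empty union in a Jaccard (both surfaces miss every grid point) is an
  error for the global index and missing for the regional one.
* All randomness (phantom noise, observation tables, QC point sampling)
  flows through explicit integer seeds; repeated runs are bit-identical,
  and the CLI stamps outputs with version, config hash and seed.

## Known limitations

* Grid metrics carry O(spacing) discretization error concentrated at the
  surface; the defaults keep it under ~1% for centimetre-scale structures,
  but thin or highly curved structures need finer spacing.
* The inside test's exactness guarantees hold for closed (even-incidence)
  meshes; self-intersecting surfaces are not detected and their parity
  follows the even-odd rule, which may not match intuition there.
* The regional split is a geometric convention (PCA axis + volume
  quantiles), not an anatomical parcellation.
* The mixed model supports a single random intercept per subject; random
  slopes or crossed random effects are out of scope.
* Consistency is blind to motions that map the chosen surface onto itself;
  pick an asymmetric structure surface.
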