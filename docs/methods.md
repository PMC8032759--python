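# Methods

## Model

The tissue is a homogeneous, modestly compressible neo-Hookean solid.  With
deformation gradient F and J = det F, the strain energy density is the
isochoric/volumetric split

    W = (μ/2) (J^{-2/3} tr(F Fᵀ) − 3) + (K/2)(J − 1)²,

with shear modulus μ and bulk modulus K = 5 μ by default.  All mechanics run
in normalized units (μ = ρ = 1, coordinates scaled so the longest geometry
axis spans [−1, 1]); only the ratios K/μ and the growth parameters matter.

Growth is multiplicative and tangential.  Each tetrahedron carries a fixed
material surface normal n̂ (the outward normal of its nearest boundary
triangle in the undeformed configuration) and a material depth y (mean of
its four vertex distances to the boundary surface).  The growth tensor

    G = g I + (1 − g) n̂ ⊗ n̂,   g = 1 + α_t / (1 + e^{10 (y/H_i − 1)}),

expands the stress-free reference tangentially by g (eigenvalues g, g, 1;
det G = g²), decaying from the surface value 1 + α_t to 1 over the initial
cortical thickness H_i.  The element deformation gradient relative to the
grown reference is F = A (G Â)⁻¹, with A and Â the deformed and material
edge matrices, and the element's reference volume is det(G) · V_material.
Elastic nodal forces are the exact negative gradient of the total energy
(verified against finite differences to < 10⁻⁴ relative in the tests).
Both n̂ and y are material-frame quantities fixed at initialization; an
option to co-rotate n̂ exists but is off by default.

Growth laws α_t on model time t ∈ [0, 1] (t = 0 ≈ 22 gestational weeks via
a fixed cubic in gestational age, t = 1 ≈ adult):

* linear: α_t = (√8 − 1) t ≈ 1.829 t, so the surface areal growth factor at
  t = 1 is g² ≈ 8;
* Gompertz: α_t = a·exp(−exp(−b(t − c))), defaults (b, c) = (6.6, 0.43) and
  (7.5, 0.19);
* logistic: α_t = a / (1 + exp(−b(t − c))), default (50, 0.9) — no growth
  for most of the simulation, then a burst near t = 0.9.

All share a = √8 − 1.  The printed Gompertz parameters give α(1) ≈ 1.787
and, for (7.5, 0.19), α(0) ≈ 0.029; they are used unmodified.

## Coordinate normalization and the thickness convention

Geometries are defined in millimetres and normalized by 2/L (L = full
longitudinal length) so coordinates span [−1, 1].  Two conventions exist
for the thickness parameter fed to the growth sigmoid:

* ``longitudinal``: H_i = H_mm / L.  A 0.83 mm cortex on the 20 mm
  reference ellipsoid maps to 0.042.  Because y is measured in coordinate
  units (scale 2/L), this convention makes the effective growing layer half
  the nominal physical thickness.
* ``coordinate``: H_i = 2 H_mm / L, i.e. the thickness measured in the same
  units as y.  Dimensionally consonant; the effective layer matches the
  nominal thickness.

Both are exposed on `NormalizationRecord.thickness_parameter`.  The
simulation protocols in `experiments` and the trend tests use the
``coordinate`` convention: at desk-scale mesh densities the halved
effective layer of the ``longitudinal`` convention pushes every thickness
in the study set below one element layer, suppressing the buckling the
model exists to capture.  The ``longitudinal`` convention remains available
and is the one that reproduces the printed normalized thickness 0.042.

## Numerical scheme

* **Integration.** Damped symplectic Euler with the stability step
  dt = dt_factor · a · √(ρ/K), a = mean tetrahedron edge length
  (dt_factor default 0.05).  Mass-proportional viscous damping γ (default
  20 in normalized 1/time units) keeps the dynamics quasi-static; the
  kinetic-to-elastic energy ratio stays below 10⁻² away from buckling
  events.  A per-step displacement cap of 0.1 a per node is a guardrail
  against transiently stiff configurations.
* **Selective mass scaling.** The global dt is sized by the *mean* spacing;
  thin elements (a few slivers initially, any strongly compressed element
  during folding) carry higher eigenfrequencies.  Their nodes receive extra
  lumped mass so every element fits the global step — the standard explicit
  quasi-static remedy; re-evaluated on the deformed configuration every
  `contact_rebuild` steps.  Added mass is negligible globally and
  irrelevant at equilibrium.
* **Transient inversion handling.** Deep post-buckling contact can
  transiently invert single elements.  The stepper evaluates the singular
  J^{-2/3} and 1/J stress factors at max(J, 0.05), writing the volumetric
  term with the cofactor (polynomial in F), so forces stay finite and
  restoring; the strict force evaluator used by the oracle tests raises on
  det F ≤ 0 instead.  Rescued-element counts are reported per step.
* **Contact.** Vertex–triangle penalty between boundary vertices and
  non-adjacent boundary triangles: force = stiffness × (threshold −
  separation) along the face normal, equal and opposite on the triangle via
  barycentric weights.  Threshold defaults to a/2, stiffness to K.
  Candidate pairs come from a KD-tree with per-face radii, rebuilt every 10
  steps; pairs sharing a vertex or closer than 2.5 × threshold in the
  *material* frame are excluded (intrinsic neighbours, not collisions).
* **Settling.** `settle_time` continues the damped dynamics after t = 1
  with growth frozen at its final value.  The model's quasi-static reading
  of "the state at t = 1" is the equilibrium under final growth; at desk
  densities the late-burst logistic law (and thick-cortex runs) have not
  finished relaxing at t = 1, so final-state comparisons are made after a
  settle phase.

## Synthetic geometry generator

Interior vertices form a body-centered cubic lattice (pitch set from the
target density in tets/cm³) with a deterministic 0.15·pitch jitter — the
symmetry-breaking perturbation buckling needs; surface vertices come from a
subdivided icosahedron mapped onto the exact ellipsoid; connectivity is the
Delaunay tetrahedralization of the combined points.  Flat hull caps are
dropped, interface slivers are relieved by guarded interior Laplacian
smoothing.  Realized density tracks the request within ~25 %, summed
volume is within 5 % of the analytic ellipsoid volume at 10³ tets/cm³ and
within 0.5 % at 10⁵.  What this generator does *not* emulate: the graded
(boundary-refined) element sizes of a production mesher, and any real
cortical geometry — results transfer to ellipsoids, not to brain-shaped
domains.

## Morphometry

* **Curvature** uses the Rusinkiewicz estimator: per-face second-fundamental
  tensors fit from edge directions and vertex-normal differences, rotated
  into per-vertex tangent frames, accumulated with mixed-Voronoi corner
  weights; positive principal curvatures on convex surfaces with outward
  normals.  The dimensionless statistic is mean |mean curvature| × √(area)
  (2√π ≈ 3.545 for any sphere).
* **GI** divides folded area by the area of the *scaled initial smooth
  surface* whose axis-aligned bounding box matches the folded surface's —
  not a computational convex hull (a true-hull mode exists for imported
  meshes).  Exact invariances are translation, global scaling and axis
  permutation; the study geometries are axis-aligned by construction.
* **Sulcal depth** casts, for each vertex, the ray from its initial
  position through its deformed position and takes the first hull
  intersection (watertight Möller–Trumbore over all hull triangles);
  misses and degenerate rays fall back to nearest-point distance and are
  flagged.  On strongly folded coarse meshes tangential displacement makes
  some rays oblique, inflating the upper depth quantiles; distribution
  medians are the robust summary.
* **Fold orientation**: cotangent Laplace–Beltrami with lumped mixed-
  Voronoi masses; the Fiedler vector is the eigenvector of the smallest
  nonzero eigenvalue (fixed starting vector, sign pinned at the max-x
  vertex; near-degenerate λ₁ — the sphere — is flagged but still used).
  Per-vertex fold angles are arccos |⟨ĝ, d̂⟩| ∈ [0°, 90°] between the
  tangent-projected Fiedler gradient and the principal direction of larger
  |K|; vertices with vanishing gradient or near-isotropic curvature
  (within 5 %) are excluded.  Angles are histogrammed in 18 × 5° bins with
  ε = 10⁻¹² regularization, and anisotropy is the KL divergence to the
  uniform distribution in nats (point mass → ln 18 ≈ 2.89).

## Desk-scale experiment protocols

The convergence-grade protocol (10⁶ tets/cm³, `experiments.full_protocol`)
reproduces the study's operating point and costs hours per run; it is kept
behind an explicit flag.  The test suite runs scaled-down protocols chosen
to fit a desktop budget while preserving the phenomena:

* **Growth-law comparison** — reference ellipsoid at 10⁴ tets/cm³,
  H = 0.83 mm, dt_factor 0.005, γ = 20, settle 0.9.  The late-logistic law
  only develops folds during settling at this scale; after settling the
  four final GIs agree closely.
* **Thickness sweep** — 8×10⁴ tets/cm³, dt_factor 0.025, γ = 20,
  settle 0.4, comparing H = 0.43 vs 1.63 mm.  Below ~5×10⁴ tets/cm³ the
  0.43 mm layer is under one element thick and its folds are
  amplitude-limited, reversing the thin-folds-more ordering; at 8×10⁴ the
  ordering is resolved.
* **Elongation family** — sphere-like (19, 18, 18 mm axes), 1.53
  (23, 18, 15) and 2.25 (27, 18, 12) at 5×10⁴ tets/cm³, dt_factor 0.05,
  γ = 30, no settle: fold-angle KL at t ≈ 0.32 grows with elongation and
  decays by t ≈ 0.55 for the slender geometry, and the sulcal-depth
  distribution at t ≈ 0.55 — once the primary sulci have formed, before
  the ray-cast statistic is dominated by overall crumple depth — is deeper
  for the elongated geometry than for the sphere.

Passing these trend tests shows the implementation reproduces the model's
qualitative parameter dependences at reduced resolution; it does not
certify the full-density quantitative values (e.g. the converged curvature
statistic ≈ 61), which require the flagged full protocol.

## Known limitations

* Explicit quasi-static relaxation at coarse densities develops folds more
  slowly than at study densities, which is why settling is part of the
  final-state protocols.
* The penalty contact prevents gross interpenetration but allows
  penetration up to the threshold; sulcal walls in deep folds can touch.
* Uniform mesh density everywhere; no boundary grading or adaptivity.
* Single homogeneous material; no regional growth maps, no bi-hemispheric
  geometry.
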