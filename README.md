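# corticofold

Biomechanical simulation of cortical folding on ellipsoidal geometries, with
the surface morphometry needed to quantify the resulting folding patterns.

During fetal development the cerebral cortex expands tangentially faster
than the underlying white matter.  The resulting compressive stress buckles
the surface into gyri and sulci.  `corticofold` implements this
*differential tangential growth* model as a finite-element simulation and
asks how the folding pattern depends on three biophysical inputs: the
temporal growth law, the initial cortical thickness, and the elongation of
the initial geometry.

## Model

The tissue is a modestly compressible neo-Hookean solid (bulk modulus
K = 5 μ) discretized into tetrahedra.  Growth enters through a per-element
tangential growth tensor

    G = g I + (1 − g) n̂ ⊗ n̂,        g = 1 + α_t / (1 + e^{10(y/H_i − 1)}),

where n̂ is the element's material surface normal, y its material depth
below the surface, H_i the initial cortical thickness, and α_t the
cumulative tangential expansion at model time t ∈ [0, 1] (t = 0 ≈ 22
gestational weeks, t = 1 ≈ adult).  The element deformation gradient is
F = A (G Â)⁻¹: elasticity penalizes the mismatch between the deformed
element and its tangentially *grown* stress-free reference, so a thin
fast-growing surface layer on a slow substrate buckles.  Four growth laws
are provided — linear α_t = (√8 − 1) t ≈ 1.829 t (surface areal growth
g² ≈ 8 at t = 1), two Gompertz laws, and a late logistic law, all sharing
the asymptote √8 − 1.  A damped explicit solver integrates the quasi-static
dynamics with the stability step dt = 0.05 a √(ρ/K), with vertex–triangle
penalty contact preventing surface self-penetration.

Folding patterns are quantified by:

* **Dimensionless curvature** — the mean over vertices of |mean curvature|
  × √(surface area), from a Rusinkiewicz per-vertex curvature tensor.
* **3D gyrification index (GI)** — folded surface area over the area of its
  smooth enclosing reference (the initial surface rescaled per axis).
* **Sulcal depth** — ray-cast distance from the folded surface to that
  reference.
* **Fold-orientation anisotropy** — angles between the Laplace–Beltrami
  Fiedler-vector gradient (the elongation axis) and the principal curvature
  direction, histogrammed and scored with a KL divergence against uniform.

All geometries are synthetic ellipsoids meshed in-package at a controllable
density (tetrahedra/cm³); Netgen neutral meshes can be imported, and VTK /
STL snapshots exported.

## Worked example

```python
import corticofold as cf
from corticofold import curvature as cv, simulate as sim

mesh = cf.build_ellipsoid_tetmesh(cf.EllipsoidSpec.reference(), 1e4, seed=0)
print(f"{mesh.n_tets} tets at {cf.mesh_density(mesh):.0f} tets/cm^3")

config = sim.SimConfig(thickness_mm=0.83, damping=20.0, dt_factor=0.01,
                       settle_time=0.4, thickness_convention="coordinate")
traj = sim.run(mesh, config)

final = traj.surface(len(traj.snapshots) - 1)
hull = cv.convex_hull_reference(traj.initial_surface(), final)
print(f"GI = {cv.gyrification_index(final, hull):.2f}")
print(f"curvature statistic = {cv.dimensionless_curvature_stat(final):.1f}")
```

Output (one CPU, ~40 s):

```
26001 tets at 9876 tets/cm^3
GI = 1.52
curvature statistic = 21.1
```

The 20 mm ellipsoid (semi-axes 10, 9, 7 mm) with a 0.83 mm cortex folds
from a smooth surface (GI = 1, curvature statistic ≈ 3.6, the smooth-
ellipsoid value; a sphere gives exactly 2√π ≈ 3.54) to a convoluted one:
GI = 1.52 means the folded surface carries 52 % more area than its smooth
envelope.  At this demonstration density the folds are coarse; the sweep
densities in `corticofold.experiments` resolve them further.

A command line mirrors the library:

```bash
corticofold simulate --config run.yaml --outdir out/   # STL snapshots + manifest
corticofold sweep    --config sweep.yaml --out sweep.csv
corticofold compare  --config run.yaml --out corr.csv  # growth-law correlations
corticofold measure  --deformed d.mesh --initial i.mesh --out metrics.json
```

`corticofold sweep --full` selects the convergence-grade protocol
(10⁶ tets/cm³, all growth laws and thicknesses); expect hours per run.

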