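"""Experiment orchestration: growth-law comparison, thickness and elongation
sweeps, mesh-density study, with GI-matched checkpointing.

Each experiment simulates ellipsoid geometries under the growth FEM and
tabulates the folding descriptors (3D GI, dimensionless curvature statistic,
sulcal-depth quantiles, fold-orientation KL divergence) per snapshot into a
tidy table.  Sweeps persist partial results per combination so interrupted
runs resume, and are deterministic given their seed.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import curvature as cv
from . import orientation as ori
from .growth import DEFAULT_LAWS, GrowthLaw
from .meshing import (DEFAULT_X_LENGTHS, DEFAULT_Y_LENGTH, DEFAULT_Z_LENGTHS,
                      EllipsoidSpec, TetMesh, build_ellipsoid_tetmesh)
from .simulate import Material, SimConfig, Trajectory, run

__all__ = [
    "SweepSpec",
    "GINotReachedError",
    "simulate_geometry",
    "snapshot_gi",
    "snapshot_metrics",
    "trajectory_table",
    "checkpoint_at_gi",
    "run_sweep",
    "growth_model_comparison",
    "full_protocol",
]

# Snapshot times and GI checkpoints used for cross-model comparisons.
DEFAULT_SNAPSHOT_TIMES = (0.27, 0.32, 0.55, 0.77, 0.79, 1.0)
DEFAULT_GI_TARGETS = (1.0, 1.4, 2.3, 2.8)
DEFAULT_THICKNESSES_MM = (0.03, 0.43, 0.63, 0.83, 1.03, 1.23, 1.63)
# Desk-scale default mesh density (tets/cm^3); the convergence-grade density
# of 1e6 sits behind full_protocol().
DEFAULT_DENSITY = 5e4
FULL_DENSITY = 1e6


class GINotReachedError(RuntimeError):
    def __init__(self, target: float, max_gi: float):
        super().__init__(
            f"GI target {target} never reached (max attained {max_gi:.3f})"
        )
        self.target = target
        self.max_gi = max_gi


@dataclass
class SweepSpec:
    """Cartesian sweep over growth laws, thicknesses, geometries, densities.

    ``geometries`` maps elongation ratio to an EllipsoidSpec (``None`` keys
    the reference ellipsoid under its own label).  ``desk_scale`` marks
    whether this is the desk-sized protocol; the full-density protocol
    carries desk_scale=False and is constructed by ``full_protocol()``.
    """

    growth_laws: tuple = (GrowthLaw.linear(),)
    thicknesses_mm: tuple = (0.83,)
    geometries: dict = field(default_factory=lambda: {"reference": EllipsoidSpec.reference()})
    densities: tuple = (DEFAULT_DENSITY,)
    snapshot_times: tuple = DEFAULT_SNAPSHOT_TIMES
    gi_targets: tuple = DEFAULT_GI_TARGETS
    seed: int = 0
    desk_scale: bool = True
    # protocol default: thickness measured in coordinate units (see
    # docs/methods.md, "Coordinate normalization and the thickness
    # convention")
    sim_overrides: dict = field(
        default_factory=lambda: {"thickness_convention": "coordinate"})

    def combinations(self):
        for law, h, (geom_label, spec), density in itertools.product(
            self.growth_laws, self.thicknesses_mm,
            sorted(self.geometries.items(), key=lambda kv: str(kv[0])),
            self.densities,
        ):
            yield law, h, geom_label, spec, density


def elongation_geometries(
    y_length_mm: float = DEFAULT_Y_LENGTH,
    x_lengths_mm=DEFAULT_X_LENGTHS,
    z_lengths_mm=DEFAULT_Z_LENGTHS,
) -> dict:
    """Elongation-family geometries keyed by their true elongation ratio."""
    out = {}
    for lx, lz in zip(x_lengths_mm, z_lengths_mm):
        out[round(lx / lz, 4)] = EllipsoidSpec(lx / 2, y_length_mm / 2, lz / 2)
    return out


def simulate_geometry(
    spec: EllipsoidSpec | TetMesh,
    thickness_mm: float = 0.83,
    law: GrowthLaw | None = None,
    density: float = DEFAULT_DENSITY,
    seed: int = 0,
    material: Material | None = None,
    **config_overrides,
) -> Trajectory:
    """Mesh a geometry (if needed) and run one growth simulation."""
    law = law or GrowthLaw.linear()
    mesh = (spec if isinstance(spec, TetMesh)
            else build_ellipsoid_tetmesh(spec, density, seed=seed))
    config = SimConfig(growth_law=law, thickness_mm=thickness_mm, seed=seed,
                       **config_overrides)
    return run(mesh, config, material)


def snapshot_gi(traj: Trajectory, i: int) -> float:
    """3D GI of snapshot ``i`` against its bbox-matched smooth hull (cached)."""
    snap = traj.snapshots[i]
    if "gi" not in snap.metrics:
        surf = traj.surface(i)
        hull = cv.convex_hull_reference(traj.initial_surface(), surf)
        snap.metrics["gi"] = cv.gyrification_index(surf, hull)
    return snap.metrics["gi"]


def snapshot_metrics(traj: Trajectory, i: int, full: bool = True) -> dict:
    """Folding descriptors of snapshot ``i``.

    Always: t, GI, dimensionless curvature statistic, energies.  With
    ``full``: sulcal-depth quantiles and the fold-orientation KL divergence
    (the expensive ray-cast and eigensolve).
    """
    snap = traj.snapshots[i]
    surf = traj.surface(i)
    init = traj.initial_surface()
    hull = cv.convex_hull_reference(init, surf)
    field_ = cv.curvature_field(surf)
    out = {
        "t": snap.t,
        "gi": cv.gyrification_index(surf, hull),
        "curvature_stat": cv.dimensionless_curvature_stat(surf, field_),
        "elastic_energy": snap.elastic_energy,
        "kinetic_energy": snap.kinetic_energy,
        "n_contacts": snap.n_contacts,
    }
    if full:
        depth = cv.sulcal_depth(surf, init, hull)
        q = np.nanquantile(depth.depth, [0.25, 0.5, 0.75, 0.9])
        out.update(depth_q25=q[0], depth_q50=q[1], depth_q75=q[2],
                   depth_q90=q[3], depth_mean=float(np.nanmean(depth.depth)))
        spectral = ori.laplace_beltrami_fiedler(surf)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            angles = ori.fold_angles(surf, field_, spectral)
        finite = np.isfinite(angles)
        if finite.any():
            dist = ori.angle_distribution(angles)
            out["kl"] = dist.kl
        else:
            out["kl"] = np.nan
        out["fiedler_degenerate"] = spectral.degenerate
    snap.metrics.update(out)
    return out


def trajectory_table(traj: Trajectory, metric_times=DEFAULT_SNAPSHOT_TIMES,
                     full: bool = True) -> pd.DataFrame:
    """One row per requested snapshot time (nearest stored snapshot)."""
    rows = []
    for t in metric_times:
        i = traj.snapshot_nearest(t)
        row = snapshot_metrics(traj, i, full=full)
        row["requested_t"] = t
        rows.append(row)
    return pd.DataFrame(rows)


def checkpoint_at_gi(traj: Trajectory, gi_target: float) -> int:
    """Index of the stored snapshot nearest the first GI crossing.

    GI is linearly interpolated over time between stored snapshots; the
    nearer of the two bracketing snapshots is returned.  A target below the
    initial GI returns the initial snapshot.
    """
    gis = np.array([snapshot_gi(traj, i) for i in range(len(traj.snapshots))])
    times = traj.times
    if gi_target <= gis[0]:
        return 0
    above = np.flatnonzero(gis >= gi_target)
    if above.size == 0:
        raise GINotReachedError(gi_target, float(gis.max()))
    i = int(above[0])
    t0, t1 = times[i - 1], times[i]
    g0, g1 = gis[i - 1], gis[i]
    t_star = t0 + (gi_target - g0) / (g1 - g0) * (t1 - t0) if g1 > g0 else t1
    return i - 1 if abs(t_star - t0) < abs(t_star - t1) else i


def _combo_key(law, h, geom_label, spec, density, seed) -> str:
    text = f"{law.label}|{h}|{geom_label}|{spec.semi_axes.tolist()}|{density}|{seed}"
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def run_sweep(spec: SweepSpec, outdir=None, full_metrics: bool = True,
              material: Material | None = None) -> pd.DataFrame:
    """Run every combination and tabulate descriptors per snapshot time.

    With ``outdir`` each combination's rows persist to a CSV keyed by its
    parameters; existing files are loaded instead of re-simulated, so an
    interrupted sweep resumes.  Individual run failures are recorded in the
    table (``error`` column) and the sweep continues.
    """
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    schema = ["growth_law", "thickness_mm", "geometry", "density", "seed",
              "requested_t", "t", "gi", "curvature_stat", "error"]
    for law, h, geom_label, gspec, density in spec.combinations():
        key = _combo_key(law, h, geom_label, gspec, density, spec.seed)
        cache = outdir / f"combo_{key}.csv" if outdir is not None else None
        if cache is not None and cache.exists():
            cached = pd.read_csv(cache)
            if "error" in cached.columns:
                cached["error"] = cached["error"].fillna("")
            frames.append(cached)
            continue
        meta = {
            "growth_law": law.label,
            "thickness_mm": h,
            "geometry": geom_label,
            "density": density,
            "seed": spec.seed,
        }
        try:
            traj = simulate_geometry(
                gspec, thickness_mm=h, law=law, density=density,
                seed=spec.seed, material=material, **spec.sim_overrides,
            )
            table = trajectory_table(traj, spec.snapshot_times, full=full_metrics)
            table = table.assign(**meta, error="")
        except Exception as exc:  # noqa: BLE001 - recorded, sweep continues
            table = pd.DataFrame([{**meta, "error": f"{type(exc).__name__}: {exc}"}])
        frames.append(table)
        if cache is not None:
            table.to_csv(cache, index=False, float_format="%.12g")
    if not frames:
        return pd.DataFrame(columns=schema)
    out = pd.concat(frames, ignore_index=True)
    for col in schema:
        if col not in out.columns:
            out[col] = np.nan
    return out


def growth_model_comparison(trajectories: dict, gi_grid=DEFAULT_GI_TARGETS) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-vertex mean curvature at matched GI.

    ``trajectories`` maps model label to a Trajectory; all must share the
    input mesh so vertices correspond.  For each GI on the grid and each
    unordered model pair, the correlation is computed between the snapshots
    nearest that GI crossing; pairs whose models never reach the GI are
    skipped.  The mean over pairs is appended per GI (label "mean").
    """
    labels = sorted(trajectories)
    ref_faces = None
    fields: dict = {}
    for lbl in labels:
        faces = trajectories[lbl].surface_faces
        if ref_faces is None:
            ref_faces = faces
        elif faces.shape != ref_faces.shape or not np.array_equal(faces, ref_faces):
            raise ValueError("trajectories must share the input mesh")
    rows = []
    for gi in gi_grid:
        snaps = {}
        for lbl in labels:
            try:
                snaps[lbl] = checkpoint_at_gi(trajectories[lbl], gi)
            except GINotReachedError:
                continue
        rs = []
        for a, b in itertools.combinations(sorted(snaps), 2):
            for lbl, i in ((a, snaps[a]), (b, snaps[b])):
                if (lbl, i) not in fields:
                    fields[(lbl, i)] = cv.curvature_field(
                        trajectories[lbl].surface(i)
                    )
            r = cv.curvature_correlation(fields[(a, snaps[a])],
                                         fields[(b, snaps[b])])
            rows.append({"gi": gi, "model_a": a, "model_b": b, "r": r})
            rs.append(r)
        if rs:
            rows.append({"gi": gi, "model_a": "mean", "model_b": "mean",
                         "r": float(np.nanmean(rs))})
    return pd.DataFrame(rows, columns=["gi", "model_a", "model_b", "r"])


def full_protocol(**overrides) -> SweepSpec:
    """The convergence-grade protocol: reference ellipsoid at 1e6 tets/cm^3,
    all four growth laws, the printed thickness set.  Hours of compute; run
    explicitly (CLI --full), never by the default suite."""
    spec = SweepSpec(
        growth_laws=DEFAULT_LAWS,
        thicknesses_mm=DEFAULT_THICKNESSES_MM,
        geometries={"reference": EllipsoidSpec.reference(),
                    **elongation_geometries()},
        densities=(FULL_DENSITY,),
        desk_scale=False,
    )
    return replace(spec, **overrides)
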