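"""Quasi-static growth FEM.

Explicit damped dynamics of a modestly compressible neo-Hookean tetrahedral
solid undergoing differential tangential growth, with vertex-triangle
penalty contact on the boundary surface.  The deformation gradient of each
element is F = A (G Ahat)^{-1}: the growth tensor G inflates the stress-free
reference configuration tangentially, and elasticity penalizes the mismatch
between the deformed element A and that grown reference.  Once the cortical
layer's tangential expansion outruns the white matter's, the compressive
stress buckles the surface into folds.

All mechanics run in normalized coordinates (longest axis spanning [-1, 1])
with mu = rho = 1; only the ratios K/mu and the growth parameters matter.
The stability time step is dt = factor * a * sqrt(rho / K) with a the mean
mesh spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels, meshing
from .growth import GrowthLaw, alpha, tangential_ratio
from .meshing import NormalizationRecord, TetMesh, mesh_spacing

__all__ = [
    "Material",
    "SimConfig",
    "SimState",
    "Snapshot",
    "Trajectory",
    "ElementInversionError",
    "initialize",
    "deformation_gradient",
    "elastic_nodal_forces",
    "contact_pairs",
    "contact_nodal_forces",
    "step",
    "update_mass_scaling",
    "run",
]


class ElementInversionError(RuntimeError):
    pass


@dataclass(frozen=True)
class Material:
    """Neo-Hookean material: bulk modulus five times the shear modulus by
    default, unit shear modulus and mass density in normalized units."""

    mu: float = 1.0
    K: float | None = None
    rho: float = 1.0

    @property
    def bulk(self) -> float:
        return 5.0 * self.mu if self.K is None else self.K


@dataclass
class SimConfig:
    """Simulation protocol.

    ``thickness_mm`` is the initial cortical thickness in millimetres on the
    un-normalized geometry; ``thickness_convention`` selects how it is
    normalized for the growth sigmoid (see NormalizationRecord).
    ``settle_time`` continues the damped dynamics past ``end_time`` with
    growth frozen, relaxing toward the quasi-static equilibrium under the
    final growth.  ``dt_factor`` scales the stability time step
    dt = dt_factor * a * sqrt(rho/K).  Contact threshold and stiffness
    default to half the mesh spacing and the bulk modulus.  ``damping`` is
    the mass-proportional viscous coefficient (1/time, normalized units)
    that keeps the explicit dynamics quasi-static.
    """

    growth_law: GrowthLaw = field(default_factory=GrowthLaw.linear)
    thickness_mm: float = 0.83
    end_time: float = 1.0
    settle_time: float = 0.0
    dt_factor: float = 0.05
    contact_threshold: float | None = None
    contact_stiffness: float | None = None
    contact_rebuild: int = 10
    contact_exclusion_factor: float = 2.5
    damping: float = 20.0
    max_step_displacement: float = 0.1
    inversion_floor: float = 0.05
    snapshot_interval: float = 0.02
    thickness_convention: str = "longitudinal"
    seed: int = 0

    def timestep(self, spacing: float, material: Material) -> float:
        return self.dt_factor * spacing * np.sqrt(material.rho / material.bulk)


@dataclass
class SimState:
    """Mutable state of one growth simulation (normalized units)."""

    t: float
    pos: np.ndarray
    vel: np.ndarray
    mesh: TetMesh
    material_pos: np.ndarray
    bhat: np.ndarray          # per-tet inverse material edge matrix
    normals: np.ndarray       # per-tet material surface normal n_hat
    y_tet: np.ndarray         # per-tet material depth (mean of 4 vertices)
    vol_mat: np.ndarray       # per-tet material volume
    masses: np.ndarray        # per-node lumped mass
    thickness: float          # normalized H_i fed to the growth sigmoid
    spacing: float
    g_tet: np.ndarray = field(default=None)
    elastic_energy: float = 0.0
    kinetic_energy: float = 0.0
    n_contacts: int = 0
    min_J: float = 1.0
    n_rescued: int = 0
    base_masses: np.ndarray = field(default=None)
    _pairs: tuple | None = None
    _steps_since_rebuild: int = 0


def initialize(mesh: TetMesh, config: SimConfig, material: Material,
               thickness_normalized: float | None = None) -> SimState:
    """Build the simulation state from a normalized mesh at t = 0.

    Per tetrahedron: the material edge-matrix inverse, the outward normal of
    the nearest boundary triangle (the material-frame n_hat that generates
    G), and the depth y averaged over the four vertex depths.  Initial
    displacement and velocity are zero; boundary conditions are free.
    """
    if mesh.units != "normalized":
        raise ValueError("initialize expects a normalized mesh (see meshing.normalize)")
    verts = mesh.vertices
    v = verts[mesh.tets]
    ahat = np.stack(
        [v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=2
    )
    det = np.linalg.det(ahat)
    bad = np.flatnonzero(det <= 0)
    if bad.size:
        raise ValueError(f"inverted tetrahedra in input mesh: {bad[:10].tolist()}")
    bhat = np.linalg.inv(ahat)
    vol_mat = det / 6.0

    tri = verts[mesh.boundary_faces]
    centroids = v.mean(axis=1)
    _, nearest = meshing.nearest_triangle(centroids, tri)
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fn /= np.linalg.norm(fn, axis=1)[:, None]
    normals = fn[nearest]

    depth = meshing.material_depth(mesh)
    y_tet = depth[mesh.tets].mean(axis=1)

    masses = np.zeros(mesh.n_vertices)
    np.add.at(masses, mesh.tets.ravel(),
              np.repeat(material.rho * vol_mat / 4.0, 4))

    spacing = mesh_spacing(mesh)

    if thickness_normalized is None:
        # Without a normalization record, interpret thickness_mm against
        # L = the full longest extent of this mesh (2 for [-1,1] meshes).
        extent = verts.max(axis=0) - verts.min(axis=0)
        thickness_normalized = config.thickness_mm / float(extent.max())

    state = SimState(
        t=0.0,
        pos=verts.copy(),
        vel=np.zeros_like(verts),
        mesh=mesh,
        material_pos=verts.copy(),
        bhat=np.ascontiguousarray(bhat),
        normals=np.ascontiguousarray(normals),
        y_tet=y_tet,
        vol_mat=vol_mat,
        masses=masses,
        thickness=float(thickness_normalized),
        spacing=spacing,
    )
    state.base_masses = masses.copy()
    update_mass_scaling(state, config, material)
    return state


def update_mass_scaling(state: SimState, config: SimConfig,
                        material: Material) -> None:
    """Selective mass scaling for explicit stability.

    The global time step dt = factor * a * sqrt(rho/K) is sized by the
    *mean* spacing a, but thin elements — a few slivers initially, and any
    element strongly compressed during folding — carry a higher
    eigenfrequency ~ c_eff / altitude.  Nodes of such elements receive extra
    lumped mass so every element fits the global dt; the standard explicit
    quasi-static remedy (added mass is negligible globally and irrelevant at
    equilibrium).  Re-evaluated periodically on the deformed configuration.
    """
    mesh = state.mesh
    dt = config.timestep(state.spacing, material)
    c_wave = np.sqrt((material.bulk + 4.0 * material.mu / 3.0) / material.rho)
    v = state.pos[mesh.tets]
    vols = np.einsum(
        "ij,ij->i",
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
        v[:, 3] - v[:, 0],
    ) / 6.0
    areas_max = np.zeros(mesh.n_tets)
    for fidx in ([0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]):
        a = 0.5 * np.linalg.norm(
            np.cross(v[:, fidx[1]] - v[:, fidx[0]],
                     v[:, fidx[2]] - v[:, fidx[0]]), axis=1)
        areas_max = np.maximum(areas_max, a)
    altitude = np.maximum(3.0 * np.abs(vols) / np.maximum(areas_max, 1e-300),
                          1e-6 * state.spacing)
    scale = np.maximum(1.0, (1.5 * dt * c_wave / altitude) ** 2)
    masses = state.base_masses.copy()
    if (scale > 1.0).any():
        extra = (scale - 1.0) * material.rho * state.vol_mat / 4.0
        np.add.at(masses, mesh.tets.ravel(), np.repeat(extra, 4))
    state.masses = masses


def deformation_gradient(A: np.ndarray, G: np.ndarray, Ahat: np.ndarray) -> np.ndarray:
    """F = A (G Ahat)^{-1} for a single element (reference implementation)."""
    GA = G @ Ahat
    if abs(np.linalg.det(GA)) < 1e-300:
        raise np.linalg.LinAlgError("singular grown reference edge matrix")
    return A @ np.linalg.inv(GA)


def _refresh_growth(state: SimState, config: SimConfig) -> None:
    # growth follows alpha(t) up to end_time, then stays frozen while the
    # system settles toward quasi-static equilibrium
    a_t = alpha(config.growth_law, min(state.t, config.end_time, 1.0))
    state.g_tet = np.ascontiguousarray(
        tangential_ratio(state.y_tet, state.thickness, a_t)
    )


def elastic_nodal_forces(state: SimState, material: Material,
                         j_floor: float = 0.0) -> np.ndarray:
    """Exact negative gradient of the total elastic energy (updates the
    cached elastic energy on the state).

    With the default ``j_floor = 0`` an inverted element (det F <= 0) raises
    ElementInversionError.  A positive floor instead evaluates the singular
    parts of the stress at max(J, j_floor), keeping forces finite and
    restoring through transient inversions (used by the time stepper).
    """
    if state.g_tet is None:
        state.g_tet = np.ones(state.mesh.n_tets)
    forces = np.zeros_like(state.pos)
    energy, minJ, arg, n_rescued = _kernels.elastic_forces(
        state.pos, state.mesh.tets, state.bhat, state.normals,
        np.asarray(state.g_tet, dtype=np.float64), state.vol_mat,
        material.mu, material.bulk, forces, j_floor,
    )
    if j_floor <= 0.0 and minJ <= 0.0:
        raise ElementInversionError(
            f"element inversion (det F = {minJ:.3g}) in tetrahedron {arg} "
            f"at t = {state.t:.4f}"
        )
    state.elastic_energy = energy
    state.min_J = minJ
    state.n_rescued = n_rescued
    return forces


def contact_pairs(state: SimState, threshold: float, slack: float = 2.0,
                  exclusion_factor: float = 2.5):
    """Candidate (vertex, boundary-triangle) pairs within an inflated search
    radius.  Pairs sharing a vertex are excluded, as are pairs whose
    *material* separation is below ``exclusion_factor * threshold`` — those
    are surface neighbours whose proximity is intrinsic, not a collision.
    Rebuilt periodically; the slack covers motion between rebuilds."""
    faces = state.mesh.boundary_faces
    bverts = np.flatnonzero(state.mesh.is_boundary_vertex)
    tri = state.pos[faces]
    cent = tri.mean(axis=1)
    # per-face search radius: a face can only touch a vertex within its own
    # circumradius plus the contact threshold (plus motion slack)
    rface = np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(state.pos[bverts])
    hits = tree.query_ball_point(cent, r=rface + slack * threshold)
    counts = np.fromiter((len(h) for h in hits), dtype=np.int64, count=len(hits))
    if counts.sum() == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    pf = np.repeat(np.arange(len(faces), dtype=np.int64), counts)
    pv = bverts[np.concatenate([np.asarray(h, dtype=np.int64) for h in hits])]
    # drop pairs sharing a vertex
    share = (faces[pf] == pv[:, None]).any(axis=1)
    # drop intrinsic neighbours: pairs close in the material frame
    mat_cent = state.material_pos[faces].mean(axis=1)
    dm = state.material_pos[pv] - mat_cent[pf]
    near = np.einsum("ij,ij->i", dm, dm) < (exclusion_factor * threshold) ** 2
    keep = ~(share | near)
    return (np.ascontiguousarray(pv[keep]), np.ascontiguousarray(pf[keep]))


def contact_nodal_forces(state: SimState, threshold: float, stiffness: float,
                         pairs=None) -> np.ndarray:
    """Penalty contact force field (zero when no pair is within threshold)."""
    if pairs is None:
        pairs = contact_pairs(state, threshold)
    forces = np.zeros_like(state.pos)
    pv, pf = pairs
    if len(pv):
        state.n_contacts = _kernels.contact_forces(
            state.pos, state.mesh.boundary_faces, pv, pf,
            threshold, stiffness, forces,
        )
    else:
        state.n_contacts = 0
    return forces


def step(state: SimState, config: SimConfig, material: Material,
         dt: float | None = None) -> SimState:
    """One damped symplectic-Euler step; growth refreshed from alpha(t)."""
    if dt is None:
        dt = config.timestep(state.spacing, material)
    threshold = (config.contact_threshold if config.contact_threshold is not None
                 else 0.5 * state.spacing)
    stiffness = (config.contact_stiffness if config.contact_stiffness is not None
                 else material.bulk)

    _refresh_growth(state, config)
    forces = elastic_nodal_forces(state, material, j_floor=config.inversion_floor)
    if state._pairs is None or state._steps_since_rebuild >= config.contact_rebuild:
        state._pairs = contact_pairs(
            state, threshold, exclusion_factor=config.contact_exclusion_factor)
        update_mass_scaling(state, config, material)
        state._steps_since_rebuild = 0
    forces += contact_nodal_forces(state, threshold, stiffness, pairs=state._pairs)
    state._steps_since_rebuild += 1

    acc = forces / state.masses[:, None]
    state.vel += dt * acc
    state.vel *= max(0.0, 1.0 - config.damping * dt)
    # guardrail: cap per-step displacement at a fraction of the mesh
    # spacing so a transiently stiff element cannot trigger a blow-up
    vmax = config.max_step_displacement * state.spacing / dt
    speed = np.sqrt(np.einsum("ij,ij->i", state.vel, state.vel))
    fast = speed > vmax
    if fast.any():
        state.vel[fast] *= (vmax / speed[fast])[:, None]
    state.pos += dt * state.vel
    state.t += dt
    state.kinetic_energy = 0.5 * float(
        (state.masses * np.einsum("ij,ij->i", state.vel, state.vel)).sum()
    )
    if not np.isfinite(state.pos).all():
        raise ElementInversionError(f"non-finite coordinates at t = {state.t:.4f}")
    return state


@dataclass
class Snapshot:
    t: float
    boundary_coords: np.ndarray  # compact surface vertex coordinates
    elastic_energy: float
    kinetic_energy: float
    n_contacts: int
    metrics: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Stored surface snapshots of one growth run (normalized units)."""

    mesh: TetMesh
    config: SimConfig
    material: Material
    record: NormalizationRecord | None
    surface_vertex_index: np.ndarray   # compact -> full vertex index
    surface_faces: np.ndarray          # compact surface faces
    snapshots: list[Snapshot] = field(default_factory=list)
    final_state: SimState | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    def surface(self, i: int):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.snapshots[i].boundary_coords.copy(),
            faces=self.surface_faces.copy(),
            process=False,
        )

    def initial_surface(self):
        return self.surface(0)

    def snapshot_nearest(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))


def run(mesh: TetMesh, config: SimConfig, material: Material | None = None,
        progress: bool = False) -> Trajectory:
    """Run a growth simulation to ``config.end_time``.

    A millimetre mesh is normalized internally (the record is kept on the
    trajectory) and the thickness parameter becomes H_mm / L.  Snapshots of
    the boundary surface are stored every ``snapshot_interval`` of model
    time, plus the initial and final states.  Deterministic given (mesh,
    config): the integration itself draws no random numbers.
    """
    material = material or Material()
    record = None
    if mesh.units == "mm":
        mesh, record = meshing.normalize(mesh)
        thickness_normalized = record.thickness_parameter(
            config.thickness_mm, config.thickness_convention
        )
    else:
        thickness_normalized = None

    state = initialize(mesh, config, material,
                       thickness_normalized=thickness_normalized)
    dt = config.timestep(state.spacing, material)

    surf_idx = np.unique(mesh.boundary_faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[surf_idx] = np.arange(len(surf_idx))
    faces = remap[mesh.boundary_faces]

    traj = Trajectory(
        mesh=mesh, config=config, material=material, record=record,
        surface_vertex_index=surf_idx, surface_faces=faces,
    )

    def snap():
        traj.snapshots.append(
            Snapshot(
                t=state.t,
                boundary_coords=state.pos[surf_idx].copy(),
                elastic_energy=state.elastic_energy,
                kinetic_energy=state.kinetic_energy,
                n_contacts=state.n_contacts,
            )
        )

    snap()
    next_snap = config.snapshot_interval
    n_steps = 0
    t_stop = config.end_time + config.settle_time
    while state.t < t_stop - 1e-12:
        dt_eff = min(dt, t_stop - state.t)
        step(state, config, material, dt=dt_eff)
        n_steps += 1
        if state.t >= next_snap - 1e-12:
            snap()
            next_snap += config.snapshot_interval
        if progress and n_steps % 50 == 0:
            print(f"t = {state.t:.3f}  E_el = {state.elastic_energy:.4g}  "
                  f"E_kin = {state.kinetic_energy:.4g}  "
                  f"contacts = {state.n_contacts}")
    if not traj.snapshots or traj.snapshots[-1].t < state.t - 1e-12:
        snap()
    traj.final_state = state
    return traj
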