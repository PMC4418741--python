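"""Identify the loading regime consistent with a fracture surface.

Two field criteria, scored on a linear-static FE solution:

* C1, strain localization — the top-decile von Mises strain in the proximal
  half of the bone should be spatially restricted to the neighbourhood of the
  fracture surface (fraction of high-strain elements within a distance d of
  the surface).
* C2, shear consistency — near the surface, the principal stress frame should
  be the Mohr configuration of shear failure on that plane: the maximum
  principal stress s11 at a high angle to the plane, the minimum s33 at a low
  angle, and the intermediate s22 lying in the plane, perpendicular to the
  slip direction.

A grid of candidate loads (surface patch x direction cone) replaces the manual
trial-and-error search of the original workflow: one linear solve per
candidate (the stiffness is factorised once; by linearity the magnitude does
not affect the ranking), candidates ranked by C1 * C2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fe import (
    LoadCase,
    StaticSolver,
    TetMesh,
    _axis_frame,
    distribute_force,
    end_restraint_nodes,
)

__all__ = [
    "FractureSurface",
    "RegimeScore",
    "strain_localization_score",
    "shear_consistency_score",
    "score_result",
    "proximal_patch_grid",
    "direction_cone",
    "search_loading",
]


@dataclass
class FractureSurface:
    """Sampled fracture surface: points (k, 3) mm, outward unit normals
    (k, 3), and unit slip directions (k, 3), all in the mesh frame."""

    points: np.ndarray
    normals: np.ndarray
    slip: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        self.slip = np.atleast_2d(np.asarray(self.slip, dtype=float))
        self.normals /= np.linalg.norm(self.normals, axis=1, keepdims=True)
        self.slip /= np.linalg.norm(self.slip, axis=1, keepdims=True)
        dot = np.abs(np.einsum("ij,ij->i", self.normals, self.slip))
        if np.any(dot > np.sin(np.radians(5.0))):
            raise ValueError("slip must lie in the fracture plane (within 5 degrees)")
        self._tree = cKDTree(self.points)

    @classmethod
    def from_paraboloid(cls, patch, phantom_spec, n_axial: int = 24, n_angular: int = 32):
        """Sample the phantom's paraboloid fracture patch analytically."""
        z = patch.z_center + np.linspace(
            -patch.axial_halfwidth, patch.axial_halfwidth, n_axial
        )
        th = patch.angular_center + np.linspace(
            -patch.angular_halfwidth, patch.angular_halfwidth, n_angular
        )
        Z, T = np.meshgrid(z, th, indexing="ij")
        R = patch.radius_at(Z, phantom_spec.inner_shell_radius)
        pts = np.stack([R * np.cos(T), R * np.sin(T), Z], axis=-1).reshape(-1, 3)
        normals = patch.normals_at(pts)
        slip = patch.slip_at(pts)
        return cls(points=pts, normals=normals, slip=slip)

    def nearest(self, query: np.ndarray):
        d, idx = self._tree.query(query)
        return d, idx


@dataclass
class RegimeScore:
    """Scores of one candidate loading regime; combined = C1 * C2."""

    c1: float
    c2: float
    combined: float
    patch_id: int = -1
    patch_center: np.ndarray | None = None
    direction: np.ndarray | None = None
    magnitude: float = float("nan")
    degenerate_fraction: float = 0.0
    description: str = ""
    failed: bool = False


def _proximal_mask(mesh: TetMesh) -> np.ndarray:
    axis, (tmin, tmax), _, _, c = _axis_frame(mesh)
    t = (mesh.centroids() - c) @ axis
    return t > (tmin + tmax) / 2.0


def _default_d(mesh: TetMesh) -> float:
    return 1.5 * float(mesh.edge_lengths().mean())


def strain_localization_score(
    result,
    surface: FractureSurface,
    mesh: TetMesh,
    peak_fraction: float = 0.5,
    d: float | None = None,
    restrict_factor: float = 3.0,
) -> float:
    """C1: localization of high von Mises strain to the fracture surface.

    The high-strain region H is the set of proximal-half elements whose von
    Mises strain reaches `peak_fraction` of the proximal peak (relative to the
    field's own maximum, so the construction is mesh- and magnitude-
    independent).  C1 is the product of two fractions:

    * restriction — share of H within `restrict_factor` * d of the surface:
      high strain is spatially restricted to the fracture zone;
    * coverage — share of surface sample points with an H element within d:
      the high-strain region is aligned with, and extends along, the whole
      fracture.

    Coverage is what rules out a concentrated (bite-like) load that lights up
    only one corner of the surface; restriction rules out diffuse fields that
    light up everything.  `d` defaults to 1.5x the mean element edge.
    """
    if d is None:
        d = _default_d(mesh)
    prox = _proximal_mask(mesh)
    vm = result.vm_strain_ue[prox]
    if vm.size == 0 or np.all(vm == 0):
        raise ValueError("degenerate field: no strain in the proximal half")
    hi = prox.copy()
    hi[prox] = vm >= peak_fraction * vm.max()
    if not hi.any():
        raise ValueError("degenerate field: empty high-strain set")
    hi_pts = mesh.centroids()[hi]
    dist, _ = surface.nearest(hi_pts)
    restriction = float(np.mean(dist <= restrict_factor * d))
    dsurf, _ = cKDTree(hi_pts).query(surface.points)
    coverage = float(np.mean(dsurf <= d))
    return restriction * coverage


def shear_consistency_score(
    result,
    surface: FractureSurface,
    mesh: TetMesh,
    d: float | None = None,
    thresholds=(45.0, 45.0, 30.0, 60.0),
    return_degeneracy: bool = False,
):
    """C2: mean of three indicator fractions over elements within `d` of the
    surface, testing the Mohr shear configuration.

    thresholds = (a11, a33, a22_plane, a22_slip) in degrees: s11 direction at
    angle >= a11 to the plane; s33 at <= a33 to the plane; s22 at <= a22_plane
    to the plane AND >= a22_slip from the slip direction.  Elements whose
    principal values are numerically degenerate (ties) are counted in the
    returned degeneracy fraction; their (arbitrary) eigenvector split still
    scores, so callers can inspect the flag.
    """
    if d is None:
        d = _default_d(mesh)
    cent = mesh.centroids()
    dist, idx = surface.nearest(cent)
    near = dist <= d
    if not near.any():
        raise ValueError("no elements within d of the fracture surface")
    vals, dirs = result.principal()
    vals, dirs = vals[near], dirs[near]
    n = surface.normals[idx[near]]
    s = surface.slip[idx[near]]

    def sin_to_plane(vec):
        return np.abs(np.einsum("ij,ij->i", vec, n))  # sin(angle to plane)

    a11, a33, a22p, a22s = np.radians(np.asarray(thresholds, dtype=float))
    c_s11 = sin_to_plane(dirs[:, 0]) >= np.sin(a11)
    c_s33 = sin_to_plane(dirs[:, 2]) <= np.sin(a33)
    cos_slip = np.abs(np.einsum("ij,ij->i", dirs[:, 1], s))
    c_s22 = (sin_to_plane(dirs[:, 1]) <= np.sin(a22p)) & (cos_slip <= np.cos(a22s))
    c2 = float((c_s11.mean() + c_s33.mean() + c_s22.mean()) / 3.0)

    scale = np.abs(vals).max(axis=1) + 1e-30
    degen = float(
        np.mean(
            (np.abs(vals[:, 0] - vals[:, 1]) / scale < 1e-6)
            | (np.abs(vals[:, 1] - vals[:, 2]) / scale < 1e-6)
        )
    )
    if return_degeneracy:
        return c2, degen
    return c2


def score_result(
    result, surface: FractureSurface, mesh: TetMesh, d: float | None = None, **kw
) -> RegimeScore:
    """Score one solved load case against the fracture surface."""
    c1 = strain_localization_score(result, surface, mesh, d=d)
    c2, degen = shear_consistency_score(
        result, surface, mesh, d=d, return_degeneracy=True, **kw
    )
    return RegimeScore(c1=c1, c2=c2, combined=c1 * c2, degenerate_fraction=degen)


def proximal_patch_grid(
    mesh: TetMesh, n_patches: int = 12, patch_angle: float = 1.0
):
    """Candidate load patches: angular sectors of the proximal-third lateral
    surface.  Returns a list of (patch_center, node_ids); `patch_angle` is the
    sector half-width in radians."""
    axis, (tmin, tmax), e1, e2, c = _axis_frame(mesh)
    surf = mesh.surface_nodes()
    t = (mesh.nodes[surf] - c) @ axis
    length = tmax - tmin
    lateral = surf[(t >= tmax - length / 3.0) & (t <= tmax - 0.02 * length)]
    rel = mesh.nodes[lateral] - c
    theta = np.arctan2(rel @ e2, rel @ e1)
    patches = []
    for i in range(n_patches):
        th0 = -np.pi + (2 * np.pi * i) / n_patches
        dth = np.angle(np.exp(1j * (theta - th0)))
        nodes = lateral[np.abs(dth) <= patch_angle]
        if nodes.size < 3:
            continue
        patches.append((mesh.nodes[nodes].mean(axis=0), nodes))
    return patches


def direction_cone(axis, step_deg: float = 15.0, max_deg: float = 45.0) -> np.ndarray:
    """Unit directions on a cone grid around `axis` (rings every `step_deg`
    up to `max_deg`, 8 azimuths per ring plus the axis itself)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(tmp @ a) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    dirs = [a]
    for dev in np.arange(step_deg, max_deg + 1e-9, step_deg):
        for az in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            dirs.append(
                np.cos(np.radians(dev)) * a
                + np.sin(np.radians(dev)) * (np.cos(az) * e1 + np.sin(az) * e2)
            )
    return np.array(dirs)


def search_loading(
    mesh: TetMesh,
    materials,
    surface: FractureSurface,
    patch_grid=None,
    direction_grid=None,
    magnitude: float = 56.1,
    d: float | None = None,
) -> list[RegimeScore]:
    """Grid search over candidate (patch, direction) loads; returns scores
    ranked by combined C1*C2, best first.

    `materials` is a MaterialCard (applied through mesh.element_class) or an
    (E, nu) tuple of per-element arrays.  All candidates share the distal
    centre restraint, so the stiffness is factorised once.  A singular or
    failed candidate is flagged, not fatal.
    """
    if hasattr(materials, "arrays"):
        _, E, nu = materials.arrays(mesh.element_class)
    else:
        E, nu = materials
    axis, (tmin, tmax), _, _, c = _axis_frame(mesh)
    if patch_grid is None:
        patch_grid = proximal_patch_grid(mesh)
    if direction_grid is None:
        direction_grid = direction_cone(-axis)
    if len(patch_grid) == 0 or len(direction_grid) == 0:
        raise ValueError("patch and direction grids must be non-empty")
    solver = StaticSolver(mesh, E, nu)
    distal = end_restraint_nodes(mesh, "distal")
    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    fixed[distal] = True
    scores: list[RegimeScore] = []
    for pid, (center, nodes) in enumerate(patch_grid):
        for direction in direction_grid:
            direction = np.asarray(direction, dtype=float)
            forces = distribute_force(mesh, nodes, magnitude * direction)
            case = LoadCase(fixed, forces, f"patch {pid}")
            try:
                res = solver.solve(case)
                sc = score_result(res, surface, mesh, d=d)
            except ValueError as exc:
                sc = RegimeScore(
                    c1=0.0, c2=0.0, combined=0.0, failed=True, description=str(exc)
                )
            sc.patch_id = pid
            sc.patch_center = center
            sc.direction = direction
            sc.magnitude = magnitude
            scores.append(sc)
    scores.sort(key=lambda s: s.combined, reverse=True)
    return scores
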