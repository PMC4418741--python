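"""Synthetic bone phantoms with analytic ground truth.

The fossil CT volume this pipeline was designed around is not publicly
deposited, so every stage is exercised against phantoms that emulate its
documented features: a dense cortical shell, a cancellous interior with an
axially concentric pattern of decreasing density (four classes by default),
an oriented trabecular microstructure with a controllable principal axis and
anisotropy, a narrow (~2 voxel) subsurface pathologic fracture surface that is
parabolic in longitudinal section and concentric with the cortical margin, and
wider taphonomic cracks that reach the bone surface.

Two imaging regimes are generated separately:

* :func:`generate_phantom` renders the *bulk-density* regime — each material
  class is a solid greyscale level (density x gain + noise).  This is the
  regime in which segmentation and mass accounting are exact, and it carries a
  closed-form analytic mass.
* :func:`generate_trabecular_volume` renders the *texture-resolved* regime — a
  binary micro-structure with a known fabric axis and anisotropy, used by the
  mean-intercept-length analysis.

Array index order for volumes is (z, y, x), slowest to fastest; meshes use
(x, y, z) world coordinates in mm with the bone's long axis along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fe import TetMesh

__all__ = [
    "ImageVolume",
    "ParaboloidPatchSpec",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_trabecular_volume",
    "generate_tet_phantom",
    "box_tet_mesh",
    "DEFAULT_CLASS_DENSITIES",
    "CORTICAL_DENSITY",
]

#: cancellous class densities, outer -> inner, g/cm^3 (the canonical four-class table)
DEFAULT_CLASS_DENSITIES = (1.6, 1.4, 1.2, 1.1)
CORTICAL_DENSITY = 2.06  # g/cm^3


@dataclass
class ImageVolume:
    """3D greyscale volume.  `voxels[z, y, x]`; `spacing`/`origin` in mm per
    (z, y, x) axis; world coordinate = origin + index * spacing."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)
        ).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ParaboloidPatchSpec:
    """Subsurface fracture surface: a patch of a paraboloid of revolution,
    concentric with the cortical margin.

    In a longitudinal section the trace is the parabola
    r(z) = r0 - curvature * (z - z_center)^2, where r0 sits `depth_below_shell`
    beneath the inner cortical surface.  The patch spans `axial_halfwidth` in z
    (centred on z_center, measured from the bone mid-length, +z proximal) and
    `angular_halfwidth` around `angular_center` (radians; 0 = +x, the lateral
    side).  `thickness_voxels` controls the rendered dark-sheet thickness.
    The slip sense is distal displacement of the external fragment.
    """

    z_center: float = 22.0  # mm from bone centre, proximal end positive
    axial_halfwidth: float = 5.0  # mm
    angular_center: float = 0.0  # radians, 0 = +x (lateral)
    angular_halfwidth: float = 1.2  # radians
    depth_below_shell: float = 0.8  # mm beneath the inner cortical surface
    curvature: float = 0.02  # mm^-1
    thickness_voxels: float = 2.0

    def radius_at(self, z: float | np.ndarray, inner_shell_radius: float):
        r0 = inner_shell_radius - self.depth_below_shell
        return r0 - self.curvature * (np.asarray(z) - self.z_center) ** 2

    def normals_at(self, points: np.ndarray) -> np.ndarray:
        """Outward unit normals of the surface at (k, 3) xyz points (mm,
        bone-centred frame)."""
        p = np.atleast_2d(points)
        theta = np.arctan2(p[:, 1], p[:, 0])
        dz = 2.0 * self.curvature * (p[:, 2] - self.z_center)
        n = np.stack([np.cos(theta), np.sin(theta), dz], axis=1)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def slip_at(self, points: np.ndarray) -> np.ndarray:
        """Unit slip directions: distal (-z) projected into the surface."""
        n = self.normals_at(points)
        s = np.tile([0.0, 0.0, -1.0], (len(n), 1)) - n * (-n[:, 2:3])
        return s / np.linalg.norm(s, axis=1, keepdims=True)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and composition of the capped-cylinder bone phantom.

    Lengths in mm, densities in g/cm^3 (strictly decreasing inward, mirroring
    the axially concentric density pattern of the fossil), `trabecular_axis` a
    unit vector in xyz, `anisotropy_ratio` >= 1 (1 = statistically isotropic),
    `bone_volume_fraction` in (0, 1).
    """

    outer_radius: float = 10.0
    cortical_thickness: float = 2.0
    length: float = 60.0
    cancellous_class_densities: tuple = DEFAULT_CLASS_DENSITIES
    cortical_density: float = CORTICAL_DENSITY
    trabecular_axis: tuple = (0.0, 0.0, 1.0)
    anisotropy_ratio: float = 1.0
    bone_volume_fraction: float = 0.3
    fracture_plane: ParaboloidPatchSpec | None = None
    taphonomic_cracks: int = 0
    taphonomic_width_voxels: float = 5.0
    spacing: float = 0.3  # mm, isotropic
    greyscale_gain: float = 100.0  # greyscale units per g/cm^3
    noise_sigma_frac: float = 0.02  # of the dynamic range
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cortical_thickness < self.outer_radius:
            raise ValueError("require 0 < cortical_thickness < outer_radius")
        if self.length <= 2 * self.cortical_thickness:
            raise ValueError("length must exceed twice the cortical thickness")
        d = np.asarray(self.cancellous_class_densities, dtype=float)
        if len(d) < 1 or np.any(np.diff(d) >= 0) and len(d) > 1:
            raise ValueError("cancellous densities must strictly decrease inward")
        if np.any(d <= 0) or d.max() >= self.cortical_density:
            raise ValueError("cancellous densities must be positive and below cortical")
        if not 0 < self.bone_volume_fraction < 1:
            raise ValueError("bone_volume_fraction must lie in (0, 1)")
        if self.anisotropy_ratio < 1:
            raise ValueError("anisotropy_ratio must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.outer_radius / self.spacing < 4 or self.length / self.spacing < 8:
            raise ValueError(
                "geometry does not fit the voxel grid: refine spacing or enlarge bone"
            )

    # ------------------------------------------------------------ analytic solid
    @property
    def inner_shell_radius(self) -> float:
        return self.outer_radius - self.cortical_thickness

    @property
    def cancellous_length(self) -> float:
        return self.length - 2 * self.cortical_thickness

    def class_radii(self) -> np.ndarray:
        """Annulus boundaries of the cancellous classes, outer -> inner."""
        k = len(self.cancellous_class_densities)
        return np.linspace(self.inner_shell_radius, 0.0, k + 1)

    def analytic_class_volumes(self) -> dict[int, float]:
        """Closed-form volume (mm^3) of each material class; class 1 cortical,
        2..K+1 cancellous outer -> inner."""
        r = self.class_radii()
        lc = self.cancellous_length
        vols = {1: np.pi * self.outer_radius**2 * self.length - np.pi * r[0] ** 2 * lc}
        for i in range(len(self.cancellous_class_densities)):
            vols[2 + i] = np.pi * (r[i] ** 2 - r[i + 1] ** 2) * lc
        return vols

    def analytic_mass(self) -> float:
        """Closed-form phantom mass in grams."""
        vols = self.analytic_class_volumes()
        rho = self.class_density_map()
        return sum(rho[k] * v for k, v in vols.items()) * 1e-3

    def class_density_map(self) -> dict[int, float]:
        rho = {1: self.cortical_density}
        for i, d in enumerate(self.cancellous_class_densities):
            rho[2 + i] = float(d)
        return rho


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    material_labels: np.ndarray  # per-voxel class id (0 background)
    fracture_voxels: np.ndarray  # boolean mask of the pathologic fracture sheet
    crack_voxels: list  # list of boolean masks, one per taphonomic crack
    crack_class: list  # 'pathologic' / 'preservational', fracture first
    true_fabric_axis: np.ndarray
    analytic_mass: float
    spec: PhantomSpec = None


# ------------------------------------------------------------------- generators


def _cylinder_labels(spec: PhantomSpec):
    """Voxel label grid and the (z, y, x) coordinate arrays (bone-centred mm)."""
    h = spec.spacing
    margin = 2 * h
    nxy = int(np.ceil(2 * (spec.outer_radius + margin) / h))
    nz = int(np.ceil((spec.length + 2 * margin) / h))
    zs = (np.arange(nz) - (nz - 1) / 2.0) * h
    ys = (np.arange(nxy) - (nxy - 1) / 2.0) * h
    xs = ys.copy()
    Z = zs[:, None, None]
    Y = ys[None, :, None]
    X = xs[None, None, :]
    R = np.sqrt(X**2 + Y**2)
    inside = (R <= spec.outer_radius) & (np.abs(Z) <= spec.length / 2.0)
    labels = np.zeros((nz, nxy, nxy), dtype=np.int16)
    cancellous = (
        inside
        & (R < spec.inner_shell_radius)
        & (np.abs(Z) < spec.length / 2.0 - spec.cortical_thickness)
    )
    labels[inside] = 1  # cortical shell and caps
    radii = spec.class_radii()
    for i in range(len(spec.cancellous_class_densities)):
        ring = cancellous & (R <= radii[i]) & (R >= radii[i + 1] - 1e-12)
        labels[ring] = 2 + i
    return labels, (Z, Y, X, R)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Render the bulk-density phantom volume and its ground truth.

    Greyscale = class density x gain, plus Gaussian noise with standard
    deviation `noise_sigma_frac` of the dynamic range.  The pathologic
    fracture is a dark sheet about `thickness_voxels` voxels thick, strictly
    interior to the bone; taphonomic cracks are dark slabs >= 3 voxels wide
    intersecting the outer surface, placed in the distal half.  Deterministic
    for fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels, (Z, Y, X, R) = _cylinder_labels(spec)
    h = spec.spacing

    rho = spec.class_density_map()
    grey = np.zeros(labels.shape, dtype=float)
    for k, d in rho.items():
        grey[labels == k] = d * spec.greyscale_gain

    fracture_mask = np.zeros(labels.shape, dtype=bool)
    crack_class: list[str] = []
    if spec.fracture_plane is not None:
        fp = spec.fracture_plane
        theta = np.arctan2(Y, X)
        dtheta = np.angle(np.exp(1j * (theta - fp.angular_center)))
        rf = fp.radius_at(Z, spec.inner_shell_radius)
        half = fp.thickness_voxels * h / 2.0
        fracture_mask = (
            (np.abs(R - rf) <= half)
            & (np.abs(dtheta) <= fp.angular_halfwidth)
            & (np.abs(Z - fp.z_center) <= fp.axial_halfwidth)
            & (labels >= 2)  # strictly inside cancellous bone
        )
        grey[fracture_mask] = 0.0
        crack_class.append("pathologic")

    crack_masks: list[np.ndarray] = []
    if spec.taphonomic_cracks > 0:
        w = spec.taphonomic_width_voxels
        if w < 3:
            raise ValueError("taphonomic cracks must be at least 3 voxels wide")
        bone = labels > 0
        for c in range(spec.taphonomic_cracks):
            # entry point on the lateral surface, distal half, well separated
            theta_c = 2 * np.pi * c / spec.taphonomic_cracks + rng.uniform(-0.3, 0.3)
            z_c = -spec.length / 2.0 + spec.length * rng.uniform(0.12, 0.38)
            p = np.array(
                [
                    spec.outer_radius * np.cos(theta_c),
                    spec.outer_radius * np.sin(theta_c),
                    z_c,
                ]
            )
            # crack plane: contains the radial direction, tilted randomly
            radial = np.array([np.cos(theta_c), np.sin(theta_c), 0.0])
            tang = np.array([-np.sin(theta_c), np.cos(theta_c), 0.0])
            tilt = rng.uniform(-0.4, 0.4)
            normal = np.array([0.0, 0.0, 1.0]) * np.cos(tilt) + tang * np.sin(tilt)
            d_plane = (
                (X - p[0]) * normal[0] + (Y - p[1]) * normal[1] + (Z - p[2]) * normal[2]
            )
            d_entry = np.sqrt((X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2)
            extent = rng.uniform(0.4, 0.6) * spec.outer_radius
            mask = (np.abs(d_plane) <= w * h / 2.0) & (d_entry <= extent) & bone
            crack_masks.append(mask)
            grey[mask] = 0.0
            crack_class.append("preservational")

    dyn = spec.cortical_density * spec.greyscale_gain
    grey += rng.normal(0.0, spec.noise_sigma_frac * dyn, size=grey.shape)

    vol = ImageVolume(voxels=grey, spacing=np.full(3, h))
    truth = GroundTruth(
        material_labels=labels,
        fracture_voxels=fracture_mask,
        crack_voxels=crack_masks,
        crack_class=crack_class,
        true_fabric_axis=np.asarray(spec.trabecular_axis, dtype=float),
        analytic_mass=spec.analytic_mass(),
        spec=spec,
    )
    return vol, truth


def generate_trabecular_volume(
    axis,
    anisotropy_ratio: float,
    bvf: float,
    shape,
    seed: int = 0,
    spacing: float = 0.065,
    sigma_transverse: float = 1.5,
) -> ImageVolume:
    """Binary trabecular micro-structure with a controlled fabric.

    A Gaussian random field is smoothed with an anisotropic Gaussian kernel
    whose standard deviation along `axis` is `anisotropy_ratio` times the
    transverse one (`sigma_transverse`, voxels), then thresholded at the
    (1 - bvf) quantile so the realised bone volume fraction matches `bvf` to
    within a voxel-count rounding.  `axis` is a unit vector in (x, y, z);
    anisotropy_ratio = 1 gives a statistically isotropic structure.  Default
    spacing mirrors a 65 um micro-CT voxel.
    """
    if not 0 < bvf < 1:
        raise ValueError("bvf must lie strictly between 0 and 1")
    if anisotropy_ratio < 1:
        raise ValueError("anisotropy_ratio must be >= 1")
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("axis must be a nonzero vector")
    a = a / norm
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)

    # anisotropic Gaussian smoothing via FFT: kernel FT = exp(-0.5 k^T S k)
    st2 = sigma_transverse**2
    sa2 = (sigma_transverse * anisotropy_ratio) ** 2
    # covariance in (x, y, z); array axes are (z, y, x)
    S = st2 * np.eye(3) + (sa2 - st2) * np.outer(a, a)
    ks = [np.fft.fftfreq(n) * 2 * np.pi for n in shape]  # (z, y, x) axes
    KZ = ks[0][:, None, None]
    KY = ks[1][None, :, None]
    KX = ks[2][None, None, :]
    quad = (
        S[0, 0] * KX**2
        + S[1, 1] * KY**2
        + S[2, 2] * KZ**2
        + 2.0 * (S[0, 1] * KX * KY + S[0, 2] * KX * KZ + S[1, 2] * KY * KZ)
    )
    field = np.fft.ifftn(np.fft.fftn(noise) * np.exp(-0.5 * quad)).real
    thr = np.quantile(field, 1.0 - bvf)
    return ImageVolume(voxels=(field >= thr), spacing=np.full(3, spacing))


# ------------------------------------------------------------------ tet meshing


_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _kuhn_tets() -> np.ndarray:
    """Local vertex indices (cube corner bit-codes) of the six Kuhn tets.

    Corner code = ix + 2*iy + 4*iz.  Every tet runs along the main diagonal
    000 -> 111; the subdivision is translation-invariant, hence conforming
    across neighbouring cubes.
    """
    tets = []
    for perm in _KUHN_PERMS:
        v = [0]
        code = 0
        for axis in perm:
            code |= 1 << axis
            v.append(code)
        tets.append(v)
    return np.array(tets)


def box_tet_mesh(
    nx: int, ny: int, nz: int, h, origin=(0.0, 0.0, 0.0)
) -> TetMesh:
    """Structured box of nx*ny*nz cubes of size h (scalar or (3,)), Kuhn-split
    into 6 tets each.  Used by the FE verification problems."""
    h = np.broadcast_to(np.asarray(h, dtype=float), (3,))
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), -1
    ).reshape(-1, 3)
    return _mesh_from_cubes(idx, h, np.asarray(origin, dtype=float))


def _mesh_from_cubes(cubes: np.ndarray, h: np.ndarray, origin: np.ndarray) -> TetMesh:
    """Conforming tet mesh from integer cube indices (k, 3) in xyz order."""
    corners = np.array(
        [[(c >> 0) & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)]
    )
    all_nodes = (cubes[:, None, :] + corners[None]).reshape(-1, 3)
    uniq, inverse = np.unique(all_nodes, axis=0, return_inverse=True)
    node_ids = inverse.reshape(len(cubes), 8)
    tets_local = _kuhn_tets()
    elements = node_ids[:, tets_local].reshape(-1, 4)
    nodes = origin + uniq * h
    mesh = TetMesh(nodes=nodes, elements=elements)
    vols = mesh.element_volumes()
    flip = vols < 0
    if flip.any():
        elements[flip] = elements[flip][:, [0, 1, 3, 2]]
        mesh = TetMesh(nodes=nodes, elements=elements)
    return mesh


def generate_tet_phantom(
    spec: PhantomSpec, target_elements: int
) -> tuple[TetMesh, np.ndarray]:
    """Tetrahedral mesh of the capped-cylinder phantom with per-element density.

    A structured cube grid is clipped to the solid: cubes are ranked by the
    signed distance of their centre to the capped cylinder and the
    round(V / h^3) most interior are kept, so the summed mesh volume matches
    the closed-form solid volume to within half a cell.  Each cube is split
    into six conforming Kuhn tetrahedra; every element carries the density of
    the material class containing its centroid.
    """
    if target_elements < 500:
        raise ValueError("target_elements must be at least 500")
    V = np.pi * spec.outer_radius**2 * spec.length
    h = (6.0 * V / target_elements) ** (1.0 / 3.0)
    if h > min(spec.outer_radius, spec.length / 2.0):
        raise ValueError(
            "meshing failure (grid sizing): target_elements too small for geometry"
        )
    nxy = int(np.ceil(2 * spec.outer_radius / h)) + 2
    nz = int(np.ceil(spec.length / h)) + 2
    ix = np.arange(nxy)
    iz = np.arange(nz)
    ox = -nxy * h / 2.0
    oz = -nz * h / 2.0
    gx, gy, gz = np.meshgrid(ix, ix, iz, indexing="ij")
    cubes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    centers = np.stack(
        [ox + (cubes[:, 0] + 0.5) * h, ox + (cubes[:, 1] + 0.5) * h,
         oz + (cubes[:, 2] + 0.5) * h], axis=1,
    )
    r = np.linalg.norm(centers[:, :2], axis=1)
    sd = np.maximum(r - spec.outer_radius, np.abs(centers[:, 2]) - spec.length / 2.0)
    n_keep = int(round(V / h**3))
    if n_keep > len(cubes):
        raise ValueError("meshing failure (grid coverage): internal sizing error")
    order = np.argsort(sd, kind="stable")
    keep = order[:n_keep]
    mesh = _mesh_from_cubes(cubes[keep], np.full(3, h), np.array([ox, ox, oz]))

    cent = mesh.centroids()
    rc = np.linalg.norm(cent[:, :2], axis=1)
    zc = cent[:, 2]
    labels = np.ones(len(cent), dtype=np.int64)  # cortical by default
    cancellous = (rc < spec.inner_shell_radius) & (
        np.abs(zc) < spec.length / 2.0 - spec.cortical_thickness
    )
    radii = spec.class_radii()
    for i in range(len(spec.cancellous_class_densities)):
        ring = cancellous & (rc <= radii[i]) & (rc >= radii[i + 1] - 1e-12)
        labels[ring] = 2 + i
    mesh.element_class = labels
    rho_map = spec.class_density_map()
    density = np.array([rho_map[k] for k in labels])
    return mesh, density
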