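"""Linear-static finite elements on 4-node tetrahedral meshes.

Constant-strain tetrahedra (CST) with isotropic linear elasticity, matching the
low-order tetrahedral discretisation conventional in image-based bone models.
CST elements are stiff in bending — verification against beam theory quantifies
the bias — but they pass the patch test exactly and their strain fields are
piecewise constant, which makes element-level post-processing (von Mises
measures, principal stresses) unambiguous.

Conventions: node coordinates in mm, moduli in MPa, forces in N; stresses come
out in MPa, strains are dimensionless but reported in microstrain; tension is
positive.  Strain vectors use Voigt order (xx, yy, zz, xy, yz, zx) with
engineering shear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TetMesh",
    "LoadCase",
    "FEResult",
    "element_stiffness",
    "StaticSolver",
    "solve_linear_static",
    "von_mises",
    "von_mises_strain",
    "principal_stresses",
    "canonical_load_cases",
    "mean_vm_strain",
    "compare_het_hom",
    "distribute_force",
]


# --------------------------------------------------------------------------- mesh


@dataclass
class TetMesh:
    """4-node tetrahedral mesh: `nodes` (n, 3) mm, `elements` (m, 4) int,
    `element_class` (m,) material class ids."""

    nodes: np.ndarray
    elements: np.ndarray
    element_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (m, 4)")
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= len(
            self.nodes
        ):
            raise ValueError("element connectivity out of range")
        if self.element_class is None:
            self.element_class = np.ones(len(self.elements), dtype=np.int64)
        else:
            self.element_class = np.asarray(self.element_class, dtype=np.int64)
            if self.element_class.shape != (len(self.elements),):
                raise ValueError("one class id per element required")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self) -> np.ndarray:
        """(m, 4, 3) node coordinates per element."""
        return self.nodes[self.elements]

    def element_volumes(self) -> np.ndarray:
        """Signed volumes (mm^3); positive for correctly oriented elements."""
        x = self.element_coords()
        d = x[:, 1:] - x[:, :1]
        return np.einsum("ei,ei->e", np.cross(d[:, 0], d[:, 1]), d[:, 2]) / 6.0

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def edge_lengths(self) -> np.ndarray:
        """All six edge lengths per element, shape (m, 6)."""
        x = self.element_coords()
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        return np.stack(
            [np.linalg.norm(x[:, a] - x[:, b], axis=1) for a, b in pairs], axis=1
        )

    def surface_triangles(self) -> np.ndarray:
        """Boundary faces (k, 3), each appearing in exactly one element."""
        faces = self.elements[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(
            -1, 3
        )
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def surface_nodes(self) -> np.ndarray:
        return np.unique(self.surface_triangles())

    def min_dihedral_angles(self) -> np.ndarray:
        """Minimum dihedral angle per element, degrees (quality measure)."""
        x = self.element_coords()
        # outward normals of the four faces
        fidx = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
        normals = []
        for a, b, c in fidx:
            n = np.cross(x[:, b] - x[:, a], x[:, c] - x[:, a])
            normals.append(n / np.linalg.norm(n, axis=1, keepdims=True))
        normals = np.stack(normals, axis=1)  # (m, 4, 3)
        mins = np.full(len(x), np.inf)
        for i in range(4):
            for j in range(i + 1, 4):
                cosang = np.einsum("ek,ek->e", normals[:, i], normals[:, j])
                # dihedral angle = pi - angle between outward normals
                ang = np.degrees(np.pi - np.arccos(np.clip(cosang, -1.0, 1.0)))
                mins = np.minimum(mins, ang)
        return mins


# --------------------------------------------------------------- loads & results


@dataclass
class LoadCase:
    """Restraints and nodal forces.

    fixed : boolean (n_nodes, 3); True where the translation component is held.
    forces: (n_nodes, 3) nodal force vectors in N.
    prescribed: optional (n_nodes, 3) displacement values (mm) imposed at the
    fixed components (zero if omitted).
    """

    fixed: np.ndarray
    forces: np.ndarray
    description: str = ""
    prescribed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fixed = np.asarray(self.fixed, dtype=bool)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.fixed.shape != self.forces.shape or self.fixed.shape[1] != 3:
            raise ValueError("fixed and forces must both be (n_nodes, 3)")
        if not np.isfinite(self.forces).all():
            raise ValueError("forces must be finite")
        if self.prescribed is not None:
            self.prescribed = np.asarray(self.prescribed, dtype=float)
            if self.prescribed.shape != self.fixed.shape:
                raise ValueError("prescribed displacements must be (n_nodes, 3)")


@dataclass
class FEResult:
    """Solution fields of a linear static solve."""

    displacements: np.ndarray  # (n, 3) mm
    strain: np.ndarray  # (m, 6) Voigt, engineering shear
    stress: np.ndarray  # (m, 6) MPa
    vm_stress: np.ndarray  # (m,) MPa
    vm_strain_ue: np.ndarray  # (m,) microstrain
    reactions: np.ndarray  # (n, 3) N (nonzero only at restrained dofs)
    equilibrium_residual: float  # |sum reactions + sum applied| / |applied|
    load: LoadCase | None = None
    _principals: tuple | None = field(default=None, repr=False)

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-element principal stresses (m, 3) sorted s11 >= s22 >= s33 and
        unit directions (m, 3, 3) with directions[:, i, :] the i-th eigenvector."""
        if self._principals is None:
            self._principals = principal_stresses(voigt_to_tensor(self.stress))
        return self._principals


def voigt_to_tensor(v: np.ndarray) -> np.ndarray:
    """(… ,6) Voigt (engineering shear for strain callers must pre-halve) to (…, 3, 3)."""
    v = np.asarray(v, dtype=float)
    t = np.empty(v.shape[:-1] + (3, 3))
    t[..., 0, 0], t[..., 1, 1], t[..., 2, 2] = v[..., 0], v[..., 1], v[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = v[..., 3]
    t[..., 1, 2] = t[..., 2, 1] = v[..., 4]
    t[..., 0, 2] = t[..., 2, 0] = v[..., 5]
    return t


# ------------------------------------------------------------------- element ops


def _elasticity_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic D matrices, shape (m, 6, 6), Voigt engineering-shear convention."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    nu = np.broadcast_to(np.atleast_1d(np.asarray(nu, dtype=float)), E.shape)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            D[..., i, j] = lam
        D[..., i, i] += 2 * mu
        D[..., 3 + i, 3 + i] = mu
    return D


def _b_matrices(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices for CST tets.

    coords: (m, 4, 3) -> B (m, 6, 12) and volumes (m,).  Raises on
    non-positive volume, naming the first offending element.
    """
    m = coords.shape[0]
    ones = np.ones((m, 4, 1))
    M = np.concatenate([ones, coords], axis=2)  # (m, 4, 4)
    vol6 = np.linalg.det(M)
    vols = vol6 / 6.0
    bad = np.where(vols <= 0)[0]
    if bad.size:
        raise ValueError(f"degenerate or inverted tetrahedron (element {bad[0]})")
    # gradients of shape functions: rows 1:4 of inv(M)^T
    Minv = np.linalg.inv(M)
    grads = Minv[:, 1:, :].transpose(0, 2, 1)  # (m, 4, 3): grad of N_a
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B, vols


def element_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness of a single CST tet with node coords (4, 3) mm, E in MPa."""
    B, vols = _b_matrices(np.asarray(coords, dtype=float)[None])
    D = _elasticity_matrix(np.array([E]), np.array([nu]))
    K = vols[0] * B[0].T @ D[0] @ B[0]
    return K


# ----------------------------------------------------------------------- solver


class StaticSolver:
    """Assembles the global stiffness once and factorises per restraint pattern.

    Reusing the factorisation makes multi-load-case studies (the five canonical
    regimes, the fracture-regime grid search) cost one sparse solve per extra
    right-hand side.
    """

    def __init__(self, mesh: TetMesh, E, nu):
        self.mesh = mesh
        m = mesh.n_elements
        self.E = np.broadcast_to(np.asarray(E, dtype=float), (m,)).copy()
        self.nu = np.broadcast_to(np.asarray(nu, dtype=float), (m,)).copy()
        self.B, self.vols = _b_matrices(mesh.element_coords())
        self.D = _elasticity_matrix(self.E, self.nu)
        Ke = np.einsum("e,eji,ejk,ekl->eil", self.vols, self.B, self.D, self.B)
        dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(m, 12)
        rows = np.repeat(dofs, 12, axis=1).ravel()
        cols = np.tile(dofs, (1, 12)).ravel()
        n = 3 * mesh.n_nodes
        self.K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsc()
        self._factor = None
        self._fixed_key = None
        self._free = None

    def _factorize(self, fixed: np.ndarray) -> None:
        key = fixed.tobytes()
        if self._fixed_key == key:
            return
        free = ~fixed.ravel()
        if free.all():
            raise ValueError("insufficient restraints: no dof is fixed")
        Kff = self.K[free][:, free]
        try:
            self._factor = spla.factorized(Kff.tocsc())
        except RuntimeError as exc:  # singular factorisation
            raise ValueError(f"insufficient restraints (singular system): {exc}")
        self._free = free
        self._fixed_key = key

    def solve(self, load: LoadCase) -> FEResult:
        mesh = self.mesh
        if load.fixed.shape[0] != mesh.n_nodes:
            raise ValueError("load case does not match mesh size")
        self._factorize(load.fixed)
        f = load.forces.ravel()
        u = np.zeros(3 * mesh.n_nodes)
        rhs = f[self._free]
        if load.prescribed is not None:
            u[~self._free] = load.prescribed.ravel()[~self._free]
            rhs = rhs - self.K[self._free][:, ~self._free] @ u[~self._free]
        u[self._free] = self._factor(rhs)
        if not np.isfinite(u).all():
            raise ValueError("insufficient restraints: singular system")
        ue = u.reshape(-1, 3)[mesh.elements].reshape(mesh.n_elements, 12)
        strain = np.einsum("eij,ej->ei", self.B, ue)
        stress = np.einsum("eij,ej->ei", self.D, strain)
        residual = self.K @ u - f
        reactions = np.zeros_like(f)
        fixed_flat = load.fixed.ravel()
        reactions[fixed_flat] = residual[fixed_flat]
        total = reactions.reshape(-1, 3).sum(axis=0) + load.forces.sum(axis=0)
        fscale = max(np.abs(load.forces).sum(), 1e-30)
        eq = float(np.linalg.norm(total) / fscale)
        return FEResult(
            displacements=u.reshape(-1, 3),
            strain=strain,
            stress=stress,
            vm_stress=von_mises(stress),
            vm_strain_ue=von_mises_strain(strain, self.nu) * 1e6,
            reactions=reactions.reshape(-1, 3),
            equilibrium_residual=eq,
            load=load,
        )


def solve_linear_static(mesh: TetMesh, E, nu, load: LoadCase) -> FEResult:
    """One-shot solve; use :class:`StaticSolver` for repeated load cases."""
    return StaticSolver(mesh, E, nu).solve(load)


# ----------------------------------------------------------------- field measures


def von_mises(stress_voigt: np.ndarray) -> np.ndarray:
    """Von Mises equivalent of stress in Voigt form (…, 6)."""
    s = np.asarray(stress_voigt, dtype=float)
    xx, yy, zz, xy, yz, zx = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((xx - yy) ** 2 + (yy - zz) ** 2 + (zz - xx) ** 2)
        + 3.0 * (xy**2 + yz**2 + zx**2)
    )


def von_mises_strain(strain_voigt: np.ndarray, nu) -> np.ndarray:
    """Von Mises equivalent strain (dimensionless).

    Uses the (1+nu)-normalised deviatoric form: for uniaxial stress this equals
    the axial strain sigma/E, i.e. vm_strain = vm_stress / E in any uniaxial
    state, which is the convention assumed when comparing against a yield
    strain.  Engineering shears in the Voigt vector are halved internally.
    """
    e = np.asarray(strain_voigt, dtype=float)
    xx, yy, zz = e[..., 0], e[..., 1], e[..., 2]
    xy, yz, zx = e[..., 3] / 2.0, e[..., 4] / 2.0, e[..., 5] / 2.0
    eq = np.sqrt(
        0.5 * ((xx - yy) ** 2 + (yy - zz) ** 2 + (zz - xx) ** 2)
        + 3.0 * (xy**2 + yz**2 + zx**2)
    )
    return eq / (1.0 + np.asarray(nu, dtype=float))


def principal_stresses(tensors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of symmetric (…, 3, 3) tensors, tension positive.

    Returns (values, directions): values sorted descending (s11 >= s22 >= s33),
    directions[..., i] is the unit eigenvector of values[..., i].
    """
    t = np.asarray(tensors, dtype=float)
    w, v = np.linalg.eigh(t)  # ascending
    order = w.argsort(axis=-1)[..., ::-1]
    w_sorted = np.take_along_axis(w, order, axis=-1)
    v_sorted = np.take_along_axis(v, order[..., None, :], axis=-1)
    return w_sorted, np.swapaxes(v_sorted, -1, -2)


def mean_vm_strain(result: FEResult, volumes: np.ndarray | None = None):
    """Mean and SD of element von Mises strain in microstrain.

    Returns a dict with the unweighted statistics (primary) and, when element
    volumes are supplied, the volume-weighted variants.
    """
    v = result.vm_strain_ue
    out = {"mean_ue": float(v.mean()), "sd_ue": float(v.std(ddof=0))}
    if volumes is not None:
        w = np.asarray(volumes, dtype=float)
        w = w / w.sum()
        mu = float(np.dot(w, v))
        out["mean_ue_volweighted"] = mu
        out["sd_ue_volweighted"] = float(np.sqrt(np.dot(w, (v - mu) ** 2)))
    return out


# -------------------------------------------------------- canonical load cases


def distribute_force(
    mesh: TetMesh, nodes: np.ndarray, total: np.ndarray, directions=None
) -> np.ndarray:
    """Nodal force array distributing `total` (vector, N) over surface `nodes`.

    Weights are tributary areas: each boundary triangle contributes a third of
    its area to each of its vertices.  With `directions` (per-node unit
    vectors), `total` is instead a scalar magnitude applied along them (used
    for torsion couples).  Distributed loading avoids the point-load artifacts
    a concentrated force would create.
    """
    tris = mesh.surface_triangles()
    mask = np.isin(tris, nodes).all(axis=1)
    tris = tris[mask]
    weights = np.zeros(mesh.n_nodes)
    if len(tris):
        p = mesh.nodes[tris]
        area = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        np.add.at(weights, tris.ravel(), np.repeat(area / 3.0, 3))
    else:  # patch smaller than one face: fall back to equal weights
        weights[nodes] = 1.0
    w = weights[nodes]
    w = w / w.sum()
    forces = np.zeros((mesh.n_nodes, 3))
    if directions is None:
        forces[nodes] = w[:, None] * np.asarray(total, dtype=float)
    else:
        forces[nodes] = (w * float(total))[:, None] * directions
    return forces


def _axis_frame(mesh: TetMesh):
    """Long axis (unit), its span, and two transverse unit axes, via node PCA."""
    c = mesh.nodes.mean(axis=0)
    x = mesh.nodes - c
    cov = x.T @ x
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    t = x @ axis
    # transverse frame
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(tmp @ axis) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return axis, (t.min(), t.max()), e1, e2, c


def end_restraint_nodes(mesh: TetMesh, which: str = "distal", frac: float = 0.02):
    """Nodes near the centre of an end face: within `frac` of bone length of the
    extreme axial coordinate and within 4x that of the end-face centroid."""
    axis, (tmin, tmax), _, _, c = _axis_frame(mesh)
    t = (mesh.nodes - c) @ axis
    length = tmax - tmin
    if which == "distal":
        near_end = t <= tmin + frac * length
    else:
        near_end = t >= tmax - frac * length
    idx = np.where(near_end)[0]
    if idx.size == 0:
        raise ValueError("axis identification failure: empty end face")
    face_c = mesh.nodes[idx].mean(axis=0)
    r = np.linalg.norm(
        (mesh.nodes[idx] - face_c) - ((mesh.nodes[idx] - face_c) @ axis)[:, None] * axis,
        axis=1,
    )
    rcut = max(4 * frac * length, np.sort(r)[min(3, r.size - 1)] + 1e-9)
    sel = idx[r <= rcut]
    if sel.size < 3:
        sel = idx[np.argsort(r)[: max(3, min(6, idx.size))]]
    return sel


def canonical_load_cases(mesh: TetMesh, magnitude: float = 50.0) -> list[LoadCase]:
    """The five comparative regimes: uniaxial compression, uniaxial tension,
    torsion about the long axis, anteroposterior bending, mediolateral bending.

    Compression/tension/torsion load the proximal end and restrain translation
    at the distal end centre; the bending cases apply a transverse midshaft
    surface load and restrain both end centres.
    """
    axis, (tmin, tmax), e1, e2, c = _axis_frame(mesh)
    t = (mesh.nodes - c) @ axis
    length = tmax - tmin
    surf = mesh.surface_nodes()
    prox_face = surf[t[surf] >= tmax - 0.02 * length]
    if prox_face.size < 3:
        raise ValueError("axis identification failure: empty proximal face")
    distal = end_restraint_nodes(mesh, "distal")
    proximal = end_restraint_nodes(mesh, "proximal")
    n = mesh.n_nodes

    def fixed_at(node_sets):
        fixed = np.zeros((n, 3), dtype=bool)
        for s in node_sets:
            fixed[s] = True
        return fixed

    cases = []
    comp = distribute_force(mesh, prox_face, -magnitude * axis)
    cases.append(LoadCase(fixed_at([distal]), comp, "uniaxial compression"))
    cases.append(LoadCase(fixed_at([distal]), -comp, "uniaxial tension"))

    # torsion: tangential couple on the proximal face, zero net force
    rel = mesh.nodes[prox_face] - mesh.nodes[prox_face].mean(axis=0)
    rel -= (rel @ axis)[:, None] * axis
    rnorm = np.linalg.norm(rel, axis=1)
    good = rnorm > 1e-9
    tang = np.zeros_like(rel)
    tang[good] = np.cross(axis, rel[good]) / rnorm[good, None]
    fr = np.zeros((n, 3))
    fr[prox_face] = (rnorm / max(rnorm.max(), 1e-12))[:, None] * tang * magnitude
    fr[prox_face] -= fr[prox_face].mean(axis=0)  # exact zero net force
    cases.append(LoadCase(fixed_at([distal]), fr, "uniaxial torsion"))

    mid = surf[np.abs(t[surf]) <= 0.05 * length]
    for name, tdir in (("anteroposterior bending", e1), ("mediolateral bending", e2)):
        side = mid[(mesh.nodes[mid] - c) @ tdir < 0]  # load the far surface, push across
        if side.size == 0:
            side = mid
        f = distribute_force(mesh, side, magnitude * tdir)
        cases.append(LoadCase(fixed_at([distal, proximal]), f, name))
    return cases


def compare_het_hom(
    mesh: TetMesh, het_card, hom_card, magnitude: float = 50.0
) -> list[dict]:
    """Mean von Mises brick-strain comparison between two material cards.

    Runs the five canonical regimes on the same mesh under each card and
    reports, per regime, mean [SD] element von Mises strain for both models and
    the percentage difference in means relative to the heterogeneous card.
    """
    E_het, nu_het = het_card.arrays(mesh.element_class)[1:]
    E_hom, nu_hom = hom_card.arrays(mesh.element_class)[1:]
    solver_het = StaticSolver(mesh, E_het, nu_het)
    solver_hom = StaticSolver(mesh, E_hom, nu_hom)
    vols = mesh.element_volumes()
    rows = []
    for case in canonical_load_cases(mesh, magnitude):
        s_het = mean_vm_strain(solver_het.solve(case), vols)
        s_hom = mean_vm_strain(solver_hom.solve(case), vols)
        diff = abs(s_het["mean_ue"] - s_hom["mean_ue"]) / s_het["mean_ue"] * 100.0
        rows.append(
            {
                "regime": case.description,
                "het_mean_ue": s_het["mean_ue"],
                "het_sd_ue": s_het["sd_ue"],
                "hom_mean_ue": s_hom["mean_ue"],
                "hom_sd_ue": s_hom["sd_ue"],
                "difference_pct": diff,
            }
        )
    return rows
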