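"""Readers and writers for the pipeline's artifact formats.

Volumes: NIfTI (via nibabel) or a TIFF stack (via tifffile), each with a JSON
sidecar recording spacing, origin and the (z, y, x) index convention.  Meshes:
VTK legacy ASCII unstructured grids (written and read here directly — the
format is plain text) and a two-file node/element text format.  Tables and
reports: JSON/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .fe import TetMesh
from .phantoms import ImageVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_vtk_mesh",
    "read_vtk_mesh",
    "write_mesh_text",
    "read_mesh_text",
    "write_json",
    "read_json",
]


def _sidecar(vol: ImageVolume) -> dict:
    return {
        "index_order": "zyx (slowest to fastest)",
        "spacing_mm": vol.spacing.tolist(),
        "origin_mm": vol.origin.tolist(),
    }


def write_volume(vol: ImageVolume, path) -> Path:
    """Write a volume as .nii/.nii.gz or .tif with a .json sidecar."""
    path = Path(path)
    data = vol.voxels
    if path.suffix in {".nii", ".gz"}:
        affine = np.diag([*vol.spacing[::-1], 1.0])
        affine[:3, 3] = vol.origin[::-1]
        # nibabel stores (i, j, k) fastest-first; transpose so i=x, j=y, k=z
        nib.save(nib.Nifti1Image(np.asarray(data).T.astype(np.float32), affine), path)
    elif path.suffix in {".tif", ".tiff"}:
        tifffile.imwrite(
            path, np.asarray(data).astype(np.float32), photometric="minisblack"
        )
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(_sidecar(vol)))
    return path


def read_volume(path) -> ImageVolume:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if path.suffix in {".nii", ".gz"}:
        img = nib.load(path)
        data = np.asarray(img.dataobj).T
        spacing = meta.get("spacing_mm", np.abs(np.diag(img.affine)[:3])[::-1])
    elif path.suffix in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        spacing = meta.get("spacing_mm", [1.0, 1.0, 1.0])
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return ImageVolume(
        voxels=data,
        spacing=np.asarray(spacing, dtype=float),
        origin=np.asarray(meta.get("origin_mm", [0.0, 0.0, 0.0]), dtype=float),
    )


def write_vtk_mesh(mesh: TetMesh, path, cell_data: dict | None = None,
                   point_data: dict | None = None) -> Path:
    """Write a tet mesh as a VTK legacy ASCII unstructured grid.

    cell_data/point_data map field name -> array (scalars (n,) or vectors
    (n, 3))."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "paleofract tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in p) for p in mesh.nodes]
    m = mesh.n_elements
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(str(i) for i in e) for e in mesh.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += ["10"] * m

    def emit(block: dict, n: int, header: str):
        out = [f"{header} {n}"]
        for name, arr in block.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out += [f"{v:.10g}" for v in arr]
            else:
                out.append(f"VECTORS {name} double")
                out += [" ".join(f"{v:.10g}" for v in row) for row in arr]
        return out

    data = dict(cell_data or {})
    data.setdefault("material", mesh.element_class.astype(float))
    lines += emit(data, m, "CELL_DATA")
    if point_data:
        lines += emit(point_data, mesh.n_nodes, "POINT_DATA")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_mesh(path) -> tuple[TetMesh, dict]:
    """Read a VTK legacy ASCII unstructured grid written by this package."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    nodes, elements, cell_data = None, None, {}
    current = None
    n_cells = 0
    for line in it:
        parts = line.split()
        if not parts:
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            nodes = np.array(
                [[float(x) for x in next(it).split()] for _ in range(n)]
            )
        elif key == "CELLS":
            n_cells = int(parts[1])
            elements = np.array(
                [[int(x) for x in next(it).split()[1:]] for _ in range(n_cells)]
            )
        elif key == "CELL_TYPES":
            for _ in range(int(parts[1])):
                next(it)
        elif key == "SCALARS":
            name = parts[1]
            next(it)  # LOOKUP_TABLE
            cell_data[name] = np.array(
                [float(next(it)) for _ in range(n_cells)]
            )
        elif key == "VECTORS":
            name = parts[1]
            cell_data[name] = np.array(
                [[float(x) for x in next(it).split()] for _ in range(n_cells)]
            )
    if nodes is None or elements is None:
        raise ValueError("not a VTK unstructured grid")
    cls = cell_data.get("material")
    mesh = TetMesh(
        nodes=nodes,
        elements=elements,
        element_class=None if cls is None else cls.astype(np.int64),
    )
    return mesh, cell_data


def write_mesh_text(mesh: TetMesh, nodes_path, elements_path) -> None:
    """Two-file text format: `id x y z` per node; `id n0 n1 n2 n3 class` per
    element.  0-based ids."""
    with open(nodes_path, "w") as f:
        f.write("# node_id x_mm y_mm z_mm\n")
        for i, p in enumerate(mesh.nodes):
            f.write(f"{i} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
    with open(elements_path, "w") as f:
        f.write("# element_id n0 n1 n2 n3 class\n")
        for i, (e, c) in enumerate(zip(mesh.elements, mesh.element_class)):
            f.write(f"{i} {e[0]} {e[1]} {e[2]} {e[3]} {c}\n")


def read_mesh_text(nodes_path, elements_path) -> TetMesh:
    nd = np.loadtxt(nodes_path)
    el = np.loadtxt(elements_path, dtype=np.int64)
    return TetMesh(
        nodes=nd[:, 1:4], elements=el[:, 1:5], element_class=el[:, 5]
    )


def write_json(obj, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
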