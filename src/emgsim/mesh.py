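"""Tetrahedral tissue meshes: container, structured generation, file I/O.

A :class:`TissueMesh` carries nodes (mm), tetrahedra, a per-element tissue
label, and named boundary patches (triangles) for electrode contacts, the
ground face (domain truncation) and the insulated skin-air surface.
Meshes are exchanged as Gmsh MSH v2.2 ASCII (region labels and patches as
physical groups) or legacy VTK ASCII; both writers/readers live here so the
package has no binary-mesh dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TissueMesh", "box_tet_mesh", "write_msh2", "read_msh2", "write_vtk"]

#: canonical tissue labels used across the package
TISSUES = {
    "skin": 1,
    "fat": 2,
    "muscle": 3,
    "cortical_bone": 4,
    "cancellous_bone": 5,
}


@dataclass
class TissueMesh:
    """Conforming tetrahedral mesh of a layered tissue phantom.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, mm
    tets : (n_tets, 4) int array
    region_labels : (n_tets,) int array — tissue id per element
    boundary_patches : dict mapping patch name -> (n_faces, 3) int array of
        boundary triangles (node triples).  Electrode patches, the ground
        patch and the insulated surface are all stored here.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_labels: np.ndarray
    boundary_patches: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        if self.tets.shape[1] != 4:
            raise ValueError("tets must be (n, 4)")
        if len(self.region_labels) != len(self.tets):
            raise ValueError("one region label per element required")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
        return np.abs(v) / 6.0

    def validate(self) -> None:
        """Raise if labels, patches or element orientations are broken."""
        if self.n_tets == 0:
            raise ValueError("empty mesh")
        if np.any(self.element_volumes() <= 0):
            raise ValueError("degenerate (zero-volume) elements present")
        if self.tets.max() >= self.n_nodes or self.tets.min() < 0:
            raise ValueError("tet connectivity references missing nodes")
        bset = self.boundary_face_set()
        for name, faces in self.boundary_patches.items():
            if len(faces) == 0:
                raise ValueError(f"boundary patch {name!r} is empty")
            for f in faces:
                if tuple(sorted(f)) not in bset:
                    raise ValueError(
                        f"patch {name!r} contains a non-boundary face {f}"
                    )

    def boundary_face_set(self) -> set[tuple[int, int, int]]:
        """Sorted node-triples of the true boundary (faces used once)."""
        faces = _tet_faces(self.tets)
        key = np.sort(faces, axis=1)
        uniq, counts = np.unique(key, axis=0, return_counts=True)
        return {tuple(f) for f in uniq[counts == 1]}

    def boundary_faces(self) -> np.ndarray:
        """All boundary triangles, outward orientation not guaranteed."""
        return np.array(sorted(self.boundary_face_set()), dtype=np.int64)


def _tet_faces(tets: np.ndarray) -> np.ndarray:
    idx = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    return np.concatenate([tets[:, i] for i in idx], axis=0)


# 6-tet (Kuhn) subdivision of the unit cube, consistent across neighbours
_KUHN = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 5, 7],
        [0, 2, 3, 7],
        [0, 2, 6, 7],
        [0, 4, 5, 7],
        [0, 4, 6, 7],
    ]
)


def box_tet_mesh(
    extent_mm: tuple[float, float, float],
    h_mm: float,
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TissueMesh:
    """Structured tetrahedral mesh of a box (6 tets per cubic cell).

    The Kuhn subdivision keeps faces between neighbouring cells conforming.
    All elements are initially labelled muscle; callers relabel regions and
    tag boundary patches afterwards.
    """
    nx, ny, nz = (max(1, int(round(e / h_mm))) for e in extent_mm)
    xs = origin_mm[0] + np.arange(nx + 1) * (extent_mm[0] / nx)
    ys = origin_mm[1] + np.arange(ny + 1) * (extent_mm[1] / ny)
    zs = origin_mm[2] + np.arange(nz + 1) * (extent_mm[2] / nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    # cube corner ids, bit order (di, dj, dk) -> corner index di*4+dj*2+dk
    corners = np.stack(
        [
            nid(i + di, j + dj, k + dk)
            for di in (0, 1)
            for dj in (0, 1)
            for dk in (0, 1)
        ],
        axis=1,
    )
    tets = corners[:, _KUHN].reshape(-1, 4)
    labels = np.full(len(tets), TISSUES["muscle"], dtype=np.int64)
    return TissueMesh(nodes=nodes, tets=tets, region_labels=labels)


def tag_boundary_patch(
    mesh: TissueMesh,
    name: str,
    predicate,
) -> int:
    """Tag boundary triangles whose centroid satisfies ``predicate``.

    ``predicate`` maps an (n, 3) array of face centroids (mm) to a boolean
    mask.  Returns the number of faces tagged; falls back to the single
    nearest face when the predicate selects none and ``predicate.center``
    is available (used for sub-resolution electrode contacts).
    """
    faces = mesh.boundary_faces()
    cent = mesh.nodes[faces].mean(axis=1)
    sel = predicate(cent)
    faces_sel = faces[sel]
    if len(faces_sel) == 0 and hasattr(predicate, "center"):
        d = np.linalg.norm(cent - np.asarray(predicate.center), axis=1)
        faces_sel = faces[[int(np.argmin(d))]]
    mesh.boundary_patches[name] = faces_sel
    return len(faces_sel)


# ----------------------------------------------------------------- file I/O

_MSH_TET = 4
_MSH_TRI = 2


def write_msh2(mesh: TissueMesh, path) -> None:
    """Write Gmsh MSH v2.2 ASCII; patches become 2-D physical groups."""
    patch_ids = {name: 100 + i for i, name in enumerate(mesh.boundary_patches)}
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    if patch_ids or True:
        lines.append("$PhysicalNames")
        names = [
            f'2 {pid} "{name}"' for name, pid in patch_ids.items()
        ] + [
            f'3 {tid} "{tname}"'
            for tname, tid in TISSUES.items()
            if np.any(mesh.region_labels == tid)
        ]
        lines.append(str(len(names)))
        lines.extend(names)
        lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.9g} {y:.9g} {z:.9g}")
    lines.append("$EndNodes")
    elems = []
    eid = 1
    for name, faces in mesh.boundary_patches.items():
        pid = patch_ids[name]
        for f in faces:
            a, b, c = (int(v) + 1 for v in f)
            elems.append(f"{eid} {_MSH_TRI} 2 {pid} {pid} {a} {b} {c}")
            eid += 1
    for tet, lab in zip(mesh.tets, mesh.region_labels):
        a, b, c, d = (int(v) + 1 for v in tet)
        elems.append(f"{eid} {_MSH_TET} 2 {lab} {lab} {a} {b} {c} {d}")
        eid += 1
    lines.append("$Elements")
    lines.append(str(len(elems)))
    lines.extend(elems)
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh2(path) -> TissueMesh:
    """Read the MSH v2.2 subset written by :func:`write_msh2`."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)
    phys_names: dict[int, str] = {}
    nodes = None
    tets, labels = [], []
    patches: dict[str, list] = {}
    for line in it:
        if line == "$PhysicalNames":
            n = int(next(it))
            for _ in range(n):
                dim, pid, name = next(it).split(maxsplit=2)
                phys_names[int(pid)] = name.strip('"')
            next(it)  # End
        elif line == "$Nodes":
            n = int(next(it))
            nodes = np.empty((n, 3))
            for _ in range(n):
                parts = next(it).split()
                nodes[int(parts[0]) - 1] = [float(v) for v in parts[1:4]]
            next(it)
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                phys = int(parts[3])
                conn = [int(v) - 1 for v in parts[3 + ntags :]]
                if etype == _MSH_TET:
                    tets.append(conn)
                    labels.append(phys)
                elif etype == _MSH_TRI:
                    name = phys_names.get(phys, f"patch_{phys}")
                    patches.setdefault(name, []).append(conn)
            next(it)
    mesh = TissueMesh(
        nodes=nodes,
        tets=np.array(tets),
        region_labels=np.array(labels),
        boundary_patches={k: np.array(v) for k, v in patches.items()},
    )
    return mesh


def write_vtk(mesh: TissueMesh, path, point_data: dict | None = None) -> None:
    """Write legacy VTK ASCII (UNSTRUCTURED_GRID) with tissue labels."""
    lines = [
        "# vtk DataFile Version 3.0",
        "emgsim tissue mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines.extend(f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.nodes)
    lines.append(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}")
    lines.extend(
        f"4 {a} {b} {c} {d}" for a, b, c, d in mesh.tets
    )
    lines.append(f"CELL_TYPES {mesh.n_tets}")
    lines.extend("10" for _ in range(mesh.n_tets))
    lines.append(f"CELL_DATA {mesh.n_tets}")
    lines.append("SCALARS tissue int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(v)) for v in mesh.region_labels)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, vals in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in np.asarray(vals))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
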