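"""Electrode weighting functions in the volume conductor.

The static conduction problem  div(sigma grad phi) = 0  is solved with a
prescribed surface current density on an electrode patch (Neumann), a
ground condition on the domain-truncation patch (Dirichlet phi = 0) and an
insulated skin-air surface (homogeneous Neumann).  By reciprocity, one
solve with a unit current at an electrode yields the weighting function
h(x) — the potential a unit point source at x produces at that electrode —
everywhere in the domain at once, so the number of field solves equals the
number of electrodes, not the number of muscle fibers.

Two routes are provided:

* closed-form potentials of a point source in an infinite homogeneous
  (possibly anisotropic) medium, used for the analytic "model I" scenario
  and as oracle for the numerics;
* a Lagrange P1/P2 tetrahedral finite-element solver (conjugate gradients,
  Jacobi preconditioned) assembled from per-element conductivity tensors.

Units: node coordinates in mm, conductivities in S/m, currents in A,
potentials in V.  The mm mesh is scaled to meters inside the assembly so
no hidden unit factors leak out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .mesh import TissueMesh, TISSUES

__all__ = [
    "CONDUCTIVITIES_150HZ",
    "ConductivityField",
    "LeadField",
    "FEMOperator",
    "analytic_infinite_potential",
    "assemble_and_solve",
    "reciprocal_lead_field",
]

#: tissue conductivities at 150 Hz, S/m
CONDUCTIVITIES_150HZ = {
    "skin": 4.88e-4,
    "fat": 4.07e-2,
    "cancellous_bone": 7.56e-2,
    "cortical_bone": 2.00e-2,
    "muscle_isotropic": 0.28,
    "muscle_longitudinal": 0.40,
    "muscle_transversal": 0.09,
}


# --------------------------------------------------------------- analytic

def analytic_infinite_potential(x, source, current_a: float, sigma) -> np.ndarray:
    """Potential of a point source in an infinite homogeneous medium (V).

    For an anisotropic conductivity tensor Sigma (S/m),

        phi(x) = I / (4 pi sqrt(det(Sigma) * d^T Sigma^{-1} d)),  d = x - s

    which reduces to I / (4 pi sigma r) in the isotropic case.  ``x`` may
    be a single point or an (n, 3) array, in mm; ``sigma`` a scalar or a
    3x3 SPD tensor.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    s = np.asarray(source, dtype=float)
    d = (x - s) * 1e-3  # mm -> m
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 == 0.0):
        raise ValueError("observation point coincides with the source")
    sig = np.asarray(sigma, dtype=float)
    if sig.ndim == 0:
        val = current_a / (4.0 * np.pi * float(sig) * np.sqrt(r2))
    else:
        if sig.shape != (3, 3):
            raise ValueError("sigma must be scalar or 3x3")
        w, _ = np.linalg.eigh(sig)
        if np.any(w <= 0):
            raise ValueError("sigma must be symmetric positive-definite")
        det = np.linalg.det(sig)
        quad = np.einsum("ij,jk,ik->i", d, np.linalg.inv(sig), d)
        val = current_a / (4.0 * np.pi * np.sqrt(det * quad))
    return val if val.size > 1 else float(val[0])


# --------------------------------------------------------- conductivity

@dataclass
class ConductivityField:
    """Per-element symmetric 3x3 conductivity tensors (S/m)."""

    tensors: np.ndarray  # (n_tets, 3, 3)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise ValueError("tensors must be (n, 3, 3)")

    @classmethod
    def isotropic(cls, mesh: TissueMesh, sigma_by_tissue: dict[str, float]):
        """Isotropic tensors from a tissue-name -> sigma map."""
        sig = np.zeros(mesh.n_tets)
        for name, tid in TISSUES.items():
            m = mesh.region_labels == tid
            if np.any(m):
                if name not in sigma_by_tissue:
                    raise KeyError(f"no conductivity given for tissue {name!r}")
                sig[m] = sigma_by_tissue[name]
        t = np.einsum("i,jk->ijk", sig, np.eye(3))
        return cls(t)

    def validate_spd(self, tol: float = 0.0) -> None:
        sym = np.abs(self.tensors - self.tensors.transpose(0, 2, 1)).max()
        if sym > 1e-10:
            raise ValueError("conductivity tensors must be symmetric")
        w = np.linalg.eigvalsh(self.tensors)
        if np.any(w <= tol):
            raise ValueError("conductivity tensors must be positive-definite")


@dataclass
class LeadField:
    """Electrode weighting function sampled on points or a polyline.

    ``values`` is the potential per unit ampere (V/A) at ``points`` (mm).
    For polyline sampling ``arc_mm`` carries the arc-length coordinate at
    the fiber discretization step.
    """

    electrode: str
    points: np.ndarray
    values: np.ndarray
    arc_mm: np.ndarray | None = None


# --------------------------------------------------------------- FEM core

# 4-point degree-2 quadrature on the reference tetrahedron
_QA = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_QB = (5.0 - np.sqrt(5.0)) / 20.0
_QPOINTS = np.array(
    [
        [_QA, _QB, _QB, _QB],
        [_QB, _QA, _QB, _QB],
        [_QB, _QB, _QA, _QB],
        [_QB, _QB, _QB, _QA],
    ]
)
_QW = np.full(4, 0.25)

_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class FEMOperator:
    """Assembled stiffness operator for one mesh + conductivity field.

    Parameters
    ----------
    mesh : TissueMesh
    cond : ConductivityField
    order : int
        1 for linear, 2 for quadratic Lagrange elements (default 2, the
        production setting; linear is the fast-test option).
    ground : str
        Name of the boundary patch carrying the Dirichlet condition.
    """

    def __init__(
        self,
        mesh: TissueMesh,
        cond: ConductivityField,
        order: int = 2,
        ground: str = "ground",
        rtol: float = 1e-9,
        maxiter: int = 20000,
    ):
        if order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if ground not in mesh.boundary_patches:
            raise ValueError(
                f"mesh has no ground patch {ground!r}; the conduction "
                "problem would be singular"
            )
        cond.validate_spd()
        if len(cond.tensors) != mesh.n_tets:
            raise ValueError("one conductivity tensor per element required")
        self.mesh = mesh
        self.cond = cond
        self.order = order
        self.ground = ground
        self.rtol = rtol
        self.maxiter = maxiter
        self.solve_count = 0
        self.last_iterations = 0

        self._nodes_m = mesh.nodes * 1e-3
        self._build_dofs()
        self._assemble()
        self._factorize_ground()
        self._tree = cKDTree(mesh.element_centroids())

    # -- dof layout -------------------------------------------------------
    def _build_dofs(self) -> None:
        mesh = self.mesh
        if self.order == 1:
            self.n_dofs = mesh.n_nodes
            self.edge_index = None
            return
        edges = np.concatenate(
            [mesh.tets[:, e] for e in _EDGES], axis=0
        )
        edges = np.sort(edges, axis=1)
        uniq, inv = np.unique(edges, axis=0, return_inverse=True)
        self.edge_nodes = uniq  # (n_edges, 2)
        self.tet_edge_dofs = mesh.n_nodes + inv.reshape(
            len(_EDGES), mesh.n_tets
        ).T  # (n_tets, 6)
        self.n_dofs = mesh.n_nodes + len(uniq)
        self.edge_index = {
            (int(a), int(b)): mesh.n_nodes + i
            for i, (a, b) in enumerate(uniq)
        }
        mid = 0.5 * (self._nodes_m[uniq[:, 0]] + self._nodes_m[uniq[:, 1]])
        self._dof_coords_m = np.vstack([self._nodes_m, mid])

    # -- assembly ---------------------------------------------------------
    def _assemble(self) -> None:
        mesh = self.mesh
        pts = self._nodes_m[mesh.tets]  # (M, 4, 3)
        d = pts[:, 1:] - pts[:, :1]  # (M, 3, 3) edge matrix
        vol = np.abs(np.linalg.det(d)) / 6.0
        dinv = np.linalg.inv(d)  # rows of dinv give grads of lambda 1..3
        g = np.empty((len(vol), 4, 3))
        g[:, 1:] = dinv.transpose(0, 2, 1)
        g[:, 0] = -g[:, 1:].sum(axis=1)  # grad lambda_0
        sig = self.cond.tensors

        if self.order == 1:
            ke = np.einsum("mia,mab,mjb,m->mij", g, sig, g, vol)
            dofs = mesh.tets
        else:
            ke = np.zeros((len(vol), 10, 10))
            for q, wq in zip(_QPOINTS, _QW):
                b = np.empty((len(vol), 10, 3))
                for i in range(4):
                    b[:, i] = (4.0 * q[i] - 1.0) * g[:, i]
                for e, (i, j) in enumerate(_EDGES):
                    b[:, 4 + e] = 4.0 * (q[i] * g[:, j] + q[j] * g[:, i])
                ke += wq * np.einsum("mia,mab,mjb,m->mij", b, sig, b, vol)
            dofs = np.concatenate([mesh.tets, self.tet_edge_dofs], axis=1)

        n_local = dofs.shape[1]
        rows = np.repeat(dofs, n_local, axis=1).ravel()
        cols = np.tile(dofs, (1, n_local)).ravel()
        K = sp.coo_matrix(
            (ke.ravel(), (rows, cols)), shape=(self.n_dofs, self.n_dofs)
        ).tocsr()
        self.K = K

    def _face_dofs(self, face: np.ndarray) -> np.ndarray:
        """All dofs on a boundary triangle (vertices + midedges for P2)."""
        if self.order == 1:
            return face
        mids = [
            self.edge_index[tuple(sorted((int(face[i]), int(face[j]))))]
            for i, j in ((0, 1), (1, 2), (0, 2))
        ]
        return np.concatenate([face, mids])

    def _patch_nodes(self, name: str) -> np.ndarray:
        faces = self.mesh.boundary_patches[name]
        dofs = np.concatenate([self._face_dofs(f) for f in faces])
        return np.unique(dofs)

    def _factorize_ground(self) -> None:
        gnd = self._patch_nodes(self.ground)
        free = np.ones(self.n_dofs, dtype=bool)
        free[gnd] = False
        self.ground_dofs = gnd
        self.free = free
        self.Kff = self.K[free][:, free].tocsr()
        self.Kfd = self.K[free][:, ~free].tocsr()
        diag = self.Kff.diagonal()
        diag[diag <= 0] = 1.0
        self._precond = spla.LinearOperator(
            self.Kff.shape, matvec=lambda v: v / diag
        )

    # -- loads ------------------------------------------------------------
    def patch_area_m2(self, name: str) -> float:
        faces = self.mesh.boundary_patches[name]
        p = self._nodes_m[faces]
        return float(
            0.5
            * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
            ).sum()
        )

    def patch_load(self, name: str, total_current_a: float = 1.0) -> np.ndarray:
        """Consistent load vector for uniform current density on a patch.

        The surface density Js = I / area is integrated against the trace
        of the basis functions: A/3 per vertex for P1; for quadratic
        elements the vertex integrals vanish and each midedge takes A/3.
        """
        faces = self.mesh.boundary_patches[name]
        p = self._nodes_m[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        js = total_current_a / areas.sum()
        b = np.zeros(self.n_dofs)
        for f, a in zip(faces, areas):
            if self.order == 1:
                np.add.at(b, f, js * a / 3.0)
            else:
                np.add.at(b, self._face_dofs(f)[3:], js * a / 3.0)
        return b

    def point_load(self, points_mm, currents_a) -> np.ndarray:
        """Load vector for interior point sources (shape-function weights)."""
        points_mm = np.atleast_2d(points_mm)
        currents_a = np.atleast_1d(currents_a)
        elems, lam = self.locate(points_mm)
        dofs, shp = self._shapes(elems, lam)
        b = np.zeros(self.n_dofs)
        np.add.at(b, dofs.ravel(), (currents_a[:, None] * shp).ravel())
        return b

    # -- solve ------------------------------------------------------------
    def solve(self, load: np.ndarray, ground_values: np.ndarray | None = None):
        """Solve K u = load with the ground Dirichlet condition.

        ``ground_values`` optionally prescribes nonzero potentials on the
        ground dofs (used for truncation boundaries with known far-field
        values); default is 0.
        """
        bf = load[self.free].copy()
        u = np.zeros(self.n_dofs)
        if ground_values is not None:
            u[self.ground_dofs] = ground_values
            bf -= self.Kfd @ ground_values
        it = [0]

        def cb(_):
            it[0] += 1

        uf, info = spla.cg(
            self.Kff,
            bf,
            rtol=self.rtol,
            atol=0.0,
            maxiter=self.maxiter,
            M=self._precond,
            callback=cb,
        )
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
        self.solve_count += 1
        self.last_iterations = it[0]
        u[self.free] = uf
        return u

    # -- evaluation -------------------------------------------------------
    def _tet_geometry(self):
        if not hasattr(self, "_tinv"):
            pts = self.mesh.nodes[self.mesh.tets]  # mm
            T = (pts[:, 1:] - pts[:, :1]).transpose(0, 2, 1)  # (M,3,3)
            self._tinv = np.linalg.inv(T)
            self._t0 = pts[:, 0]
        return self._tinv, self._t0

    def locate(self, points_mm, k: int = 8, tol: float = 1e-8):
        """Find containing tets and barycentric coordinates of points.

        Candidate tets come from a centroid k-d tree; the candidate with
        the least-negative barycentric coordinate wins.  Points outside
        the mesh raise (no silent extrapolation).
        """
        points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
        n = len(points_mm)
        tinv, t0 = self._tet_geometry()
        elems = np.full(n, -1, dtype=int)
        lams = np.zeros((n, 4))
        best_min = np.full(n, -np.inf)
        kq = min(k, self.mesh.n_tets)
        pending = np.arange(n)
        while len(pending) and kq <= min(256, self.mesh.n_tets):
            _, cand = self._tree.query(points_mm[pending], k=kq)
            cand = cand.reshape(len(pending), -1)
            d = points_mm[pending][:, None, :] - t0[cand]  # (n,k,3)
            lam123 = np.einsum("nkab,nkb->nka", tinv[cand], d)
            lam = np.concatenate(
                [1.0 - lam123.sum(axis=2, keepdims=True), lam123], axis=2
            )
            mins = lam.min(axis=2)  # (n,k)
            pick = mins.argmax(axis=1)
            rows = np.arange(len(pending))
            elems[pending] = cand[rows, pick]
            lams[pending] = lam[rows, pick]
            best_min[pending] = mins[rows, pick]
            pending = pending[best_min[pending] < -tol]
            kq *= 4
        if len(pending):
            worst = best_min[pending].min()
            raise ValueError(
                f"{len(pending)} query point(s) lie outside the mesh "
                f"(worst barycentric deficit {worst:.2e})"
            )
        return elems, np.clip(lams, 0.0, 1.0)

    def _shapes(self, elems: np.ndarray, lams: np.ndarray):
        """Dofs and shape values for located points, vectorized."""
        tets = self.mesh.tets[elems]
        if self.order == 1:
            return tets, lams
        shp = np.empty((len(elems), 10))
        shp[:, :4] = lams * (2.0 * lams - 1.0)
        for e, (i, j) in enumerate(_EDGES):
            shp[:, 4 + e] = 4.0 * lams[:, i] * lams[:, j]
        dofs = np.concatenate([tets, self.tet_edge_dofs[elems]], axis=1)
        return dofs, shp

    def evaluate(self, u: np.ndarray, points_mm) -> np.ndarray:
        """Interpolate a solution at interior points (element-local)."""
        points_mm = np.atleast_2d(points_mm)
        elems, lams = self.locate(points_mm)
        dofs, shp = self._shapes(elems, lams)
        return np.einsum("ni,ni->n", u[dofs], shp)

    def patch_mean(self, u: np.ndarray, name: str) -> float:
        """Area-weighted mean potential over a boundary patch."""
        w = self.patch_load(name, total_current_a=1.0)
        # patch_load integrates basis traces scaled by Js = 1/area, so
        # w . u is exactly the area-averaged potential
        return float(w @ u)


# ------------------------------------------------------------ high level

def assemble_and_solve(
    mesh: TissueMesh,
    cond: ConductivityField,
    source_patch: str,
    total_current_a: float = 1.0,
    order: int = 2,
    ground: str = "ground",
    operator: FEMOperator | None = None,
):
    """Solve the conduction problem for a current-carrying electrode patch.

    Returns (nodal/dof potentials, operator).  Pass ``operator`` to reuse a
    factorized system across electrodes.
    """
    op = operator or FEMOperator(mesh, cond, order=order, ground=ground)
    u = op.solve(op.patch_load(source_patch, total_current_a))
    return u, op


def reciprocal_lead_field(
    mesh: TissueMesh,
    cond: ConductivityField,
    electrode: str,
    query_points_mm=None,
    polylines_mm=None,
    order: int = 2,
    ground: str = "ground",
    operator: FEMOperator | None = None,
):
    """Lead field h of one electrode by a single reciprocal solve.

    A unit current (1 A) is injected at the electrode patch; the resulting
    potential field, evaluated at query points or along polylines, is the
    weighting function h (V/A) of that electrode for sources anywhere in
    the mesh.  Exactly one field solve per electrode, independent of how
    many fibers are queried.

    Returns (LeadField or list of LeadField per polyline, operator).
    """
    op = operator or FEMOperator(mesh, cond, order=order, ground=ground)
    u = op.solve(op.patch_load(electrode, 1.0))
    if polylines_mm is not None:
        out = []
        for line in polylines_mm:
            line = np.asarray(line, dtype=float)
            seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            vals = op.evaluate(u, line)
            out.append(
                LeadField(electrode=electrode, points=line, values=vals, arc_mm=arc)
            )
        return out, op
    pts = np.atleast_2d(query_points_mm)
    vals = op.evaluate(u, pts)
    return LeadField(electrode=electrode, points=pts, values=vals), op
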