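"""Desk-scale tissue phantom: every synthetic input the pipeline needs.

The phantom is a layered box (skin over fat over muscle, with a two-shell
bone cylinder buried in the muscle) carrying a bipennate-like analytic
fiber-direction field, a diffusion-tensor volume consistent with that
field, a five-contact electrode array on the skin surface and a reference
cross-section polygon for fiber seeding.  Everything is deterministic
given the spec's seed, and the analytic field is retained as ground truth
for tractography oracles.

Geometry conventions: x runs along the muscle's line of action, y across
it, z is depth with the skin surface on top (z = extent_z).  The muscle
belly is an elliptic tube around the box's mid axis; the two fiber
families tilt toward the central aponeurosis plane y = y_c with a
pennation angle that tapers smoothly to zero at the plane, so streamlines
converge without kinks.  Three activation states modulate the field:

* ``rest``      — pennation tilt in the skin-parallel plane only;
* ``abduction`` — fanned (larger tilt) plus a constant dip of the fibers
  toward depth, emulating fibers projecting from dorsum to palm;
* ``flexion``   — families nearly aligned and parallel to the surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from shapely.geometry import Point

from .mesh import TissueMesh, TISSUES, box_tet_mesh
from .muscle import DirectionField
from .tractography import TensorVolume

__all__ = ["PhantomSpec", "Phantom", "build_phantom", "add_tensor_noise"]

STATES = ("rest", "abduction", "flexion")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom.

    Default tensor eigenvalues (axial 1.85, radial 1.09, in 1e-3 mm^2/s)
    reproduce resting skeletal-muscle diffusivities with FA ~ 0.316; the
    2 mm voxel mirrors a typical muscle DTI acquisition.
    """

    extent_mm: tuple[float, float, float] = (40.0, 28.0, 24.0)
    skin_mm: float = 1.0
    fat_mm: float = 2.0
    pennation_deg: float = 15.0
    fan_deg: float = 25.0  # abduction-state edge tilt
    dip_deg: float = 20.0  # abduction-state dip toward depth
    aligned_deg: float = 5.0  # flexion-state edge tilt
    state: str = "rest"
    voxel_mm: float = 2.0
    mesh_h_mm: float = 2.0
    ad: float = 1.85
    rd: float = 1.09
    belly_semi_y_mm: float = 9.0
    belly_semi_z_mm: float = 6.0
    bone_radius_mm: float = 2.5
    bone_center_z_mm: float = 3.5
    electrode_square_mm: float = 5.0
    electrode_radius_mm: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        if self.ad <= self.rd or self.rd <= 0:
            raise ValueError("need axial > radial > 0 diffusivities")
        if self.skin_mm + self.fat_mm >= self.extent_mm[2]:
            raise ValueError("layers thicker than the phantom")

    @property
    def center_y(self) -> float:
        return self.extent_mm[1] / 2.0

    @property
    def z_top(self) -> float:
        return self.extent_mm[2]

    @property
    def belly_center_z(self) -> float:
        # belly sits just under the fat layer
        return self.z_top - self.skin_mm - self.fat_mm - self.belly_semi_z_mm - 2.0

    @property
    def array_center_xy(self) -> tuple[float, float]:
        return (self.extent_mm[0] / 2.0, self.center_y)


@dataclass
class Phantom:
    """Bundle of all synthetic inputs for one phantom state."""

    spec: PhantomSpec
    mesh: TissueMesh
    direction_field: DirectionField
    tensors: TensorVolume
    electrodes: dict[str, np.ndarray]  # name -> surface position (mm)
    section_polygon: object  # shapely Polygon on the reference plane
    reference_plane_x: float

    def inside_belly(self, points_mm) -> np.ndarray:
        return _belly_mask(self.spec)(points_mm)

    def plane_to_world(self, yz) -> np.ndarray:
        yz = np.asarray(yz, dtype=float)
        return np.concatenate([[self.reference_plane_x], yz])

    def manifest(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "electrodes": {k: v.tolist() for k, v in self.electrodes.items()},
            "reference_plane_x": self.reference_plane_x,
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def _belly_mask(spec: PhantomSpec):
    cy, cz = spec.center_y, spec.belly_center_z
    ay, az = spec.belly_semi_y_mm, spec.belly_semi_z_mm
    x0, x1 = 0.5, spec.extent_mm[0] - 0.5

    def mask(points_mm):
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        r2 = ((p[:, 1] - cy) / ay) ** 2 + ((p[:, 2] - cz) / az) ** 2
        return (r2 <= 1.0) & (p[:, 0] >= x0) & (p[:, 0] <= x1)

    return mask


def _state_field(spec: PhantomSpec):
    """Analytic unit direction field for the configured state.

    Tilt toward the aponeurosis plane y = y_c tapers linearly with the
    normalized offset (y - y_c)/a_y, so the two converging families blend
    smoothly; the abduction state adds a constant dip toward depth.
    """
    cy, ay = spec.center_y, spec.belly_semi_y_mm
    if spec.state == "abduction":
        edge_deg, dip_deg = spec.fan_deg, spec.dip_deg
    elif spec.state == "flexion":
        edge_deg, dip_deg = spec.aligned_deg, 0.0
    else:
        edge_deg, dip_deg = spec.pennation_deg, 0.0
    tan_dip = np.tan(np.radians(dip_deg))

    def func(points_mm):
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        off = np.clip((p[:, 1] - cy) / ay, -1.0, 1.0)
        psi = np.radians(edge_deg) * off
        d = np.stack(
            [np.ones(len(p)), -np.tan(psi), -tan_dip * np.ones(len(p))],
            axis=1,
        )
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    return DirectionField.from_function(func)


def _label_regions(mesh: TissueMesh, spec: PhantomSpec) -> None:
    cent = mesh.element_centroids()
    z = cent[:, 2]
    hz = spec.extent_mm[2] / max(1, int(round(spec.extent_mm[2] / spec.mesh_h_mm)))
    b1 = spec.z_top - max(hz, round(spec.skin_mm / hz) * hz or hz)
    b2 = b1 - max(hz, round(spec.fat_mm / hz) * hz or hz)
    lab = np.full(mesh.n_tets, TISSUES["muscle"], dtype=np.int64)
    lab[(z > b2) & (z <= b1)] = TISSUES["fat"]
    lab[z > b1] = TISSUES["skin"]
    r = np.sqrt(
        (cent[:, 1] - spec.center_y) ** 2 + (cent[:, 2] - spec.bone_center_z_mm) ** 2
    )
    bone = (r < spec.bone_radius_mm) & (z <= b2)
    lab[bone & (r < 0.6 * spec.bone_radius_mm)] = TISSUES["cancellous_bone"]
    lab[bone & (r >= 0.6 * spec.bone_radius_mm)] = TISSUES["cortical_bone"]
    mesh.region_labels = lab


def _tag_patches(mesh: TissueMesh, spec: PhantomSpec) -> dict[str, np.ndarray]:
    faces = mesh.boundary_faces()
    cent = mesh.nodes[faces].mean(axis=1)
    top = np.abs(cent[:, 2] - spec.z_top) < 1e-9
    gnd = np.abs(cent[:, 0]) < 1e-9
    mesh.boundary_patches["ground"] = faces[gnd]

    cx, cy = spec.array_center_xy
    half = spec.electrode_square_mm / 2.0
    positions = {
        "e1": np.array([cx - half, cy - half, spec.z_top]),
        "e2": np.array([cx + half, cy - half, spec.z_top]),
        "e3": np.array([cx + half, cy + half, spec.z_top]),
        "e4": np.array([cx - half, cy + half, spec.z_top]),
        "e5": np.array([cx, cy, spec.z_top]),
    }
    top_idx = np.flatnonzero(top)
    used: set[int] = set()
    for name, pos in positions.items():
        d = np.linalg.norm(cent[top_idx] - pos, axis=1)
        within = top_idx[d <= spec.electrode_radius_mm]
        within = [i for i in within if i not in used]
        if not within:  # sub-resolution contact: nearest unused face
            order = top_idx[np.argsort(d)]
            within = [next(i for i in order if i not in used)]
        used.update(within)
        mesh.boundary_patches[name] = faces[np.asarray(within)]
    # everything else on the boundary is the insulated skin-air interface
    tagged = set()
    for nm in ("ground", "e1", "e2", "e3", "e4", "e5"):
        tagged.update(map(tuple, np.sort(mesh.boundary_patches[nm], axis=1)))
    rest = [f for f in faces if tuple(np.sort(f)) not in tagged]
    mesh.boundary_patches["insulated"] = np.asarray(rest)
    return positions


def _tensor_volume(spec: PhantomSpec, dfield: DirectionField) -> TensorVolume:
    v = spec.voxel_mm
    dims = tuple(max(1, int(round(e / v))) for e in spec.extent_mm)
    affine = np.eye(4) * v
    affine[3, 3] = 1.0
    affine[:3, 3] = v / 2.0  # voxel centers at (i + 1/2) * v
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in dims), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * v + v / 2.0
    mask = _belly_mask(spec)(centers).reshape(dims)

    mats = np.zeros(dims + (3, 3))
    iso = spec.rd * np.eye(3)  # isotropic background -> FA = 0
    mats[...] = iso
    in_pts = centers.reshape(dims + (3,))[mask]
    e1 = dfield(in_pts)
    helper = np.where(
        np.abs(e1[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
    )
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    mats[mask] = (
        spec.ad * np.einsum("ni,nj->nij", e1, e1)
        + spec.rd * np.einsum("ni,nj->nij", e2, e2)
        + spec.rd * np.einsum("ni,nj->nij", e3, e3)
    )

    # end regions: belly voxels at the two x extremes ("metacarpal"
    # analogues), dilated by 3 voxels with a 6-connected element
    struct = ndimage.generate_binary_structure(3, 1)
    end_a = np.zeros(dims, dtype=bool)
    end_b = np.zeros(dims, dtype=bool)
    end_a[:2] = mask[:2]
    end_b[-2:] = mask[-2:]
    end_a = ndimage.binary_dilation(end_a, struct, iterations=3)
    end_b = ndimage.binary_dilation(end_b, struct, iterations=3)
    return TensorVolume(
        tensors=TensorVolume.from_matrices(mats, affine).tensors,
        affine=affine,
        roi=mask,
        end_regions=(end_a, end_b),
    )


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Construct mesh, direction field, tensors, electrodes and section."""
    mesh = box_tet_mesh(spec.extent_mm, spec.mesh_h_mm)
    _label_regions(mesh, spec)
    electrodes = _tag_patches(mesh, spec)
    dfield = _state_field(spec)
    tensors = _tensor_volume(spec, dfield)

    cy, cz = spec.center_y, spec.belly_center_z
    section = Point(cy, cz).buffer(1.0, quad_segs=96)
    # elliptic belly cross-section on the reference plane
    import shapely.affinity as aff

    section = aff.scale(
        section, xfact=spec.belly_semi_y_mm, yfact=spec.belly_semi_z_mm,
        origin=(cy, cz),
    )
    return Phantom(
        spec=spec,
        mesh=mesh,
        direction_field=dfield,
        tensors=tensors,
        electrodes=electrodes,
        section_polygon=section,
        reference_plane_x=spec.array_center_xy[0],
    )


def add_tensor_noise(
    tensors: TensorVolume, snr_db: float, seed: int = 0
) -> TensorVolume:
    """Additive Gaussian perturbation of the tensor components.

    The per-component standard deviation is calibrated so the mean
    Frobenius-norm SNR over ROI voxels matches ``snr_db``; eigenvalues are
    clipped to stay positive.  Noise acts on tensor components directly
    (tensor estimation from raw diffusion signals is out of scope).
    """
    if snr_db <= 0:
        raise ValueError("snr_db must be positive")
    if np.isinf(snr_db):
        return tensors
    rng = np.random.default_rng(seed)
    mats = tensors.as_matrices()
    roi = tensors.roi
    mean_norm = np.linalg.norm(mats[roi], axis=(1, 2)).mean()
    target = mean_norm / 10.0 ** (snr_db / 20.0)
    # symmetric matrix with 6 iid N(0, s) components has
    # E||N||_F^2 = 9 s^2 (off-diagonals counted twice)
    s = target / 3.0
    noise6 = rng.normal(0.0, s, size=tensors.tensors.shape)
    noisy = TensorVolume(
        tensors=tensors.tensors + noise6,
        affine=tensors.affine,
        roi=tensors.roi,
        end_regions=tensors.end_regions,
    )
    m = noisy.as_matrices()
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 1e-6, None)
    m = np.einsum("...ij,...j,...kj->...ik", v, w, v)
    return TensorVolume(
        tensors=TensorVolume.from_matrices(m, tensors.affine).tensors,
        affine=tensors.affine,
        roi=tensors.roi,
        end_regions=tensors.end_regions,
    )
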