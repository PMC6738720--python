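"""Deterministic streamline tractography on diffusion-tensor volumes.

Streamlines are integrated bidirectionally from every ROI voxel center
along the principal eigenvector of the local diffusion tensor (fixed-step
Euler, nearest-neighbor tensor lookup by default), terminating when the
fractional anisotropy falls below threshold, the per-step turning angle
exceeds the angular threshold, or the track leaves the ROI.  Only tracks
connecting the two end regions are retained.  Defaults: FA >= 0.15,
angle <= 15 degrees, step 0.4 mm.

Retained tracks are smoothed by refitting each coordinate as a cubic
polynomial of arc length, and near-duplicate tracks closer than one voxel
are pruned.

Tensor volumes follow the NIfTI convention of 6 lower-triangular
components (dxx, dxy, dyy, dxz, dyz, dzz) in 1e-3 mm^2/s; I/O goes through
nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "TensorVolume",
    "Track",
    "TrackingParams",
    "tensor_metrics",
    "track_streamlines",
    "smooth_and_prune",
    "tracks_to_tsv",
    "tracks_from_tsv",
]

_LOWER_TRI = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


@dataclass
class TensorVolume:
    """Voxelized symmetric diffusion tensors with masks.

    tensors: (nx, ny, nz, 6) lower-triangular components, 1e-3 mm^2/s
    affine: 4x4 voxel-to-world map (mm); must be invertible
    roi: boolean tracking mask; end_regions: two boolean masks whose
    connection defines an accepted track.
    """

    tensors: np.ndarray
    affine: np.ndarray
    roi: np.ndarray | None = None
    end_regions: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tensors.ndim != 4 or self.tensors.shape[-1] != 6:
            raise ValueError("tensors must be (nx, ny, nz, 6)")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.roi is None:
            self.roi = np.ones(self.tensors.shape[:3], dtype=bool)

    @property
    def shape(self):
        return self.tensors.shape[:3]

    @property
    def voxel_size_mm(self) -> float:
        sz = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(sz, sz[0], rtol=1e-6):
            raise ValueError("anisotropic voxel grids are not supported")
        return float(sz[0])

    def as_matrices(self) -> np.ndarray:
        """Expand to full (nx, ny, nz, 3, 3) symmetric matrices."""
        m = np.zeros(self.shape + (3, 3))
        for c, (i, j) in enumerate(_LOWER_TRI):
            m[..., i, j] = self.tensors[..., c]
            m[..., j, i] = self.tensors[..., c]
        return m

    @classmethod
    def from_matrices(cls, mats: np.ndarray, affine: np.ndarray, **kw):
        t = np.stack([mats[..., i, j] for i, j in _LOWER_TRI], axis=-1)
        return cls(tensors=t, affine=affine, **kw)

    # ---- NIfTI I/O
    def to_nifti(self, tensor_path, roi_path=None, end_paths=None) -> None:
        nib.save(nib.Nifti1Image(self.tensors, self.affine), tensor_path)
        if roi_path is not None:
            nib.save(
                nib.Nifti1Image(self.roi.astype(np.uint8), self.affine), roi_path
            )
        if end_paths is not None and self.end_regions is not None:
            for p, m in zip(end_paths, self.end_regions):
                nib.save(nib.Nifti1Image(m.astype(np.uint8), self.affine), p)

    @classmethod
    def from_nifti(cls, tensor_path, roi_path=None, end_paths=None):
        img = nib.load(tensor_path)
        roi = None
        if roi_path is not None:
            roi = np.asarray(nib.load(roi_path).dataobj).astype(bool)
        ends = None
        if end_paths is not None:
            ends = tuple(
                np.asarray(nib.load(p).dataobj).astype(bool) for p in end_paths
            )
        return cls(
            tensors=np.asarray(img.dataobj, dtype=float),
            affine=img.affine,
            roi=roi,
            end_regions=ends,
        )


@dataclass
class Track:
    """One streamline: ordered world-coordinate points (mm)."""

    points_mm: np.ndarray
    step_mm: float
    seed_voxel: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float)

    def __len__(self) -> int:
        return len(self.points_mm)

    @property
    def length_mm(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1).sum()
        )

    def tangents(self) -> np.ndarray:
        """Unit tangent at each point (central differences)."""
        d = np.gradient(self.points_mm, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass(frozen=True)
class TrackingParams:
    fa_min: float = 0.15
    angle_max_deg: float = 15.0
    step_mm: float = 0.4


def tensor_metrics(volume: TensorVolume):
    """Per-voxel FA, axial/radial diffusivity and principal direction.

    FA = sqrt( 0.5 * sum_{i<j} (li - lj)^2 / sum li^2 ); the zero tensor
    maps to FA = 0.  AD is the largest eigenvalue, RD the mean of the two
    smaller ones; the principal direction is the unit eigenvector of AD.
    """
    mats = volume.as_matrices()
    w, v = np.linalg.eigh(mats)  # ascending
    l1, l2, l3 = w[..., 2], w[..., 1], w[..., 0]
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    ad = l1
    rd = 0.5 * (l2 + l3)
    pdir = v[..., :, 2]
    return fa, ad, rd, pdir


def _world_to_voxel(points, inv_affine):
    p = np.atleast_2d(points)
    return p @ inv_affine[:3, :3].T + inv_affine[:3, 3]


def track_streamlines(
    volume: TensorVolume,
    params: TrackingParams | None = None,
    require_end_regions: bool = True,
) -> list[Track]:
    """Deterministic bidirectional Euler streamline tracking.

    Seeds at every ROI voxel center; integrates along the principal
    eigenvector with sign continuity (each step is flipped to align with
    the previous direction); terminates on FA below threshold, turning
    above threshold, or ROI exit.  By default a track is kept only if its
    two endpoints reach the two distinct end-region masks; pass
    ``require_end_regions=False`` to keep every streamline (useful when
    quantifying tracking error under noise).
    """
    params = params or TrackingParams()
    if require_end_regions and volume.end_regions is None:
        raise ValueError("tracking requires the two end-region masks")
    fa, _, _, pdir = tensor_metrics(volume)
    roi = volume.roi & (fa >= params.fa_min)
    inv_aff = np.linalg.inv(volume.affine)
    cos_max = np.cos(np.radians(params.angle_max_deg))
    if volume.end_regions is not None:
        end_a, end_b = volume.end_regions
    else:
        end_a = end_b = None
    shape = volume.shape

    def vox_of(p):
        v = np.round(_world_to_voxel(p, inv_aff)[0]).astype(int)
        return tuple(v)

    def inside(v):
        return all(0 <= v[i] < shape[i] for i in range(3))

    def march(start_mm, d0):
        """Integrate one direction; returns points after start (excl)."""
        pts = []
        p = start_mm.copy()
        d_prev = d0
        for _ in range(100000):
            p_new = p + params.step_mm * d_prev
            v = vox_of(p_new)
            if not inside(v) or not roi[v]:
                break
            d_new = pdir[v]
            if d_new @ d_prev < 0:
                d_new = -d_new
            if d_new @ d_prev < cos_max:
                break
            pts.append(p_new)
            p = p_new
            d_prev = d_new
        return pts

    seeds = np.argwhere(roi)
    tracks: list[Track] = []
    for v in seeds:
        v = tuple(v)
        seed_mm = (volume.affine[:3, :3] @ np.asarray(v, float)) + volume.affine[
            :3, 3
        ]
        d0 = pdir[v]
        fwd = march(seed_mm, d0)
        bwd = march(seed_mm, -d0)
        pts = np.array(bwd[::-1] + [seed_mm] + fwd)
        if len(pts) < 2:
            continue
        if require_end_regions:
            va, vb = vox_of(pts[0]), vox_of(pts[-1])
            hits_a = inside(va) and end_a[va]
            hits_b = inside(vb) and end_b[vb]
            hits_a_rev = inside(vb) and end_a[vb]
            hits_b_rev = inside(va) and end_b[va]
            if not ((hits_a and hits_b) or (hits_a_rev and hits_b_rev)):
                continue
        tracks.append(Track(points_mm=pts, step_mm=params.step_mm, seed_voxel=v))
    return tracks


def _cubic_refit(track: Track) -> Track:
    pts = track.points_mm
    if len(pts) < 4:
        return Track(pts.copy(), track.step_mm, track.seed_voxel)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = arc / arc[-1] if arc[-1] > 0 else arc  # conditioning
    fitted = np.column_stack(
        [np.polyval(np.polyfit(s, pts[:, k], 3), s) for k in range(3)]
    )
    return Track(fitted, track.step_mm, track.seed_voxel)


def _mean_closest_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean of closest-point distances between two polylines."""
    ta, tb = cKDTree(a), cKDTree(b)
    da, _ = tb.query(a)
    db, _ = ta.query(b)
    return 0.5 * (da.mean() + db.mean())


def smooth_and_prune(
    tracks: list[Track], voxel_mm: float, fit: bool = True
) -> list[Track]:
    """Cubic-polynomial refit plus one-voxel duplicate pruning.

    Each coordinate is least-squares refit as a cubic in normalized arc
    length (tracks with fewer than 4 points pass through unchanged).  Of
    any pair of tracks whose symmetric mean closest-point distance is
    below one voxel edge, the later-indexed track is removed; survivor
    order is preserved.
    """
    if len(tracks) == 0:
        raise ValueError("smooth_and_prune requires at least one track")
    smoothed = [_cubic_refit(t) if fit else t for t in tracks]
    keep = np.ones(len(smoothed), dtype=bool)
    for j in range(1, len(smoothed)):
        for i in range(j):
            if not keep[i]:
                continue
            d = _mean_closest_distance(
                smoothed[i].points_mm, smoothed[j].points_mm
            )
            if d < voxel_mm:
                keep[j] = False
                break
    return [t for t, k in zip(smoothed, keep) if k]


def tracks_to_tsv(tracks: list[Track], path) -> None:
    """Export as TSV: track_id, point_index, x, y, z (world mm)."""
    with open(path, "w") as fh:
        fh.write("track_id\tpoint_index\tx\ty\tz\n")
        for ti, t in enumerate(tracks):
            for pi, (x, y, z) in enumerate(t.points_mm):
                fh.write(f"{ti}\t{pi}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def tracks_from_tsv(path, step_mm: float = 0.4) -> list[Track]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("point_index")
        out.append(Track(grp[["x", "y", "z"]].to_numpy(), step_mm))
    return out
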