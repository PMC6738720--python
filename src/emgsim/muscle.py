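"""Virtual muscle construction: fibers, motor-unit territories, tensors.

Builds the simulated muscle from a fiber-direction field (interpolated
from tractography tracks or supplied analytically by the phantom):

* fiber crossing points are Sobol-seeded on a reference cross-section at a
  uniform density of 350 fibers/mm^2;
* motor-unit innervation numbers follow the exponential ladder
  y_i = y1 * exp((ln R / n) * i), spanning 21-1764 fibers over 120 units;
* territories are circles around randomly chosen crossing points whose
  in-muscle area matches innervation number / unit fiber density (25-45
  fibers/mm^2), enlarged by bisection when clipped by the muscle border;
* fibers grow from their crossing points by bidirectional 0.1 mm Euler
  steps along the direction field, terminating at the muscle boundary or
  at a 15-degree-per-step turning limit, with innervation points drawn
  from a truncated normal centred on the fiber midpoint (SD = 10% of
  length);
* muscle conductivity tensors R diag(sigma_long, sigma_trans, sigma_trans)
  R^T are aligned with the local fiber direction.

Per-unit fiber diameter (24.8-40.6 um) and conduction velocity
(3.2-5.0 m/s) increase linearly with recruitment index (size principle);
the ranges are population values, the monotone mapping is a modelling
choice documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import qmc, truncnorm
from shapely.geometry import Point, Polygon

from .mesh import TissueMesh, TISSUES
from .volume_conductor import ConductivityField, CONDUCTIVITIES_150HZ

__all__ = [
    "DirectionField",
    "InnervationDistribution",
    "FiberPath",
    "MotorUnit",
    "innervation_numbers",
    "seed_fiber_points",
    "assign_territories",
    "grow_fiber",
    "conductivity_from_field",
    "build_motor_units",
]

FIBER_STEP_MM = 0.1
MAX_TURN_DEG = 15.0
FIBER_DENSITY_PER_MM2 = 350.0
MU_DENSITY_RANGE = (25.0, 45.0)
DIAMETER_RANGE_UM = (24.8, 40.6)
VELOCITY_RANGE_M_S = (3.2, 5.0)


class DirectionField:
    """Unit fiber-direction field over the muscle volume.

    Interpolates scattered track tangent directions with normalized
    inverse-distance weighting over the k nearest samples (k=8).  Sign
    ambiguity of tangents is resolved per query by aligning each
    neighbour's vector with the first neighbour before averaging.  Exactly
    at a sample point the field reproduces that sample's tangent.  A
    callable analytic field (phantom ground truth) can be wrapped too.
    """

    def __init__(self, points_mm=None, directions=None, func=None, k: int = 8):
        if func is not None:
            self._func = func
            self._tree = None
            return
        self._func = None
        pts = np.asarray(points_mm, dtype=float)
        dirs = np.asarray(directions, dtype=float)
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        self._tree = cKDTree(pts)
        self._dirs = dirs
        self._k = min(k, len(pts))

    @classmethod
    def from_tracks(cls, tracks, k: int = 8):
        pts, dirs = [], []
        for t in tracks:
            pts.append(t.points_mm)
            dirs.append(t.tangents())
        return cls(np.concatenate(pts), np.concatenate(dirs), k=k)

    @classmethod
    def from_function(cls, func):
        return cls(func=func)

    def __call__(self, points_mm) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        if self._func is not None:
            d = np.atleast_2d(self._func(p))
        else:
            dist, idx = self._tree.query(p, k=self._k)
            dist = np.atleast_2d(dist)
            idx = np.atleast_2d(idx)
            v = self._dirs[idx]  # (n, k, 3)
            ref = v[:, :1, :]
            sgn = np.sign(np.einsum("nkj,nij->nk", v, ref))
            sgn[sgn == 0] = 1.0
            v = v * sgn[..., None]
            w = 1.0 / np.maximum(dist, 1e-12) ** 2
            exact = dist[:, 0] < 1e-9  # exactly on a sample point
            d = np.einsum("nk,nkj->nj", w, v) / w.sum(axis=1, keepdims=True)
            d[exact] = v[exact, 0]
        n = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(n < 1e-12):
            raise ValueError("direction field returned a zero vector")
        return d / n


@dataclass(frozen=True)
class InnervationDistribution:
    """Exponential innervation-number ladder across the motor pool."""

    n: int = 120
    y1: float = 21.0
    ratio: float = 84.0

    def __post_init__(self) -> None:
        if self.n < 1 or self.y1 < 1:
            raise ValueError("need n >= 1 and y1 >= 1")
        if self.ratio <= 0:
            raise ValueError("innervation ratio R must be positive")
        if self.ratio <= 1:
            raise ValueError("largest/smallest ratio R must exceed 1")


@dataclass
class FiberPath:
    """One muscle fiber: 0.1 mm polyline, crossing point, innervation arc."""

    points_mm: np.ndarray
    crossing_point_mm: np.ndarray
    innervation_arc_mm: float
    diameter_um: float = 32.7

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1).sum())

    def arc_mm(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class MotorUnit:
    """One motor unit: territory geometry plus its fiber population."""

    index: int  # recruitment order, 1-based
    innervation_number: int
    center_mm: np.ndarray  # on the reference plane (2-D)
    radius_mm: float
    conduction_velocity: float
    fiber_diameter_um: float
    fibers: list[FiberPath] = field(default_factory=list)
    crossing_points_mm: np.ndarray | None = None  # (y, fiber) plane coords


def innervation_numbers(dist: InnervationDistribution) -> np.ndarray:
    """round(y1 * exp((ln R / n) * i)) for i = 1..n (ints, increasing)."""
    i = np.arange(1, dist.n + 1)
    y = dist.y1 * np.exp((np.log(dist.ratio) / dist.n) * i)
    return np.floor(y + 0.5).astype(int)  # round half up


def seed_fiber_points(
    cross_section: Polygon,
    density_per_mm2: float = FIBER_DENSITY_PER_MM2,
    seed: int = 0,
) -> np.ndarray:
    """Sobol-distributed fiber crossing points inside a polygon.

    Low-discrepancy points are generated in the bounding box and rejected
    into the polygon until round(area * density) survive.  Deterministic
    for a given scramble seed.
    """
    if density_per_mm2 <= 0:
        raise ValueError("density must be positive")
    area = cross_section.area
    if area <= 0:
        raise ValueError("degenerate cross-section polygon")
    target = int(round(area * density_per_mm2))
    minx, miny, maxx, maxy = cross_section.bounds
    sob = qmc.Sobol(d=2, scramble=True, seed=seed)
    pts: list[np.ndarray] = []
    from shapely import contains_xy

    while sum(len(p) for p in pts) < target:
        raw = sob.random(4096)
        xy = np.column_stack(
            [
                minx + raw[:, 0] * (maxx - minx),
                miny + raw[:, 1] * (maxy - miny),
            ]
        )
        inside = contains_xy(cross_section, xy[:, 0], xy[:, 1])
        pts.append(xy[inside])
    return np.concatenate(pts)[:target]


def _clipped_circle_area(
    center: np.ndarray, radius: float, section: Polygon
) -> float:
    return Point(center).buffer(radius, quad_segs=64).intersection(section).area


def _radius_for_area(
    center: np.ndarray, target_area: float, section: Polygon
) -> float:
    """Bisection on the radius so (circle ∩ muscle) area hits the target."""
    lo = np.sqrt(target_area / np.pi)  # unclipped solution is a lower bound
    hi = lo
    diam = max(
        section.bounds[2] - section.bounds[0],
        section.bounds[3] - section.bounds[1],
    )
    for _ in range(60):
        if _clipped_circle_area(center, hi, section) >= target_area:
            break
        hi *= 1.5
        if hi > 4 * diam:
            raise ValueError(
                "territory quota unsatisfiable: required radius exceeds "
                "the muscle section"
            )
    else:
        raise ValueError("territory radius search failed to bracket")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _clipped_circle_area(center, mid, section) < target_area:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return 0.5 * (lo + hi)


def assign_territories(
    points: np.ndarray,
    dist: InnervationDistribution,
    section: Polygon,
    rng: np.random.Generator,
    mu_density_range: tuple[float, float] = MU_DENSITY_RANGE,
    unit_indices: np.ndarray | None = None,
) -> list[MotorUnit]:
    """Place circular motor-unit territories and assign fiber points.

    Centers are drawn from the crossing-point set; the territory radius is
    solved so the circle's in-muscle area equals innervation number / unit
    fiber density.  Crossing points are then attributed unit by unit: each
    unit claims its quota from the unassigned points nearest its center
    (falling back to nearest overall if its circle is underfull), then the
    remaining points go to the nearest unit with unfilled quota, so the
    union re-covers the point set.
    """
    y = innervation_numbers(dist)
    if unit_indices is None:
        unit_indices = np.arange(1, dist.n + 1)
    y = y[np.asarray(unit_indices) - 1]
    total_quota = int(y.sum())
    if total_quota > len(points):
        raise ValueError(
            f"not enough fiber points ({len(points)}) for the total "
            f"innervation quota ({total_quota})"
        )
    units: list[MotorUnit] = []
    dens = rng.uniform(*mu_density_range, size=len(y))
    centers = points[rng.integers(0, len(points), size=len(y))]
    n_total = dist.n
    for k, (idx, yk, dk) in enumerate(zip(unit_indices, y, dens)):
        frac = (idx - 1) / max(n_total - 1, 1)
        try:
            radius = _radius_for_area(centers[k], yk / dk, section)
        except ValueError as e:
            raise ValueError(f"motor unit {idx}: {e}") from e
        units.append(
            MotorUnit(
                index=int(idx),
                innervation_number=int(yk),
                center_mm=centers[k],
                radius_mm=radius,
                conduction_velocity=VELOCITY_RANGE_M_S[0]
                + frac * (VELOCITY_RANGE_M_S[1] - VELOCITY_RANGE_M_S[0]),
                fiber_diameter_um=DIAMETER_RANGE_UM[0]
                + frac * (DIAMETER_RANGE_UM[1] - DIAMETER_RANGE_UM[0]),
            )
        )

    # point attribution: each point goes to the nearest unit whose quota
    # is unfilled, resolved in rounds (overflow spills to the next-nearest
    # center; any surplus points stay unassigned, scattered at random so
    # the covered set stays uniform)
    assigned = np.full(len(points), -1, dtype=int)
    remaining = np.array([u.innervation_number for u in units])
    centers_arr = np.array([u.center_mm for u in units])
    while remaining.sum() > 0:
        free = np.flatnonzero(assigned < 0)
        if len(free) == 0:
            break
        open_units = np.flatnonzero(remaining > 0)
        d = np.linalg.norm(
            points[free][:, None, :] - centers_arr[open_units][None, :, :],
            axis=2,
        )
        nearest = open_units[np.argmin(d, axis=1)]
        for k in open_units:
            cand = free[nearest == k]
            if len(cand) > remaining[k]:
                cand = rng.permutation(cand)[: remaining[k]]
            assigned[cand] = k
            remaining[k] -= len(cand)
    for k, u in enumerate(units):
        u.crossing_points_mm = points[assigned == k]
    return units


def grow_fiber(
    seed_point_mm: np.ndarray,
    direction_field: DirectionField,
    inside_mask,
    rng: np.random.Generator,
    step_mm: float = FIBER_STEP_MM,
    max_turn_deg: float = MAX_TURN_DEG,
    max_steps: int = 5000,
    diameter_um: float = 32.7,
) -> FiberPath:
    """Grow one fiber bidirectionally from a crossing point.

    ``inside_mask`` maps (n, 3) points (mm) to a boolean in-muscle mask.
    Growth follows +/- the local field direction in fixed 0.1 mm Euler
    steps, stopping at the muscle boundary or when one step turns by more
    than 15 degrees.  The innervation point is a truncated-normal draw
    centred on the fiber midpoint with SD = 10% of fiber length.
    """
    p0 = np.asarray(seed_point_mm, dtype=float)
    if not bool(np.atleast_1d(inside_mask(p0[None]))[0]):
        raise ValueError(f"fiber seed {p0} lies outside the muscle volume")
    cos_max = np.cos(np.radians(max_turn_deg))

    def march(sign):
        pts = []
        p = p0.copy()
        d_prev = sign * direction_field(p[None])[0]
        for _ in range(max_steps):
            d = direction_field(p[None])[0]
            if d @ d_prev < 0:
                d = -d
            if d @ d_prev < cos_max:
                break
            p_new = p + step_mm * d
            if not bool(np.atleast_1d(inside_mask(p_new[None]))[0]):
                break
            pts.append(p_new)
            p = p_new
            d_prev = d
        return pts

    fwd = march(+1.0)
    bwd = march(-1.0)
    pts = np.array(bwd[::-1] + [p0] + fwd)
    if len(pts) < 2:
        raise ValueError("fiber collapsed to a point at the muscle boundary")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(seg.sum())
    mid, sd = 0.5 * length, 0.1 * length
    a, b = (0.0 - mid) / sd, (length - mid) / sd
    inn = float(truncnorm.rvs(a, b, loc=mid, scale=sd, random_state=rng))
    return FiberPath(
        points_mm=pts,
        crossing_point_mm=p0,
        innervation_arc_mm=inn,
        diameter_um=diameter_um,
    )


def build_motor_units(
    units: list[MotorUnit],
    plane_to_world,
    direction_field: DirectionField,
    inside_mask,
    rng: np.random.Generator,
) -> list[MotorUnit]:
    """Grow every fiber of every unit; returns the same units, populated.

    ``plane_to_world`` lifts 2-D reference-plane coordinates to 3-D mm.
    Crossing points that cannot grow (seed on the discrete boundary) are
    dropped; the unit keeps its remaining fibers.
    """
    for u in units:
        u.fibers = []
        for cp in u.crossing_points_mm:
            p3 = plane_to_world(cp)
            try:
                f = grow_fiber(
                    p3,
                    direction_field,
                    inside_mask,
                    rng,
                    diameter_um=u.fiber_diameter_um,
                )
            except ValueError:
                continue
            f.params_velocity = u.conduction_velocity
            u.fibers.append(f)
    return units


def conductivity_from_field(
    mesh: TissueMesh,
    direction_field: DirectionField,
    sigma_long: float = CONDUCTIVITIES_150HZ["muscle_longitudinal"],
    sigma_trans: float = CONDUCTIVITIES_150HZ["muscle_transversal"],
    isotropic_table: dict[str, float] | None = None,
) -> ConductivityField:
    """Fiber-aligned muscle conductivity tensors on a tissue mesh.

    For muscle elements the tensor is R diag(s_long, s_trans, s_trans) R^T
    with R's first column the local fiber direction at the element
    centroid; other tissues get isotropic tensors from the 150 Hz table.
    """
    table = dict(isotropic_table or {})
    table.setdefault("skin", CONDUCTIVITIES_150HZ["skin"])
    table.setdefault("fat", CONDUCTIVITIES_150HZ["fat"])
    table.setdefault("cortical_bone", CONDUCTIVITIES_150HZ["cortical_bone"])
    table.setdefault("cancellous_bone", CONDUCTIVITIES_150HZ["cancellous_bone"])
    table.setdefault("muscle", CONDUCTIVITIES_150HZ["muscle_isotropic"])
    field_ = ConductivityField.isotropic(mesh, table)
    t = field_.tensors
    m = mesh.region_labels == TISSUES["muscle"]
    if np.any(m):
        cent = mesh.element_centroids()[m]
        e1 = direction_field(cent)
        # complete an orthonormal frame around e1
        helper = np.where(
            np.abs(e1[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
        )
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
        e3 = np.cross(e1, e2)
        tm = (
            sigma_long * np.einsum("ni,nj->nij", e1, e1)
            + sigma_trans * np.einsum("ni,nj->nij", e2, e2)
            + sigma_trans * np.einsum("ni,nj->nij", e3, e3)
        )
        t[m] = tm
    return ConductivityField(t)


def units_to_csv(units: list[MotorUnit], path) -> None:
    rows = [
        {
            "index": u.index,
            "innervation_number": u.innervation_number,
            "center_x_mm": u.center_mm[0],
            "center_y_mm": u.center_mm[1],
            "radius_mm": u.radius_mm,
            "conduction_velocity_m_s": u.conduction_velocity,
            "fiber_diameter_um": u.fiber_diameter_um,
            "n_fibers_grown": len(u.fibers),
        }
        for u in units
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
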