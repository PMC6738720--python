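"""Virtual-muscle construction: ladder, seeding, territories, fibers."""

import numpy as np
import pytest
from shapely.geometry import Polygon, Point

from emgsim.muscle import (
    DirectionField,
    InnervationDistribution,
    assign_territories,
    conductivity_from_field,
    grow_fiber,
    innervation_numbers,
    seed_fiber_points,
)
from emgsim.mesh import TISSUES, box_tet_mesh
from emgsim.tractography import Track


class TestInnervationNumbers:
    def test_largest_unit_attains_full_ratio(self):
        y = innervation_numbers(InnervationDistribution())
        assert y[-1] == 21 * 84  # 1764

    def test_first_ninety_units_total(self):
        y = innervation_numbers(InnervationDistribution())
        assert y[:90].sum() == 15493  # "nearly 15,500" fibers
        assert abs(y[:90].sum() / 15500 - 1.0) < 0.01

    def test_single_unit_pool(self):
        y = innervation_numbers(InnervationDistribution(n=1))
        assert len(y) == 1 and y[0] == 21 * 84

    def test_strictly_increasing(self):
        y = innervation_numbers(InnervationDistribution())
        assert np.all(np.diff(y) >= 0)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            InnervationDistribution(ratio=-2.0)


class TestSobolSeeding:
    def test_unit_square_count(self):
        sq = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        pts = seed_fiber_points(sq, 350.0, seed=1)
        assert len(pts) == 350

    def test_quadrant_uniformity(self):
        sq = Polygon([(0, 0), (2, 0), (2, 2), (0, 2)])
        pts = seed_fiber_points(sq, 500.0, seed=2)
        for qx, qy in [(0, 0), (1, 0), (0, 1), (1, 1)]:
            frac = np.mean(
                (pts[:, 0] >= qx) & (pts[:, 0] < qx + 1)
                & (pts[:, 1] >= qy) & (pts[:, 1] < qy + 1)
            )
            assert abs(frac - 0.25) < 0.05 * 0.25 + 0.02

    def test_deterministic_given_seed(self):
        sq = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        np.testing.assert_array_equal(
            seed_fiber_points(sq, 200.0, seed=7),
            seed_fiber_points(sq, 200.0, seed=7),
        )

    def test_degenerate_polygon_rejected(self):
        line = Polygon([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError):
            seed_fiber_points(line, 100.0)


class TestTerritories:
    def test_interior_unit_radius_closed_form(self, rng):
        # y = 600 fibers at 35 fb/mm^2 -> r = sqrt(600/35/pi) ~ 2.335 mm
        big = Point(0, 0).buffer(30.0, quad_segs=64)
        pts = rng.uniform(-20, 20, size=(4000, 2))
        dist = InnervationDistribution(n=1, y1=600 / 84.0)
        units = assign_territories(
            pts, dist, big, rng, mu_density_range=(35.0, 35.0)
        )
        expect = np.sqrt(600 / 35.0 / np.pi)
        assert abs(units[0].radius_mm / expect - 1.0) < 0.01

    def test_boundary_unit_radius_compensates_clipping(self, rng):
        # center on a straight border: only a half-disc is available, so
        # the radius must grow by ~sqrt(2)
        half = Polygon([(0, -50), (50, -50), (50, 50), (0, 50)])
        pts = np.column_stack([np.zeros(800), np.linspace(-20, 20, 800)])
        dist = InnervationDistribution(n=1, y1=600 / 84.0)
        units = assign_territories(
            pts, dist, half, rng, mu_density_range=(35.0, 35.0)
        )
        interior = np.sqrt(600 / 35.0 / np.pi)
        assert abs(units[0].radius_mm / (np.sqrt(2) * interior) - 1.0) < 0.02

    def test_unsatisfiable_quota_names_unit(self, rng):
        tiny = Point(0, 0).buffer(1.0, quad_segs=16)
        pts = rng.uniform(-1, 1, size=(4000, 2))
        dist = InnervationDistribution(n=2, y1=900.0, ratio=2.0)
        with pytest.raises(ValueError, match="motor unit"):
            assign_territories(pts, dist, tiny, rng,
                               mu_density_range=(25.0, 25.0))

    def test_full_population_covers_section_uniformly(self, rng):
        # all 120 units on a section sized so the fiber count matches the
        # total innervation quota (48,082 fibers at 350 fb/mm^2): per-bin
        # coverage of assigned points deviates < 20% from the mean
        import shapely.affinity as aff

        section = aff.scale(
            Point(0, 0).buffer(1.0, quad_segs=64), 9.0, 5.0, origin=(0, 0)
        )
        pts = seed_fiber_points(section, 350.0, seed=3)
        dist = InnervationDistribution()
        units = assign_territories(pts, dist, section, rng)
        total = sum(len(u.crossing_points_mm) for u in units)
        assert total == innervation_numbers(dist).sum()
        taken = np.concatenate([u.crossing_points_mm for u in units])
        # 2 mm^2 bins (sqrt(2) mm squares) over the interior
        w = np.sqrt(2.0)
        frac_mean = total / len(pts)
        devs = []
        for bx in np.arange(-6, 6, w):
            for by in np.arange(-4, 4, w):
                def inb(p):
                    return (
                        (p[:, 0] >= bx) & (p[:, 0] < bx + w)
                        & (p[:, 1] >= by) & (p[:, 1] < by + w)
                    )
                n_all = inb(pts).sum()
                if n_all < 100:  # skip boundary slivers
                    continue
                devs.append(inb(taken).sum() / n_all / frac_mean - 1.0)
        assert len(devs) > 10
        assert np.abs(devs).max() < 0.20


class TestGrowFiber:
    def _mask_box(self, lo, hi):
        lo, hi = np.asarray(lo, float), np.asarray(hi, float)

        def mask(p):
            p = np.atleast_2d(p)
            return np.all((p >= lo) & (p <= hi), axis=1)

        return mask

    def test_uniform_field_spans_mask_chord(self, rng):
        field = DirectionField.from_function(
            lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1))
        )
        mask = self._mask_box([0, 0, 0], [30, 10, 10])
        f = grow_fiber(np.array([12.0, 5.0, 5.0]), field, mask, rng)
        assert abs(f.length_mm - 30.0) < 0.2 + 0.2
        assert np.ptp(f.points_mm[:, 1]) < 1e-9

    def test_kink_terminates_growth(self, rng):
        def func(p):
            p = np.atleast_2d(p)
            d = np.where(
                p[:, [0]] < 10.0, [[1.0, 0.0, 0.0]], [[np.cos(np.radians(20)),
                                                       np.sin(np.radians(20)), 0.0]]
            )
            return d

        field = DirectionField.from_function(func)
        mask = self._mask_box([0, -20, -1], [30, 20, 1])
        f = grow_fiber(np.array([5.0, 0.0, 0.0]), field, mask, rng)
        assert f.points_mm[:, 0].max() <= 10.0 + 0.2

    def test_innervation_arc_distribution(self, rng):
        # truncated normal about the midpoint, SD 10% of length
        from scipy.stats import truncnorm

        L = 40.0
        a, b = (0 - L / 2) / (0.1 * L), (L / 2) / (0.1 * L)
        draws = truncnorm.rvs(
            a, b, loc=L / 2, scale=0.1 * L, size=10000, random_state=rng
        )
        assert np.all((draws >= 0) & (draws <= L))
        assert 0.09 * L <= draws.std() <= 0.11 * L

    def test_innervation_arc_within_fiber(self, rng):
        field = DirectionField.from_function(
            lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1))
        )
        mask = self._mask_box([0, 0, 0], [25, 10, 10])
        for _ in range(20):
            f = grow_fiber(np.array([10.0, 5.0, 5.0]), field, mask, rng)
            assert 0.0 <= f.innervation_arc_mm <= f.length_mm

    def test_seed_outside_mask_rejected(self, rng):
        field = DirectionField.from_function(
            lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1))
        )
        mask = self._mask_box([0, 0, 0], [10, 10, 10])
        with pytest.raises(ValueError):
            grow_fiber(np.array([50.0, 5.0, 5.0]), field, mask, rng)

    def test_max_turning_respected_on_phantom(self, phantom_rest, rng):
        ph = phantom_rest
        f = grow_fiber(
            ph.plane_to_world([10.0, 13.0]), ph.direction_field,
            ph.inside_belly, rng
        )
        t = np.diff(f.points_mm, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        cos = np.clip(np.einsum("ij,ij->i", t[:-1], t[1:]), -1, 1)
        assert np.degrees(np.arccos(cos)).max() <= 15.0 + 1e-6


class TestDirectionField:
    def test_reproduces_track_tangents(self):
        ts = np.linspace(0, 1, 60)
        tracks = []
        for off in (0.0, 4.0, 8.0):
            pts = np.column_stack(
                [30 * ts, off + 2 * np.sin(2 * ts), np.full(60, off)]
            )
            tracks.append(Track(points_mm=pts, step_mm=0.5))
        field = DirectionField.from_tracks(tracks)
        for t in tracks:
            d = field(t.points_mm[10:50])
            gt = t.tangents()[10:50]
            cos = np.abs(np.sum(d * gt, axis=1))
            assert np.degrees(np.arccos(np.clip(cos, 0, 1))).max() < 1.0

    def test_returns_unit_vectors(self):
        field = DirectionField(
            points_mm=np.random.default_rng(0).uniform(0, 10, (50, 3)),
            directions=np.random.default_rng(1).normal(size=(50, 3)),
        )
        d = field(np.random.default_rng(2).uniform(0, 10, (20, 3)))
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)


class TestConductivityFromField:
    def _mesh(self):
        m = box_tet_mesh((10, 6, 6), 2.0)
        return m

    def test_axis_aligned_field_gives_diagonal_tensor(self):
        m = self._mesh()
        field = DirectionField.from_function(
            lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1))
        )
        cf = conductivity_from_field(m, field)
        np.testing.assert_allclose(
            cf.tensors,
            np.broadcast_to(np.diag([0.40, 0.09, 0.09]), cf.tensors.shape),
            atol=1e-15,
        )

    def test_eigenvalues_invariant_under_rotation(self):
        m = self._mesh()
        d = np.array([0.3, -0.5, 0.8])
        d /= np.linalg.norm(d)
        field = DirectionField.from_function(lambda p: np.tile(d, (len(p), 1)))
        cf = conductivity_from_field(m, field)
        w = np.sort(np.linalg.eigvalsh(cf.tensors), axis=1)
        np.testing.assert_allclose(
            w, np.broadcast_to([0.09, 0.09, 0.40], w.shape), atol=1e-12
        )

    def test_trace_is_conserved(self):
        m = self._mesh()
        field = DirectionField.from_function(
            lambda p: np.tile([0.6, 0.8, 0.0], (len(p), 1))
        )
        cf = conductivity_from_field(m, field)
        np.testing.assert_allclose(
            np.trace(cf.tensors, axis1=1, axis2=2), 0.58, atol=1e-12
        )

    def test_non_muscle_elements_stay_isotropic(self, phantom_rest):
        ph = phantom_rest
        cf = conductivity_from_field(ph.mesh, ph.direction_field)
        fat = ph.mesh.region_labels == TISSUES["fat"]
        np.testing.assert_allclose(
            cf.tensors[fat],
            np.broadcast_to(4.07e-2 * np.eye(3), cf.tensors[fat].shape),
            atol=1e-15,
        )
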