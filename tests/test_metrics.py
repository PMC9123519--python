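import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conemetrics import (ParameterError, ROI, RoiTransform,
                         UndefinedMetricError, colocalize_roi,
                         compute_metrics, density_to_spacing, icd_mean,
                         nnd_mean, spacing_to_density, voronoi_bound_density)
from conemetrics.synthetic import hex_lattice
from oracles import density_oracle, icd_oracle, nnd_oracle


def _random_pattern(seed, n=None):
    rng = np.random.default_rng(seed)
    n = n or rng.integers(15, 41)
    return rng.uniform(0, 100, (int(n), 2)), ROI(origin=(20, 20), size=(60, 60))


class TestHexClosedForms:
    @pytest.mark.parametrize("s", [5.0, 8.0, 10.0, 12.0])
    def test_density_nnd_icd_on_perfect_lattice(self, s):
        pts = hex_lattice(s, (40 * s, 40 * s))
        roi = ROI(origin=(10 * s, 10 * s), size=(20 * s, 20 * s))
        density, n_bound = voronoi_bound_density(pts, roi)
        assert density == pytest.approx(2.0e6 / (np.sqrt(3) * s ** 2), rel=5e-3)
        assert n_bound > 0
        assert nnd_mean(pts, roi) == pytest.approx(s, rel=5e-3)
        assert icd_mean(pts, roi) == pytest.approx(s, rel=5e-3)

    def test_reported_mean_density_recovered_from_lattice(self):
        d = 12375.0
        s = density_to_spacing(d)
        pts = hex_lattice(s, (400.0, 400.0))
        roi = ROI(origin=(100.0, 100.0), size=(200.0, 200.0))
        density, _ = voronoi_bound_density(pts, roi)
        assert density == pytest.approx(d, rel=5e-3)

    def test_central_cell_of_hex_ring_has_icd_equal_spacing(self):
        s = 7.0
        ring = [(s * np.cos(a), s * np.sin(a))
                for a in np.deg2rad(np.arange(0, 360, 60))]
        pts = np.array([(0.0, 0.0)] + ring)
        roi = ROI(origin=(-s, -s), size=(2 * s, 2 * s))
        assert icd_mean(pts, roi) == pytest.approx(s, rel=1e-9)


class TestNnd:
    def test_collinear_hand_enumeration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        roi = ROI(origin=(-1, -1), size=(5, 2))
        assert nnd_mean(pts, roi) == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_kdtree_equals_exhaustive_search(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 200, (500, 2))
        roi = ROI(origin=(0, 0), size=(200, 200))
        assert nnd_mean(pts, roi) == pytest.approx(
            nnd_oracle(pts, roi.bounds), rel=1e-12)

    def test_neighbors_outside_roi_count(self):
        pts = np.array([[10.0, 10.0], [10.5, 25.0]])
        roi = ROI(origin=(0, 0), size=(20, 20))  # second point outside
        assert nnd_mean(pts, roi) == pytest.approx(np.hypot(0.5, 15.0))

    def test_single_point_rejected(self):
        with pytest.raises(UndefinedMetricError):
            nnd_mean(np.array([[1.0, 1.0]]), ROI())


class TestBoundDensity:
    def test_oracle_equivalence_random_patterns(self):
        for seed in (0, 1, 2):
            pts, roi = _random_pattern(seed)
            try:
                density, n_bound = voronoi_bound_density(pts, roi)
            except UndefinedMetricError:
                continue
            d_ref, n_ref = density_oracle(pts, roi.bounds)
            assert n_bound == n_ref
            assert density == pytest.approx(d_ref, rel=1e-9)
            assert icd_mean(pts, roi) == pytest.approx(
                icd_oracle(pts, roi.bounds), rel=1e-9)

    def test_too_few_points_rejected(self):
        roi = ROI(origin=(0, 0), size=(10, 10))
        with pytest.raises(UndefinedMetricError):
            voronoi_bound_density(np.array([[1.0, 1.0], [2.0, 2.0]]), roi)

    def test_collinear_points_rejected(self):
        roi = ROI(origin=(0, 0), size=(10, 10))
        pts = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        with pytest.raises(UndefinedMetricError):
            voronoi_bound_density(pts, roi)

    def test_all_cells_unbounded_rejected(self):
        # a small triangle has no finite interior cell
        roi = ROI(origin=(0, 0), size=(10, 10))
        pts = np.array([[2.0, 2.0], [8.0, 2.0], [5.0, 8.0]])
        with pytest.raises(UndefinedMetricError):
            voronoi_bound_density(pts, roi)


class TestInvariances:
    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_nnd_never_exceeds_icd(self, seed):
        # the nearest neighbor is always a Voronoi neighbor
        pts, roi = _random_pattern(seed, n=40)
        try:
            icd = icd_mean(pts, roi)
        except UndefinedMetricError:
            return
        assert nnd_mean(pts, roi) <= icd + 1e-12

    @given(st.floats(-50, 50), st.floats(-50, 50),
           st.integers(0, 3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, tx, ty, quarter_turns):
        # quarter-turns about the ROI center map the square ROI onto itself,
        # so metrics must be invariant under rotation + translation
        pts, roi = _random_pattern(123, n=30)
        base = compute_metrics(pts, roi)
        center = np.array(roi.center)
        moved = pts - center
        for _ in range(quarter_turns):
            moved = np.column_stack([-moved[:, 1], moved[:, 0]])
        moved = moved + center + np.array([tx, ty])
        moved_roi = ROI(origin=(roi.origin[0] + tx, roi.origin[1] + ty),
                        size=roi.size)
        m = compute_metrics(moved, moved_roi)
        assert m.bound_density == pytest.approx(base.bound_density, rel=1e-9)
        assert m.nnd_mean == pytest.approx(base.nnd_mean, rel=1e-9)
        assert m.icd_mean == pytest.approx(base.icd_mean, rel=1e-9)

    @pytest.mark.parametrize("k", [0.5, 2.0, 3.7])
    def test_scale_equivariance(self, k):
        pts, roi = _random_pattern(7, n=35)
        base = compute_metrics(pts, roi)
        scaled_roi = ROI(origin=(roi.origin[0] * k, roi.origin[1] * k),
                         size=(roi.size[0] * k, roi.size[1] * k))
        m = compute_metrics(pts * k, scaled_roi)
        assert m.nnd_mean == pytest.approx(k * base.nnd_mean, rel=1e-9)
        assert m.icd_mean == pytest.approx(k * base.icd_mean, rel=1e-9)
        assert m.bound_density == pytest.approx(base.bound_density / k ** 2,
                                                rel=1e-9)

    def test_dropout_does_not_inflate_density(self):
        from conemetrics import generate_mosaic
        density = 12000.0
        roi = ROI(origin=(50, 50), size=(150, 150))
        vals = []
        for seed in range(5):
            mosaic = generate_mosaic(density, (250.0, 250.0),
                                     dropout_frac=0.2, seed=seed)
            vals.append(voronoi_bound_density(mosaic.points, roi)[0])
        assert np.mean(vals) < density


class TestSpacingConversions:
    @pytest.mark.parametrize("d,s", [(11547.005383792515, 10.0),
                                     (15528.0, 8.6234),
                                     (12375.0, 9.6597)])
    def test_density_spacing_pairs(self, d, s):
        assert density_to_spacing(d) == pytest.approx(s, abs=2e-4)
        assert spacing_to_density(density_to_spacing(d)) == pytest.approx(
            d, rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ParameterError):
            density_to_spacing(0.0)
        with pytest.raises(ParameterError):
            spacing_to_density(-1.0)


class TestColocalizeRoi:
    def test_identity_transform(self):
        roi = ROI(origin=(10, 20), size=(200, 200))
        out = colocalize_roi(roi, RoiTransform())
        assert out.origin == roi.origin and out.size == roi.size

    def test_pure_translation(self):
        roi = ROI(origin=(10, 20), size=(200, 200))
        t = RoiTransform(matrix=((1, 0, 50.0), (0, 1, -30.0)))
        out = colocalize_roi(roi, t)
        assert out.origin == pytest.approx((60.0, -10.0))
        assert out.size == roi.size

    def test_small_scale_mismatch_displaces_center_proportionally(self):
        # a 0.3% scale difference between modalities moves the center by
        # at most 0.3% of its norm
        roi = ROI(origin=(400, 300), size=(200, 200))
        t = RoiTransform(matrix=((1.003, 0, 0), (0, 1.003, 0)))
        out = colocalize_roi(roi, t)
        shift = np.hypot(out.center[0] - roi.center[0],
                         out.center[1] - roi.center[1])
        assert shift <= 0.003 * np.hypot(*roi.center) + 1e-9
        assert out.size == roi.size

    def test_singular_transform_rejected(self):
        with pytest.raises(ParameterError):
            colocalize_roi(ROI(), RoiTransform(matrix=((1, 0, 0), (1, 0, 0))))


def test_vertex_on_roi_boundary_counts_as_inside():
    # place the ROI's right edge exactly on a cell vertex: under the closed
    # boundary rule that cell stays bound; nudging the edge inward by one
    # ulp-scale step drops it
    from scipy.spatial import Voronoi

    from conemetrics.metrics import bound_cells

    pts, _ = _random_pattern(42, n=30)
    vor = Voronoi(pts)
    center = pts.mean(axis=0)
    order = np.argsort(np.linalg.norm(pts - center, axis=1))
    i = next(i for i in order
             if -1 not in vor.regions[vor.point_region[i]]
             and len(vor.regions[vor.point_region[i]]) >= 3)
    verts = vor.vertices[vor.regions[vor.point_region[i]]]
    x_edge = float(verts[:, 0].max())
    roi = ROI(origin=(0.0, 0.0), size=(x_edge, 100.0))
    idx, _ = bound_cells(pts, roi)
    assert i in idx
    roi_tight = ROI(origin=(0.0, 0.0), size=(np.nextafter(x_edge, 0.0), 100.0))
    idx_tight, _ = bound_cells(pts, roi_tight)
    assert i not in idx_tight
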