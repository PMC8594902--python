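import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesobrush import fixtures as fx
from mesobrush.geometry import (
    Circle,
    Contour,
    GeometryError,
    Polygon,
    Rect,
    eigen_frame,
    extract_contour,
    graham_hull,
    mean_shift_clusters,
    orientation,
    polygon_area,
    select_collider,
    triangulate,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_cov_eigvals(pts):
    """Closed-form eigenvalues of the 2x2 vertex covariance."""
    d = pts - pts.mean(axis=0)
    sxx = (d[:, 0] ** 2).mean()
    syy = (d[:, 1] ** 2).mean()
    sxy = (d[:, 0] * d[:, 1]).mean()
    tr, det = sxx + syy, sxx * syy - sxy**2
    disc = np.sqrt(max(tr**2 / 4 - det, 0.0))
    return tr / 2 + disc, tr / 2 - disc


def connected_components(points, cutoff):
    """Union-find components with edges at pairwise distance < cutoff."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) < cutoff:
                parent[find(i)] = find(j)
    roots = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    return sorted(sorted(v) for v in roots.values())


# ---------------------------------------------------------------------------
# extract_contour
# ---------------------------------------------------------------------------

class TestExtractContour:
    def test_disc_radius(self):
        contour = extract_contour(fx.disc_mask(5), 1.0)
        radii = np.linalg.norm(contour.vertices, axis=1)
        assert radii.max() == pytest.approx(5.0, abs=0.8)
        assert radii.min() > 3.5

    def test_bar_aspect(self):
        contour = extract_contour(fx.bar_mask(20, 2), 1.0)
        ext = contour.vertices.max(axis=0) - contour.vertices.min(axis=0)
        assert ext[0] / ext[1] == pytest.approx(10.0, rel=0.35)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_blob_area_matches_pixel_count(self, seed):
        mask = fx.blob_mask(seed)
        scale = 0.5
        contour = extract_contour(mask, scale)
        assert contour.area() == pytest.approx(mask.sum() * scale**2, rel=0.10)

    def test_counter_clockwise_and_centered(self):
        contour = extract_contour(fx.disc_mask(6), 2.0)
        assert polygon_area(contour.vertices) > 0
        assert np.allclose(contour.centroid, 0.0, atol=1e-9)

    def test_largest_component_only(self):
        mask = np.zeros((30, 30))
        mask[2:20, 2:20] = 1
        mask[25:27, 25:27] = 1
        contour = extract_contour(mask, 1.0)
        assert contour.area() > 100

    def test_empty_mask(self):
        with pytest.raises(GeometryError, match="no opaque"):
            extract_contour(np.zeros((5, 5)), 1.0)

    def test_bad_scale(self):
        with pytest.raises(GeometryError):
            extract_contour(fx.disc_mask(3), 0.0)


# ---------------------------------------------------------------------------
# eigen_frame
# ---------------------------------------------------------------------------

class TestEigenFrame:
    def test_circle_isotropy(self, unit_circle_contour):
        f = eigen_frame(unit_circle_contour)
        assert abs(f.eigenvalues[0] - f.eigenvalues[1]) < 1e-6

    def test_ellipse_ratio_and_axis(self, ellipse_4_1):
        f = eigen_frame(ellipse_4_1)
        assert f.ratio == pytest.approx(16.0, rel=0.01)
        assert np.allclose(f.axes[0], [1.0, 0.0], atol=1e-9)

    def test_rotated_square_matches_hand_oracle(self):
        square = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=float)
        th = np.radians(30)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = square @ rot.T
        f = eigen_frame(Contour(pts))
        lam1, lam2 = brute_cov_eigvals(pts)
        assert f.eigenvalues[0] == pytest.approx(lam1, abs=1e-12)
        assert f.eigenvalues[1] == pytest.approx(lam2, abs=1e-12)

    def test_axes_orthonormal_and_center(self, ellipse_4_1):
        f = eigen_frame(ellipse_4_1)
        assert np.allclose(f.axes @ f.axes.T, np.eye(2), atol=1e-12)
        assert np.allclose(f.center, ellipse_4_1.centroid)

    @given(theta=st.floats(0, 2 * np.pi))
    @settings(max_examples=40, deadline=None)
    def test_rotation_equivariance(self, theta):
        base = fx.ellipse_contour(3.0, 1.0, n=48)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        f0 = eigen_frame(base)
        f1 = eigen_frame(Contour(base.vertices @ rot.T))
        assert np.allclose(np.sort(f0.eigenvalues), np.sort(f1.eigenvalues),
                           atol=1e-9)
        rotated_major = rot @ f0.axes[0]
        assert abs(abs(rotated_major @ f1.axes[0]) - 1.0) < 1e-9

    def test_degenerate_collinear_warns(self):
        pts = np.column_stack([np.linspace(0, 10, 8), np.zeros(8)])
        with pytest.warns(UserWarning, match="degenerate"):
            f = eigen_frame(Contour(pts, closed=False))
        assert f.eigenvalues[1] > 0


# ---------------------------------------------------------------------------
# select_collider
# ---------------------------------------------------------------------------

class TestSelectCollider:
    def test_isotropic_gives_circle(self, unit_circle_contour):
        f = eigen_frame(unit_circle_contour)
        shape = select_collider(f, unit_circle_contour)
        assert isinstance(shape, Circle)
        assert shape.radius == pytest.approx(1.0, rel=1e-6)

    def test_elongated_gives_rect(self, ellipse_4_1):
        f = eigen_frame(ellipse_4_1)
        shape = select_collider(f, ellipse_4_1)
        assert isinstance(shape, Rect)
        assert shape.width == pytest.approx(8.0, rel=1e-6)
        assert shape.height == pytest.approx(2.0, rel=1e-6)

    def test_sweep_flips_exactly_at_threshold(self):
        threshold = 1.15
        ratios = np.round(np.arange(1.0, 2.0001, 0.005), 9)
        decisions = []
        for r in ratios:
            c = fx.ellipse_contour(np.sqrt(r), 1.0, n=256)
            shape = select_collider(eigen_frame(c), c, threshold=threshold)
            decisions.append(isinstance(shape, Rect))
        first_rect = ratios[int(np.argmax(decisions))]
        # oracle: direct ratio comparison on the same grid
        oracle_first = ratios[int(np.argmax(ratios >= threshold))]
        assert first_rect == oracle_first == pytest.approx(1.15)

    @pytest.mark.parametrize("scale", [0.1, 1.0, 37.5])
    def test_scale_equivariance(self, scale):
        base = fx.ellipse_contour(2.0, 1.0, n=64)
        scaled = Contour(base.vertices * scale)
        s0 = select_collider(eigen_frame(base), base)
        s1 = select_collider(eigen_frame(scaled), scaled)
        assert type(s0) is type(s1)
        assert s1.width == pytest.approx(s0.width * scale, rel=1e-9)
        assert s1.height == pytest.approx(s0.height * scale, rel=1e-9)

    def test_difference_mode_is_scale_sensitive(self):
        base = fx.ellipse_contour(2.0, 1.0, n=64)
        small = Contour(base.vertices * 0.1)
        s_big = select_collider(eigen_frame(base), base, mode="difference")
        s_small = select_collider(eigen_frame(small), small, mode="difference")
        assert isinstance(s_big, Rect)
        assert isinstance(s_small, Circle)


# ---------------------------------------------------------------------------
# graham_hull
# ---------------------------------------------------------------------------

class TestGrahamHull:
    def test_interior_point_excluded(self):
        pts = np.array([[0, 0], [4, 0], [4, 4], [0, 4], [2, 2]], dtype=float)
        hull = graham_hull(pts)
        assert len(hull.vertices) == 4
        assert polygon_area(hull.vertices) == pytest.approx(16.0)

    def test_random_points_inside_hull(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(100, 2))
        hull = graham_hull(pts)
        v = hull.vertices
        # all-pairs half-plane oracle: every point left of every CCW edge
        for i in range(len(v)):
            edge = v[(i + 1) % len(v)] - v[i]
            rel = pts - v[i]
            cross = edge[0] * rel[:, 1] - edge[1] * rel[:, 0]
            assert (cross >= -1e-9).all()

    def test_convex_input_is_fixed_point(self):
        pts = fx.ellipse_contour(3.0, 2.0, n=16).vertices
        hull = graham_hull(pts)
        assert len(hull.vertices) == 16
        hull2 = graham_hull(hull.vertices)
        assert len(hull2.vertices) == len(hull.vertices)
        assert polygon_area(hull2.vertices) == pytest.approx(
            polygon_area(hull.vertices))

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(GeometryError, match="collinear|hull"):
            graham_hull(pts)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            graham_hull(np.array([[0.0, 0.0], [1.0, 1.0]]))


# ---------------------------------------------------------------------------
# mean_shift_clusters
# ---------------------------------------------------------------------------

class TestMeanShift:
    def test_single_point(self):
        assert mean_shift_clusters(np.array([[1.0, 2.0]]), 8.0) == [[0]]

    def test_two_groups_far_apart(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [30, 0], [31, 0], [30, 1]],
                       dtype=float)
        clusters = mean_shift_clusters(pts, bandwidth=8.0)
        assert sorted(sorted(c) for c in clusters) == connected_components(pts, 8.0)
        assert len(clusters) == 2

    def test_two_groups_close_merge(self):
        pts = np.array([[0, 0], [1, 0], [4, 0], [5, 0]], dtype=float)
        clusters = mean_shift_clusters(pts, bandwidth=8.0)
        assert len(clusters) == 1
        assert connected_components(pts, 8.0) == [[0, 1, 2, 3]]

    def test_infinite_bandwidth_single_cluster(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-50, 50, size=(20, 2))
        assert len(mean_shift_clusters(pts, bandwidth=1e9)) == 1

    def test_tiny_bandwidth_one_cluster_per_point(self):
        pts = np.array([[0, 0], [5, 5], [10, 0]], dtype=float)
        assert len(mean_shift_clusters(pts, bandwidth=1e-6)) == 3

    def test_every_point_assigned_once(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 40, size=(30, 2))
        clusters = mean_shift_clusters(pts, bandwidth=8.0)
        flat = sorted(i for c in clusters for i in c)
        assert flat == list(range(30))


# ---------------------------------------------------------------------------
# triangulate / orientation
# ---------------------------------------------------------------------------

class TestTriangulate:
    def test_convex_quad(self):
        quad = Contour(np.array([[0, 0], [3, 0], [3, 2], [0, 2]], dtype=float))
        tris = triangulate(quad)
        assert len(tris) == 2

    def test_l_shape_area_conserved(self):
        hexagon = Contour(np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2],
                                    [0, 2]], dtype=float))
        tris = triangulate(hexagon)
        assert len(tris) == 4
        total = sum(abs(polygon_area(t)) for t in tris)
        assert total == pytest.approx(abs(polygon_area(hexagon.vertices)),
                                      rel=1e-12)

    def test_triangle_identity(self):
        tri = Contour(np.array([[0, 0], [1, 0], [0, 1]], dtype=float))
        out = triangulate(tri)
        assert len(out) == 1
        assert abs(polygon_area(out[0])) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_star_polygons_area(self, seed):
        poly = fx.blob_contour(seed, n=40)
        tris = triangulate(poly)
        assert len(tris) == len(poly.vertices) - 2
        total = sum(abs(polygon_area(t)) for t in tris)
        assert total == pytest.approx(poly.area(), rel=1e-6)

    def test_self_intersecting_fails(self):
        bowtie = Contour(np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float))
        with pytest.raises(GeometryError, match="triangulation failed"):
            triangulate(bowtie)


class TestOrientation:
    def test_ccw_square(self):
        sq = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))
        assert orientation(sq) == "counter-clockwise"

    def test_reversed_is_cw(self):
        sq = Contour(np.array([[0, 1], [1, 1], [1, 0], [0, 0]], dtype=float))
        assert orientation(sq) == "clockwise"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_shoelace_oracle(self, seed):
        poly = fx.blob_contour(seed, n=30)
        verts = poly.vertices if seed % 2 == 0 else poly.vertices[::-1]
        expected = "counter-clockwise" if polygon_area(verts) > 0 else "clockwise"
        assert orientation(Contour(verts)) == expected

    def test_zero_area_degenerate(self):
        pts = np.array([[0, 0], [1, 0], [2, 0], [1, 0.0]])
        with pytest.raises(GeometryError):
            orientation(Contour(np.array([[0, 0], [1, 1e-15], [2, 0]])))


class TestContourInvariants:
    def test_duplicate_points_rejected(self):
        with pytest.raises(GeometryError, match="duplicate"):
            Contour(np.array([[0, 0], [0, 0], [1, 1], [0, 1]], dtype=float))

    def test_too_few_vertices(self):
        with pytest.raises(GeometryError):
            Contour(np.array([[0, 0], [1, 1]], dtype=float))
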