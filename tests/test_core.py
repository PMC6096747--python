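import numpy as np
import pytest

from tubegeom.core import (Centerline, Contour, ContourStack, assign_theta,
                           build_centerline, build_surface, centerline_tangents,
                           compute_centroid, polyline_length)
from tubegeom.errors import (DegenerateCenterlineError, InvalidContourError,
                             OutOfDomainError, ZeroRadiusError)

from conftest import (circle_points, random_rigid_motion, straight_tube_stack,
                      straight_tube_surface, transform_stack)


class TestComputeCentroid:
    def test_uniform_circle(self):
        pts = circle_points((0, 0, 0), 1.0, 360)
        np.testing.assert_allclose(compute_centroid(pts), [0, 0, 0], atol=1e-14)

    def test_square_corners(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [2, 4, 0], [0, 4, 0]], dtype=float)
        pts += np.array([0.0, 0.0, 3.0])
        np.testing.assert_allclose(compute_centroid(pts), [1, 2, 3])

    def test_three_points_on_circle(self):
        # polar angles 0, pi/2, pi on the unit circle: mean y is (0+1+0)/3
        pts = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0]], dtype=float)
        np.testing.assert_allclose(compute_centroid(pts), [0, 1 / 3, 0])

    def test_too_few_points(self):
        with pytest.raises(InvalidContourError):
            compute_centroid([[0, 0, 0], [1, 0, 0]])

    def test_nonfinite(self):
        with pytest.raises(InvalidContourError):
            compute_centroid([[0, 0, 0], [1, 0, 0], [np.nan, 0, 0]])


class TestBuildCenterline:
    def test_sigma_from_first_node(self):
        stack = straight_tube_stack(n=5, spacing=10.0)
        cl = build_centerline(stack, 0)
        np.testing.assert_allclose(cl.sigma_of_node, [0, 10, 20, 30, 40], atol=1e-9)

    def test_sigma_from_interior_node(self):
        stack = straight_tube_stack(n=5, spacing=10.0)
        cl = build_centerline(stack, 2)
        np.testing.assert_allclose(cl.sigma_of_node, [-20, -10, 0, 10, 20], atol=1e-9)

    def test_l_shaped_path(self):
        # two 10 mm legs; total sigma span is the summed polyline length
        centers = [(0, 0, 0), (0, 0, 10), (10, 0, 10)]
        normals = [(0, 0, 1), (0, 0, 1), (1, 0, 0)]
        contours = []
        for i, (c, nrm) in enumerate(zip(centers, normals)):
            u = np.array([1.0, 0, 0]) if nrm[2] else np.array([0.0, 0, 1])
            v = np.cross(nrm, u)
            contours.append(Contour.from_points(i, circle_points(c, 2.0, 24, u, v)))
        cl = build_centerline(ContourStack(contours), 0)
        assert cl.sigma_of_node[-1] == pytest.approx(20.0, abs=1e-9)

    def test_origin_out_of_range(self):
        stack = straight_tube_stack()
        with pytest.raises(IndexError):
            build_centerline(stack, 99)

    def test_coincident_centroids_rejected(self):
        pts = circle_points((0, 0, 0), 5.0, 12)
        with pytest.raises(DegenerateCenterlineError):
            ContourStack([pts, pts.copy()])

    def test_sigma_additivity(self):
        stack = straight_tube_stack(n=8, spacing=7.5)
        cl = build_centerline(stack, 3)
        for i in range(stack.n):
            for j in range(i + 1, stack.n):
                seg = polyline_length(cl.nodes[i:j + 1])
                assert cl.sigma_of_node[j] - cl.sigma_of_node[i] == pytest.approx(seg, abs=1e-9)


class TestAssignTheta:
    def make(self):
        contour = Contour.from_points(0, circle_points((0, 0, 0), 5.0, 36))
        return contour

    def test_quarter_turn(self):
        contour = self.make()
        theta = assign_theta(contour, contour.points[0], (0, 0, 1))
        j = 9  # point at polar angle pi/2
        assert theta[j] == pytest.approx(np.pi / 2)

    def test_greenwich_is_zero(self):
        contour = self.make()
        theta = assign_theta(contour, contour.points[0], (0, 0, 1))
        assert theta[0] == 0.0

    def test_flipped_tangent_reverses_handedness(self):
        contour = self.make()
        theta = assign_theta(contour, contour.points[0], (0, 0, -1))
        assert theta[9] == pytest.approx(3 * np.pi / 2)

    def test_point_on_centroid_rejected(self):
        pts = circle_points((0, 0, 0), 5.0, 12)
        pts[3] = [0, 0, 0]  # exactly at the (stated) centroid
        contour = Contour(index=0, points=pts, centroid=np.zeros(3),
                          plane_normal=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ZeroRadiusError):
            assign_theta(contour, pts[0], (0, 0, 1))


class TestSurfaceEvaluation:
    def test_stored_samples_exact(self):
        _, _, surface = straight_tube_surface()
        for i in range(surface.n):
            for j in range(len(surface.theta_samples[i])):
                r = surface.evaluate(surface.sigma_grid[i], surface.theta_samples[i][j])
                assert r == surface.radii[i][j]

    def test_constant_radius_everywhere(self):
        _, _, surface = straight_tube_surface(radius=10.0)
        rng = np.random.default_rng(0)
        for sigma in rng.uniform(0, 40, 10):
            for theta in rng.uniform(-10, 10, 5):
                assert surface.evaluate(sigma, theta) == pytest.approx(10.0, abs=1e-9)

    def test_linear_in_sigma(self):
        c0 = circle_points((0, 0, 0), 10.0, 36)
        c1 = circle_points((0, 0, 10), 20.0, 36)
        stack = ContourStack([c0, c1])
        cl = build_centerline(stack, 0)
        surface = build_surface(stack, cl, np.array([c0[0], c1[0]]))
        for theta in (0.0, 1.0, 4.0):
            assert surface.evaluate(5.0, theta) == pytest.approx(15.0, abs=1e-9)

    def test_out_of_domain(self):
        _, _, surface = straight_tube_surface()
        with pytest.raises(OutOfDomainError):
            surface.evaluate(41.0, 0.0)
        with pytest.raises(OutOfDomainError):
            surface.evaluate(-1.0, 0.0)

    def test_theta_wraps(self):
        _, _, surface = straight_tube_surface()
        a = surface.evaluate(5.0, 0.3)
        b = surface.evaluate(5.0, 0.3 + 2 * np.pi)
        assert a == pytest.approx(b, abs=1e-12)


class TestSurfacePoint:
    def test_round_trip_stored_points(self):
        _, _, surface = straight_tube_surface()
        for i in range(surface.n):
            for j in range(len(surface.theta_samples[i])):
                p = surface.point(surface.sigma_grid[i], surface.theta_samples[i][j])
                np.testing.assert_allclose(p, surface.points[i][j], atol=1e-9)

    def test_cylinder_axis_ray(self):
        _, _, surface = straight_tube_surface(radius=10.0, z0=2.0)
        p = surface.point(5.0, 0.0)
        np.testing.assert_allclose(p, [10.0, 0.0, 7.0], atol=1e-9)

    def test_midpoint_between_identical_contours(self):
        _, _, surface = straight_tube_surface(radius=10.0, m=24)
        theta = surface.theta_samples[0][5]
        p0 = surface.points[0][5]
        p1 = surface.points[1][5]
        p = surface.point(5.0, theta)
        np.testing.assert_allclose(p, (p0 + p1) / 2, atol=1e-9)


class TestRigidMotionEquivariance:
    def test_sigma_theta_r_invariant(self):
        stack, cl, surface = straight_tube_surface(m=24)
        rng = np.random.default_rng(42)
        R, t = random_rigid_motion(rng)
        stack2 = transform_stack(stack, R, t)
        cl2 = build_centerline(stack2, 0)
        gamma2 = np.array([c.points[0] for c in stack2])
        surface2 = build_surface(stack2, cl2, gamma2)
        np.testing.assert_allclose(cl2.sigma_of_node, cl.sigma_of_node, atol=1e-9)
        for i in range(surface.n):
            np.testing.assert_allclose(surface2.theta_samples[i],
                                       surface.theta_samples[i], atol=1e-9)
            np.testing.assert_allclose(surface2.radii[i], surface.radii[i], atol=1e-9)
        # surface points transform with the same motion
        p = surface.point(12.0, 1.1)
        p2 = surface2.point(12.0, 1.1)
        np.testing.assert_allclose(p2, p @ R.T + t, atol=1e-9)

    def test_centroids_transform(self):
        stack = straight_tube_stack()
        rng = np.random.default_rng(7)
        R, t = random_rigid_motion(rng)
        stack2 = transform_stack(stack, R, t)
        np.testing.assert_allclose(stack2.centroids(), stack.centroids() @ R.T + t,
                                   atol=1e-9)


class TestContour:
    def test_plane_fit_and_deviation(self):
        pts = circle_points((0, 0, 5), 10.0, 36)
        c = Contour.from_points(0, pts, orient_along=(0, 0, 1))
        np.testing.assert_allclose(np.abs(c.plane_normal), [0, 0, 1], atol=1e-12)
        assert c.max_plane_deviation < 1e-12
        assert float(np.dot(c.plane_normal, [0, 0, 1])) > 0

    def test_stack_requires_two_contours(self):
        with pytest.raises(InvalidContourError):
            ContourStack([circle_points((0, 0, 0), 5.0, 12)])

    def test_crossing_planes_warn(self):
        # second contour tilted so its plane cuts the centroid segment
        c0 = circle_points((0, 0, 0), 5.0, 24)
        c1 = circle_points((0, 0, 4), 5.0, 24,
                           u=(1, 0, 0), v=(0, np.cos(1.2), np.sin(1.2)))
        c2 = circle_points((0, 0, 8), 5.0, 24)
        with pytest.warns(UserWarning, match="intersect"):
            ContourStack([c0, c1, c2])

    def test_tangents_point_distally(self):
        stack = straight_tube_stack()
        cl = build_centerline(stack, 0)
        tangents = centerline_tangents(cl)
        np.testing.assert_allclose(tangents, np.tile([0, 0, 1.0], (5, 1)), atol=1e-12)
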