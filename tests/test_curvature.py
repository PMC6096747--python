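import numpy as np
import pytest

from tubegeom.core import ContourStack, build_centerline, build_surface
from tubegeom.curvature import (CurvatureField, circle_fit_curvature,
                                circumferential_curvature, curvature_field,
                                difference_field, longitudinal_curvature,
                                proxy_fields)
from tubegeom.errors import (DegenerateInputError, GridAlignmentError,
                             OutOfDomainError)
from tubegeom.phantoms import PhantomSpec, generate_simple, theta_column

from conftest import (ellipse_points, random_rigid_motion,
                      straight_tube_surface, transform_stack)


def algebraic_circumradius(p1, p2, p3):
    """Independent oracle: project to the triangle plane and solve the 2x2
    linear system for the circumcenter."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p2 - p1
    w = p3 - p1
    n = np.cross(u, w)
    nn = np.linalg.norm(n)
    if nn < 1e-14:
        return np.inf
    ex = u / np.linalg.norm(u)
    ey = np.cross(n / nn, ex)
    a = np.array([np.dot(p2 - p1, ex), np.dot(p2 - p1, ey)])
    b = np.array([np.dot(p3 - p1, ex), np.dot(p3 - p1, ey)])
    A = 2.0 * np.vstack([a, b])
    rhs = np.array([np.dot(a, a), np.dot(b, b)])
    center = np.linalg.solve(A, rhs)
    return float(np.linalg.norm(center))


class TestCircleFit:
    def test_unit_circle_triple(self):
        k = circle_fit_curvature((0, 1, 0), (1, 0, 0), (0, -1, 0))
        assert k == pytest.approx(1.0, rel=1e-12)

    def test_collinear_returns_zero(self):
        assert circle_fit_curvature((0, 0, 0), (1, 0, 0), (2, 0, 0)) == 0.0

    def test_coincident_raises(self):
        with pytest.raises(DegenerateInputError):
            circle_fit_curvature((1, 0, 0), (1, 0, 0), (0, 1, 0))

    def test_ellipse_vertex_triple(self):
        # points on the a=2, b=1 (cm) ellipse at the vertex and +-pi/8 polar
        phi = np.pi / 8
        r = 2 * 1 / np.sqrt((np.cos(phi)) ** 2 + (2 * np.sin(phi)) ** 2)
        p2 = (r * np.cos(phi), r * np.sin(phi), 0.0)
        p3 = (r * np.cos(phi), -r * np.sin(phi), 0.0)
        k = circle_fit_curvature((2, 0, 0), p2, p3)
        oracle = 1.0 / algebraic_circumradius((2, 0, 0), p2, p3)
        assert k == pytest.approx(oracle, rel=1e-12)
        assert k == pytest.approx(1.49, abs=0.01)

    def test_oracle_equivalence_bulk(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 10_000:
            p = rng.uniform(-10, 10, size=(3, 3))
            R = algebraic_circumradius(*p)
            if not np.isfinite(R) or R > 1e6:
                continue
            k = circle_fit_curvature(*p)
            assert k == pytest.approx(1.0 / R, rel=1e-9)
            checked += 1

    def test_exact_on_circles(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            R = rng.uniform(0.1, 100.0)
            ang = np.sort(rng.uniform(0, 2 * np.pi, 3))
            if np.min(np.diff(ang)) < 1e-3:
                continue
            center = rng.uniform(-50, 50, 3)
            Rm, _ = random_rigid_motion(rng)
            pts = [center + Rm @ (R * np.array([np.cos(a), np.sin(a), 0.0]))
                   for a in ang]
            assert circle_fit_curvature(*pts) == pytest.approx(1.0 / R, rel=1e-12)

    def test_scale_covariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(-5, 5, size=(3, 3))
        s = 3.7
        k1 = circle_fit_curvature(*p)
        k2 = circle_fit_curvature(*(s * p))
        assert k2 == pytest.approx(k1 / s, rel=1e-12)


class TestDirectionalCurvature:
    def test_straight_cylinder_longitudinal_zero(self):
        _, _, surface = straight_tube_surface(n=7, spacing=10.0)
        for theta in (0.0, 1.0, 3.0):
            assert longitudinal_curvature(surface, 30.0, theta, 30.0) == 0.0

    def test_longitudinal_window_out_of_domain(self):
        _, _, surface = straight_tube_surface(n=5, spacing=10.0)
        with pytest.raises(OutOfDomainError):
            longitudinal_curvature(surface, 5.0, 0.0, 30.0)

    def test_circumferential_circle_any_window(self):
        # radius 10 mm = 1 cm -> 1.0 cm^-1; exact when the window endpoints
        # hit stored samples, within sampling error otherwise
        _, _, surface = straight_tube_surface(radius=10.0, m=96)
        theta0 = float(surface.theta_samples[1][5])
        for w in (np.pi / 8, np.pi / 4, 3 * np.pi / 8):
            k = circumferential_curvature(surface, 20.0, theta0, w)
            assert k == pytest.approx(1.0, rel=1e-9)
        for w in (np.pi / 8, np.pi / 4, 3 * np.pi / 8):
            k = circumferential_curvature(surface, 20.0, 0.7, w)
            assert k == pytest.approx(1.0, rel=0.05)

    def ellipse_surface(self):
        # 4 cm x 2 cm diameter elliptical tube along z (mm coordinates)
        contours = [ellipse_points((0, 0, z), 20.0, 10.0, 96) for z in (0, 10, 20)]
        stack = ContourStack(contours)
        cl = build_centerline(stack, 0)
        gamma = np.array([c.points[0] for c in stack])
        return build_surface(stack, cl, gamma)

    def test_ellipse_vertex_pi4_window(self):
        surface = self.ellipse_surface()
        k = circumferential_curvature(surface, 10.0, 0.0, np.pi / 4)
        assert k == pytest.approx(1.486, abs=0.01)   # ~25% below analytic 2.0

    def test_ellipse_flat_pi4_window(self):
        surface = self.ellipse_surface()
        k = circumferential_curvature(surface, 10.0, np.pi / 2, np.pi / 4)
        assert k == pytest.approx(0.255, abs=0.005)  # analytic 0.25

    def test_torus_track_exact(self, simple_result, simple_phantom):
        # all three points inside the bend lie on a circle of radius R - r*cos(psi)
        _, _, ref = simple_phantom
        surface = simple_result.surface
        arc_mid = 60.0 + 30.0 * np.pi / 4
        i0 = int(np.argmin(np.abs(ref.s_grid - arc_mid)))
        sigma0 = float(surface.sigma_grid[i0])
        for psi in (0.0, np.pi / 2, np.pi):
            j = theta_column(surface, i0, psi)
            theta = float(surface.theta_samples[i0][j])
            k = longitudinal_curvature(surface, sigma0, theta, 20.0)
            analytic = 10.0 / (30.0 - 10.0 * np.cos(psi))
            assert k == pytest.approx(analytic, rel=5e-3)

    def test_invalid_windows(self):
        _, _, surface = straight_tube_surface()
        with pytest.raises(ValueError):
            longitudinal_curvature(surface, 20.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            circumferential_curvature(surface, 20.0, 0.0, np.pi)


class TestCurvatureField:
    def test_circumferential_constant_on_tube(self):
        _, _, surface = straight_tube_surface(radius=10.0, m=48)
        f = curvature_field(surface, "circumferential", np.pi / 4)
        vals, defined = f.as_arrays()
        assert defined.all()
        np.testing.assert_allclose(vals, 1.0, rtol=1e-9)

    def test_longitudinal_ends_masked(self):
        _, _, surface = straight_tube_surface(n=7, spacing=10.0)
        f = curvature_field(surface, "longitudinal", 30.0)
        _, defined = f.as_arrays()
        assert not defined[0].any() and not defined[1].any()
        assert not defined[-1].any() and not defined[-2].any()
        assert defined[2].all() and defined[3].all() and defined[4].all()

    def test_rigid_motion_invariance(self):
        stack, _, surface = straight_tube_surface(m=24)
        f = curvature_field(surface, "circumferential", np.pi / 4)
        rng = np.random.default_rng(21)
        R, t = random_rigid_motion(rng)
        stack2 = transform_stack(stack, R, t)
        cl2 = build_centerline(stack2, 0)
        surface2 = build_surface(stack2, cl2, np.array([c.points[0] for c in stack2]))
        f2 = curvature_field(surface2, "circumferential", np.pi / 4)
        np.testing.assert_allclose(f2.as_arrays()[0], f.as_arrays()[0], atol=1e-9)

    def test_unknown_direction(self):
        _, _, surface = straight_tube_surface()
        with pytest.raises(ValueError):
            curvature_field(surface, "diagonal")


class TestProxyFields:
    def test_cylinder_proxies(self):
        _, _, surface = straight_tube_surface(n=7, radius=10.0, spacing=10.0, m=48)
        lf = curvature_field(surface, "longitudinal", 30.0)
        cf = curvature_field(surface, "circumferential", np.pi / 4)
        px = proxy_fields(lf, cf)
        defined = np.array(px.defined)
        gauss = np.array(px.gaussian_proxy)
        mean = np.array(px.mean_proxy)
        assert defined[2:5].all()
        np.testing.assert_allclose(gauss[defined], 0.0, atol=1e-12)
        np.testing.assert_allclose(mean[defined], 0.5, rtol=1e-9)

    def test_masked_parent_masks_proxy(self):
        _, _, surface = straight_tube_surface(n=7, spacing=10.0)
        lf = curvature_field(surface, "longitudinal", 30.0)
        cf = curvature_field(surface, "circumferential", np.pi / 4)
        px = proxy_fields(lf, cf)
        assert not np.array(px.defined)[0].any()

    def test_grid_mismatch(self):
        _, _, s1 = straight_tube_surface(n=5)
        _, _, s2 = straight_tube_surface(n=6)
        lf = curvature_field(s1, "longitudinal", 30.0)
        cf = curvature_field(s2, "circumferential", np.pi / 4)
        with pytest.raises(GridAlignmentError):
            proxy_fields(lf, cf)


class TestDifferenceField:
    def test_self_difference_is_zero(self, simple_result):
        f = simple_result.longitudinal
        d = difference_field(f, f)
        for vals, mask in zip(d.values, d.defined):
            np.testing.assert_allclose(vals[mask], 0.0, atol=1e-15)

    def test_bend_change_localized(self):
        spec_a = PhantomSpec(kind="simple", leg2=60.0, branch=False)
        spec_b = PhantomSpec(kind="simple", leg2=60.0, bend1_radius=40.0, branch=False)
        ma, _, _ = generate_simple(spec_a)
        mb, _, _ = generate_simple(spec_b)

        def field(stack):
            cl = build_centerline(stack, 0)
            gamma = np.array([c.points[0] for c in stack])
            surface = build_surface(stack, cl, gamma)
            return curvature_field(surface, "longitudinal", 30.0)

        d = difference_field(field(ma), field(mb))
        sig = d.sigma_grid
        vals, mask = np.array(d.values), np.array(d.defined)
        proximal = (sig <= 45.0 + 1e-9)
        assert np.all(vals[proximal & (mask.T.all(axis=0))] < 1e-12)
        in_bend = (sig > 60) & (sig < 100)
        assert vals[in_bend].max() > 0.05

    def test_disjoint_grids_raise(self, simple_result):
        f = simple_result.longitudinal
        g = CurvatureField(direction=f.direction, window=f.window,
                           sigma_grid=f.sigma_grid, theta_samples=f.theta_samples,
                           values=f.values, defined=f.defined, units=f.units,
                           contour_indices=f.contour_indices + 1000)
        with pytest.raises(GridAlignmentError):
            difference_field(f, g)

    def test_direction_mismatch(self, simple_result):
        with pytest.raises(GridAlignmentError):
            difference_field(simple_result.longitudinal, simple_result.circumferential)


class TestScaleCovariance:
    def test_field_scales_inversely(self):
        stack, _, surface = straight_tube_surface(radius=10.0, m=48)
        f1 = curvature_field(surface, "circumferential", np.pi / 4, units="mm")
        stack2 = transform_stack(stack, 2.0 * np.eye(3), np.zeros(3))
        cl2 = build_centerline(stack2, 0)
        surface2 = build_surface(stack2, cl2, np.array([c.points[0] for c in stack2]))
        f2 = curvature_field(surface2, "circumferential", np.pi / 4, units="mm")
        np.testing.assert_allclose(f2.as_arrays()[0], f1.as_arrays()[0] / 2.0,
                                   rtol=1e-12)
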