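import warnings

import numpy as np
import pytest

from tubegeom import AnalysisConfig, analyze
from tubegeom.core import Contour, ContourStack, build_centerline, build_surface
from tubegeom.phantoms import generate_complex, generate_simple


def circle_points(center, radius, m, u=(1.0, 0.0, 0.0), v=(0.0, 1.0, 0.0)):
    """m points on a circle in the plane spanned by u, v."""
    center = np.asarray(center, dtype=float)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    ang = np.arange(m) * (2 * np.pi / m)
    return center + radius * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)


def ellipse_points(center, a, b, m, u=(1.0, 0.0, 0.0), v=(0.0, 1.0, 0.0)):
    """m points sampled at uniform polar angle on an ellipse (semi-axes a
    along u, b along v)."""
    center = np.asarray(center, dtype=float)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    ang = np.arange(m) * (2 * np.pi / m)
    r = a * b / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
    return center + r[:, None] * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)


def straight_tube_stack(n=5, radius=10.0, spacing=10.0, m=36, z0=0.0):
    """Straight circular tube along +z."""
    return ContourStack([
        Contour.from_points(i, circle_points((0, 0, z0 + i * spacing), radius, m))
        for i in range(n)
    ])


def straight_tube_surface(n=5, radius=10.0, spacing=10.0, m=36, z0=0.0, origin=0):
    """(stack, centerline, surface) with the Greenwich track on +x."""
    stack = straight_tube_stack(n, radius, spacing, m, z0)
    centerline = build_centerline(stack, origin)
    gamma = np.array([c.points[0] for c in stack])
    surface = build_surface(stack, centerline, gamma)
    return stack, centerline, surface


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-50, 50, size=3)
    return R, t


def transform_stack(stack, R, t):
    return ContourStack([
        Contour.from_points(c.index, c.points @ R.T + t) for c in stack
    ], label=stack.label, time_label=stack.time_label)


@pytest.fixture(scope="session")
def simple_phantom():
    return generate_simple()


@pytest.fixture(scope="session")
def complex_phantom():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_complex()


@pytest.fixture(scope="session")
def simple_result(simple_phantom):
    mother, branch, ref = simple_phantom
    cfg = AnalysisConfig(fiducial_tolerance=ref.recommended_fiducial_tolerance)
    return analyze(mother, daughter=branch, config=cfg)


@pytest.fixture(scope="session")
def complex_result(complex_phantom):
    mother, branch, ref = complex_phantom
    cfg = AnalysisConfig(fiducial_tolerance=ref.recommended_fiducial_tolerance)
    return analyze(mother, daughter=branch, config=cfg)
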