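"""Core geometric model: contours, contour stacks, centerline, radial surface.

A tubular surface is represented by an ordered stack of closed cross-sectional
boundary loops (proximal to distal).  Each loop carries its arithmetic-mean
centroid and a least-squares plane.  The piecewise-linear curve through the
centroids is the centerline; its signed arc length ``sigma`` (zero at a chosen
origin contour, negative proximally) is the longitudinal coordinate.  Together
with an angular coordinate ``theta`` measured from a per-contour reference
("Greenwich") point, the boundary samples define a radial surface function
``r(sigma, theta)`` that is interpolated linearly in both dimensions.

All coordinates are millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateCenterlineError,
    InvalidContourError,
    OutOfDomainError,
    ZeroRadiusError,
)

__all__ = [
    "Contour",
    "ContourStack",
    "Centerline",
    "CylindricalSurface",
    "compute_centroid",
    "best_fit_plane",
    "build_centerline",
    "centerline_tangents",
    "assign_theta",
    "build_surface",
    "polyline_length",
]

_TWO_PI = 2.0 * np.pi


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidContourError(f"expected an (m, 3) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidContourError("contour points must be finite")
    return pts


def compute_centroid(points) -> np.ndarray:
    """Arithmetic mean of an ordered list of boundary points.

    This is the mean of the sampled points, not the area centroid of the
    enclosed region; for strongly nonuniform sampling the two differ.

    Raises
    ------
    InvalidContourError
        If fewer than 3 points are supplied.
    """
    pts = _as_points(points)
    if pts.shape[0] < 3:
        raise InvalidContourError(f"a contour needs at least 3 points, got {pts.shape[0]}")
    return pts.mean(axis=0)


def best_fit_plane(points) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane of a point cloud.

    Returns ``(centroid, unit_normal, max_out_of_plane_deviation)``.  The
    normal's sign is arbitrary; callers orient it against a reference
    direction.
    """
    pts = _as_points(points)
    c = pts.mean(axis=0)
    rel = pts - c
    # Smallest right singular vector of the centered cloud.
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    normal = vt[-1]
    dev = float(np.max(np.abs(rel @ normal))) if len(pts) else 0.0
    return c, normal, dev


@dataclass(frozen=True)
class Contour:
    """One closed, ordered cross-sectional boundary loop.

    ``points`` is an (m, 3) array of the ordered boundary samples (the loop
    closes from the last point back to the first).  ``centroid`` is their
    arithmetic mean, ``plane_normal`` the unit normal of the least-squares
    plane, and ``max_plane_deviation`` the largest out-of-plane distance
    (reported, not enforced).
    """

    index: int
    points: np.ndarray
    centroid: np.ndarray
    plane_normal: np.ndarray
    max_plane_deviation: float = 0.0

    @classmethod
    def from_points(cls, index: int, points, orient_along: Optional[np.ndarray] = None) -> "Contour":
        """Build a contour, optionally orienting the plane normal.

        ``orient_along`` is a direction with which the normal should have a
        positive dot product (typically the local proximal-to-distal
        centerline direction).
        """
        pts = _as_points(points)
        centroid = compute_centroid(pts)
        _, normal, dev = best_fit_plane(pts)
        if orient_along is not None and float(np.dot(normal, orient_along)) < 0.0:
            normal = -normal
        return cls(index=int(index), points=pts, centroid=centroid,
                   plane_normal=normal, max_plane_deviation=dev)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def radii(self) -> np.ndarray:
        """Distance of each boundary point from the centroid (mm)."""
        return np.linalg.norm(self.points - self.centroid, axis=1)


class ContourStack:
    """Ordered sequence of contours, proximal to distal.

    Parameters
    ----------
    contours
        Sequence of :class:`Contour` (or raw (m, 3) point arrays, which are
        wrapped).  At least two contours with distinct consecutive centroids
        are required.  A warning is emitted if consecutive contour planes
        appear to intersect near the tube (the surface would then be folded).
    """

    def __init__(self, contours: Sequence, label: str = "", time_label: Optional[str] = None):
        built: list[Contour] = []
        for i, c in enumerate(contours):
            if isinstance(c, Contour):
                built.append(c)
            else:
                built.append(Contour.from_points(i, c))
        if len(built) < 2:
            raise InvalidContourError(f"a contour stack needs at least 2 contours, got {len(built)}")
        self.contours: list[Contour] = built
        self.label = label
        self.time_label = time_label
        self._orient_normals()
        self._validate()

    def _orient_normals(self) -> None:
        cents = self.centroids()
        n = len(self.contours)
        for i, c in enumerate(self.contours):
            lo, hi = max(i - 1, 0), min(i + 1, n - 1)
            direction = cents[hi] - cents[lo]
            if float(np.dot(c.plane_normal, direction)) < 0.0:
                object.__setattr__(c, "plane_normal", -c.plane_normal)

    def _validate(self) -> None:
        cents = self.centroids()
        steps = np.linalg.norm(np.diff(cents, axis=0), axis=1)
        if np.any(steps < 1e-12):
            bad = int(np.argmin(steps))
            raise DegenerateCenterlineError(
                f"centroids of contours {bad} and {bad + 1} coincide")
        for a, b in zip(self.contours[:-1], self.contours[1:]):
            if self._planes_cross_between(a, b):
                warnings.warn(
                    f"planes of contours {a.index} and {b.index} intersect near "
                    "the tube between their centroids; the surface may fold",
                    stacklevel=3)

    @staticmethod
    def _planes_cross_between(a: Contour, b: Contour) -> bool:
        # The two planes intersect in a line; the surface folds when that line
        # passes strictly inside the radial reach of both contours.
        n1, n2 = a.plane_normal, b.plane_normal
        axis = np.cross(n1, n2)
        norm = np.linalg.norm(axis)
        if norm < 1e-9:  # parallel planes never cross
            return False
        axis = axis / norm
        d1 = float(np.dot(n1, a.centroid))
        d2 = float(np.dot(n2, b.centroid))
        A = np.vstack([n1, n2, axis])
        p0 = np.linalg.solve(A, np.array([d1, d2, 0.0]))

        def reaches_line(contour: Contour) -> bool:
            rel = contour.centroid - p0
            perp = rel - np.dot(rel, axis) * axis
            dist = float(np.linalg.norm(perp))
            if dist < 1e-12:
                return True
            # Support of the contour in the direction toward the line.
            toward = -perp / dist
            support = float(np.max((contour.points - contour.centroid) @ toward))
            return dist < support - 1e-9

        return reaches_line(a) and reaches_line(b)

    @property
    def n(self) -> int:
        return len(self.contours)

    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.contours])

    def all_points(self) -> np.ndarray:
        """All boundary points stacked into one (N, 3) array."""
        return np.vstack([c.points for c in self.contours])

    def point_labels(self) -> np.ndarray:
        """(N, 2) integer array of (contour position, point index) per row of
        :meth:`all_points`."""
        labels = [np.column_stack([np.full(c.n_points, i), np.arange(c.n_points)])
                  for i, c in enumerate(self.contours)]
        return np.vstack(labels)

    def __iter__(self):
        return iter(self.contours)

    def __getitem__(self, i: int) -> Contour:
        return self.contours[i]


@dataclass(frozen=True)
class Centerline:
    """Piecewise-linear centroid polyline with signed arc length.

    ``sigma_of_node[i]`` is the cumulative polyline length from the origin
    node (``origin_index``), negative for proximal nodes.
    """

    nodes: np.ndarray
    sigma_of_node: np.ndarray
    origin_index: int

    @property
    def n(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def sigma_range(self) -> tuple[float, float]:
        return float(self.sigma_of_node[0]), float(self.sigma_of_node[-1])

    def length(self) -> float:
        return float(self.sigma_of_node[-1] - self.sigma_of_node[0])


def polyline_length(points) -> float:
    """Total Euclidean length of a polyline given as an (n, 3) array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def build_centerline(stack: ContourStack, origin_index: int) -> Centerline:
    """Arc-length-parameterize the centroid polyline.

    ``sigma`` of node ``i`` is the signed cumulative Euclidean length along
    the polyline from node ``origin_index`` (negative proximally).
    """
    if not 0 <= origin_index < stack.n:
        raise IndexError(f"origin_index {origin_index} out of range [0, {stack.n})")
    nodes = stack.centroids()
    steps = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    if np.any(steps < 1e-12):
        raise DegenerateCenterlineError("coincident consecutive centroids")
    cumulative = np.concatenate([[0.0], np.cumsum(steps)])
    sigma = cumulative - cumulative[origin_index]
    return Centerline(nodes=nodes, sigma_of_node=sigma, origin_index=int(origin_index))


def centerline_tangents(centerline: Centerline) -> np.ndarray:
    """Unit proximal-to-distal tangent per node (central differences)."""
    nodes = centerline.nodes
    tangents = np.empty_like(nodes)
    tangents[0] = nodes[1] - nodes[0]
    tangents[-1] = nodes[-1] - nodes[-2]
    if len(nodes) > 2:
        tangents[1:-1] = nodes[2:] - nodes[:-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return tangents


def assign_theta(contour: Contour, greenwich_point, distal_tangent) -> np.ndarray:
    """Angular coordinate of every boundary point of one contour.

    ``theta`` is the polar angle of ``b - C`` about the centroid ``C`` within
    the contour plane, measured from the in-plane direction toward the
    Greenwich point, right-handed about ``distal_tangent``.  The Greenwich
    point itself gets exactly 0; all values lie in ``[0, 2*pi)``.
    """
    gamma = np.asarray(greenwich_point, dtype=float)
    tangent = np.asarray(distal_tangent, dtype=float)
    n = contour.plane_normal
    if float(np.dot(n, tangent)) < 0.0:
        n = -n
    c = contour.centroid
    u = gamma - c
    u = u - np.dot(u, n) * n
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise ZeroRadiusError("Greenwich point coincides with the contour centroid")
    u /= nu
    v = np.cross(n, u)
    rel = contour.points - c
    x = rel @ u
    y = rel @ v
    if np.any(np.hypot(x, y) < 1e-12):
        raise ZeroRadiusError("a boundary point coincides with the contour centroid")
    theta = np.mod(np.arctan2(y, x), _TWO_PI)
    # Pin the Greenwich point itself to exactly zero if it is a member.
    d = np.linalg.norm(contour.points - gamma, axis=1)
    j = int(np.argmin(d))
    if d[j] < 1e-9:
        theta[j] = 0.0
    return theta


@dataclass
class CylindricalSurface:
    """The sampled radial surface ``r(sigma, theta)``.

    Per contour, boundary samples are stored sorted by ``theta`` starting at
    the Greenwich point (``theta = 0``).  ``point_order[i]`` maps the sorted
    position back to the original boundary-point index, preserving the
    Lagrangian labelling of material points.

    Evaluation is bilinear: circular linear interpolation in ``theta`` along
    the contour polygon, then linear interpolation in ``sigma`` between the
    two bracketing contours.  Stored samples are reproduced exactly.
    """

    sigma_grid: np.ndarray                 # (n,) sigma per contour
    theta_samples: list[np.ndarray]        # per contour, sorted, theta[0] == 0
    radii: list[np.ndarray]                # per contour, |b - C| in the sorted order
    points: list[np.ndarray]               # per contour, boundary points, sorted order
    centroids: np.ndarray                  # (n, 3)
    contour_indices: np.ndarray            # (n,) original Contour.index values
    point_order: list[np.ndarray] = field(default_factory=list)
    time_label: Optional[str] = None

    @property
    def n(self) -> int:
        return int(len(self.sigma_grid))

    @property
    def sigma_range(self) -> tuple[float, float]:
        return float(self.sigma_grid[0]), float(self.sigma_grid[-1])

    def _bracket_sigma(self, sigma: float) -> tuple[int, int, float]:
        lo, hi = self.sigma_range
        tol = 1e-9
        if sigma < lo - tol or sigma > hi + tol:
            raise OutOfDomainError(f"sigma={sigma} outside [{lo}, {hi}]")
        sigma = min(max(sigma, lo), hi)
        i = int(np.searchsorted(self.sigma_grid, sigma, side="right")) - 1
        i = min(max(i, 0), self.n - 2)
        s0, s1 = self.sigma_grid[i], self.sigma_grid[i + 1]
        frac = 0.0 if s1 == s0 else (sigma - s0) / (s1 - s0)
        return i, i + 1, float(frac)

    def _theta_bracket(self, i: int, theta: float) -> tuple[int, int, float]:
        t = self.theta_samples[i]
        m = len(t)
        tw = float(np.mod(theta, _TWO_PI))
        j = int(np.searchsorted(t, tw, side="right"))
        if j == 0:      # cannot happen (t[0] == 0, tw >= 0) but be safe
            j = 1
        j0 = j - 1
        if j == m:
            t0, t1 = t[m - 1], t[0] + _TWO_PI
            j1 = 0
        else:
            t0, t1 = t[j0], t[j]
            j1 = j
        frac = 0.0 if t1 == t0 else (tw - t0) / (t1 - t0)
        return j0, j1, float(frac)

    def _contour_radius(self, i: int, theta: float) -> float:
        j0, j1, f = self._theta_bracket(i, theta)
        r = self.radii[i]
        return float((1.0 - f) * r[j0] + f * r[j1])

    def _contour_point(self, i: int, theta: float) -> np.ndarray:
        j0, j1, f = self._theta_bracket(i, theta)
        p = self.points[i]
        return (1.0 - f) * p[j0] + f * p[j1]

    def evaluate(self, sigma: float, theta: float) -> float:
        """Radius ``r(sigma, theta)`` in mm (theta wraps mod 2*pi)."""
        i0, i1, f = self._bracket_sigma(sigma)
        r0 = self._contour_radius(i0, theta)
        if f == 0.0:
            return r0
        r1 = self._contour_radius(i1, theta)
        return (1.0 - f) * r0 + f * r1

    def point(self, sigma: float, theta: float) -> np.ndarray:
        """3D surface location at ``(sigma, theta)``.

        The in-plane point of each bracketing contour is obtained by linear
        interpolation along the contour polygon in ``theta``; the two are
        then blended linearly in ``sigma``.  Stored samples are returned
        exactly.
        """
        i0, i1, f = self._bracket_sigma(sigma)
        p0 = self._contour_point(i0, theta)
        if f == 0.0:
            return p0
        p1 = self._contour_point(i1, theta)
        return (1.0 - f) * p0 + f * p1


def build_surface(stack: ContourStack, centerline: Centerline,
                  gamma_points: np.ndarray,
                  time_label: Optional[str] = None) -> CylindricalSurface:
    """Assemble the radial surface from a stack, centerline and Greenwich points.

    ``gamma_points`` holds one Greenwich point per contour (each a member of
    that contour's boundary points).
    """
    gamma_points = np.asarray(gamma_points, dtype=float)
    if gamma_points.shape != (stack.n, 3):
        raise ValueError(f"expected ({stack.n}, 3) Greenwich points, got {gamma_points.shape}")
    tangents = centerline_tangents(centerline)
    thetas, radii, points, orders = [], [], [], []
    for i, contour in enumerate(stack):
        theta = assign_theta(contour, gamma_points[i], tangents[i])
        order = np.argsort(theta, kind="stable")
        thetas.append(theta[order])
        points.append(contour.points[order])
        radii.append(np.linalg.norm(contour.points[order] - contour.centroid, axis=1))
        orders.append(order)
    return CylindricalSurface(
        sigma_grid=centerline.sigma_of_node.copy(),
        theta_samples=thetas,
        radii=radii,
        points=points,
        centroids=stack.centroids(),
        contour_indices=np.array([c.index for c in stack], dtype=int),
        point_order=orders,
        time_label=time_label if time_label is not None else stack.time_label,
    )
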