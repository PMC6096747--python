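"""Fiducial detection, Greenwich point selection, and Greenwich-curve propagation.

The angular origin of the coordinate system is anchored at a material fiducial
``delta`` (for vessels, the most distal intersection of mother and daughter
lumen boundaries).  The boundary point closest to ``delta`` is the Greenwich
point ``gamma`` on contour ``k``; it is propagated to every other contour by
one of three methods, and the polyline through the propagated points is the
Greenwich curve (the surface's prime meridian, ``theta = 0``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Centerline, ContourStack, build_centerline, polyline_length
from .errors import NoIntersectionError

logger = logging.getLogger(__name__)

__all__ = [
    "GreenwichFrame",
    "default_fiducial_tolerance",
    "find_fiducial",
    "find_greenwich_point",
    "propagate_greenwich",
    "greenwich_curve",
    "build_frame",
]

METHOD_NAMES = {1: "centroid_ray_projection", 2: "normal_projection", 3: "closest_point"}


@dataclass(frozen=True)
class GreenwichFrame:
    """Fiducial, Greenwich points and curve for one contour stack.

    ``gamma_points[i]`` is bit-identical to a boundary point of contour ``i``
    (``gamma_point_indices[i]`` gives its index in that contour's point list).
    """

    delta: np.ndarray                 # fiducial point (3,)
    gamma_index: int                  # contour index k of the seed gamma
    gamma_points: np.ndarray          # (n, 3), one per contour
    gamma_point_indices: np.ndarray   # (n,) boundary-point index per contour
    method: int

    @property
    def method_name(self) -> str:
        return METHOD_NAMES[self.method]

    @property
    def curve(self) -> np.ndarray:
        return self.gamma_points

    def curve_length(self) -> float:
        return polyline_length(self.gamma_points)


def default_fiducial_tolerance(mother: ContourStack) -> float:
    """Half the median inter-point spacing of the mother contours (mm)."""
    spacings = []
    for c in mother:
        d = np.linalg.norm(np.roll(c.points, -1, axis=0) - c.points, axis=1)
        spacings.append(np.median(d))
    return 0.5 * float(np.median(spacings))


def find_fiducial(mother: ContourStack, daughter: ContourStack,
                  tolerance: float | None = None,
                  centerline: Centerline | None = None) -> np.ndarray:
    """Most distal mother boundary point adjacent to the daughter boundary.

    Among all mother boundary points lying within ``tolerance`` of any
    daughter boundary point, the one whose nearest centerline node is most
    distal (largest sigma) is returned.  Ties are broken by lowest contour
    index, then lowest point index.

    Raises
    ------
    NoIntersectionError
        If no point pair is within tolerance (branch not adjacent, or the
        tolerance is too small for the sampling density).
    """
    if tolerance is None:
        tolerance = default_fiducial_tolerance(mother)
    if centerline is None:
        centerline = build_centerline(mother, 0)
    mpts = mother.all_points()
    dpts = daughter.all_points()
    # Chunked nearest-neighbour distances (keeps memory bounded).
    mind = np.full(len(mpts), np.inf)
    step = max(1, int(2e7) // max(len(dpts), 1))
    for start in range(0, len(mpts), step):
        block = mpts[start:start + step]
        d2 = np.sum((block[:, None, :] - dpts[None, :, :]) ** 2, axis=2)
        mind[start:start + step] = np.sqrt(d2.min(axis=1))
    candidates = np.flatnonzero(mind <= tolerance)
    if candidates.size == 0:
        raise NoIntersectionError(
            f"no mother/daughter boundary points within {tolerance:g} mm; "
            "the branch may not touch the mother surface, or the tolerance is too small")
    labels = mother.point_labels()[candidates]
    # sigma of the nearest centerline node per candidate point.
    d_nodes = np.linalg.norm(mpts[candidates][:, None, :] - centerline.nodes[None, :, :], axis=2)
    sigma = centerline.sigma_of_node[np.argmin(d_nodes, axis=1)]
    # Most distal first; ties resolved by (contour index, point index).
    order = np.lexsort((labels[:, 1], labels[:, 0], -sigma))
    return mpts[candidates[order[0]]].copy()


def find_greenwich_point(delta, stack: ContourStack) -> tuple[np.ndarray, int, int]:
    """Globally closest boundary point to the fiducial.

    Returns ``(gamma, contour_index, point_index)``.  Ties are broken by
    lowest contour index, then lowest point index (first occurrence).
    """
    delta = np.asarray(delta, dtype=float)
    pts = stack.all_points()
    labels = stack.point_labels()
    d = np.linalg.norm(pts - delta, axis=1)
    dmin = float(d.min())
    # distances equal up to rounding count as ties, resolved to lowest (i, j)
    tied = np.flatnonzero(d <= dmin + max(1e-12 * dmin, 1e-15))
    first = tied[np.lexsort((labels[tied, 1], labels[tied, 0]))[0]]
    k, j = (int(v) for v in labels[first])
    return stack[k].points[j].copy(), k, j


def _nearest_point_index(contour, target: np.ndarray) -> int:
    d = np.linalg.norm(contour.points - target, axis=1)
    return int(np.argmin(d))


def _propagate_step(contour_from, contour_to, gamma: np.ndarray,
                    step_dir: np.ndarray, method: int) -> int:
    """One propagation step; returns the boundary-point index on contour_to."""
    if method == 3:
        return _nearest_point_index(contour_to, gamma)
    if method == 1:
        direction = step_dir
    else:  # method 2: along the source contour's plane normal
        direction = contour_from.plane_normal
    n = contour_to.plane_normal
    denom = float(np.dot(n, direction))
    if abs(denom) < 1e-9 * float(np.linalg.norm(direction)):
        logger.warning("propagation direction parallel to target plane; "
                       "falling back to closest-point for this step")
        return _nearest_point_index(contour_to, gamma)
    s = float(np.dot(n, contour_to.centroid - gamma)) / denom
    projected = gamma + s * direction
    return _nearest_point_index(contour_to, projected)


def propagate_greenwich(stack: ContourStack, centerline: Centerline,
                        gamma, k: int, method: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Propagate the Greenwich point to every contour.

    Method 1 translates the current point along the local centroid-to-centroid
    direction to its intersection with the next contour's plane, then snaps to
    the nearest boundary point there; method 2 translates along the source
    contour's plane normal; method 3 snaps directly to the nearest boundary
    point.  Propagation runs distally from ``k`` to the end and proximally
    from ``k`` to the start (the proximal step uses the mirrored direction).

    Returns ``(gamma_points, gamma_point_indices)``.
    """
    if method not in (1, 2, 3):
        raise ValueError(f"method must be 1, 2 or 3, got {method}")
    gamma = np.asarray(gamma, dtype=float)
    n = stack.n
    indices = np.full(n, -1, dtype=int)
    points = np.zeros((n, 3))
    jk = _nearest_point_index(stack[k], gamma)
    indices[k] = jk
    points[k] = stack[k].points[jk]
    nodes = centerline.nodes
    # Distal sweep.
    for i in range(k, n - 1):
        j = _propagate_step(stack[i], stack[i + 1], points[i],
                            nodes[i + 1] - nodes[i], method)
        indices[i + 1] = j
        points[i + 1] = stack[i + 1].points[j]
    # Proximal sweep (mirrored construction).
    for i in range(k, 0, -1):
        j = _propagate_step(stack[i], stack[i - 1], points[i],
                            nodes[i - 1] - nodes[i], method)
        indices[i - 1] = j
        points[i - 1] = stack[i - 1].points[j]
    return points, indices


def greenwich_curve(gamma_points) -> tuple[np.ndarray, float]:
    """Ordered Greenwich polyline and its length in mm."""
    pts = np.atleast_2d(np.asarray(gamma_points, dtype=float))
    return pts, polyline_length(pts)


def build_frame(stack: ContourStack, centerline: Centerline, delta,
                method: int = 1) -> GreenwichFrame:
    """Locate gamma from a fiducial and propagate it over the whole stack."""
    gamma, k, _ = find_greenwich_point(delta, stack)
    points, indices = propagate_greenwich(stack, centerline, gamma, k, method)
    return GreenwichFrame(delta=np.asarray(delta, dtype=float), gamma_index=k,
                          gamma_points=points, gamma_point_indices=indices,
                          method=method)
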