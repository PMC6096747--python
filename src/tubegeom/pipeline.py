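"""End-to-end analysis: stack -> frame -> surface -> curvature + eccentricity.

The pipeline anchors the coordinate frame from one of three fiducial sources
(a daughter-branch stack, an explicit 3D point, or an explicit (arc, angle)
seed), builds the sigma/theta surface, and evaluates both curvature fields,
their proxies, and the eccentricity profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import curvature as curv
from . import eccentricity as ecc
from .core import (Centerline, ContourStack, CylindricalSurface,
                   build_centerline, build_surface, centerline_tangents)
from .errors import TubegeomError
from .greenwich import (GreenwichFrame, build_frame, find_fiducial,
                        find_greenwich_point, propagate_greenwich)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisResult", "resolve_fiducial", "analyze"]


@dataclass
class AnalysisConfig:
    """Knobs for a full analysis run.

    ``window_sigma`` (mm) and ``window_theta`` (rad) are the curvature
    windows; ``scale_windows`` rescales the longitudinal window to the mean
    vessel diameter instead.  ``method`` selects the Greenwich propagation
    scheme (1: along the centerline step, 2: along the section normal,
    3: closest point).
    """

    window_sigma: float = curv.DEFAULT_WINDOW_SIGMA
    window_theta: float = curv.DEFAULT_WINDOW_THETA
    angular_step: float = ecc.DEFAULT_ANGULAR_STEP
    method: int = 1
    units: str = "cm"
    fiducial_tolerance: Optional[float] = None
    scale_windows: bool = False

    def __post_init__(self):
        if self.window_sigma <= 0 or not 0 < self.window_theta < np.pi:
            raise ValueError("invalid curvature windows")
        if self.method not in (1, 2, 3):
            raise ValueError("method must be 1, 2 or 3")
        if self.units not in ("cm", "mm"):
            raise ValueError("units must be 'cm' or 'mm'")


@dataclass
class AnalysisResult:
    stack: ContourStack
    centerline: Centerline
    frame: GreenwichFrame
    surface: CylindricalSurface
    longitudinal: curv.CurvatureField
    circumferential: curv.CurvatureField
    proxies: curv.ProxyField
    eccentricity: list
    spirality: np.ndarray
    config: AnalysisConfig = field(default_factory=AnalysisConfig)


def _median_contour_spacing(stack: ContourStack) -> float:
    cents = stack.centroids()
    return float(np.median(np.linalg.norm(np.diff(cents, axis=0), axis=1)))


def resolve_fiducial(stack: ContourStack,
                     daughter: Optional[ContourStack] = None,
                     fiducial_point=None,
                     seed: Optional[tuple[float, float]] = None,
                     tolerance: Optional[float] = None) -> np.ndarray:
    """Resolve the fiducial from one of the three supported sources.

    ``seed = (arc_mm, angle_rad)`` places the fiducial on the boundary point
    of the contour nearest ``arc_mm`` along the centerline from the proximal
    end, at polar angle ``angle_rad`` measured from the contour's first
    stored boundary point, right-handed about the distal tangent.
    """
    sources = sum(x is not None for x in (daughter, fiducial_point, seed))
    if sources == 0:
        raise TubegeomError(
            "no fiducial source given; provide a daughter branch stack, an "
            "explicit 3D fiducial point, or an (arc, angle) seed")
    if sources > 1:
        raise TubegeomError("give exactly one fiducial source")
    if fiducial_point is not None:
        return np.asarray(fiducial_point, dtype=float)
    if daughter is not None:
        if tolerance is None:
            # Half the contour spacing: discrete 'intersection' of two sampled
            # surfaces needs a proximity window on the order of the sampling.
            tolerance = 0.5 * _median_contour_spacing(stack)
        return find_fiducial(stack, daughter, tolerance=tolerance)
    arc, angle = seed
    cl = build_centerline(stack, 0)
    k = int(np.argmin(np.abs(cl.sigma_of_node - arc)))
    contour = stack[k]
    tangent = centerline_tangents(cl)[k]
    n = contour.plane_normal if np.dot(contour.plane_normal, tangent) >= 0 \
        else -contour.plane_normal
    rel = contour.points - contour.centroid
    u = rel[0] - np.dot(rel[0], n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    theta = np.mod(np.arctan2(rel @ v, rel @ u), 2 * np.pi)
    j = int(np.argmin(np.abs(np.mod(theta - angle + np.pi, 2 * np.pi) - np.pi)))
    return contour.points[j].copy()


def analyze(stack: ContourStack,
            daughter: Optional[ContourStack] = None,
            fiducial_point=None,
            seed: Optional[tuple[float, float]] = None,
            config: Optional[AnalysisConfig] = None) -> AnalysisResult:
    """Run the full pipeline on one contour stack."""
    config = config or AnalysisConfig()
    delta = resolve_fiducial(stack, daughter, fiducial_point, seed,
                             tolerance=config.fiducial_tolerance)
    gamma, k, _ = find_greenwich_point(delta, stack)
    centerline = build_centerline(stack, k)
    logger.info("fiducial delta=%s, gamma on contour %d, method %d",
                np.round(delta, 3), k, config.method)
    points, indices = propagate_greenwich(stack, centerline, gamma, k, config.method)
    frame = GreenwichFrame(delta=delta, gamma_index=k, gamma_points=points,
                           gamma_point_indices=indices, method=config.method)
    surface = build_surface(stack, centerline, frame.gamma_points)
    w_sigma = curv.scaled_window_sigma(surface) if config.scale_windows \
        else config.window_sigma
    logger.info("windows: sigma=%.3g mm, theta=%.3g rad", w_sigma, config.window_theta)
    long_field = curv.curvature_field(surface, "longitudinal", w_sigma, config.units)
    circ_field = curv.curvature_field(surface, "circumferential",
                                      config.window_theta, config.units)
    proxies = curv.proxy_fields(long_field, circ_field)
    profile = ecc.eccentricity_profile(stack, frame, centerline, config.angular_step)
    spiral = ecc.spirality(profile) if len(profile) >= 3 else np.full(len(profile), np.nan)
    return AnalysisResult(stack=stack, centerline=centerline, frame=frame,
                          surface=surface, longitudinal=long_field,
                          circumferential=circ_field, proxies=proxies,
                          eccentricity=profile, spirality=spiral, config=config)
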