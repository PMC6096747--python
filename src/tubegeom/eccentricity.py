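"""Generalized cross-sectional eccentricity, orientation, and spirality.

For each contour, orthogonal diameter pairs through the centroid are scanned
over direction; the pair minimizing the ratio of the shorter chord ``d`` to
the longer chord ``D`` defines the generalized eccentricity
``e = sqrt(1 - d**2 / D**2)`` (the classical ellipse value when the contour is
an ellipse).  The orientation ``theta_e`` is the angle between the major
diameter and the in-plane Greenwich direction, folded to ``[0, pi)`` because a
diameter is undirected.  The rate of change of ``theta_e`` with sigma is the
spirality of eccentricity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import Centerline, Contour, ContourStack
from .errors import CentroidOutsideError
from .greenwich import GreenwichFrame

__all__ = [
    "DEFAULT_ANGULAR_STEP",
    "EccentricityRecord",
    "chord_through_centroid",
    "eccentricity",
    "orientation",
    "eccentricity_profile",
    "spirality",
    "profile_to_dataframe",
]

DEFAULT_ANGULAR_STEP = np.pi / 720


def _plane_basis(contour: Contour) -> tuple[np.ndarray, np.ndarray]:
    """A fixed orthonormal in-plane basis (u, v) with v = n x u."""
    n = contour.plane_normal
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(n, ref))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _projected_polygon(contour: Contour) -> np.ndarray:
    """Boundary points projected to 2D plane coordinates about the centroid."""
    u, v = _plane_basis(contour)
    rel = contour.points - contour.centroid
    return np.column_stack([rel @ u, rel @ v])


def _ray_reaches(poly: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Farthest boundary intersection distance per 2D unit direction.

    For each direction the ray from the origin (the centroid) is intersected
    with every polygon edge and the largest hit distance is kept, so
    non-convex wiggles do not truncate diameters.  Rays that miss the polygon
    entirely yield -inf.
    """
    p1 = poly
    p2 = np.roll(poly, -1, axis=0)
    e = p2 - p1                                       # (m, 2)
    dx, dy = directions[:, 0:1], directions[:, 1:2]   # (k, 1)
    cross_de = dx * e[None, :, 1] - dy * e[None, :, 0]        # (k, m)
    cross_p1e = p1[:, 0] * e[:, 1] - p1[:, 1] * e[:, 0]       # (m,)
    cross_p1d = p1[None, :, 0] * dy - p1[None, :, 1] * dx     # (k, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = cross_p1e[None, :] / cross_de                     # hit distance along ray
        t = cross_p1d / cross_de                              # position along edge
    valid = (np.abs(cross_de) > 1e-14) & (t >= -1e-12) & (t <= 1.0 + 1e-12) & (s > 0)
    s = np.where(valid, s, -np.inf)
    return s.max(axis=1)


def _is_convex(poly: np.ndarray) -> bool:
    e = np.roll(poly, -1, axis=0) - poly
    cr = e[:, 0] * np.roll(e, -1, axis=0)[:, 1] - e[:, 1] * np.roll(e, -1, axis=0)[:, 0]
    cr = cr[np.abs(cr) > 1e-12 * np.max(np.abs(cr), initial=1.0)]
    return bool(len(cr) == 0 or np.all(cr > 0) or np.all(cr < 0))


def chord_through_centroid(contour: Contour, direction) -> float:
    """Length (mm) of the centroid chord collinear with an in-plane direction.

    Each of the two opposite rays is intersected with the closed boundary
    polygon and the farthest hit is used; the chord is the sum of the two ray
    distances.

    Raises
    ------
    CentroidOutsideError
        If either ray misses the polygon (centroid outside the loop).
    """
    u, v = _plane_basis(contour)
    d3 = np.asarray(direction, dtype=float)
    d2 = np.array([float(np.dot(d3, u)), float(np.dot(d3, v))])
    norm = np.linalg.norm(d2)
    if norm < 1e-12:
        raise ValueError("direction has no in-plane component")
    d2 /= norm
    poly = _projected_polygon(contour)
    reach = _ray_reaches(poly, np.vstack([d2, -d2]))
    if not np.all(np.isfinite(reach)):
        raise CentroidOutsideError("a centroid ray misses the contour polygon")
    return float(reach.sum())


@dataclass
class EccentricityRecord:
    """Per-contour eccentricity magnitude and orientation.

    ``theta_e`` is NaN when the contour is (numerically) circular, in which
    case the major direction is undefined.
    """

    sigma: float                      # mm (NaN when computed without a centerline)
    D: float                          # major diameter, mm
    d: float                          # orthogonal minor diameter, mm
    e: float                          # sqrt(1 - d^2/D^2), dimensionless
    theta_e: float                    # rad in [0, pi), NaN if undefined
    major_direction: np.ndarray       # in-plane unit vector (3,)
    contour_index: int = -1


def eccentricity(contour: Contour, angular_step: float = DEFAULT_ANGULAR_STEP) -> EccentricityRecord:
    """Orthogonal-diameter scan minimizing d/D.

    Directions ``phi`` are scanned over ``[0, pi)`` at ``angular_step``; for
    each, the orthogonal chord pair ``(chord(phi), chord(phi + pi/2))`` is
    evaluated, ``D`` is the longer and ``d`` the shorter of the minimizing
    pair (ties resolved toward the smallest ``phi``).  ``theta_e`` is left NaN
    here; see :func:`orientation`.
    """
    if angular_step <= 0 or angular_step > np.pi / 2:
        raise ValueError("angular_step must lie in (0, pi/2]")
    n_angles = int(np.ceil(np.pi / angular_step))
    n_angles += n_angles % 2  # quarter-turn partner must land on the grid
    poly = _projected_polygon(contour)
    if not _is_convex(poly):
        warnings.warn(f"contour {contour.index} is non-convex; chords use the "
                      "farthest boundary intersection per ray", stacklevel=2)
    phi = np.arange(2 * n_angles) * (np.pi / n_angles)   # full circle of rays
    directions = np.column_stack([np.cos(phi), np.sin(phi)])
    reach = _ray_reaches(poly, directions)
    if not np.all(np.isfinite(reach)):
        raise CentroidOutsideError("a centroid ray misses the contour polygon")
    chords = reach[:n_angles] + reach[n_angles:]          # chord(phi), phi in [0, pi)
    partner = np.roll(chords, -n_angles // 2)             # chord(phi + pi/2)
    big = np.maximum(chords, partner)
    small = np.minimum(chords, partner)
    ratio = small / big
    best = int(np.argmin(ratio))                          # first occurrence = smallest phi
    D, d = float(big[best]), float(small[best])
    phi_major = phi[best] if chords[best] >= partner[best] else phi[best] + np.pi / 2
    u, v = _plane_basis(contour)
    major3 = np.cos(phi_major) * u + np.sin(phi_major) * v
    e = float(np.sqrt(max(0.0, 1.0 - (d * d) / (D * D))))
    return EccentricityRecord(sigma=np.nan, D=D, d=d, e=e, theta_e=np.nan,
                              major_direction=major3, contour_index=contour.index)


def orientation(record: EccentricityRecord, contour: Contour, gamma_point,
                e_min: float = 1e-6) -> float:
    """Angle between the major diameter and the Greenwich direction.

    Because a diameter is undirected, the angle is folded to the acute
    representative ``min(a, pi - a)``; the result lies in ``[0, pi/2]``
    (subset of ``[0, pi)``).  Returns NaN when the eccentricity is below
    ``e_min`` (circular contour, orientation undefined).
    """
    if record.e < e_min:
        return float("nan")
    n = contour.plane_normal
    g = np.asarray(gamma_point, dtype=float) - contour.centroid
    g = g - np.dot(g, n) * n
    ng = np.linalg.norm(g)
    if ng < 1e-12:
        return float("nan")
    g /= ng
    m = record.major_direction
    angle = float(np.arctan2(np.linalg.norm(np.cross(g, m)), np.dot(g, m)))
    return min(angle, np.pi - angle)


def eccentricity_profile(stack: ContourStack, frame: GreenwichFrame,
                         centerline: Centerline,
                         angular_step: float = DEFAULT_ANGULAR_STEP) -> list[EccentricityRecord]:
    """One eccentricity record per contour, ordered by sigma."""
    records = []
    for i, contour in enumerate(stack):
        rec = eccentricity(contour, angular_step)
        rec.sigma = float(centerline.sigma_of_node[i])
        rec.theta_e = orientation(rec, contour, frame.gamma_points[i])
        records.append(rec)
    return records


def spirality(profile: list[EccentricityRecord]) -> np.ndarray:
    """Central finite difference of unwrapped ``theta_e`` with sigma (rad/mm).

    ``theta_e`` lives on ``[0, pi)`` and is unwrapped with period pi before
    differencing.  Contours with undefined orientation are skipped (logged as
    gaps); the result has one value per record, NaN at the two ends of each
    defined run and at skipped records.
    """
    if len(profile) < 3:
        raise ValueError("spirality needs at least 3 records")
    sigma = np.array([r.sigma for r in profile])
    theta = np.array([r.theta_e for r in profile])
    out = np.full(len(profile), np.nan)
    good = np.flatnonzero(np.isfinite(theta))
    if len(good) < 3:
        return out
    if len(good) < len(profile):
        warnings.warn(f"{len(profile) - len(good)} contours with undefined "
                      "orientation skipped in spirality", stacklevel=2)
    unwrapped = np.unwrap(theta[good], period=np.pi)
    s = sigma[good]
    out[good[1:-1]] = (unwrapped[2:] - unwrapped[:-2]) / (s[2:] - s[:-2])
    return out


def profile_to_dataframe(profile: list[EccentricityRecord]) -> pd.DataFrame:
    """Tabulate a profile (sigma_mm, D_mm, d_mm, e, theta_e_rad)."""
    return pd.DataFrame({
        "contour": [r.contour_index for r in profile],
        "sigma_mm": [r.sigma for r in profile],
        "D_mm": [r.D for r in profile],
        "d_mm": [r.d for r in profile],
        "e": [r.e for r in profile],
        "theta_e_rad": [r.theta_e for r in profile],
    })
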