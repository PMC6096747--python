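"""Pointwise surface curvature by windowed three-point circle fitting.

Curvature at a surface point is the reciprocal of the radius of the circle
through the point and its two symmetric window neighbours, taken either along
the longitudinal direction (neighbours at ``sigma +/- w/2``, same ``theta``)
or along the circumferential direction (neighbours at ``theta +/- w/2`` on the
same interpolated contour).  The window is the full span between the two outer
points.  Curvature is an unsigned magnitude, reported in 1/cm by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CylindricalSurface
from .errors import DegenerateInputError, GridAlignmentError, OutOfDomainError

__all__ = [
    "DEFAULT_WINDOW_SIGMA",
    "DEFAULT_WINDOW_THETA",
    "CurvatureField",
    "ProxyField",
    "circle_fit_curvature",
    "longitudinal_curvature",
    "circumferential_curvature",
    "curvature_field",
    "proxy_fields",
    "difference_field",
    "scaled_window_sigma",
]

DEFAULT_WINDOW_SIGMA = 30.0       # mm; roughly one vessel diameter
DEFAULT_WINDOW_THETA = np.pi / 4  # rad; one eighth of the circumference

#: triangles with area below COLLINEARITY_TOL * max_side**2 are treated as flat
COLLINEARITY_TOL = 1e-12

_UNIT_SCALE = {"cm": 10.0, "mm": 1.0}  # multiply 1/mm curvature by this


def circle_fit_curvature(p1, p2, p3) -> float:
    """Curvature magnitude 1/R of the circle through three 3D points.

    Computed from the circumradius ``R = |a||b||c| / (4 * area)``.  Collinear
    triples (area below tolerance) return 0.  Units follow the input
    coordinates (1/mm for mm input).

    Raises
    ------
    DegenerateInputError
        If any two of the points coincide.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    longest = max(a, b, c)
    if min(a, b, c) <= 1e-12 * max(longest, 1.0):
        raise DegenerateInputError("coincident points in three-point circle fit")
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
    if area < COLLINEARITY_TOL * longest ** 2:
        return 0.0
    return float(4.0 * area / (a * b * c))


def longitudinal_curvature(surface: CylindricalSurface, sigma0: float,
                           theta0: float, window: float = DEFAULT_WINDOW_SIGMA,
                           units: str = "cm") -> float:
    """Curvature along the sigma direction at ``(sigma0, theta0)``.

    The circle is fit through the surface points at ``sigma0 - w/2``,
    ``sigma0`` and ``sigma0 + w/2``, all at angular coordinate ``theta0``.

    Raises
    ------
    OutOfDomainError
        If the window extends beyond the sampled sigma range.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = 0.5 * window
    p1 = surface.point(sigma0 - half, theta0)
    p2 = surface.point(sigma0, theta0)
    p3 = surface.point(sigma0 + half, theta0)
    return circle_fit_curvature(p1, p2, p3) * _UNIT_SCALE[units]


def circumferential_curvature(surface: CylindricalSurface, sigma0: float,
                              theta0: float, window: float = DEFAULT_WINDOW_THETA,
                              units: str = "cm") -> float:
    """Curvature along the theta direction at ``(sigma0, theta0)``.

    The circle is fit through the interpolated contour points at
    ``theta0 - w/2``, ``theta0`` and ``theta0 + w/2`` (theta wraps
    circularly), all at ``sigma0``.
    """
    if not 0 < window < np.pi:
        raise ValueError("circumferential window must lie in (0, pi)")
    half = 0.5 * window
    p1 = surface.point(sigma0, theta0 - half)
    p2 = surface.point(sigma0, theta0)
    p3 = surface.point(sigma0, theta0 + half)
    return circle_fit_curvature(p1, p2, p3) * _UNIT_SCALE[units]


@dataclass
class CurvatureField:
    """Directional curvature magnitude on the stored (sigma, theta) grid.

    ``values[i][j]`` is the curvature at contour ``i``, sorted theta sample
    ``j``; ``defined[i][j]`` is False where the window exceeded the domain or
    the fit was degenerate.
    """

    direction: str                    # "longitudinal" | "circumferential"
    window: float                     # mm or radians
    sigma_grid: np.ndarray
    theta_samples: list[np.ndarray]
    values: list[np.ndarray]
    defined: list[np.ndarray]
    units: str = "cm"
    contour_indices: np.ndarray | None = None
    point_order: list[np.ndarray] | None = None  # sorted-theta -> original index

    @property
    def n(self) -> int:
        return int(len(self.sigma_grid))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, defined) as 2D arrays; requires a uniform point count."""
        m = {len(v) for v in self.values}
        if len(m) != 1:
            raise GridAlignmentError("ragged field cannot be converted to a 2D array")
        return np.array(self.values), np.array(self.defined)

    def defined_values(self) -> np.ndarray:
        return np.concatenate([v[d] for v, d in zip(self.values, self.defined)]) \
            if self.n else np.empty(0)


def curvature_field(surface: CylindricalSurface, direction: str,
                    window: float | None = None, units: str = "cm") -> CurvatureField:
    """Evaluate directional curvature at every stored grid node.

    Longitudinal nodes within ``window/2`` of either sigma end are masked
    (no one-sided windows); degenerate fits are masked rather than raised.
    """
    if direction not in ("longitudinal", "circumferential"):
        raise ValueError(f"unknown direction {direction!r}")
    if window is None:
        window = DEFAULT_WINDOW_SIGMA if direction == "longitudinal" else DEFAULT_WINDOW_THETA
    lo, hi = surface.sigma_range
    half = 0.5 * window
    values, defined = [], []
    for i in range(surface.n):
        sigma = float(surface.sigma_grid[i])
        thetas = surface.theta_samples[i]
        vals = np.zeros(len(thetas))
        mask = np.ones(len(thetas), dtype=bool)
        in_domain = (direction == "circumferential") or \
            (sigma - half >= lo - 1e-9 and sigma + half <= hi + 1e-9)
        if not in_domain:
            mask[:] = False
        else:
            for j, theta in enumerate(thetas):
                try:
                    if direction == "longitudinal":
                        vals[j] = longitudinal_curvature(surface, sigma, theta, window, units)
                    else:
                        vals[j] = circumferential_curvature(surface, sigma, theta, window, units)
                except (DegenerateInputError, OutOfDomainError):
                    mask[j] = False
        values.append(vals)
        defined.append(mask)
    return CurvatureField(direction=direction, window=float(window),
                          sigma_grid=surface.sigma_grid.copy(),
                          theta_samples=[t.copy() for t in surface.theta_samples],
                          values=values, defined=defined, units=units,
                          contour_indices=surface.contour_indices.copy(),
                          point_order=[o.copy() for o in surface.point_order])


@dataclass
class ProxyField:
    """Products and means of the two directional curvatures.

    The product approximates the Gaussian curvature (1/cm^2) and the mean
    approximates the mean curvature (1/cm); both are proxies, not the true
    patch-based quantities.  Defined only where both parents are defined.
    """

    gaussian_proxy: list[np.ndarray]
    mean_proxy: list[np.ndarray]
    defined: list[np.ndarray]
    sigma_grid: np.ndarray
    units: str = "cm"


def _check_same_grid(a: CurvatureField, b: CurvatureField) -> None:
    if a.n != b.n or any(len(x) != len(y) for x, y in zip(a.values, b.values)):
        raise GridAlignmentError("fields are not on the same grid")
    if not np.allclose(a.sigma_grid, b.sigma_grid, atol=1e-9):
        raise GridAlignmentError("fields have different sigma grids")


def proxy_fields(long_field: CurvatureField, circ_field: CurvatureField) -> ProxyField:
    """Elementwise product and mean of the two directional fields."""
    _check_same_grid(long_field, circ_field)
    if long_field.units != circ_field.units:
        raise GridAlignmentError("fields carry different units")
    gauss, mean, defined = [], [], []
    for lv, ld, cv, cd in zip(long_field.values, long_field.defined,
                              circ_field.values, circ_field.defined):
        d = ld & cd
        g = np.where(d, lv * cv, 0.0)
        m = np.where(d, 0.5 * (lv + cv), 0.0)
        gauss.append(g)
        mean.append(m)
        defined.append(d)
    return ProxyField(gaussian_proxy=gauss, mean_proxy=mean, defined=defined,
                      sigma_grid=long_field.sigma_grid.copy(), units=long_field.units)


def difference_field(field_a: CurvatureField, field_b: CurvatureField) -> CurvatureField:
    """Pointwise ``|kappa_a - kappa_b|`` on the common Lagrangian grid.

    Nodes are matched by contour index (the Lagrangian label shared by two
    states of the same vessel) and sorted theta position; the sigma ranges may
    differ, in which case the difference is restricted to the overlap.
    """
    if field_a.direction != field_b.direction:
        raise GridAlignmentError("cannot difference fields of different directions")
    if field_a.units != field_b.units:
        raise GridAlignmentError("fields carry different units")
    ia = {int(ci): i for i, ci in enumerate(field_a.contour_indices)}
    ib = {int(ci): i for i, ci in enumerate(field_b.contour_indices)}
    common = sorted(set(ia) & set(ib))
    if not common:
        raise GridAlignmentError("fields share no contour labels (disjoint sigma ranges)")
    sigma, thetas, values, defined, labels = [], [], [], [], []
    for ci in common:
        a, b = ia[ci], ib[ci]
        if len(field_a.values[a]) != len(field_b.values[b]):
            raise GridAlignmentError(f"contour {ci} has different point counts in the two fields")
        d = field_a.defined[a] & field_b.defined[b]
        values.append(np.where(d, np.abs(field_a.values[a] - field_b.values[b]), 0.0))
        defined.append(d)
        thetas.append(field_a.theta_samples[a].copy())
        sigma.append(field_a.sigma_grid[a])
        labels.append(ci)
    return CurvatureField(direction=field_a.direction, window=field_a.window,
                          sigma_grid=np.array(sigma), theta_samples=thetas,
                          values=values, defined=defined, units=field_a.units,
                          contour_indices=np.array(labels, dtype=int))


def scaled_window_sigma(surface: CylindricalSurface) -> float:
    """Longitudinal window rescaled to the mean vessel diameter.

    The default 30 mm window corresponds to roughly one vessel diameter for a
    ~30 mm vessel; this helper returns ``2 * mean(r)`` so analyses of vessels
    of a different caliber can keep the same relative window.
    """
    mean_r = float(np.mean(np.concatenate([r for r in surface.radii])))
    return 2.0 * mean_r
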