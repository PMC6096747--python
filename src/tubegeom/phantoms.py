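"""Idealized software phantoms with analytic reference geometry.

Two phantoms are generated as ordinary contour stacks (plus a small branch
stub used for fiducial detection), together with per-node analytic curvature
and per-contour analytic eccentricity:

* ``simple``  -- one 90 degree bend, uniform circular cross sections.
* ``complex`` -- two 90 degree bends in orthogonal planes, elliptical cross
  sections whose orientation rotates by a quarter turn through a short
  circular transition on the middle straight segment.

Both carry their minor in-plane semi-extent in the bend plane, so the surface
track radii (and hence the analytic longitudinal curvatures) follow directly
from the bend radii.  The generated contours are exactly orthogonal to the
analytic centerline, and centroids of the evenly sampled sections lie exactly
on it (point sets are centrally symmetric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Contour, ContourStack, CylindricalSurface
from .curvature import CurvatureField, curvature_field
from .errors import DegeneratePhantomError, NoDataError

__all__ = [
    "PhantomSpec",
    "TrackRef",
    "AnalyticReference",
    "generate_simple",
    "generate_complex",
    "error_summary",
    "window_sweep",
    "track_peak",
    "theta_column",
]

_TWO_PI = 2.0 * np.pi


# --------------------------------------------------------------------------
# parametric centerline path with a transported frame
# --------------------------------------------------------------------------

class _Path:
    """Piecewise straight/arc centerline carrying an orthonormal frame.

    State is ``(p, t, e1, e2)`` with ``t = e1 x e2``.  Bends rotate the
    tangent toward ``e1`` or ``e2``; the turning frame vector keeps pointing
    at the bend center while the other is parallel-transported unchanged.
    """

    def __init__(self):
        self._segments: list[dict] = []
        self._state = (np.zeros(3), np.array([0.0, 0.0, 1.0]),
                       np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        self.total = 0.0

    def add_straight(self, length: float) -> "_Path":
        p, t, e1, e2 = self._state
        self._segments.append(dict(kind="straight", s0=self.total, length=length,
                                   p=p, t=t, e1=e1, e2=e2))
        self._state = (p + length * t, t, e1, e2)
        self.total += length
        return self

    def add_bend(self, radius: float, angle: float, toward: str) -> "_Path":
        p, t, e1, e2 = self._state
        length = radius * angle
        self._segments.append(dict(kind="bend", s0=self.total, length=length,
                                   radius=radius, toward=toward, p=p, t=t, e1=e1, e2=e2))
        u = e1 if toward == "e1" else e2
        phi = angle
        t1 = t * np.cos(phi) + u * np.sin(phi)
        u1 = -t * np.sin(phi) + u * np.cos(phi)
        p1 = p + radius * (np.sin(phi) * t + (1.0 - np.cos(phi)) * u)
        if toward == "e1":
            self._state = (p1, t1, u1, e2)
        else:
            self._state = (p1, t1, e1, u1)
        self.total += length
        return self

    def segment_at(self, s: float) -> dict:
        for seg in self._segments:
            if s <= seg["s0"] + seg["length"] + 1e-9:
                return seg
        return self._segments[-1]

    def frame_at(self, s: float):
        seg = self.segment_at(s)
        ds = s - seg["s0"]
        p, t, e1, e2 = seg["p"], seg["t"], seg["e1"], seg["e2"]
        if seg["kind"] == "straight":
            return p + ds * t, t, e1, e2
        radius = seg["radius"]
        u = e1 if seg["toward"] == "e1" else e2
        phi = ds / radius
        t1 = t * np.cos(phi) + u * np.sin(phi)
        u1 = -t * np.sin(phi) + u * np.cos(phi)
        p1 = p + radius * (np.sin(phi) * t + (1.0 - np.cos(phi)) * u)
        if seg["toward"] == "e1":
            return p1, t1, u1, e2
        return p1, t1, e1, u1


# --------------------------------------------------------------------------
# specs and references
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters for phantom generation.  All lengths in mm.

    For the simple phantom ``semi_major == semi_minor`` is the circular
    radius.  ``transition_*`` applies to the complex phantom only.
    """

    kind: str = "simple"
    contour_spacing: float = 5.0
    points_per_contour: int = 96
    semi_major: float = 10.0
    semi_minor: float = 10.0
    leg1: float = 60.0
    leg2: float = 60.0
    leg3: float = 0.0
    bend1_radius: float = 30.0
    bend2_radius: float = 0.0           # 0: no second bend
    transition_center_arc: float = 0.0  # 0: no transition
    transition_length: float = 30.0
    branch: bool = True
    branch_radius: float = 6.0
    branch_length: float = 15.0
    branch_arc: float = 20.0            # attach position along the proximal leg
    branch_points: int = 32
    branch_contours: int = 6
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.contour_spacing <= 0:
            raise DegeneratePhantomError("contour_spacing must be positive")
        if self.points_per_contour < 16:
            raise DegeneratePhantomError("points_per_contour must be >= 16")
        for name in ("semi_major", "semi_minor", "leg1", "leg2", "bend1_radius"):
            if getattr(self, name) <= 0:
                raise DegeneratePhantomError(f"{name} must be positive")


@dataclass(frozen=True)
class TrackRef:
    """A named reference line on the phantom surface.

    ``psi`` is the material angle of the track (radians from the branch-side
    frame direction, which the pipeline resolves to ``theta``);
    ``arc_range`` bounds the centerline arc positions of its contours;
    ``analytic_cm`` is the analytic curvature along the track in 1/cm.
    """

    name: str
    direction: str
    psi: float
    arc_range: tuple[float, float]
    analytic_cm: float


@dataclass
class AnalyticReference:
    """Analytic per-node curvature and per-contour eccentricity.

    Arrays are indexed by (contour position, original point index); masks are
    False inside blend zones where a finite window necessarily mixes segments
    of different analytic curvature.
    """

    kind: str
    s_grid: np.ndarray                 # (n,) centerline arc position per contour
    psi_grid: np.ndarray               # (m,) material angles of the samples
    long_curvature: np.ndarray         # (n, m), 1/cm (may contain inf at a cusp)
    long_mask: np.ndarray              # (n, m) bool
    circ_curvature: np.ndarray         # (n, m), 1/cm
    circ_mask: np.ndarray              # (n, m) bool
    ecc_e: np.ndarray                  # (n,)
    ecc_theta: np.ndarray              # (n,) rad, NaN where undefined
    tracks: dict = field(default_factory=dict)
    gamma_seed_arc: float = 0.0        # expected arc position of the origin contour
    transition_interval: Optional[tuple[float, float]] = None
    recommended_fiducial_tolerance: float = 2.5
    blend_margin: float = 15.0

    def sigma_from_arc(self, s: float) -> float:
        """Convert an arc position to the sigma of the anchored frame."""
        return s - self.gamma_seed_arc


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _section_points(p, e1, e2, psis, a, b, rho):
    """Sample an ellipse (semi-axes a, b; major axis at angle rho from e1)
    at fixed material angles ``psis`` measured from e1 toward e2."""
    ang = psis - rho
    r = a * b / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
    return (p[None, :]
            + r[:, None] * np.cos(psis)[:, None] * e1[None, :]
            + r[:, None] * np.sin(psis)[:, None] * e2[None, :]), r


def _ellipse_circ_curvature(a, b, psis, rho):
    """Analytic curvature (1/mm) of the ellipse at the sampled polar angles."""
    ang = psis - rho
    r = a * b / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
    ct = r * np.cos(ang) / a
    st = r * np.sin(ang) / b
    return a * b / ((a * st) ** 2 + (b * ct) ** 2) ** 1.5


def _make_branch(spec: PhantomSpec, attach_arc: float, path: _Path) -> ContourStack:
    """Straight daughter stub along +e1, its first section centered on the
    mother surface so the discrete boundaries interleave."""
    p, t, e1, e2 = path.frame_at(attach_arc)
    betas = np.arange(spec.branch_points) * (_TWO_PI / spec.branch_points)
    # in-plane mother half-width along e1 at the attach point is semi_minor
    start = spec.semi_minor
    centers = start + np.linspace(0.0, spec.branch_length, spec.branch_contours)
    contours = []
    for i, x in enumerate(centers):
        c = p + x * e1
        pts = (c[None, :]
               + spec.branch_radius * np.cos(betas)[:, None] * e2[None, :]
               + spec.branch_radius * np.sin(betas)[:, None] * t[None, :])
        contours.append(Contour.from_points(i, pts, orient_along=e1))
    return ContourStack(contours, label="branch")


def _assemble(spec: PhantomSpec, path: _Path, section_fn, long_fn) -> tuple[ContourStack, AnalyticReference]:
    """Build the mother stack and the analytic reference on a common grid."""
    m = spec.points_per_contour
    psis = np.arange(m) * (_TWO_PI / m)
    n = int(np.floor(path.total / spec.contour_spacing + 1e-9)) + 1
    s_grid = np.arange(n) * spec.contour_spacing
    rng = np.random.default_rng(spec.seed)

    contours = []
    long_c = np.zeros((n, m))
    circ_c = np.zeros((n, m))
    ecc_e = np.zeros(n)
    ecc_th = np.full(n, np.nan)
    boundaries = [seg["s0"] for seg in path._segments[1:]]
    for i, s in enumerate(s_grid):
        p, t, e1, e2 = path.frame_at(s)
        a, b, rho = section_fn(s)
        pts, _ = _section_points(p, e1, e2, psis, a, b, rho)
        if spec.jitter > 0:
            pts = pts + rng.normal(0.0, spec.jitter, pts.shape)
        contours.append(Contour.from_points(i, pts, orient_along=t))
        long_c[i] = 10.0 * long_fn(s, psis)          # 1/mm -> 1/cm
        circ_c[i] = 10.0 * _ellipse_circ_curvature(a, b, psis, rho)
        if a > b:
            ecc_e[i] = np.sqrt(1.0 - (b / a) ** 2)
            ecc_th[i] = rho % np.pi
    stack = ContourStack(contours, label=f"{spec.kind}-phantom")

    # Blend mask: a symmetric window of +-blend_margin must not straddle a
    # segment boundary (or the cross-section transition, handled by caller).
    margin = 15.0
    long_mask = np.ones((n, m), dtype=bool)
    for i, s in enumerate(s_grid):
        near = any(abs(s - bd) < margin - 1e-9 for bd in boundaries)
        edge = s - margin < s_grid[0] - 1e-9 or s + margin > s_grid[-1] + 1e-9
        if near or edge:
            long_mask[i] = False
    long_mask &= np.isfinite(long_c) & (long_c < 50.0)   # exclude cusp blowup
    circ_mask = np.ones((n, m), dtype=bool)

    ref = AnalyticReference(kind=spec.kind, s_grid=s_grid, psi_grid=psis,
                            long_curvature=long_c, long_mask=long_mask,
                            circ_curvature=circ_c, circ_mask=circ_mask,
                            ecc_e=ecc_e, ecc_theta=ecc_th, blend_margin=margin)
    return stack, ref


def _expected_gamma_arc(spec: PhantomSpec) -> float:
    """Arc position of the contour the fiducial search is expected to pick:
    the grid contour nearest the distal edge of the branch ostium."""
    edge = spec.branch_arc + spec.branch_radius
    return round(edge / spec.contour_spacing) * spec.contour_spacing


def generate_simple(spec: Optional[PhantomSpec] = None):
    """Simple phantom: circular sections, one 90 degree bend.

    Returns ``(mother, branch, reference)``.  Defaults: radius 10 mm,
    centerline bend radius 30 mm (inner/outer surface track radii 20/40 mm),
    60 mm straight legs, 5 mm contour spacing, 96 points per contour, and a
    6 mm branch stub on the proximal leg for fiducial detection.
    """
    if spec is None:
        spec = PhantomSpec(kind="simple", leg2=60.0)
    if spec.semi_major != spec.semi_minor:
        raise DegeneratePhantomError("simple phantom sections must be circular")
    r, R = spec.semi_major, spec.bend1_radius
    if r >= R:
        raise DegeneratePhantomError(
            f"section radius {r} must be smaller than the bend radius {R}")
    path = _Path().add_straight(spec.leg1).add_bend(R, np.pi / 2, "e1").add_straight(spec.leg2)
    bend_lo, bend_hi = spec.leg1, spec.leg1 + R * np.pi / 2

    def section_fn(s):
        return r, r, 0.0

    def long_fn(s, psis):
        if bend_lo - 1e-9 <= s <= bend_hi + 1e-9:
            return 1.0 / (R - r * np.cos(psis))
        return np.zeros_like(psis)

    mother, ref = _assemble(spec, path, section_fn, long_fn)
    branch = _make_branch(spec, spec.branch_arc, path) if spec.branch else None
    ref.gamma_seed_arc = _expected_gamma_arc(spec)
    ref.recommended_fiducial_tolerance = spec.contour_spacing / 2.0
    ref.tracks = {
        "bend_inner": TrackRef("bend_inner", "longitudinal", 0.0,
                               (bend_lo, bend_hi), 10.0 / (R - r)),
        "bend_outer": TrackRef("bend_outer", "longitudinal", np.pi,
                               (bend_lo, bend_hi), 10.0 / (R + r)),
        "straight_proximal": TrackRef("straight_proximal", "longitudinal", 0.0,
                                      (0.0, bend_lo), 0.0),
        "straight_distal": TrackRef("straight_distal", "longitudinal", 0.0,
                                    (bend_hi, path.total), 0.0),
        "circumference": TrackRef("circumference", "circumferential", 0.0,
                                  (0.0, path.total), 10.0 / r),
    }
    return mother, branch, ref


def generate_complex(spec: Optional[PhantomSpec] = None):
    """Complex phantom: elliptical sections, two 90 degree bends in
    orthogonal planes, and a quarter-turn section-orientation transition
    through a circular cross section on the middle segment.

    Returns ``(mother, branch, reference)``.  Defaults: 40 mm major / 20 mm
    minor section diameters with the minor semi-axis in each bend plane;
    centerline bend radii 10 mm (first) and 20 mm (second), giving outer /
    inner surface track radii of 20 mm and 10 mm; the transition is centered
    96 mm distal of the expected coordinate origin.
    """
    if spec is None:
        leg1 = 60.0
        spec = PhantomSpec(kind="complex", semi_major=20.0, semi_minor=10.0,
                           bend1_radius=10.0, bend2_radius=20.0,
                           leg1=leg1, leg2=80.0 - 5.0 * np.pi, leg3=60.0,
                           transition_center_arc=0.0, transition_length=30.0)
    a0, b0 = spec.semi_major, spec.semi_minor
    R1, R2 = spec.bend1_radius, spec.bend2_radius
    if a0 <= b0:
        raise DegeneratePhantomError("complex phantom needs semi_major > semi_minor")
    if b0 > R1 or (R2 > 0 and b0 >= R2):
        raise DegeneratePhantomError("in-plane semi-extent exceeds a bend radius")
    if b0 == R1:
        warnings.warn("in-plane semi-extent equals the first bend radius; the "
                      "inner surface of that bend degenerates to a cusp", stacklevel=2)

    path = (_Path().add_straight(spec.leg1).add_bend(R1, np.pi / 2, "e1")
            .add_straight(spec.leg2).add_bend(R2, np.pi / 2, "e2")
            .add_straight(spec.leg3))
    b1_lo = spec.leg1
    b1_hi = b1_lo + R1 * np.pi / 2
    b2_lo = b1_hi + spec.leg2
    b2_hi = b2_lo + R2 * np.pi / 2

    gamma_arc = _expected_gamma_arc(spec)
    t_center = spec.transition_center_arc or (gamma_arc + 96.0)
    half_t = spec.transition_length / 2.0
    t_lo, t_hi = t_center - half_t, t_center + half_t
    if not (b1_hi < t_lo and t_hi < b2_lo):
        raise DegeneratePhantomError("transition does not fit on the middle segment")

    def section_fn(s):
        # Major semi-axis ramps a0 -> b0 -> a0 through the transition while
        # the major-axis direction flips a quarter turn at the (circular)
        # center, keeping the sampled material points continuous.
        if s <= t_lo or s >= t_hi:
            a = a0
        elif s < t_center:
            a = b0 + (a0 - b0) * 0.5 * (1.0 + np.cos(np.pi * (s - t_lo) / half_t))
        else:
            a = b0 + (a0 - b0) * 0.5 * (1.0 - np.cos(np.pi * (s - t_center) / half_t))
        rho = np.pi / 2 if s < t_center else 0.0
        return a, b0, rho

    def long_fn(s, psis):
        if b1_lo - 1e-9 <= s <= b1_hi + 1e-9:
            track = R1 - b0 * np.cos(psis)      # bend toward e1
            with np.errstate(divide="ignore"):
                return np.where(np.abs(track) < 1e-9, np.inf, 1.0 / track)
        if b2_lo - 1e-9 <= s <= b2_hi + 1e-9:
            return 1.0 / (R2 - b0 * np.sin(psis))  # bend toward e2
        return np.zeros_like(psis)

    mother, ref = _assemble(spec, path, section_fn, long_fn)
    branch = _make_branch(spec, spec.branch_arc, path) if spec.branch else None
    ref.gamma_seed_arc = gamma_arc
    ref.recommended_fiducial_tolerance = spec.contour_spacing / 2.0
    ref.transition_interval = (t_lo, t_hi)
    # Longitudinal windows must not straddle the transition either.
    margin = ref.blend_margin
    for i, s in enumerate(ref.s_grid):
        if t_lo - margin < s < t_hi + margin:
            ref.long_mask[i] = False
    ref.tracks = {
        "bend1_outer": TrackRef("bend1_outer", "longitudinal", np.pi,
                                (b1_lo, b1_hi), 10.0 / (R1 + b0)),
        "bend2_inner": TrackRef("bend2_inner", "longitudinal", np.pi / 2,
                                (b2_lo, b2_hi), 10.0 / (R2 - b0)),
        "straight_proximal": TrackRef("straight_proximal", "longitudinal", 0.0,
                                      (0.0, b1_lo), 0.0),
        "straight_distal": TrackRef("straight_distal", "longitudinal", 0.0,
                                    (b2_hi, path.total), 0.0),
        # Circumferential reference points on the proximal straight: the
        # ellipse major-axis vertices sit a quarter turn from the branch side.
        "vertex_proximal": TrackRef("vertex_proximal", "circumferential", np.pi / 2,
                                    (5.0, b1_lo - 5.0), 10.0 * a0 / b0 ** 2),
        "flat_proximal": TrackRef("flat_proximal", "circumferential", 0.0,
                                  (5.0, b1_lo - 5.0), 10.0 * b0 / a0 ** 2),
        "vertex_distal": TrackRef("vertex_distal", "circumferential", 0.0,
                                  (b2_hi + 5.0, path.total - 5.0), 10.0 * a0 / b0 ** 2),
    }
    return mother, branch, ref


# --------------------------------------------------------------------------
# computed-vs-analytic comparison
# --------------------------------------------------------------------------

def _reference_arrays(reference: AnalyticReference, direction: str):
    if direction == "longitudinal":
        return reference.long_curvature, reference.long_mask
    return reference.circ_curvature, reference.circ_mask


def error_summary(computed: CurvatureField, reference: AnalyticReference):
    """(min, max, median) of ``|computed - analytic|`` in 1/cm.

    Masked nodes (window out of domain, degenerate fits, analytic blend
    zones) are excluded.
    """
    ref_vals, ref_mask = _reference_arrays(reference, computed.direction)
    scale = 1.0 if computed.units == "cm" else 0.1
    diffs = []
    for i in range(computed.n):
        order = (computed.point_order[i] if computed.point_order is not None
                 else np.arange(len(computed.values[i])))
        ok = computed.defined[i] & ref_mask[i][order]
        if not np.any(ok):
            continue
        diffs.append(np.abs(computed.values[i][ok] - scale * ref_vals[i][order][ok]))
    if not diffs:
        raise NoDataError("no overlapping defined nodes between field and reference")
    combined = np.concatenate(diffs)
    return float(combined.min()), float(combined.max()), float(np.median(combined))


def theta_column(field_or_surface, i: int, psi: float) -> int:
    """Sorted-theta column index on contour ``i`` closest to material angle
    ``psi`` (valid when the Greenwich track follows the branch-side material
    line, as it does on the phantoms)."""
    thetas = field_or_surface.theta_samples[i]
    d = np.abs(np.mod(thetas - psi + np.pi, _TWO_PI) - np.pi)
    return int(np.argmin(d))


def track_peak(field: CurvatureField, reference: AnalyticReference,
               track: TrackRef) -> float:
    """Maximum defined curvature over the nodes of a named track (1/cm)."""
    lo, hi = track.arc_range
    best = -np.inf
    for i, s in enumerate(reference.s_grid):
        if not lo - 1e-9 <= s <= hi + 1e-9:
            continue
        j = theta_column(field, i, track.psi)
        if field.defined[i][j]:
            best = max(best, float(field.values[i][j]))
    if not np.isfinite(best):
        raise NoDataError(f"track {track.name} has no defined nodes")
    return best * (10.0 if field.units == "mm" else 1.0)


def window_sweep(surface: CylindricalSurface, reference: AnalyticReference,
                 direction: str, windows, track: Optional[str] = None):
    """Curvature error versus window size.

    For each window the field is recomputed; the summary rows report the
    (min, max, median) absolute error and the relative error of the peak
    curvature on the named track (default: the track with the largest
    analytic curvature in that direction).
    """
    if track is None:
        candidates = [t for t in reference.tracks.values() if t.direction == direction
                      and t.analytic_cm > 0]
        track_ref = max(candidates, key=lambda t: t.analytic_cm)
    else:
        track_ref = reference.tracks[track]
    rows = []
    for w in windows:
        f = curvature_field(surface, direction, window=w)
        mn, mx, md = error_summary(f, reference)
        peak = track_peak(f, reference, track_ref)
        rel = abs(peak - track_ref.analytic_cm) / track_ref.analytic_cm
        rows.append(dict(window=float(w), err_min=mn, err_max=mx, err_median=md,
                         track=track_ref.name, peak_cm=peak,
                         peak_rel_error=rel))
    return rows
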