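"""ONL-Base extraction: level-set contours, admissibility criteria, selection.

The deformation of the ONL is read off a single iso-height contour of the
height image — the ONL-Base (ONL-B). Candidate contours are superlevel-set
boundaries traced at sub-pixel precision (marching squares with linear
interpolation along grid edges), restricted to the connected component that
contains the foveal peak. A candidate is admissible when it satisfies four
criteria:

1. the contour lies entirely within the height image (no border contact);
2. the concave portion (convex-hull area minus region area) is at most
   20,000 px^2;
3. the hull-to-region area ratio A/A0 is at most 1.2 (a solidity bound);
4. the contour is *restorable*: resampling its boundary to 100, 50 and 25
   points, fitting five elliptic Fourier harmonics and reconstructing must
   retain at least 95% of the original area (A1/A0 >= 0.95) for every
   point count.

The ONL-B is the lowest admissible level at or above the reference plane.

Elliptic Fourier descriptors follow the Kuhl-Giardina formulation over the
arc-length parameterization of the closed polygon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from skimage import measure

from .errors import (
    GeometryError,
    NoContourError,
    ParameterError,
    SelectionFailureError,
)
from .height_map import HeightImage, ReferenceLevel

logger = logging.getLogger(__name__)

# admissibility thresholds, in (lateral) pixel units on the 512x512 grid
CONCAVE_AREA_MAX_PX2 = 20_000.0
HULL_RATIO_MAX = 1.2
RESTORE_RATIO_MIN = 0.95
N_HARMONICS = 5
RESTORE_POINT_COUNTS = (100, 50, 25)


def _shoelace(vertices: np.ndarray) -> float:
    """Signed polygon area (positive for counterclockwise vertex order)."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """Closed simple polygon in image pixel coordinates (x = column, y = row).

    Vertices are stored in counterclockwise order (positive shoelace area);
    the closing edge from the last vertex back to the first is implicit.
    """

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError(f"vertices must be (n, 2), got {v.shape}")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 8:
            raise GeometryError(f"contour needs >= 8 vertices, got {len(v)}")
        signed = _shoelace(v)
        if signed == 0:
            raise GeometryError("contour has zero area")
        if signed < 0:
            v = v[::-1].copy()
        self.vertices = v

    @property
    def area_S(self) -> float:
        return abs(_shoelace(self.vertices))

    @property
    def perimeter_L(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def is_simple(self) -> bool:
        return Polygon(self.vertices).is_valid

    def closed_vertices(self) -> np.ndarray:
        """Vertex array with the first point repeated at the end."""
        return np.vstack([self.vertices, self.vertices[:1]])


@dataclass
class EfdCoefficients:
    """Kuhl-Giardina elliptic Fourier coefficients of a closed contour.

    ``harmonics[n-1] = (a_n, b_n, c_n, d_n)`` multiply cos/sin terms of the
    x (a, b) and y (c, d) series; ``dc`` is the contour centroid offset
    (A0, C0) of the arc-length parameterization.
    """

    harmonics: np.ndarray
    dc: tuple[float, float]

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)


def efd_fit(contour: Contour, n_harmonics: int = N_HARMONICS) -> EfdCoefficients:
    """Fit elliptic Fourier coefficients to a closed polygon.

    The polygon is traversed at constant speed along its edges (arc-length
    parameterization); coefficients are the exact Fourier integrals of that
    piecewise-linear curve.
    """
    if n_harmonics < 1:
        raise ParameterError("n_harmonics must be >= 1")
    if len(contour.vertices) < 2 * n_harmonics + 1:
        raise ParameterError(
            f"contour has {len(contour.vertices)} vertices; "
            f"need >= {2 * n_harmonics + 1} for {n_harmonics} harmonics"
        )
    pts = contour.closed_vertices()
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T == 0:
        raise GeometryError("contour has zero perimeter")

    n = np.arange(1, n_harmonics + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :] / T
    const = T / (2.0 * (n.ravel() ** 2) * np.pi**2)
    dcos = np.cos(phi[:, 1:]) - np.cos(phi[:, :-1])
    dsin = np.sin(phi[:, 1:]) - np.sin(phi[:, :-1])
    vx, vy = d[:, 0] / dt, d[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    dd = const * (dsin @ vy)

    # DC component: mean of the piecewise-linear x(t), y(t)
    xi = np.cumsum(d[:, 0]) - vx * t[1:]
    delta = np.cumsum(d[:, 1]) - vy * t[1:]
    A0 = float(np.sum(vx / 2.0 * np.diff(t**2) + xi * dt) / T + pts[0, 0])
    C0 = float(np.sum(vy / 2.0 * np.diff(t**2) + delta * dt) / T + pts[0, 1])

    return EfdCoefficients(harmonics=np.column_stack([a, b, c, dd]), dc=(A0, C0))


def efd_reconstruct(coeffs: EfdCoefficients, n_points: int) -> Contour:
    """Sample the truncated Fourier series at equally spaced parameter values."""
    if n_points < 8:
        raise ParameterError("n_points must be >= 8")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    cos = np.cos(2.0 * np.pi * n * t[None, :])
    sin = np.sin(2.0 * np.pi * n * t[None, :])
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.dc[0] + a @ cos + b @ sin
    y = coeffs.dc[1] + c @ cos + d @ sin
    return Contour(np.column_stack([x, y]))


def resample_contour(contour: Contour, n_points: int) -> Contour:
    """Resample the polygon boundary at equal arc-length spacing."""
    if n_points < 8:
        raise ParameterError("n_points must be >= 8")
    pts = contour.closed_vertices()
    d = np.diff(pts, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    t = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, t[-1], n_points, endpoint=False)
    x = np.interp(s, t, pts[:, 0])
    y = np.interp(s, t, pts[:, 1])
    return Contour(np.column_stack([x, y]))


def restore_ratio(
    contour: Contour,
    point_counts=RESTORE_POINT_COUNTS,
    n_harmonics: int = N_HARMONICS,
    recon_points: int = 512,
) -> float:
    """Minimum restored-area fraction A1/A0 over the boundary subsamplings.

    For each point count the boundary is resampled at equal arc length, a
    truncated Fourier fit is reconstructed densely, and A1 is the area of
    the original region that the reconstruction recovers (the intersection
    of the two polygons). A raw reconstruction-area quotient would stay
    near 1 for any zero-mean boundary ripple — smoothing removes outward
    and inward excursions alike — so it cannot detect non-restorable
    contours; the overlap fraction drops exactly when the truncated
    harmonics cannot follow the boundary.
    """
    from shapely.validation import make_valid

    A0 = contour.area_S
    if A0 <= 0:
        raise GeometryError("contour has zero area")
    orig = make_valid(Polygon(contour.vertices))
    ratios = []
    for m in point_counts:
        sub = resample_contour(contour, m)
        rec = efd_reconstruct(efd_fit(sub, n_harmonics), recon_points)
        recon = make_valid(Polygon(rec.vertices))
        ratios.append(orig.intersection(recon).area / A0)
    return float(min(ratios))


def convex_hull_deficit(contour: Contour) -> tuple[float, float]:
    """Concave-portion area and hull/region area ratio of the contour.

    Returns ``(concave_area_px, hull_ratio)`` where ``concave_area_px`` is
    the convex-hull area minus the region area and ``hull_ratio`` is their
    quotient (the reciprocal of solidity).
    """
    S = contour.area_S
    if S <= 0:
        raise GeometryError("contour encloses no area")
    hull = MultiPoint([tuple(p) for p in contour.vertices]).convex_hull
    if hull.geom_type != "Polygon":
        raise GeometryError("contour vertices are collinear; hull is degenerate")
    A_hull = hull.area
    return max(0.0, A_hull - S), A_hull / S


@dataclass
class CriteriaReport:
    """Diagnostics for the four ONL-B admissibility criteria at one level."""

    inside_hi: bool
    concave_area_px: float
    hull_ratio: float
    restore_ratio_min: float
    concave_area_max: float = CONCAVE_AREA_MAX_PX2
    hull_ratio_max: float = HULL_RATIO_MAX
    restore_ratio_min_allowed: float = RESTORE_RATIO_MIN

    @property
    def passed(self) -> bool:
        return (
            self.inside_hi
            and self.concave_area_px <= self.concave_area_max
            and self.hull_ratio <= self.hull_ratio_max
            and self.restore_ratio_min >= self.restore_ratio_min_allowed
        )

    def failing(self) -> list[str]:
        fails = []
        if not self.inside_hi:
            fails.append("inside_hi")
        if self.concave_area_px > self.concave_area_max:
            fails.append("concave_area")
        if self.hull_ratio > self.hull_ratio_max:
            fails.append("hull_ratio")
        if self.restore_ratio_min < self.restore_ratio_min_allowed:
            fails.append("restore_ratio")
        return fails

    def to_dict(self) -> dict:
        return {
            "inside_hi": self.inside_hi,
            "concave_area_px": self.concave_area_px,
            "hull_ratio": self.hull_ratio,
            "restore_ratio_min": self.restore_ratio_min,
            "passed": self.passed,
            "failing": self.failing(),
        }


@dataclass
class OnlBResult:
    """The selected ONL-Base: level, contour, and criteria diagnostics."""

    level_px: float
    level_um: float
    contour: Contour
    criteria: CriteriaReport

    @property
    def distance_rpe_um(self) -> float:
        """Distance from the RPE line to the ONL-B (heights are RPE-referenced)."""
        return self.level_um


def extract_level_contour(hi: HeightImage, level_px: float) -> Contour:
    """Trace the iso-height boundary at ``level_px`` around the foveal peak.

    The superlevel set ``heights >= level`` is labelled with 8-connectivity
    and only the component containing the global height maximum is kept;
    holes inside it are filled. The boundary is traced as a sub-pixel
    iso-contour (linear interpolation along grid edges). A component that is
    clipped by the image border yields a polygon closed along the border,
    which criterion 1 rejects downstream.
    """
    h = hi.heights_px
    hmax = h.max()
    if not (0 < level_px < hmax):
        raise NoContourError(
            f"level {level_px} outside the open interval (0, max height {hmax:.3f})"
        )
    mask = h >= level_px
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    peak = np.unravel_index(int(np.argmax(h)), h.shape)
    peak_label = labels[peak]
    if peak_label == 0:  # cannot happen while level < hmax, kept as a guard
        raise NoContourError("foveal peak not inside the superlevel set")
    comp = labels == peak_label
    filled = ndimage.binary_fill_holes(comp)

    # Isolate the peak component without disturbing sub-pixel interpolation:
    # other components are >= level and far from ours, push them below the
    # level; interior holes are pushed just above it so no inner boundary is
    # traced. Cells genuinely below the level next to our component are left
    # untouched -- they define the crossing positions.
    h_iso = h.copy()
    h_iso[mask & ~comp] = level_px - 1.0
    holes = filled & ~comp
    if holes.any():
        h_iso[holes] = level_px + 1e-6 * max(1.0, level_px)

    contours = measure.find_contours(h_iso, level=level_px)
    if not contours:
        raise NoContourError(f"no iso-contour found at level {level_px}")
    # find_contours returns (row, col); the component boundary is the longest
    arr = max(contours, key=len)
    verts = np.column_stack([arr[:, 1], arr[:, 0]])  # -> (x, y)
    return Contour(verts)


def evaluate_criteria(
    hi: HeightImage,
    contour: Contour,
    concave_area_max: float = CONCAVE_AREA_MAX_PX2,
    hull_ratio_max: float = HULL_RATIO_MAX,
    restore_min: float = RESTORE_RATIO_MIN,
    n_harmonics: int = N_HARMONICS,
    point_counts=RESTORE_POINT_COUNTS,
) -> CriteriaReport:
    """Evaluate the four ONL-B admissibility criteria for one contour."""
    nrows, ncols = hi.shape
    eps = 1e-9
    v = contour.vertices
    inside = bool(
        (v[:, 0] > eps).all()
        and (v[:, 0] < ncols - 1 - eps).all()
        and (v[:, 1] > eps).all()
        and (v[:, 1] < nrows - 1 - eps).all()
    )
    concave, hull_ratio = convex_hull_deficit(contour)
    rmin = restore_ratio(contour, point_counts=point_counts, n_harmonics=n_harmonics)
    return CriteriaReport(
        inside_hi=inside,
        concave_area_px=concave,
        hull_ratio=hull_ratio,
        restore_ratio_min=rmin,
        concave_area_max=concave_area_max,
        hull_ratio_max=hull_ratio_max,
        restore_ratio_min_allowed=restore_min,
    )


def select_onlb(
    hi: HeightImage,
    ref: ReferenceLevel,
    step_px: float = 1.0,
    max_level_frac: float = 0.95,
    **criteria_kwargs,
) -> OnlBResult:
    """Scan levels upward from the reference plane; return the lowest pass.

    Levels ``ref.level_px, ref.level_px + step, ...`` up to
    ``max_level_frac * max(height)`` are tested in order and the first one
    whose contour satisfies all four criteria is returned, with its height
    reported in micrometres as the distance from the RPE line. If no level
    passes, the error carries the per-level diagnostics for QC.
    """
    if step_px <= 0:
        raise ParameterError("step_px must be positive")
    hmax = float(hi.heights_px.max())
    top = max_level_frac * hmax
    diagnostics = []
    level = float(ref.level_px)
    while level <= top:
        if level <= 0:
            level += step_px
            continue
        try:
            contour = extract_level_contour(hi, level)
        except (NoContourError, GeometryError) as exc:
            # empty superlevel set, or a degenerate sliver (e.g. a clipped
            # corner fragment): record and move on
            diagnostics.append({"level_px": level, "error": str(exc)})
            level += step_px
            continue
        report = evaluate_criteria(hi, contour, **criteria_kwargs)
        entry = {"level_px": level, **report.to_dict()}
        diagnostics.append(entry)
        logger.debug("ONL-B level scan %.2f px: %s", level,
                     "pass" if report.passed else f"fail {report.failing()}")
        if report.passed:
            return OnlBResult(
                level_px=level,
                level_um=level * hi.axial_scale_um,
                contour=contour,
                criteria=report,
            )
        level += step_px
    raise SelectionFailureError(
        f"no level in [{ref.level_px}, {top:.2f}] px satisfies the ONL-B criteria",
        diagnostics=diagnostics,
    )
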