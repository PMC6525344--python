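"""Moment-method ellipse fitting and the three characteristic shape parameters.

The ONL-B region is summarized by the *equivalent ellipse* of its second
central moments: the ellipse with the same area-normalized covariance as
the region. Moments are computed analytically from the boundary polygon via
Green's-theorem line integrals (no rasterization bias). From the fit the
three size- and orientation-free deformation parameters are derived:

* circularity ``4*pi*S/L^2`` of the five-harmonic elliptic-Fourier-smoothed
  boundary (1 for a circle);
* area ratio ``S/(a*b)`` with the raw region area S and the full axis
  lengths a, b (``pi/4`` for a perfect ellipse);
* axis ratio ``a/b`` (elongation).

Angle convention: image coordinates have y = row increasing downward, but
axis angles are reported in the fundus view — degrees counterclockwise from
horizontal, wrapped to (-90, 90]. Right-eye (OD) angles are mirrored into
the left-eye frame so that "+" means the same anatomical direction in both
eyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .onlb import Contour, EfdCoefficients, N_HARMONICS, efd_fit, efd_reconstruct


@dataclass
class RegionMoments:
    """Area, centroid and area-normalized second central moments of a region."""

    area: float
    centroid: tuple[float, float]
    mu20: float
    mu02: float
    mu11: float


@dataclass
class EllipseFit:
    """Equivalent ellipse: center, full axis lengths, and major-axis angle."""

    center_O: tuple[float, float]
    major_axis_a: float
    minor_axis_b: float
    theta_deg: float  # counterclockwise from horizontal in the fundus view, (-90, 90]


@dataclass
class ShapeParams:
    """The three deformation parameters plus the laterality-adjusted angle."""

    circularity: float
    area_ratio: float
    axis_ratio: float
    axis_deg: float


def wrap_angle_deg(theta: float) -> float:
    """Wrap an axis angle (direction mod 180) into (-90, 90]."""
    w = (theta + 90.0) % 180.0 - 90.0
    return 90.0 if w == -90.0 else w


def region_moments(contour: Contour) -> RegionMoments:
    """Exact polygon moments via Green's-theorem line integrals.

    Second moments are central (about the centroid) and normalized by the
    region area, so for a disk of radius r: mu20 = mu02 = r^2/4.
    """
    v = contour.closed_vertices()
    x0, y0 = v[:-1, 0], v[:-1, 1]
    x1, y1 = v[1:, 0], v[1:, 1]
    cross = x0 * y1 - x1 * y0
    A = 0.5 * cross.sum()  # positive: vertices are stored counterclockwise
    if A <= 0:
        raise GeometryError("polygon has non-positive area")
    cx = (cross * (x0 + x1)).sum() / (6.0 * A)
    cy = (cross * (y0 + y1)).sum() / (6.0 * A)
    # raw second moments about the origin
    Ixx = (cross * (x0 * x0 + x0 * x1 + x1 * x1)).sum() / 12.0  # integral of x^2 dA
    Iyy = (cross * (y0 * y0 + y0 * y1 + y1 * y1)).sum() / 12.0  # integral of y^2 dA
    Ixy = (cross * (x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0)).sum() / 24.0
    mu20 = Ixx / A - cx * cx
    mu02 = Iyy / A - cy * cy
    mu11 = Ixy / A - cx * cy
    return RegionMoments(area=float(A), centroid=(float(cx), float(cy)),
                         mu20=float(mu20), mu02=float(mu02), mu11=float(mu11))


def fit_ellipse_moments(moments: RegionMoments) -> EllipseFit:
    """Equivalent ellipse from area-normalized second central moments.

    Eigenvalues of the covariance give ``lambda_pm``; full axis lengths are
    ``a = 4*sqrt(lambda_+)``, ``b = 4*sqrt(lambda_-)`` (a disk of radius r
    yields a = b = 2r). The major-axis angle is converted from the y-down
    image frame to the y-up fundus view (counterclockwise positive).
    """
    m20, m02, m11 = moments.mu20, moments.mu02, moments.mu11
    common = np.hypot(m20 - m02, 2.0 * m11)
    lam_plus = (m20 + m02 + common) / 2.0
    lam_minus = (m20 + m02 - common) / 2.0
    if lam_minus <= 0:
        raise GeometryError("degenerate region: vanishing minor-axis moment")
    theta_img = 0.5 * np.degrees(np.arctan2(2.0 * m11, m20 - m02))
    theta = wrap_angle_deg(-theta_img)  # y-down image frame -> y-up fundus view
    return EllipseFit(
        center_O=moments.centroid,
        major_axis_a=4.0 * float(np.sqrt(lam_plus)),
        minor_axis_b=4.0 * float(np.sqrt(lam_minus)),
        theta_deg=float(theta),
    )


def apply_laterality(theta_deg: float, laterality: str) -> float:
    """Map an axis angle into the left-eye frame.

    Left eyes (OS) are the reference frame; right-eye (OD) angles are
    negated (horizontal mirror). 90 degrees is a fixed point of the mirror.
    """
    if not (-90.0 < theta_deg <= 90.0):
        raise ParameterError(f"theta_deg={theta_deg} outside (-90, 90]")
    if laterality == "OS":
        return theta_deg
    if laterality == "OD":
        return wrap_angle_deg(-theta_deg)
    raise ParameterError(f"unknown laterality {laterality!r}")


def circularity(
    contour: Contour,
    coeffs: EfdCoefficients | None = None,
    n_harmonics: int = N_HARMONICS,
    n_points: int = 512,
) -> float:
    """``4*pi*S/L^2`` of the elliptic-Fourier-smoothed boundary.

    The contour is represented by its truncated Fourier series (5 harmonics
    by default) sampled densely; S and L are the area and perimeter of that
    smoothed curve. The statistic is scale-invariant, so the usual EFD size
    normalization leaves it unchanged and is omitted.
    """
    if coeffs is None:
        coeffs = efd_fit(contour, n_harmonics=n_harmonics)
    smooth = efd_reconstruct(coeffs, n_points)
    S, L = smooth.area_S, smooth.perimeter_L
    if L <= 0:
        raise GeometryError("smoothed contour has zero perimeter")
    return float(4.0 * np.pi * S / (L * L))


def area_ratio(S: float, fit: EllipseFit) -> float:
    """Region area over the product of full axis lengths; pi/4 for an ellipse."""
    return float(S / (fit.major_axis_a * fit.minor_axis_b))


def axis_ratio(fit: EllipseFit) -> float:
    """Elongation a/b of the equivalent ellipse (>= 1)."""
    return float(fit.major_axis_a / fit.minor_axis_b)


def shape_params(
    contour: Contour,
    laterality: str,
    n_harmonics: int = N_HARMONICS,
) -> tuple[ShapeParams, EllipseFit]:
    """Full shape characterization of an ONL-B contour."""
    mom = region_moments(contour)
    fit = fit_ellipse_moments(mom)
    return (
        ShapeParams(
            circularity=circularity(contour, n_harmonics=n_harmonics),
            area_ratio=area_ratio(contour.area_S, fit),
            axis_ratio=axis_ratio(fit),
            axis_deg=apply_laterality(fit.theta_deg, laterality),
        ),
        fit,
    )
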