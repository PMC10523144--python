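"""Relative-radius geometry for islet architecture quantification.

The central statistic of this package is the *relative radius* of a
hormone-positive pixel inside a user-supplied islet boundary polygon:

    rel_radius = 100 * r / r_boundary(theta)     [percent]

where ``(theta, r)`` are the polar coordinates of the pixel about the polygon
center and ``r_boundary(theta)`` is the boundary radius in the same direction,
obtained by **linear interpolation of vertex radius as a function of vertex
angle** (with circular wraparound). Low values mean the cell sits near the
islet center; values near 100 mean it sits at the mantle.

Note that the interpolation is over the polygon's *(angle, radius)* vertex
pairs, not an exact ray-edge intersection: for a square, the interpolated
boundary is a constant-radius (circle-like) curve through the corners. This is
the definition implemented throughout; an exact ray-edge intersection routine
exists only as a clearly named oracle in the test suite.

Coordinate convention: image coordinates, origin top-left, x to the right,
y downward; angles measured from the positive x-axis, normalized to
``[0, 2*pi)``; a point exactly at the center gets ``theta = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ANGLE_TOL",
    "Centroid",
    "DegeneratePolygonError",
    "InvalidPolygonWarning",
    "IsletPolygon",
    "IsletResult",
    "PolarPointSet",
    "analyze_islet",
    "boundary_radius_at_angle",
    "islet_summary",
    "mask_to_points",
    "points_in_polygon",
    "polygon_centroid",
    "relative_area",
    "relative_radii",
    "to_polar",
    "validate_polygon",
]

TWO_PI = 2.0 * np.pi

#: floating-point tolerance (radians) for the angular monotonicity test
ANGLE_TOL = 1e-9


class DegeneratePolygonError(ValueError):
    """Raised when a polygon has fewer than 3 distinct vertices or no interior."""


class InvalidPolygonWarning(UserWarning):
    """Emitted when a polygon's vertex angles are not monotonic and it is auto-sorted."""


@dataclass(frozen=True)
class Centroid:
    """Center of an islet polygon, in pixel coordinates."""

    cx: float
    cy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy], dtype=float)


@dataclass
class IsletPolygon:
    """Ordered vertex list defining one islet boundary.

    Consecutive duplicate vertices (including a closing repeat of the first
    vertex) are removed on construction. ``was_invalid`` records whether
    angular auto-sorting was applied by :func:`validate_polygon`.
    """

    vertices: np.ndarray
    was_invalid: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"vertices must be an (n, 2) array, got shape {v.shape}")
        # drop consecutive duplicates, cyclically (handles an explicit closing vertex)
        keep = np.any(v != np.roll(v, 1, axis=0), axis=1)
        if not keep.any():
            raise DegeneratePolygonError("all vertices coincide")
        v = v[keep]
        if len(np.unique(v, axis=0)) < 3:
            raise DegeneratePolygonError(
                f"polygon needs at least 3 distinct vertices, got {len(np.unique(v, axis=0))}"
            )
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class PolarPointSet:
    """Detected-pixel coordinates in polar form about the islet center.

    ``rel_radius`` is ``100 * r / r_boundary`` per point, in percent.
    """

    theta: np.ndarray
    r: np.ndarray
    r_boundary: np.ndarray
    rel_radius: np.ndarray

    def __len__(self) -> int:
        return len(self.theta)

    @classmethod
    def empty(cls) -> "PolarPointSet":
        z = np.empty(0, dtype=float)
        return cls(z, z.copy(), z.copy(), z.copy())


@dataclass
class IsletResult:
    """Per-islet summary record.

    ``mean_relative_radius_pct`` averages only radii <= 100%; larger radii
    (possible after auto-sorting an invalid polygon) are excluded and
    accounted for in ``n_excluded`` / ``pct_excluded``. An islet with no
    detected staining is flagged ``excluded_no_staining`` and its mean is NaN
    (reported as missing, never 0).
    """

    image_id: str
    islet_id: object
    stain_mode: str | None
    n_cell_pixels: int
    n_islet_pixels: int
    relative_area_pct: float
    mean_relative_radius_pct: float
    n_included: int
    n_excluded: int
    pct_excluded: float
    polygon_was_invalid: bool
    excluded_no_staining: bool


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def polygon_centroid(polygon: IsletPolygon, method: str = "vertex_mean") -> Centroid:
    """Center of the polygon.

    ``vertex_mean`` (default) is the arithmetic mean of the vertex
    coordinates; ``area`` is the area-weighted (shoelace) centroid. The vertex
    mean is invariant under cyclic relabeling of the vertex list and is what
    the angle-sorting validity rule presupposes.
    """
    v = polygon.vertices
    if method == "vertex_mean":
        cx, cy = v.mean(axis=0)
    elif method == "area":
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        area2 = cross.sum()
        if area2 == 0:
            raise DegeneratePolygonError("polygon has zero signed area")
        cx = ((x + xn) * cross).sum() / (3.0 * area2)
        cy = ((y + yn) * cross).sum() / (3.0 * area2)
    else:
        raise ValueError(f"unknown centroid method: {method!r}")
    return Centroid(float(cx), float(cy))


def to_polar(points: Sequence | np.ndarray, center: Centroid) -> tuple[np.ndarray, np.ndarray]:
    """Transform (x, y) points to ``(theta, r)`` about ``center``.

    theta is measured from the positive horizontal axis and normalized to
    ``[0, 2*pi)``; r is the Euclidean distance. A point exactly at the center
    gets ``theta = 0`` by convention.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if not (np.isfinite(center.cx) and np.isfinite(center.cy)):
        raise ValueError("center must be finite")
    dx = pts[:, 0] - center.cx
    dy = pts[:, 1] - center.cy
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), TWO_PI)
    # guard against rounding mod up to exactly 2*pi
    theta = np.where(theta >= TWO_PI, 0.0, theta)
    theta = np.where(r == 0.0, 0.0, theta)
    return theta, r


def validate_polygon(
    polygon: IsletPolygon, center: Centroid
) -> tuple[bool, IsletPolygon]:
    """Check angular monotonicity of the vertex list; auto-sort if violated.

    A polygon is valid iff its vertex angles about the center are weakly
    monotonic (increasing or decreasing) up to one cyclic wraparound —
    equivalently, the cyclic angle differences have at most one descent or at
    most one ascent (tolerance :data:`ANGLE_TOL`). Convex polygons are always
    valid under this rule, for any start vertex and either orientation.

    Invalid polygons make the radial projection ambiguous; they are made valid
    by sorting the vertices by ascending angle (ties broken by ascending
    radius), the change is flagged via ``was_invalid`` and reported with an
    :class:`InvalidPolygonWarning`.
    """
    theta, r = to_polar(polygon.vertices, center)
    d = np.roll(theta, -1) - theta
    descents = int(np.sum(d < -ANGLE_TOL))
    ascents = int(np.sum(d > ANGLE_TOL))
    if descents <= 1 or ascents <= 1:
        return True, polygon
    order = np.lexsort((r, theta))
    sorted_poly = IsletPolygon(polygon.vertices[order], was_invalid=True)
    warnings.warn(
        "invalid polygon (non-monotonic vertex angles); vertices auto-sorted "
        "by angle — the analyzed shape differs from the drawn one",
        InvalidPolygonWarning,
        stacklevel=2,
    )
    return False, sorted_poly


def _interp_table(polygon: IsletPolygon, center: Centroid) -> tuple[np.ndarray, np.ndarray]:
    """Angle-ascending (theta, r) vertex table, extended for circular wraparound."""
    theta, r = to_polar(polygon.vertices, center)
    order = np.lexsort((r, theta))
    t, rr = theta[order], r[order]
    # exactly-equal angles make the interpolation ill-posed; keep first (smallest r)
    keep = np.concatenate(([True], np.diff(t) > 0))
    t, rr = t[keep], rr[keep]
    t_ext = np.concatenate(([t[-1] - TWO_PI], t, [t[0] + TWO_PI]))
    r_ext = np.concatenate(([rr[-1]], rr, [rr[0]]))
    return t_ext, r_ext


def boundary_radius_at_angle(
    validated_polygon: IsletPolygon, center: Centroid, theta
) -> np.ndarray | float:
    """Boundary radius in direction ``theta`` by angular linear interpolation.

    The vertex radius is interpolated linearly as a function of vertex angle
    between the two vertices whose angles bracket ``theta``, with circular
    wraparound between the last and first vertex. ``theta`` outside
    ``[0, 2*pi)`` is normalized. Accepts a scalar or an array; returns the
    matching shape.
    """
    t_ext, r_ext = _interp_table(validated_polygon, center)
    th = np.mod(np.asarray(theta, dtype=float), TWO_PI)
    scalar = th.ndim == 0
    th = np.atleast_1d(th)
    idx = np.searchsorted(t_ext, th, side="right") - 1
    idx = np.clip(idx, 0, len(t_ext) - 2)
    t0, t1 = t_ext[idx], t_ext[idx + 1]
    r0, r1 = r_ext[idx], r_ext[idx + 1]
    dt = t1 - t0
    safe = np.where(dt == 0.0, 1.0, dt)
    out = np.where(dt == 0.0, r0, r0 + (th - t0) * (r1 - r0) / safe)
    return float(out[0]) if scalar else out


def relative_radii(
    points: Sequence | np.ndarray, validated_polygon: IsletPolygon, center: Centroid
) -> PolarPointSet:
    """Per-point relative radius, ``100 * r / r_boundary(theta)``, in percent.

    ``points`` are (x, y) coordinates of detected pixels inside the polygon;
    output order matches input order. An empty point set yields an empty
    result (the no-staining case is handled by :func:`islet_summary`).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return PolarPointSet.empty()
    theta, r = to_polar(pts, center)
    rb = boundary_radius_at_angle(validated_polygon, center, theta)
    rb = np.atleast_1d(np.asarray(rb, dtype=float))
    rel = 100.0 * r / rb
    return PolarPointSet(theta=theta, r=r, r_boundary=rb, rel_radius=rel)


# ---------------------------------------------------------------------------
# raster / area operations
# ---------------------------------------------------------------------------

def points_in_polygon(
    points: Sequence | np.ndarray, vertices: np.ndarray, chunk: int = 4096
) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test.

    Boundary-grazing points (exactly on an edge) count as inside. Vectorized
    over points, chunked to bound memory for large rasters.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    v = np.asarray(vertices, dtype=float)
    v0 = v
    v1 = np.roll(v, -1, axis=0)
    x0, y0 = v0[:, 0][None, :], v0[:, 1][None, :]
    x1, y1 = v1[:, 0][None, :], v1[:, 1][None, :]
    out = np.empty(len(pts), dtype=bool)
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]
        x = p[:, 0][:, None]
        y = p[:, 1][:, None]
        straddle = (y0 > y) != (y1 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
        crossings = straddle & (x < x_int)
        inside = (crossings.sum(axis=1) % 2) == 1
        cross = (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0)
        on_edge = (
            (cross == 0.0)
            & (x >= np.minimum(x0, x1))
            & (x <= np.maximum(x0, x1))
            & (y >= np.minimum(y0, y1))
            & (y <= np.maximum(y0, y1))
        )
        out[lo : lo + chunk] = inside | on_edge.any(axis=1)
    return out


def mask_to_points(mask: np.ndarray) -> np.ndarray:
    """Pixel-center coordinates ``(x + 0.5, y + 0.5)`` of mask-positive pixels."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    return np.column_stack((xs + 0.5, ys + 0.5)).astype(float)


def relative_area(
    mask: np.ndarray, validated_polygon: IsletPolygon
) -> tuple[int, int, float]:
    """Hormone-positive fraction of the islet raster area.

    A raster pixel belongs to the islet if its center ``(x+0.5, y+0.5)`` lies
    inside the polygon by the even-odd rule (boundary-grazing centers count as
    inside). Returns ``(n_cell_pixels, n_islet_pixels, relative_area_pct)``.
    """
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    v = validated_polygon.vertices
    x_lo = max(int(np.floor(v[:, 0].min())), 0)
    x_hi = min(int(np.ceil(v[:, 0].max())), w)
    y_lo = max(int(np.floor(v[:, 1].min())), 0)
    y_hi = min(int(np.ceil(v[:, 1].max())), h)
    if x_hi <= x_lo or y_hi <= y_lo:
        raise DegeneratePolygonError("polygon encloses no raster pixels")
    xs, ys = np.meshgrid(np.arange(x_lo, x_hi), np.arange(y_lo, y_hi))
    centers = np.column_stack((xs.ravel() + 0.5, ys.ravel() + 0.5))
    inside = points_in_polygon(centers, v)
    n_islet = int(inside.sum())
    if n_islet == 0:
        raise DegeneratePolygonError("polygon encloses no raster pixel centers")
    sub = m[y_lo:y_hi, x_lo:x_hi].ravel()
    n_cell = int((sub & inside).sum())
    return n_cell, n_islet, 100.0 * n_cell / n_islet


# ---------------------------------------------------------------------------
# per-islet summary
# ---------------------------------------------------------------------------

def islet_summary(
    polar: PolarPointSet,
    *,
    image_id: str = "",
    islet_id: object = 0,
    stain_mode: str | None = None,
    n_islet_pixels: int = 0,
    relative_area_pct: float = float("nan"),
    polygon_was_invalid: bool = False,
) -> IsletResult:
    """Aggregate per-point relative radii into one :class:`IsletResult`.

    Radii strictly greater than 100% are excluded from the arithmetic mean
    (exactly 100% is included); the excluded fraction is reported. With zero
    detected pixels the islet is flagged ``excluded_no_staining`` and the mean
    is NaN — such islets must never enter cohort averages as 0.
    """
    rel = np.asarray(polar.rel_radius, dtype=float)
    n_total = len(rel)
    included = rel <= 100.0
    n_inc = int(included.sum())
    n_exc = n_total - n_inc
    mean = float(rel[included].mean()) if n_inc > 0 else float("nan")
    pct_exc = 100.0 * n_exc / n_total if n_total > 0 else float("nan")
    return IsletResult(
        image_id=image_id,
        islet_id=islet_id,
        stain_mode=stain_mode,
        n_cell_pixels=n_total,
        n_islet_pixels=int(n_islet_pixels),
        relative_area_pct=float(relative_area_pct),
        mean_relative_radius_pct=mean,
        n_included=n_inc,
        n_excluded=n_exc,
        pct_excluded=float(pct_exc),
        polygon_was_invalid=bool(polygon_was_invalid),
        excluded_no_staining=(n_total == 0),
    )


def analyze_islet(
    mask: np.ndarray,
    vertices: Sequence | np.ndarray,
    *,
    image_id: str = "",
    islet_id: object = 0,
    stain_mode: str | None = None,
    centroid_method: str = "vertex_mean",
) -> tuple[IsletResult, int]:
    """Full per-islet chain: polygon validation → inside filter → radii → summary.

    Detection runs on the whole image, so mask-positive pixels outside the
    polygon are possible; they are discarded before the radius computation and
    returned as a separate count (they never enter ``pct_excluded``).
    """
    poly = IsletPolygon(vertices)
    center = polygon_centroid(poly, method=centroid_method)
    _, vpoly = validate_polygon(poly, center)
    n_cell, n_islet, area_pct = relative_area(mask, vpoly)
    pts = mask_to_points(mask)
    inside = points_in_polygon(pts, vpoly.vertices)
    n_outside = int((~inside).sum())
    polar = relative_radii(pts[inside], vpoly, center)
    result = islet_summary(
        polar,
        image_id=image_id,
        islet_id=islet_id,
        stain_mode=stain_mode,
        n_islet_pixels=n_islet,
        relative_area_pct=area_pct,
        polygon_was_invalid=vpoly.was_invalid,
    )
    return result, n_outside
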