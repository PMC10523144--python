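"""Independent reference implementations used only by the test suite.

Two distinct routes to a relative radius:

* ``oracle_rel_radius_interp`` — a scalar, loop-based re-implementation of
  the angular linear interpolation definition. It must agree with the
  vectorized package core bit-for-bit.
* ``oracle_rel_radius_intersection`` — the exact ray-edge intersection via
  shapely. This is deliberately NOT the package definition; it agrees with
  the core only in the many-vertex (circle) limit.

Plus a brute-force Otsu threshold sweep and shapely-based point-in-polygon,
used to cross-check detection and the raster inside rule.
"""

from __future__ import annotations

import math

import numpy as np
import shapely

TWO_PI = 2.0 * math.pi


def _scalar_polar(dx: float, dy: float) -> tuple[float, float]:
    """(theta, r) of one offset vector, package conventions.

    Uses numpy's scalar hypot/arctan2: math.hypot is correctly rounded and can
    differ from the C library routine numpy uses in the last bit, which would
    defeat the bit-for-bit comparison of the *interpolation* being validated.
    """
    r = float(np.hypot(dx, dy))
    t = float(np.arctan2(dy, dx)) % TWO_PI
    if t >= TWO_PI:
        t = 0.0
    if r == 0.0:
        t = 0.0
    return t, r


def _vertex_polar(vertices, center):
    """Per-vertex (theta, r) with the same conventions as the package core."""
    out = []
    cx, cy = center
    for x, y in vertices:
        t, r = _scalar_polar(x - cx, y - cy)
        out.append((t, r))
    return out


def oracle_boundary_radius_interp(vertices, center, theta: float) -> float:
    """Scalar-loop angular interpolation of the boundary radius."""
    pairs = sorted(_vertex_polar(vertices, center))
    # drop exactly-equal angles, keeping the smallest radius
    dedup = [pairs[0]]
    for t, r in pairs[1:]:
        if t > dedup[-1][0]:
            dedup.append((t, r))
    t_ext = [dedup[-1][0] - TWO_PI] + [t for t, _ in dedup] + [dedup[0][0] + TWO_PI]
    r_ext = [dedup[-1][1]] + [r for _, r in dedup] + [dedup[0][1]]
    th = theta % TWO_PI
    if th >= TWO_PI:
        th = 0.0
    i = 0
    for j in range(len(t_ext) - 1):
        if t_ext[j] <= th:
            i = j
        else:
            break
    t0, t1 = t_ext[i], t_ext[i + 1]
    r0, r1 = r_ext[i], r_ext[i + 1]
    dt = t1 - t0
    if dt == 0.0:
        return r0
    # identical arithmetic expression to the vectorized core
    return r0 + (th - t0) * (r1 - r0) / dt


def oracle_rel_radius_interp(point, vertices, center) -> float:
    cx, cy = center
    t, r = _scalar_polar(point[0] - cx, point[1] - cy)
    return 100.0 * r / oracle_boundary_radius_interp(vertices, center, t)


def oracle_rel_radius_intersection(point, vertices, center) -> float:
    """Exact ray-edge intersection relative radius (shapely route)."""
    cx, cy = center
    dx, dy = point[0] - cx, point[1] - cy
    r = math.hypot(dx, dy)
    if r == 0.0:
        return 0.0
    ux, uy = dx / r, dy / r
    verts = np.asarray(vertices, dtype=float)
    reach = 10.0 * np.hypot(verts[:, 0] - cx, verts[:, 1] - cy).max()
    ray = shapely.LineString([(cx, cy), (cx + reach * ux, cy + reach * uy)])
    boundary = shapely.Polygon(verts).exterior
    inter = ray.intersection(boundary)
    if inter.is_empty:
        raise ValueError("ray does not meet the polygon boundary")
    pts = []
    for geom in getattr(inter, "geoms", [inter]):
        pts.extend(geom.coords)
    r_boundary = min(math.hypot(px - cx, py - cy) for px, py in pts)
    return 100.0 * r / r_boundary


def oracle_points_in_polygon(points, vertices) -> np.ndarray:
    """shapely covers() — interior plus boundary, like the package rule."""
    poly = shapely.Polygon(np.asarray(vertices, dtype=float))
    return np.array(
        [poly.covers(shapely.Point(p)) for p in np.asarray(points, float)], dtype=bool
    )


def oracle_otsu_threshold(values: np.ndarray) -> float:
    """Exhaustive sweep maximizing between-class variance.

    Candidate thresholds are midpoints between consecutive distinct values.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise ValueError("constant input has no Otsu threshold")
    best_t, best_var = None, -1.0
    for t in (uniq[:-1] + uniq[1:]) / 2.0:
        lo, hi = v[v < t], v[v >= t]
        w0, w1 = len(lo) / len(v), len(hi) / len(v)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, float(t)
    return best_t


def random_convex_polygon(
    rng: np.random.Generator, n_points: int = 12
) -> np.ndarray:
    """Convex hull of random points, randomly scaled and translated."""
    while True:
        pts = rng.uniform(-1.0, 1.0, size=(n_points, 2))
        hull = shapely.MultiPoint(pts).convex_hull
        if isinstance(hull, shapely.Polygon):
            verts = np.asarray(hull.exterior.coords)[:-1]
            if len(verts) >= 3:
                break
    scale = rng.uniform(5.0, 200.0)
    offset = rng.uniform(-500.0, 500.0, size=2)
    return verts * scale + offset
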