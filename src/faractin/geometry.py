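"""Polygon and ellipse helpers shared by the generator and the quantifier.

Coordinate convention
---------------------
All polygons live in continuous 0-based ``(row, col)`` coordinates whose
integer values sit on *pixel corners*: pixel ``(r, c)`` spans the unit square
``[r, r+1) x [c, c+1)`` and has its center at ``(r + 0.5, c + 0.5)``.  A pixel
belongs to a polygon's raster mask iff its center point is covered by the
polygon (interior or boundary).  This is the convention ImageJ uses for its
polygon ROIs, which makes imported annotations line up without offsets.
"""

from __future__ import annotations

import numpy as np
import shapely


def ellipse_polygon(
    center: tuple[float, float],
    axes: tuple[float, float],
    orientation: float = 0.0,
    n_vertices: int = 48,
) -> np.ndarray:
    """Closed polygonal trace of an ellipse as an ``(n, 2)`` (row, col) array.

    ``axes`` are the semi-axes in pixels; ``orientation`` is the angle (rad)
    of the first axis measured from the row axis.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    u = axes[0] * np.cos(t)
    v = axes[1] * np.sin(t)
    ct, st = np.cos(orientation), np.sin(orientation)
    rr = center[0] + u * ct - v * st
    cc = center[1] + u * st + v * ct
    return np.column_stack([rr, cc])


def as_shapely(vertices: np.ndarray) -> shapely.Polygon:
    """Polygon in shapely's (x, y) = (col, row) axis order."""
    v = np.asarray(vertices, dtype=float)
    return shapely.Polygon(np.column_stack([v[:, 1], v[:, 0]]))


def polygon_bounds(
    vertices: np.ndarray, shape: tuple[int, int], pad: int = 0
) -> tuple[int, int, int, int]:
    """Integer (r0, r1, c0, c1) pixel-index bounds clipped to ``shape``."""
    v = np.asarray(vertices, dtype=float)
    r0 = max(int(np.floor(v[:, 0].min())) - pad, 0)
    c0 = max(int(np.floor(v[:, 1].min())) - pad, 0)
    r1 = min(int(np.ceil(v[:, 0].max())) + pad, shape[0])
    c1 = min(int(np.ceil(v[:, 1].max())) + pad, shape[1])
    return r0, r1, c0, c1


def _points_covered(v: np.ndarray, pr: np.ndarray, pc: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon test, boundary-inclusive, vectorized.

    Single precision keeps the (n_edges x n_points) work arrays small; the
    boundary tolerance (squared distance <= 1e-9, i.e. ~3e-5 px) sits far
    above float32 cancellation noise and far below any meaningful geometry.
    """
    v32 = np.asarray(v, dtype=np.float32)
    y1 = v32[:, 0][:, None]
    x1 = v32[:, 1][:, None]
    y2 = np.roll(v32[:, 0], -1)[:, None]
    x2 = np.roll(v32[:, 1], -1)[:, None]
    py = pr.astype(np.float32)[None, :]
    px = pc.astype(np.float32)[None, :]
    # crossing number with the half-open rule (each vertex counted once)
    straddles = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    crossings = (straddles & (px < xint)).sum(axis=0)
    inside = (crossings % 2) == 1
    # boundary inclusion: squared distance to the nearest edge ~ 0
    dx, dy = x2 - x1, y2 - y1
    l2 = np.maximum(dx * dx + dy * dy, np.float32(1e-30))
    t = np.clip(((px - x1) * dx + (py - y1) * dy) / l2, 0.0, 1.0)
    d2 = (px - x1 - t * dx) ** 2 + (py - y1 - t * dy) ** 2
    on_edge = (d2 <= np.float32(1e-9)).any(axis=0)
    return inside | on_edge


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers are covered by the polygon.

    A pixel is included iff its center lies inside the polygon or exactly on
    its boundary (within 1e-6 px).  Self-intersecting inputs (e.g. jittered
    annotations) are repaired first, keeping the largest valid part.
    """
    v = np.asarray(vertices, dtype=float)
    poly = as_shapely(v)
    if not poly.is_valid:
        fixed = poly.buffer(0)
        if fixed.geom_type == "MultiPolygon":
            fixed = max(fixed.geoms, key=lambda g: g.area)
        xy = np.asarray(fixed.exterior.coords)[:-1]
        v = np.column_stack([xy[:, 1], xy[:, 0]])
    mask = np.zeros(shape, dtype=bool)
    r0, r1, c0, c1 = polygon_bounds(v, shape)
    if r1 <= r0 or c1 <= c0:
        return mask
    rr, cc = np.mgrid[r0:r1, c0:c1]
    covered = _points_covered(v, rr.ravel() + 0.5, cc.ravel() + 0.5)
    mask[r0:r1, c0:c1] = covered.reshape(rr.shape)
    return mask


def ellipse_mask_crop(
    center: tuple[float, float],
    axes: tuple[float, float],
    orientation: float,
    bounds: tuple[int, int, int, int],
) -> np.ndarray:
    """Analytic ellipse raster on a crop, evaluated at pixel centers."""
    r0, r1, c0, c1 = bounds
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr + 0.5 - center[0]
    dc = cc + 0.5 - center[1]
    ct, st = np.cos(orientation), np.sin(orientation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def ellipse_norm2_crop(
    center: tuple[float, float],
    axes: tuple[float, float],
    orientation: float,
    bounds: tuple[int, int, int, int],
) -> np.ndarray:
    """Squared normalized elliptical radius on a crop (<= 1 inside)."""
    r0, r1, c0, c1 = bounds
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr + 0.5 - center[0]
    dc = cc + 0.5 - center[1]
    ct, st = np.cos(orientation), np.sin(orientation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2


def segment_profiles(
    p1: np.ndarray,
    p2: np.ndarray,
    bounds: tuple[int, int, int, int],
    sigma: float,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Sum of anti-aliased line segments with a Gaussian cross profile.

    ``p1``/``p2`` are ``(n, 2)`` (row, col) endpoints; the result is the crop
    raster ``sum_i amp_i * exp(-d_i^2 / 2 sigma^2)`` where ``d_i`` is the
    distance from each pixel center to segment i.
    """
    r0, r1, c0, c1 = bounds
    rr, cc = np.mgrid[r0:r1, c0:c1]
    # float32 throughout: the texture feeds a Poisson/16-bit pipeline, so
    # single precision is far below the quantization floor
    pr = (rr + 0.5).ravel()[None, :].astype(np.float32)
    pc = (cc + 0.5).ravel()[None, :].astype(np.float32)
    p1 = np.asarray(p1, dtype=np.float32)
    p2 = np.asarray(p2, dtype=np.float32)
    dr = (p2[:, 0] - p1[:, 0])[:, None]
    dc = (p2[:, 1] - p1[:, 1])[:, None]
    l2 = np.maximum(dr * dr + dc * dc, np.float32(1e-12))
    t = ((pr - p1[:, 0][:, None]) * dr + (pc - p1[:, 1][:, None]) * dc) / l2
    np.clip(t, 0.0, 1.0, out=t)
    d2 = (pr - p1[:, 0][:, None] - t * dr) ** 2 + (pc - p1[:, 1][:, None] - t * dc) ** 2
    d2 *= np.float32(-0.5 / (sigma * sigma))
    np.exp(d2, out=d2)
    out = amplitudes.astype(np.float32)[:, None] * d2
    return out.sum(axis=0, dtype=np.float64).reshape(r1 - r0, c1 - c0)
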