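"""Planar geometry helpers on a local equirectangular projection.

All analysis domains here span a few degrees at most, so distances are
computed on a flat projection x = lon * k_lon(lat0), y = lat * k_lat with
per-kilometre scale factors; the error relative to geodesic distances is
far below the ~1 km scales that matter (road buffers, IDW neighborhoods).
"""

from __future__ import annotations

import numpy as np

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQUATOR = 111.320


def km_factors(lat0: float) -> tuple[float, float]:
    """(km per degree longitude, km per degree latitude) at reference latitude."""
    return (KM_PER_DEG_LON_EQUATOR * np.cos(np.radians(lat0)), KM_PER_DEG_LAT)


def explode_polylines(lines) -> tuple[np.ndarray, ...]:
    """Break shapely LineStrings into straight edges.

    Returns (x1, y1, x2, y2, line_index) arrays in degrees, one entry per
    edge, edges of each input line contiguous.
    """
    x1 = []
    y1 = []
    x2 = []
    y2 = []
    idx = []
    for i, ln in enumerate(lines):
        cx, cy = np.asarray(ln.coords.xy[0]), np.asarray(ln.coords.xy[1])
        x1.append(cx[:-1])
        y1.append(cy[:-1])
        x2.append(cx[1:])
        y2.append(cy[1:])
        idx.append(np.full(len(cx) - 1, i))
    if not x1:
        z = np.empty(0)
        return z, z, z, z, np.empty(0, dtype=int)
    return (
        np.concatenate(x1),
        np.concatenate(y1),
        np.concatenate(x2),
        np.concatenate(y2),
        np.concatenate(idx),
    )


def point_edge_dist_km(
    lon: np.ndarray,
    lat: np.ndarray,
    ex1: np.ndarray,
    ey1: np.ndarray,
    ex2: np.ndarray,
    ey2: np.ndarray,
    lat0: float | np.ndarray | None = None,
) -> np.ndarray:
    """Distance (km) from each point to each edge; shape (n_points, n_edges).

    ``lat0`` sets the projection latitude: a scalar for a common projection,
    ``None`` to project about each point's own latitude (per-row scaling).
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lat0 is None:
        kx = KM_PER_DEG_LON_EQUATOR * np.cos(np.radians(lat))[:, None]
    else:
        kx = KM_PER_DEG_LON_EQUATOR * np.cos(np.radians(lat0))
        kx = np.asarray(kx)[..., None] if np.ndim(kx) else kx
    ky = KM_PER_DEG_LAT

    px = lon[:, None] * kx
    py = lat[:, None] * ky
    ax = ex1[None, :] * kx
    ay = ey1[None, :] * ky
    bx = ex2[None, :] * kx
    by = ey2[None, :] * ky

    dx = bx - ax
    dy = by - ay
    seg2 = dx * dx + dy * dy
    with np.errstate(divide="ignore", invalid="ignore"):
        t = ((px - ax) * dx + (py - ay) * dy) / seg2
    t = np.where(seg2 > 0, np.clip(t, 0.0, 1.0), 0.0)
    cx = ax + t * dx
    cy = ay + t * dy
    return np.hypot(px - cx, py - cy)


def min_dist_to_lines_km(lon, lat, lines, lat0=None, chunk: int = 50_000) -> np.ndarray:
    """Minimum distance (km) from points to a collection of polylines."""
    ex1, ey1, ex2, ey2, _ = explode_polylines(lines)
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    out = np.empty(lon.shape[0])
    if ex1.size == 0:
        out.fill(np.inf)
        return out
    for s in range(0, lon.shape[0], chunk):
        sl = slice(s, s + chunk)
        out[sl] = point_edge_dist_km(lon[sl], lat[sl], ex1, ey1, ex2, ey2, lat0).min(axis=1)
    return out
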