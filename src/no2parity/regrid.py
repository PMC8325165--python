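"""Quality filtering and oversampling of level-2 satellite pixels.

Level-2 trace-gas retrievals arrive as coarse (~3.5 x 5-7 km) quadrilateral
footprints. Oversampling composites many temporally offset footprints onto a
fine regular grid (0.01 degree): each grid cell's value is the overlap-area
weighted mean of every footprint that intersects it over the averaging
period. Because successive overpasses are jittered relative to the fixed
grid, the composite resolves spatial structure finer than a single footprint
while averaging down single-retrieval noise.

The overlap areas are computed by clipping each footprint quadrilateral
against the axis-aligned cells it may touch (Sutherland-Hodgman clipping,
vectorized over footprint/cell pairs). Areas are evaluated on a local
equirectangular plane about the grid; since the cos(lat) scale factor is
common to every overlap within the grid, weighted means are unaffected by
the projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geo import km_factors

__all__ = [
    "GridSpec",
    "GriddedField",
    "filter_pixels",
    "oversample",
    "merge_fields",
    "difference",
    "local_anomaly",
    "CORNER_LON_COLS",
    "CORNER_LAT_COLS",
]

#: column names of the standard pixel table
CORNER_LON_COLS = [f"corner_lon_{i}" for i in range(1, 5)]
CORNER_LAT_COLS = [f"corner_lat_{i}" for i in range(1, 5)]
PIXEL_COLUMNS = CORNER_LON_COLS + CORNER_LAT_COLS + [
    "center_lon",
    "center_lat",
    "no2_column",
    "qa_value",
    "date",
]


class GridMismatchError(ValueError):
    """Two gridded fields do not share the same grid."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid; cell (i, j) covers the half-open box
    [lon0 + i*dlon, lon0 + (i+1)*dlon) x [lat0 + j*dlat, lat0 + (j+1)*dlat).
    """

    lon0: float
    lat0: float
    n_lon: int
    n_lat: int
    dlon: float = 0.01
    dlat: float = 0.01

    @classmethod
    def from_bbox(cls, bbox, resolution: float = 0.01) -> "GridSpec":
        lon_min, lat_min, lon_max, lat_max = bbox
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError(f"degenerate bbox {bbox}")
        n_lon = int(round((lon_max - lon_min) / resolution))
        n_lat = int(round((lat_max - lat_min) / resolution))
        return cls(lon_min, lat_min, n_lon, n_lat, resolution, resolution)

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon0 + self.dlon * np.arange(self.n_lon + 1)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat0 + self.dlat * np.arange(self.n_lat + 1)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + self.dlon * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 + self.dlat * (np.arange(self.n_lat) + 0.5)

    @property
    def bbox(self):
        return (
            self.lon0,
            self.lat0,
            self.lon0 + self.n_lon * self.dlon,
            self.lat0 + self.n_lat * self.dlat,
        )

    def cell_of(self, lon, lat):
        """Cell indices (i, j) of points; -1 where outside the grid."""
        i = np.floor((np.asarray(lon) - self.lon0) / self.dlon).astype(int)
        j = np.floor((np.asarray(lat) - self.lat0) / self.dlat).astype(int)
        ok = (i >= 0) & (i < self.n_lon) & (j >= 0) & (j < self.n_lat)
        return np.where(ok, i, -1), np.where(ok, j, -1)

    def center_mesh(self):
        """(lon, lat) arrays of shape (n_lat, n_lon) of all cell centers."""
        return np.meshgrid(self.lon_centers, self.lat_centers)


@dataclass
class GriddedField:
    """Period-mean column field on a :class:`GridSpec`.

    ``values`` is NaN wherever ``weights`` is zero (no coverage); weights are
    accumulated overlap areas in km^2, counts the number of contributing
    pixels.
    """

    spec: GridSpec
    values: np.ndarray  # (n_lat, n_lon), NaN = missing
    weights: np.ndarray
    counts: np.ndarray
    period: str = ""
    wsum: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.wsum is None:
            self.wsum = np.where(self.weights > 0, self.values * self.weights, 0.0)

    @property
    def missing(self) -> np.ndarray:
        return self.weights <= 0

    def coverage_fraction(self) -> float:
        return float(np.mean(self.weights > 0))


def filter_pixels(pixels: pd.DataFrame, qa_threshold: float = 0.75) -> pd.DataFrame:
    """Keep pixels with qa_value strictly greater than ``qa_threshold``.

    Order is preserved. The conventional usability cut for these retrievals
    is qa > 0.75.
    """
    if not 0.0 <= qa_threshold <= 1.0:
        raise ValueError(f"qa_threshold must be in [0, 1], got {qa_threshold}")
    return pixels.loc[pixels["qa_value"].to_numpy() > qa_threshold]


# ---------------------------------------------------------------------------
# vectorized Sutherland-Hodgman clipping of quads against axis-aligned rects
# ---------------------------------------------------------------------------

_VMAX = 9  # 4 vertices + at most one extra per half-plane clip


def _clip_halfplane(X, Y, nv, axis, bound, keep_le):
    """One half-plane clip of padded polygons (M, VMAX) with vertex counts nv."""
    M, V = X.shape
    C = X if axis == 0 else Y
    b = np.asarray(bound)[:, None]
    d = (b - C) if keep_le else (C - b)  # signed distance, >= 0 means inside

    ks = np.broadcast_to(np.arange(V)[None, :], (M, V))
    valid = ks < nv[:, None]
    kn = ks + 1
    kn = np.where(kn >= nv[:, None], 0, kn)

    d_nxt = np.take_along_axis(d, kn, axis=1)
    x_nxt = np.take_along_axis(X, kn, axis=1)
    y_nxt = np.take_along_axis(Y, kn, axis=1)

    in_cur = d >= 0
    in_nxt = d_nxt >= 0
    cross = (in_cur != in_nxt) & valid
    emit_nxt = in_nxt & valid

    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / (d - d_nxt)
        ix = X + t * (x_nxt - X)
        iy = Y + t * (y_nxt - Y)
    # crossing a vertical/horizontal boundary: pin the exact coordinate
    if axis == 0:
        ix = np.where(cross, np.broadcast_to(b, ix.shape), ix)
    else:
        iy = np.where(cross, np.broadcast_to(b, iy.shape), iy)

    n_emit = cross.astype(np.int64) + emit_nxt.astype(np.int64)
    pos0 = np.cumsum(n_emit, axis=1) - n_emit
    nv_out = n_emit.sum(axis=1)

    Xo = np.zeros_like(X)
    Yo = np.zeros_like(Y)
    rr, cc = np.nonzero(cross)
    Xo[rr, pos0[rr, cc]] = ix[rr, cc]
    Yo[rr, pos0[rr, cc]] = iy[rr, cc]
    pos_nxt = pos0 + cross
    rr, cc = np.nonzero(emit_nxt)
    Xo[rr, pos_nxt[rr, cc]] = x_nxt[rr, cc]
    Yo[rr, pos_nxt[rr, cc]] = y_nxt[rr, cc]
    return Xo, Yo, nv_out


def _shoelace(X, Y, nv):
    M, V = X.shape
    ks = np.broadcast_to(np.arange(V)[None, :], (M, V))
    valid = ks < nv[:, None]
    kn = np.where(ks + 1 >= nv[:, None], 0, ks + 1)
    x_nxt = np.take_along_axis(X, kn, axis=1)
    y_nxt = np.take_along_axis(Y, kn, axis=1)
    terms = np.where(valid, X * y_nxt - x_nxt * Y, 0.0)
    area = 0.5 * np.abs(terms.sum(axis=1))
    return np.where(nv >= 3, area, 0.0)


try:
    import numba

    @numba.njit(cache=True)
    def _clip_areas_jit(px, py, xmin, ymin, xmax, ymax):  # pragma: no cover
        M = px.shape[0]
        out = np.zeros(M)
        X = np.empty(10)
        Y = np.empty(10)
        Xo = np.empty(10)
        Yo = np.empty(10)
        for m in range(M):
            for k in range(4):
                X[k] = px[m, k]
                Y[k] = py[m, k]
            nv = 4
            for edge in range(4):
                if nv == 0:
                    break
                no = 0
                for k in range(nv):
                    kn = k + 1 if k + 1 < nv else 0
                    if edge == 0:
                        dc = X[k] - xmin[m]
                        dn = X[kn] - xmin[m]
                    elif edge == 1:
                        dc = xmax[m] - X[k]
                        dn = xmax[m] - X[kn]
                    elif edge == 2:
                        dc = Y[k] - ymin[m]
                        dn = Y[kn] - ymin[m]
                    else:
                        dc = ymax[m] - Y[k]
                        dn = ymax[m] - Y[kn]
                    if (dc >= 0.0) != (dn >= 0.0):
                        t = dc / (dc - dn)
                        ix = X[k] + t * (X[kn] - X[k])
                        iy = Y[k] + t * (Y[kn] - Y[k])
                        if edge == 0:
                            ix = xmin[m]
                        elif edge == 1:
                            ix = xmax[m]
                        elif edge == 2:
                            iy = ymin[m]
                        else:
                            iy = ymax[m]
                        Xo[no] = ix
                        Yo[no] = iy
                        no += 1
                    if dn >= 0.0:
                        Xo[no] = X[kn]
                        Yo[no] = Y[kn]
                        no += 1
                for k in range(no):
                    X[k] = Xo[k]
                    Y[k] = Yo[k]
                nv = no
            if nv >= 3:
                s = 0.0
                for k in range(nv):
                    kn = k + 1 if k + 1 < nv else 0
                    s += X[k] * Y[kn] - X[kn] * Y[k]
                out[m] = 0.5 * abs(s)
        return out

except ImportError:  # pragma: no cover
    _clip_areas_jit = None


def clip_quads_to_rects(px, py, xmin, ymin, xmax, ymax, engine: str | None = None) -> np.ndarray:
    """Intersection areas between quadrilaterals and axis-aligned rectangles.

    ``px``/``py`` are (M, 4) vertex arrays; the rect bounds are length-M.
    Returns (M,) areas in the input coordinate units squared. ``engine`` is
    "numba" (default when available) or "numpy"; both run the same
    Sutherland-Hodgman construction.
    """
    if engine is None:
        engine = "numba" if _clip_areas_jit is not None else "numpy"
    if engine == "numba":
        return _clip_areas_jit(
            np.ascontiguousarray(px, dtype=np.float64),
            np.ascontiguousarray(py, dtype=np.float64),
            np.ascontiguousarray(xmin, dtype=np.float64),
            np.ascontiguousarray(ymin, dtype=np.float64),
            np.ascontiguousarray(xmax, dtype=np.float64),
            np.ascontiguousarray(ymax, dtype=np.float64),
        )
    M = px.shape[0]
    X = np.zeros((M, _VMAX))
    Y = np.zeros((M, _VMAX))
    X[:, :4] = px
    Y[:, :4] = py
    nv = np.full(M, 4, dtype=np.int64)
    for axis, bound, keep_le in (
        (0, xmin, False),
        (0, xmax, True),
        (1, ymin, False),
        (1, ymax, True),
    ):
        X, Y, nv = _clip_halfplane(X, Y, nv, axis, bound, keep_le)
    return _shoelace(X, Y, nv)


def _quad_area(px, py):
    return 0.5 * np.abs(
        np.sum(px * np.roll(py, -1, axis=1) - np.roll(px, -1, axis=1) * py, axis=1)
    )


def oversample(
    pixels: pd.DataFrame,
    spec: GridSpec,
    period: str = "",
    method: str = "area",
    chunk: int = 500_000,
) -> GriddedField:
    """Composite quality-filtered pixels onto ``spec`` by overlap weighting.

    Each cell value is sum(w_i * column_i) / sum(w_i) with w_i the overlap
    area between footprint i and the cell. ``method="centers"`` is a cheap
    alternative that bins each pixel's column into the single cell containing
    its center with unit weight. Footprints extending past the grid are
    clipped; zero-area footprints are skipped with a warning.
    """
    col = pixels["no2_column"].to_numpy(dtype=float)
    ncell = spec.n_lat * spec.n_lon
    wsum = np.zeros(ncell)
    w = np.zeros(ncell)
    cnt = np.zeros(ncell, dtype=np.int64)
    kx, ky = km_factors(spec.lat0 + 0.5 * spec.n_lat * spec.dlat)

    if method == "centers":
        i, j = spec.cell_of(pixels["center_lon"].to_numpy(), pixels["center_lat"].to_numpy())
        ok = i >= 0
        flat = j[ok] * spec.n_lon + i[ok]
        np.add.at(wsum, flat, col[ok])
        np.add.at(w, flat, 1.0)
        np.add.at(cnt, flat, 1)
    elif method == "area":
        px = pixels[CORNER_LON_COLS].to_numpy(dtype=float)
        py = pixels[CORNER_LAT_COLS].to_numpy(dtype=float)
        fp_area = _quad_area(px, py)
        degenerate = fp_area <= 0
        if degenerate.any():
            warnings.warn(
                f"skipping {int(degenerate.sum())} zero-area footprint(s)",
                RuntimeWarning,
                stacklevel=2,
            )
        # candidate cell index ranges from footprint bounding boxes
        i0 = np.floor((px.min(axis=1) - spec.lon0) / spec.dlon).astype(np.int64)
        i1 = np.floor((px.max(axis=1) - spec.lon0) / spec.dlon).astype(np.int64)
        j0 = np.floor((py.min(axis=1) - spec.lat0) / spec.dlat).astype(np.int64)
        j1 = np.floor((py.max(axis=1) - spec.lat0) / spec.dlat).astype(np.int64)
        i0c = np.clip(i0, 0, spec.n_lon - 1)
        i1c = np.clip(i1, 0, spec.n_lon - 1)
        j0c = np.clip(j0, 0, spec.n_lat - 1)
        j1c = np.clip(j1, 0, spec.n_lat - 1)
        usable = (~degenerate) & (i1 >= 0) & (i0 < spec.n_lon) & (j1 >= 0) & (j0 < spec.n_lat)

        pix_idx = np.nonzero(usable)[0]
        ni = i1c[pix_idx] - i0c[pix_idx] + 1
        nj = j1c[pix_idx] - j0c[pix_idx] + 1
        npairs = ni * nj
        offsets = np.concatenate([[0], np.cumsum(npairs)])
        total = int(offsets[-1])
        pair_pix = np.repeat(pix_idx, npairs)
        k = np.arange(total) - np.repeat(offsets[:-1], npairs)
        ni_rep = np.repeat(ni, npairs)
        ci = np.repeat(i0c[pix_idx], npairs) + k % ni_rep
        cj = np.repeat(j0c[pix_idx], npairs) + k // ni_rep

        lon_e = spec.lon_edges
        lat_e = spec.lat_edges
        for s in range(0, total, chunk):
            sl = slice(s, s + chunk)
            pi = pair_pix[sl]
            areas = clip_quads_to_rects(
                px[pi], py[pi], lon_e[ci[sl]], lat_e[cj[sl]], lon_e[ci[sl] + 1], lat_e[cj[sl] + 1]
            )
            flat = cj[sl] * spec.n_lon + ci[sl]
            wsum += np.bincount(flat, weights=areas * col[pi], minlength=ncell)
            w += np.bincount(flat, weights=areas, minlength=ncell)
            cnt += np.bincount(flat[areas > 0], minlength=ncell)
    else:
        raise ValueError(f"unknown method {method!r}")

    # degree^2 -> km^2; a common factor, so values are unaffected
    if method == "area":
        w *= kx * ky
        wsum *= kx * ky
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(w > 0, wsum / w, np.nan)
    shape = (spec.n_lat, spec.n_lon)
    return GriddedField(
        spec,
        values.reshape(shape),
        w.reshape(shape),
        cnt.reshape(shape),
        period=period,
        wsum=wsum.reshape(shape),
    )


def merge_fields(fields: list[GriddedField]) -> GriddedField:
    """Merge weighted sums from batches (e.g. per-day runs) into one field.

    Equivalent to oversampling all pixels in a single pass.
    """
    if not fields:
        raise ValueError("nothing to merge")
    spec = fields[0].spec
    for f in fields[1:]:
        if f.spec != spec:
            raise GridMismatchError("cannot merge fields on different grids")
    wsum = sum(f.wsum for f in fields)
    w = sum(f.weights for f in fields)
    cnt = sum(f.counts for f in fields)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(w > 0, wsum / w, np.nan)
    return GriddedField(spec, values, w, cnt, period=fields[0].period, wsum=wsum)


def difference(lockdown: GriddedField, baseline: GriddedField) -> GriddedField:
    """Cellwise lockdown minus baseline; negative values are drops.

    Missing wherever either input is missing.
    """
    if lockdown.spec != baseline.spec:
        raise GridMismatchError("difference requires identical grids")
    both = ~lockdown.missing & ~baseline.missing
    values = np.where(both, lockdown.values - baseline.values, np.nan)
    w = both.astype(float)
    cnt = np.minimum(lockdown.counts, baseline.counts) * both
    return GriddedField(lockdown.spec, values, w, cnt, period="delta", wsum=values * w)


def local_anomaly(delta: GriddedField, mask: np.ndarray) -> GriddedField:
    """Deviation of a difference field from its mean over a city mask.

    Highlights neighborhoods whose change departs from the city-wide average
    change. Missing outside the mask and where ``delta`` is missing.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != delta.values.shape:
        raise ValueError("mask shape does not match grid")
    ok = mask & ~delta.missing
    if not ok.any():
        raise ValueError("mask has no non-missing cells")
    mean = float(delta.values[ok].mean())
    values = np.where(ok, delta.values - mean, np.nan)
    w = ok.astype(float)
    return GriddedField(delta.spec, values, w, delta.counts * ok, period="delta_local",
                        wsum=np.where(ok, values, 0.0))
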