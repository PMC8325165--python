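"""Oversampling and gridded-field operations."""

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings, strategies as st

from no2parity.regrid import (
    CORNER_LAT_COLS,
    CORNER_LON_COLS,
    GridMismatchError,
    GridSpec,
    clip_quads_to_rects,
    difference,
    filter_pixels,
    local_anomaly,
    merge_fields,
    oversample,
)

from conftest import grid_from_values, pixel_frame, rect_pixel


def shapely_oversample(pixels, spec):
    """Brute-force oracle: polygon-clip every footprint against every cell."""
    vals = np.full((spec.n_lat, spec.n_lon), np.nan)
    px = pixels[CORNER_LON_COLS].to_numpy()
    py = pixels[CORNER_LAT_COLS].to_numpy()
    col = pixels["no2_column"].to_numpy()
    quads = [shapely.Polygon(np.column_stack([px[i], py[i]])) for i in range(len(pixels))]
    for j in range(spec.n_lat):
        for i in range(spec.n_lon):
            cell = shapely.box(
                spec.lon0 + i * spec.dlon,
                spec.lat0 + j * spec.dlat,
                spec.lon0 + (i + 1) * spec.dlon,
                spec.lat0 + (j + 1) * spec.dlat,
            )
            w = np.array([q.intersection(cell).area for q in quads])
            if w.sum() > 0:
                vals[j, i] = np.sum(w * col) / w.sum()
    return vals


class TestFilterPixels:
    def test_strictly_greater_than_threshold(self):
        px = pixel_frame([rect_pixel(0, 0, 0.1, 0.1, 1e15, qa=q)
                          for q in (0.5, 0.75, 0.76, 1.0)])
        kept = filter_pixels(px, 0.75)
        assert list(kept["qa_value"]) == [0.76, 1.0]

    def test_empty_and_identity(self):
        px = pixel_frame([rect_pixel(0, 0, 0.1, 0.1, 1e15, qa=0.9)])
        assert len(filter_pixels(px.iloc[:0], 0.75)) == 0
        pd.testing.assert_frame_equal(filter_pixels(px, 0.0), px)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_pixels(pixel_frame([]), 1.5)


class TestOversample:
    def test_single_pixel_covers_cell(self):
        spec = GridSpec(0.0, 0.0, 2, 2)
        px = pixel_frame([rect_pixel(-0.05, -0.05, 0.05, 0.05, 5e15)])
        field = oversample(px, spec)
        assert field.values[0, 0] == pytest.approx(5e15)

    def test_two_equal_overlaps_average(self):
        # two identical footprints centered on cell (0,0), columns 2 and 4
        spec = GridSpec(0.0, 0.0, 1, 1)
        px = pixel_frame([
            rect_pixel(-0.02, -0.02, 0.03, 0.03, 2e15),
            rect_pixel(-0.02, -0.02, 0.03, 0.03, 4e15),
        ])
        field = oversample(px, spec)
        assert field.values[0, 0] == pytest.approx(3e15)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        spec = GridSpec(0.0, 0.0, 10, 10)
        rows = []
        for _ in range(5):
            cx, cy = rng.uniform(0.0, 0.1, 2)
            ang = rng.uniform(0, np.pi)
            w, h = rng.uniform(0.02, 0.06, 2)
            hx = np.array([-w / 2, w / 2, w / 2, -w / 2])
            hy = np.array([-h / 2, -h / 2, h / 2, h / 2])
            lon = cx + hx * np.cos(ang) - hy * np.sin(ang)
            lat = cy + hx * np.sin(ang) + hy * np.cos(ang)
            rows.append(
                {**{f"corner_lon_{i+1}": lon[i] for i in range(4)},
                 **{f"corner_lat_{i+1}": lat[i] for i in range(4)},
                 "center_lon": cx, "center_lat": cy,
                 "no2_column": rng.uniform(1e15, 5e15), "qa_value": 1.0,
                 "date": "2019-03-13"}
            )
        px = pixel_frame(rows)
        field = oversample(px, spec)
        ref = shapely_oversample(px, spec)
        both = ~np.isnan(ref)
        assert np.array_equal(both, ~np.isnan(field.values))
        rel = np.abs(field.values[both] - ref[both]) / np.abs(ref[both])
        assert rel.max() < 1e-10

    def test_uniform_conservation(self):
        # spatially uniform columns reproduce exactly in every covered cell
        spec = GridSpec(0.0, 0.0, 5, 5)
        rng = np.random.default_rng(0)
        rows = [rect_pixel(x, y, x + 0.035, y + 0.025, 7.5e14)
                for x in rng.uniform(-0.03, 0.05, 8)
                for y in rng.uniform(-0.03, 0.05, 8)]
        field = oversample(pixel_frame(rows), spec)
        covered = field.weights > 0
        assert covered.any()
        np.testing.assert_allclose(field.values[covered], 7.5e14, rtol=1e-12)

    def test_weight_additivity_across_batches(self):
        rng = np.random.default_rng(3)
        spec = GridSpec(0.0, 0.0, 6, 6)
        rows = [rect_pixel(x, y, x + 0.04, y + 0.03, c)
                for x, y, c in zip(rng.uniform(-0.02, 0.05, 20),
                                   rng.uniform(-0.02, 0.05, 20),
                                   rng.uniform(1e15, 4e15, 20))]
        px = pixel_frame(rows)
        single = oversample(px, spec)
        merged = merge_fields([oversample(px.iloc[:9], spec), oversample(px.iloc[9:], spec)])
        np.testing.assert_allclose(merged.values, single.values, rtol=1e-12, equal_nan=True)
        np.testing.assert_allclose(merged.weights, single.weights, rtol=1e-12)

    def test_scale_equivariance(self):
        spec = GridSpec(0.0, 0.0, 4, 4)
        rows = [rect_pixel(0.0, 0.0, 0.035, 0.025, 2e15),
                rect_pixel(0.01, 0.005, 0.045, 0.03, 3e15)]
        px = pixel_frame(rows)
        f1 = oversample(px, spec)
        px2 = px.copy()
        px2["no2_column"] *= 3.5
        f2 = oversample(px2, spec)
        np.testing.assert_allclose(f2.values, 3.5 * f1.values, rtol=1e-12, equal_nan=True)

    def test_zero_area_footprint_warns_and_skips(self):
        spec = GridSpec(0.0, 0.0, 2, 2)
        degenerate = rect_pixel(0.005, 0.005, 0.005, 0.005, 9e15)
        good = rect_pixel(-0.05, -0.05, 0.05, 0.05, 5e15)
        with pytest.warns(RuntimeWarning, match="zero-area"):
            field = oversample(pixel_frame([degenerate, good]), spec)
        assert field.values[0, 0] == pytest.approx(5e15)

    def test_engines_agree(self):
        rng = np.random.default_rng(9)
        M = 200
        px = rng.uniform(0, 1, (M, 4))
        py = rng.uniform(0, 1, (M, 4))
        xmin = rng.uniform(0, 0.8, M)
        ymin = rng.uniform(0, 0.8, M)
        a_nb = clip_quads_to_rects(px, py, xmin, ymin, xmin + 0.3, ymin + 0.3, engine="numba")
        a_np = clip_quads_to_rects(px, py, xmin, ymin, xmin + 0.3, ymin + 0.3, engine="numpy")
        np.testing.assert_allclose(a_nb, a_np, atol=1e-14)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    cx=st.floats(-1, 1), cy=st.floats(-1, 1),
    w=st.floats(0.1, 2), h=st.floats(0.1, 2),
    ang=st.floats(0, 3.14),
    bx=st.floats(-1.5, 1.5), by=st.floats(-1.5, 1.5),
    bw=st.floats(0.05, 1.5), bh=st.floats(0.05, 1.5),
)
def test_clip_area_bounds_property(cx, cy, w, h, ang, bx, by, bw, bh):
    """Clipped area never exceeds either the quad or the rectangle area."""
    hx = np.array([-w / 2, w / 2, w / 2, -w / 2])
    hy = np.array([-h / 2, -h / 2, h / 2, h / 2])
    px = (cx + hx * np.cos(ang) - hy * np.sin(ang))[None, :]
    py = (cy + hx * np.sin(ang) + hy * np.cos(ang))[None, :]
    area = clip_quads_to_rects(
        px, py, np.array([bx]), np.array([by]), np.array([bx + bw]), np.array([by + bh])
    )[0]
    assert -1e-12 <= area <= min(w * h, bw * bh) + 1e-9
    ref = shapely.Polygon(np.column_stack([px[0], py[0]])).intersection(
        shapely.box(bx, by, bx + bw, by + bh)
    ).area
    assert area == pytest.approx(ref, abs=1e-9)


class TestDifference:
    def test_identical_fields_zero(self):
        g = grid_from_values([[1e15, 2e15], [3e15, np.nan]])
        d = difference(g, g)
        np.testing.assert_allclose(d.values[:1], 0.0)
        assert np.isnan(d.values[1, 1])

    def test_drop_sign_convention(self):
        b = grid_from_values([[5e15]])
        l = grid_from_values([[4e15]])
        assert difference(l, b).values[0, 0] == pytest.approx(-1e15)

    def test_missing_propagates(self):
        b = grid_from_values([[5e15, np.nan]])
        l = grid_from_values([[np.nan, 4e15]])
        d = difference(l, b)
        assert np.isnan(d.values).all()

    def test_grid_mismatch_raises(self):
        b = grid_from_values([[1.0]])
        l = grid_from_values([[1.0]], lon0=1.0)
        with pytest.raises(GridMismatchError):
            difference(l, b)


class TestLocalAnomaly:
    def test_uniform_delta_gives_zeros(self):
        d = grid_from_values(np.full((3, 3), -2e15))
        mask = np.ones((3, 3), dtype=bool)
        np.testing.assert_allclose(local_anomaly(d, mask).values, 0.0)

    def test_two_cell_mask_arithmetic(self):
        d = grid_from_values([[-3.0, -1.0]])
        out = local_anomaly(d, np.array([[True, True]]))
        np.testing.assert_allclose(out.values, [[-1.0, 1.0]])

    def test_centering(self):
        rng = np.random.default_rng(1)
        d = grid_from_values(rng.normal(size=(5, 5)))
        mask = rng.random((5, 5)) < 0.6
        out = local_anomaly(d, mask)
        assert np.nansum(out.values) == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(out.values[~mask]).all()

    def test_all_missing_mask_raises(self):
        d = grid_from_values([[np.nan, 1.0]])
        with pytest.raises(ValueError):
            local_anomaly(d, np.array([[True, False]]))
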