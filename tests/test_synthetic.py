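"""Scenario generator: structure, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from no2parity.synthetic import (
    ConfigError,
    ScenarioConfig,
    calibrate_excess_scale,
    generate_roads,
    generate_scenario,
    generate_swath,
    generate_tracts,
    generate_true_field,
    _city_centers,
)
from no2parity.disparity import disparity_ratio, partition_deciles


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"domain_bbox": (0.0, 0.0, 0.0, 1.0)},
            {"n_tracts": 10},
            {"n_cities": 0},
            {"pixel_noise_cv": 1.5},
            {"qa_good_fraction": -0.1},
            {"planted_disparity_ratio": 0.0},
            {"background_column": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ScenarioConfig(**kwargs)


class TestRoads:
    def test_radial_roads_touch_city_center(self):
        cfg = ScenarioConfig(n_cities=1, roads_per_city=4, n_tracts=100)
        roads = generate_roads(cfg)
        assert len(roads) == 4
        (cx, cy) = _city_centers(cfg)[0]
        for geom in roads["geometry"]:
            assert geom.distance(Point(cx, cy)) < 1e-9

    def test_deterministic_given_seed(self):
        cfg = ScenarioConfig(rng_seed=4, n_tracts=100)
        r1 = generate_roads(cfg)
        r2 = generate_roads(cfg)
        for a, b in zip(r1["geometry"], r2["geometry"]):
            assert a.equals_exact(b, 0.0)

    def test_seeds_differ(self):
        cfg1 = ScenarioConfig(rng_seed=1, n_tracts=100)
        cfg2 = ScenarioConfig(rng_seed=2, n_tracts=100)
        w1 = generate_roads(cfg1)["geometry"].apply(lambda g: g.wkt)
        w2 = generate_roads(cfg2)["geometry"].apply(lambda g: g.wkt)
        assert not w1.equals(w2)


class TestTrueField:
    def test_background_far_from_sources(self):
        cfg = ScenarioConfig(n_cities=1, n_tracts=100,
                             domain_bbox=(-102.0, 38.0, -98.0, 42.0))
        roads = generate_roads(cfg)
        field = generate_true_field(cfg, roads)
        # corner of a 4x4 degree domain: hundreds of km from the one city
        corner = field.evaluate(-101.99, 38.01, "baseline")[0]
        d_corner_km = np.hypot(*(np.array(_city_centers(cfg)[0]) - [-101.99, 38.01])) * 85
        if d_corner_km > 5 * cfg.plume_sigma_km:
            assert corner == pytest.approx(cfg.background_column, rel=0.05)

    def test_zero_drops_identity(self):
        cfg = ScenarioConfig(
            n_tracts=100,
            lockdown_drop_fraction_near_road=0.0,
            lockdown_drop_fraction_background=0.0,
        )
        roads = generate_roads(cfg)
        field = generate_true_field(cfg, roads)
        lon = np.linspace(-100.9, -99.1, 40)
        lat = np.linspace(39.1, 40.9, 40)
        np.testing.assert_allclose(
            field.evaluate(lon, lat, "lockdown"), field.evaluate(lon, lat, "baseline")
        )

    def test_closed_form_on_road_at_city_center(self):
        cfg = ScenarioConfig(n_cities=1, n_tracts=100, plume_amplitudes=(2.0e15,),
                             road_enhancement=4.0e15)
        roads = generate_roads(cfg)
        field = generate_true_field(cfg, roads)
        cx, cy = _city_centers(cfg)[0]
        # at the city center a radial road passes through: d_road=0, d_city=0
        val = field.evaluate(cx, cy, "baseline")[0]
        assert val == pytest.approx(cfg.background_column + 2.0e15 + 4.0e15, rel=1e-6)

    def test_lockdown_never_exceeds_baseline(self):
        cfg = ScenarioConfig(n_tracts=100)
        roads = generate_roads(cfg)
        field = generate_true_field(cfg, roads)
        rng = np.random.default_rng(0)
        lon = rng.uniform(-101, -99, 500)
        lat = rng.uniform(39, 41, 500)
        b = field.evaluate(lon, lat, "baseline")
        l = field.evaluate(lon, lat, "lockdown")
        assert (l <= b + 1e-9).all()
        assert (b >= 0).all() and (l >= 0).all()


class TestTracts:
    def test_race_shares_sum_to_one(self, small_scenario):
        tr = small_scenario.tracts
        np.testing.assert_allclose(
            tr["frac_white"] + tr["frac_black"] + tr["frac_other"], 1.0, atol=1e-9
        )

    def test_no_planted_effect_when_ratio_one(self):
        cfg = ScenarioConfig(rng_seed=0, n_tracts=2000, planted_disparity_ratio=1.0)
        roads = generate_roads(cfg)
        tracts = generate_tracts(cfg, roads)
        corr = np.corrcoef(tracts["frac_white"], tracts["dist_road_km"])[0, 1]
        assert abs(corr) < 0.05

    def test_planted_effect_direction(self, small_scenario):
        tr = small_scenario.tracts
        assert np.corrcoef(tr["frac_white"], tr["dist_road_km"])[0, 1] > 0.3
        assert np.corrcoef(tr["frac_hispanic"], tr["dist_road_km"])[0, 1] < -0.3
        assert np.corrcoef(tr["median_income"], tr["dist_road_km"])[0, 1] > 0.3
        assert np.corrcoef(tr["frac_no_vehicle"], tr["dist_road_km"])[0, 1] < -0.3

    def test_too_few_tracts_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(n_tracts=19)

    def test_tessellation_covers_domain(self, small_scenario):
        total = small_scenario.tracts["area_deg2"].sum()
        lon_min, lat_min, lon_max, lat_max = small_scenario.config.domain_bbox
        assert total == pytest.approx((lon_max - lon_min) * (lat_max - lat_min), rel=1e-6)


class TestCalibration:
    def test_planted_ratio_exact_on_true_field(self):
        cfg = ScenarioConfig(rng_seed=1, n_tracts=5000, planted_disparity_ratio=2.6)
        roads = generate_roads(cfg)
        field = generate_true_field(cfg, roads)
        tracts = generate_tracts(cfg, roads)
        field = calibrate_excess_scale(field, tracts, 2.6)
        truth = field.evaluate(
            tracts["centroid_lon"].to_numpy(), tracts["centroid_lat"].to_numpy(), "baseline"
        )
        part = partition_deciles(
            pd.Series(tracts["frac_white"].to_numpy(), index=tracts["tract_id"]),
            variable="frac_white",
        )
        ratio, _, _ = disparity_ratio(pd.Series(truth, index=tracts["tract_id"]), part)
        assert ratio == pytest.approx(2.6, rel=0.10)

    def test_ratio_one_leaves_field_unscaled(self):
        cfg = ScenarioConfig(rng_seed=1, n_tracts=200, planted_disparity_ratio=1.0)
        roads = generate_roads(cfg)
        field = generate_true_field(cfg, roads)
        tracts = generate_tracts(cfg, roads)
        assert calibrate_excess_scale(field, tracts, 1.0).excess_scale == 1.0


class TestSwath:
    def test_noise_free_columns_equal_field(self):
        cfg = ScenarioConfig(
            rng_seed=2, n_tracts=100, pixel_noise_cv=0.0, qa_good_fraction=1.0,
            domain_bbox=(-100.3, 39.7, -99.7, 40.3), n_days=2,
        )
        roads = generate_roads(cfg)
        field = generate_true_field(cfg, roads)
        px = generate_swath(field, cfg, "baseline")
        truth = field.evaluate(px["center_lon"].to_numpy(), px["center_lat"].to_numpy(),
                               "baseline")
        np.testing.assert_allclose(px["no2_column"], truth, rtol=1e-12)
        assert (px["qa_value"] > 0.75).all()

    def test_qa_good_fraction_binomial(self):
        cfg = ScenarioConfig(rng_seed=3, n_tracts=100, qa_good_fraction=0.8,
                             domain_bbox=(-100.5, 39.5, -99.5, 40.5), n_days=20)
        roads = generate_roads(cfg)
        field = generate_true_field(cfg, roads)
        px = generate_swath(field, cfg, "baseline")
        assert len(px) > 10_000
        frac = (px["qa_value"] > 0.75).mean()
        assert frac == pytest.approx(0.8, abs=0.01)

    def test_full_coverage_after_many_days(self):
        from no2parity.regrid import GridSpec, filter_pixels, oversample

        cfg = ScenarioConfig(rng_seed=4, n_tracts=100, qa_good_fraction=0.9,
                             domain_bbox=(-100.3, 39.7, -99.7, 40.3), n_days=90)
        roads = generate_roads(cfg)
        field = generate_true_field(cfg, roads)
        px = generate_swath(field, cfg, "baseline")
        spec = GridSpec.from_bbox(cfg.domain_bbox)
        grid = oversample(filter_pixels(px), spec)
        assert grid.coverage_fraction() == 1.0

    def test_determinism(self, small_config):
        s1 = generate_scenario(small_config)
        s2 = generate_scenario(small_config)
        pd.testing.assert_frame_equal(s1.pixels["baseline"], s2.pixels["baseline"])
        pd.testing.assert_frame_equal(
            s1.tracts.drop(columns="geometry"), s2.tracts.drop(columns="geometry")
        )
        assert s1.field.excess_scale == s2.field.excess_scale
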