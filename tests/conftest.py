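import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from no2parity.regrid import GriddedField, GridSpec
from no2parity.synthetic import ScenarioConfig, generate_roads, generate_scenario


def make_pixel(corners_lon, corners_lat, column, qa=1.0, date="2019-03-13"):
    row = {f"corner_lon_{i + 1}": corners_lon[i] for i in range(4)}
    row |= {f"corner_lat_{i + 1}": corners_lat[i] for i in range(4)}
    row["center_lon"] = float(np.mean(corners_lon))
    row["center_lat"] = float(np.mean(corners_lat))
    row["no2_column"] = column
    row["qa_value"] = qa
    row["date"] = date
    return row


def rect_pixel(lon0, lat0, lon1, lat1, column, qa=1.0):
    return make_pixel([lon0, lon1, lon1, lon0], [lat0, lat0, lat1, lat1], column, qa)


def pixel_frame(rows):
    return pd.DataFrame(rows)


def grid_from_values(values, lon0=0.0, lat0=0.0, d=0.01, period="baseline"):
    """GriddedField from a 2-D array (NaN = missing), unit weights elsewhere."""
    values = np.asarray(values, dtype=float)
    n_lat, n_lon = values.shape
    spec = GridSpec(lon0, lat0, n_lon, n_lat, d, d)
    w = (~np.isnan(values)).astype(float)
    return GriddedField(spec, values, w, w.astype(int), period=period)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(
        rng_seed=7,
        n_tracts=300,
        n_days=8,
        domain_bbox=(-100.5, 39.5, -99.5, 40.5),
        pixel_noise_cv=0.2,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture(scope="session")
def small_roads(small_config):
    return generate_roads(small_config)


@pytest.fixture()
def square_tract():
    return Polygon([(0.0, 0.0), (0.05, 0.0), (0.05, 0.05), (0.0, 0.05)])
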