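import numpy as np
import pandas as pd
import pytest

from fluxmeta.station_data import FEATURES, StationRecord
from fluxmeta.synthetic import FluxResponse, GeneratorParams, gen_network


def make_station(
    station_id="S1",
    n=40,
    zone="temperate",
    pft="GRA",
    lat=45.0,
    lon=0.0,
    seed=0,
):
    """Hand-built station record with plain random data (no generator)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "date": pd.date_range("2020-01-01", periods=n, freq="D"),
            "P": rng.gamma(0.5, 4.0, n),
            "TA": rng.normal(15, 8, n),
            "VPD": rng.gamma(2.0, 0.4, n),
            "SW_IN": rng.uniform(0, 300, n),
            "LAI": rng.uniform(0.1, 5, n),
            "GPP": rng.normal(5, 2, n),
            "RECO": rng.normal(3, 1, n),
        }
    )
    return StationRecord(station_id=station_id, data=df, zone=zone, pft=pft,
                         lat=lat, lon=lon)


@pytest.fixture(scope="session")
def small_network():
    """A modest 12-station network with a shifted sparse zone."""
    params = GeneratorParams(
        n_stations_per_zone={"temperate": 5, "continental": 3, "tropics": 2,
                             "semi-arid": 2},
        years=1,
        zone_shift={"tropics": 1.3, "semi-arid": 1.3},
        seed=11,
        noise_sd=0.2,
    )
    return gen_network(params)


@pytest.fixture()
def features():
    return list(FEATURES)


@pytest.fixture()
def base_response():
    return FluxResponse()
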