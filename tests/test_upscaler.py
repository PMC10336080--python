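import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxmeta.errors import GeometryError, PeriodError, SchemaError
from fluxmeta.learners import LearnerConfig
from fluxmeta.meta import MetaConfig, baseline_train
from fluxmeta.station_data import FEATURES
from fluxmeta.synthetic import GeneratorParams, gen_grid, gen_network
from fluxmeta.upscaler import (
    PRODUCT_VARS,
    build_mask,
    combine_products,
    compute_vpd,
    magnus_svp,
    read_product,
    regrid_mean,
    upscale_grid,
    write_product,
)


def magnus_oracle(t):
    # independent arithmetic of the Magnus formula
    import math

    return 0.61094 * math.exp(17.625 * t / (t + 243.04))


class TestComputeVpd:
    def test_saturated_air_zero(self):
        assert compute_vpd(20.0, 20.0) == 0.0

    def test_magnus_evaluation(self):
        expected = magnus_oracle(25.0) - magnus_oracle(20.0)
        assert compute_vpd(25.0, 20.0) == pytest.approx(expected, abs=1e-12)
        assert compute_vpd(25.0, 20.0) == pytest.approx(0.830, abs=0.005)

    def test_supersaturation_clamped_and_counted(self):
        vpd, n = compute_vpd(np.array([25.0]), np.array([26.0]),
                             return_clamped=True)
        assert vpd[0] == 0.0 and n == 1

    def test_monotone_in_ta(self):
        tas = np.linspace(10.0, 35.0, 50)
        vpd = compute_vpd(tas, np.full(50, 10.0))
        assert np.all(np.diff(vpd) > 0)

    def test_zero_iff_ta_below_td(self):
        ta = np.array([5.0, 10.0, 15.0])
        td = np.full(3, 10.0)
        vpd = compute_vpd(ta, td)
        assert vpd[0] == 0.0 and vpd[1] == 0.0 and vpd[2] > 0.0

    def test_svp_positive(self):
        assert magnus_svp(-20.0) > 0.0


class TestRegridMean:
    def test_constant_field(self):
        out = regrid_mean(np.full((4, 4), 7.0), 2)
        np.testing.assert_allclose(out, 7.0)

    def test_block_mean(self):
        out = regrid_mean(np.array([[1.0, 2.0], [3.0, 4.0]]), 2)
        assert out[0, 0] == pytest.approx(2.5)

    def test_missing_members_ignored(self):
        block = np.array([[1.0, np.nan], [3.0, np.nan]])
        assert regrid_mean(block, 2)[0, 0] == pytest.approx(2.0)

    def test_all_missing_block_stays_missing(self):
        assert np.isnan(regrid_mean(np.full((2, 2), np.nan), 2)[0, 0])

    def test_non_divisible_errors(self):
        with pytest.raises(GeometryError):
            regrid_mean(np.zeros((5, 4)), 2)

    @given(
        ny=st.sampled_from([2, 4, 6]),
        nx=st.sampled_from([2, 4, 8]),
        factor=st.sampled_from([1, 2]),
        seed=st.integers(0, 50),
    )
    @settings(max_examples=30, deadline=None)
    def test_bruteforce_oracle(self, ny, nx, factor, seed):
        rng = np.random.default_rng(seed)
        field = rng.normal(size=(ny, nx))
        field[rng.uniform(size=field.shape) < 0.3] = np.nan
        out = regrid_mean(field, factor)
        for i in range(ny // factor):
            for j in range(nx // factor):
                block = field[i * factor:(i + 1) * factor,
                              j * factor:(j + 1) * factor].ravel()
                vals = block[np.isfinite(block)]
                if len(vals):
                    assert out[i, j] == pytest.approx(vals.mean())
                else:
                    assert np.isnan(out[i, j])


class TestBuildMask:
    def test_arctic_cell_masked(self):
        mask = build_mask(np.array([70.0]), np.array([0.0]))
        assert bool(mask.values[0, 0])

    def test_equator_unmasked(self):
        mask = build_mask(np.array([0.0]), np.array([0.0]))
        assert not bool(mask.values[0, 0])

    def test_global_fraction_strictly_between_0_and_1(self):
        lats = np.arange(-89.875, 90, 0.25)
        mask = build_mask(lats, np.arange(0.125, 10, 0.25))
        frac = float(mask.values.mean())
        assert 0.0 < frac < 1.0


@pytest.fixture(scope="module")
def trained_pair():
    params = GeneratorParams(
        n_stations_per_zone={"temperate": 4, "tropics": 2}, years=1,
        seed=7, noise_sd=0.1,
    )
    net = gen_network(params)
    refs = {s.station_id: (0, len(s)) for s in net.stations}
    lcfg = LearnerConfig(arch="mlp", hidden_size=8, input_dim=len(FEATURES), seed=7)
    gpp = baseline_train(refs, {}, net.stations, lcfg,
                         MetaConfig(epochs=3, ensemble_size=1, seed=7))
    reco = baseline_train(refs, {}, net.stations, lcfg,
                          MetaConfig(epochs=3, ensemble_size=1, seed=7,
                                     target="RECO"))
    return params, gpp, reco


@pytest.fixture(scope="module")
def tiny_grid(trained_pair):
    params, _, _ = trained_pair
    return gen_grid((34.0, 36.0, 0.0, 2.0), 0.5, params, n_days=40)


class TestUpscaleGrid:
    def test_single_member_std_zero_and_mask(self, trained_pair, tiny_grid):
        _, gpp, reco = trained_pair
        mask = build_mask(tiny_grid["lat"].values, tiny_grid["lon"].values,
                          arctic_lat=35.0)
        product = combine_products(
            upscale_grid(gpp, tiny_grid, mask=mask),
            upscale_grid(reco, tiny_grid, mask=mask),
        )
        assert set(product.data_vars) == set(PRODUCT_VARS)
        keep = ~mask.values
        assert np.nanmax(product["GPP_std"].values[:, keep]) == 0.0
        for v in PRODUCT_VARS:
            assert np.isnan(product[v].values[:, ~keep]).all()
        assert np.isfinite(product["GPP"].values[:, keep]).all()

    def test_missing_predictor_errors(self, trained_pair, tiny_grid):
        _, gpp, _ = trained_pair
        with pytest.raises(SchemaError):
            upscale_grid(gpp, tiny_grid.drop_vars(["LAI"]))

    def test_vpd_derived_from_ta_td(self, trained_pair, tiny_grid):
        _, gpp, _ = trained_pair
        assert "VPD" not in tiny_grid
        out = upscale_grid(gpp, tiny_grid)
        assert np.isfinite(out["GPP"].values).all()

    def test_windowed_spinup_missing(self, trained_pair, tiny_grid):
        params, _, _ = trained_pair
        net = gen_network(params)
        refs = {s.station_id: (0, len(s)) for s in net.stations}
        lcfg = LearnerConfig(arch="lstm", hidden_size=4,
                             input_dim=len(FEATURES), window=10, seed=0)
        model = baseline_train(refs, {}, net.stations, lcfg,
                               MetaConfig(epochs=1, ensemble_size=1, seed=0))
        out = upscale_grid(model, tiny_grid, spinup="missing")
        assert np.isnan(out["GPP"].values[:9]).all()
        assert np.isfinite(out["GPP"].values[9:]).all()

    def test_windowed_spinup_pad(self, trained_pair, tiny_grid):
        params, _, _ = trained_pair
        net = gen_network(params)
        refs = {s.station_id: (0, len(s)) for s in net.stations}
        lcfg = LearnerConfig(arch="lstm", hidden_size=4,
                             input_dim=len(FEATURES), window=10, seed=0)
        model = baseline_train(refs, {}, net.stations, lcfg,
                               MetaConfig(epochs=1, ensemble_size=1, seed=0))
        out = upscale_grid(model, tiny_grid, spinup="pad")
        assert np.isfinite(out["GPP"].values).all()


def tiny_product(times):
    rng = np.random.default_rng(0)
    lats = np.array([40.0, 39.75])
    lons = np.array([0.0, 0.25])
    shape = (len(times), 2, 2)
    data = {
        v: (("time", "lat", "lon"),
            rng.normal(5, 1, shape).astype(np.float32))
        for v in PRODUCT_VARS
    }
    ds = xr.Dataset(data, coords={"time": times, "lat": lats, "lon": lons})
    for v in ds.data_vars:
        ds[v].attrs["units"] = "gC m-2 d-1"
    return ds


class TestWriteProduct:
    def test_daily_naming(self, tmp_path):
        times = pd.date_range("2021-03-01", "2021-03-31", freq="D")
        files = write_product(tiny_product(times), tmp_path, "daily")
        assert [f.name for f in files] == ["METAFLUX_GPP_RECO_daily_202103.nc"]

    def test_monthly_naming(self, tmp_path):
        times = pd.date_range("2021-01-01", periods=12, freq="MS")
        files = write_product(tiny_product(times), tmp_path, "monthly")
        assert [f.name for f in files] == ["METAFLUX_GPP_RECO_monthly_2021.nc"]

    def test_round_trip_float32(self, tmp_path):
        times = pd.date_range("2021-03-01", "2021-03-31", freq="D")
        ds = tiny_product(times)
        files = write_product(ds, tmp_path, "daily")
        back = read_product(files[0])
        for v in PRODUCT_VARS:
            np.testing.assert_array_equal(
                back[v].values, ds[v].values.astype(np.float32)
            )
            assert back[v].attrs["units"] == "gC m-2 d-1"
        assert set(back.data_vars) == set(PRODUCT_VARS)

    def test_partial_month_errors(self, tmp_path):
        times = pd.date_range("2021-03-01", periods=10, freq="D")
        with pytest.raises(PeriodError):
            write_product(tiny_product(times), tmp_path, "daily")

    def test_partial_year_errors(self, tmp_path):
        times = pd.date_range("2021-01-01", periods=7, freq="MS")
        with pytest.raises(PeriodError):
            write_product(tiny_product(times), tmp_path, "monthly")

    def test_missing_variable_errors(self, tmp_path):
        times = pd.date_range("2021-03-01", "2021-03-31", freq="D")
        ds = tiny_product(times).drop_vars(["Reco_std"])
        with pytest.raises(SchemaError):
            write_product(ds, tmp_path, "daily")
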