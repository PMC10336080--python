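"""Gridded-product diagnostics: seasonality, interannual CV, trend, NEE,
and correlation against a reference (SIF-like) field.

Zone correlations use zone-mean monthly series (zone-mean first, then
correlate).  Global totals integrate flux density over spherical cell
areas so trends come out in PgC per year.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats as sstats

from .errors import GeometryError, SampleSizeError, SchemaError

EARTH_RADIUS_M = 6.371e6

ZONE_LABELS = ("tropics", "semi-arid", "temperate", "continental", "masked")


@dataclasses.dataclass(frozen=True)
class TrendResult:
    slope: float
    stderr: float
    p_value: float


def zone_map_from_latitude(
    lats: np.ndarray,
    lons: np.ndarray,
    arctic_lat: float = 66.5,
    antarctic_lat: float = -60.0,
) -> xr.DataArray:
    """Categorical zone map from latitude bands (matches the generator)."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    alat = np.abs(lats)
    zone = np.where(alat < 15, "tropics",
            np.where(alat < 30, "semi-arid",
             np.where(alat < 50, "temperate", "continental"))).astype(object)
    zone[(lats > arctic_lat) | (lats < antarctic_lat)] = "masked"
    grid = np.broadcast_to(zone[:, None], (len(lats), len(lons))).copy()
    return xr.DataArray(grid, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"))


def _check_geometry(field: xr.DataArray, zonemap: xr.DataArray) -> None:
    if (field.sizes.get("lat"), field.sizes.get("lon")) != (
        zonemap.sizes.get("lat"), zonemap.sizes.get("lon")
    ):
        raise GeometryError("zone map geometry does not match the field")


def zone_seasonality(field: xr.DataArray, zonemap: xr.DataArray) -> pd.DataFrame:
    """Per-zone mean monthly climatology (rows: month 1..12, cols: zones).

    Requires at least 12 monthly steps.  Zones with no cells are omitted
    with a warning.
    """
    _check_geometry(field, zonemap)
    if field.sizes.get("time", 0) < 12:
        raise SampleSizeError("zone_seasonality needs >= 12 monthly steps")
    months = field["time"].dt.month
    out = {}
    for zone in [z for z in ZONE_LABELS if z != "masked"]:
        cells = zonemap == zone
        if not bool(cells.any()):
            warnings.warn(f"zone {zone!r} has no cells; omitted", stacklevel=2)
            continue
        series = field.where(cells).mean(("lat", "lon"))
        clim = series.groupby(months).mean("time")
        out[zone] = pd.Series(clim.values, index=clim["month"].values)
    df = pd.DataFrame(out)
    df.index.name = "month"
    return df


def interannual_cv(field: xr.DataArray) -> xr.DataArray:
    """Per-cell CV = sample sd / mean of annual means; needs >= 2 years."""
    years = np.unique(field["time"].dt.year.values)
    if len(years) < 2:
        raise SampleSizeError("interannual_cv needs >= 2 whole years")
    annual = field.groupby(field["time"].dt.year).mean("time")
    mu = annual.mean("year")
    sd = annual.std("year", ddof=1)
    cv = xr.where(mu != 0, sd / mu, np.nan)
    cv.name = "cv"
    return cv


def trend_fit(annual: "pd.Series | np.ndarray", years=None) -> TrendResult:
    """OLS of an annual series against year: slope, stderr, p-value."""
    if isinstance(annual, pd.Series):
        y = annual.to_numpy(dtype=float)
        x = np.asarray(annual.index, dtype=float)
    else:
        y = np.asarray(annual, dtype=float)
        x = (np.asarray(years, dtype=float) if years is not None
             else np.arange(len(y), dtype=float))
    if len(y) < 3:
        raise SampleSizeError("trend_fit needs >= 3 annual points")
    res = sstats.linregress(x, y)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    pval = float(res.pvalue) if np.isfinite(res.pvalue) else 0.0
    return TrendResult(slope=float(res.slope), stderr=stderr, p_value=pval)


def cell_areas_m2(lats: np.ndarray, lons: np.ndarray, resolution: float) -> np.ndarray:
    """Spherical cell areas (m^2) for a regular lat/lon grid."""
    lats = np.asarray(lats, dtype=float)
    phi1 = np.radians(lats - resolution / 2)
    phi2 = np.radians(lats + resolution / 2)
    band = EARTH_RADIUS_M**2 * np.radians(resolution) * np.abs(np.sin(phi2) - np.sin(phi1))
    return np.broadcast_to(band[:, None], (len(lats), len(lons))).copy()


def annual_global_total(field: xr.DataArray, resolution: float) -> pd.Series:
    """Area-integrated annual totals in PgC per year.

    ``field`` holds flux density in gC m-2 d-1 on (time, lat, lon).
    """
    areas = cell_areas_m2(field["lat"].values, field["lon"].values, resolution)
    weighted = field * xr.DataArray(
        areas, coords={"lat": field["lat"], "lon": field["lon"]}, dims=("lat", "lon")
    )
    daily = weighted.sum(("lat", "lon"), skipna=True)  # gC d-1
    per_year = daily.groupby(field["time"].dt.year).mean("time") * 365.0
    return pd.Series(per_year.values / 1e15, index=per_year["year"].values,
                     name="PgC_per_yr")


def nee_approx(gpp: xr.DataArray, reco: xr.DataArray) -> xr.DataArray:
    """NEE approximation ``Reco - GPP``; missing values propagate."""
    if gpp.sizes != reco.sizes:
        raise GeometryError(f"geometry mismatch: {dict(gpp.sizes)} vs {dict(reco.sizes)}")
    nee = reco - gpp
    nee.name = "NEE"
    return nee


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(sstats.pearsonr(x, y).statistic)


def zone_correlation(
    gpp: xr.DataArray, reference: xr.DataArray, zonemap: xr.DataArray
) -> dict[str, float]:
    """Pearson r between zone-mean monthly series of GPP and a reference."""
    _check_geometry(gpp, zonemap)
    if gpp.sizes.get("time") != reference.sizes.get("time") or not np.array_equal(
        gpp["time"].values, reference["time"].values
    ):
        raise SchemaError("time axes of GPP and reference differ")
    if gpp.sizes.get("time", 0) < 3:
        raise SchemaError("need >= 3 common timesteps")
    out: dict[str, float] = {}
    for zone in [z for z in ZONE_LABELS if z != "masked"]:
        cells = zonemap == zone
        if not bool(cells.any()):
            continue
        a = gpp.where(cells).mean(("lat", "lon")).values
        b = reference.where(cells).mean(("lat", "lon")).values
        out[zone] = _pearson(a, b)
    return out


def pixel_correlation(gpp: xr.DataArray, reference: xr.DataArray) -> xr.DataArray:
    """Per-pixel Pearson r over time; zero-variance pixels are missing."""
    if not np.array_equal(gpp["time"].values, reference["time"].values):
        raise SchemaError("time axes of GPP and reference differ")
    a = gpp.transpose("time", "lat", "lon").values
    b = reference.transpose("time", "lat", "lon").values
    am = a - np.nanmean(a, axis=0)
    bm = b - np.nanmean(b, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.nanmean(am * bm, axis=0)
        sa = np.sqrt(np.nanmean(am**2, axis=0))
        sb = np.sqrt(np.nanmean(bm**2, axis=0))
        r = cov / (sa * sb)
    r = np.where((sa == 0) | (sb == 0), np.nan, r)
    return xr.DataArray(
        r, coords={"lat": gpp["lat"], "lon": gpp["lon"]}, dims=("lat", "lon"),
        name="pearson_r",
    )
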