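"""Gridded upscaling: VPD derivation, regridding, masking, prediction, I/O.

The product holds exactly four variables — ``GPP``, ``Reco``, ``GPP_std``,
``Reco_std`` — on a (time, lat, lon) grid, stored as float32 NetCDF with
units ``gC m-2 d-1``.  Daily files are written per month as
``METAFLUX_GPP_RECO_daily_<year><month>.nc`` and monthly files per year as
``METAFLUX_GPP_RECO_monthly_<year>.nc``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import xarray as xr

from .errors import GeometryError, PeriodError, SchemaError
from .station_data import FEATURES, NormStats

if TYPE_CHECKING:  # pragma: no cover
    from .meta import EnsembleModel

log = logging.getLogger(__name__)

PRODUCT_VARS = ("GPP", "Reco", "GPP_std", "Reco_std")
UNITS = "gC m-2 d-1"
_LONG_NAMES = {
    "GPP": "ensemble mean gross primary production",
    "Reco": "ensemble mean ecosystem respiration",
    "GPP_std": "ensemble standard deviation of GPP",
    "Reco_std": "ensemble standard deviation of Reco",
}

#: Magnus saturation-vapor-pressure coefficients (kPa, dimensionless, degC)
MAGNUS_A = 0.61094
MAGNUS_B = 17.625
MAGNUS_C = 243.04


def magnus_svp(t_celsius):
    """Saturation vapor pressure (kPa) at temperature ``t_celsius`` (degC)."""
    t = np.asarray(t_celsius, dtype=float)
    return MAGNUS_A * np.exp(MAGNUS_B * t / (t + MAGNUS_C))


def compute_vpd(ta, td, return_clamped: bool = False):
    """Vapor pressure deficit (kPa) from air and dewpoint temperature.

    ``VPD = SVP(Ta) - SVP(Td)``; supersaturated cells (Td > Ta) are clamped
    to 0 and counted.  With ``return_clamped=True`` the clamp count is
    returned alongside the field.
    """
    vpd = magnus_svp(ta) - magnus_svp(td)
    neg = vpd < 0
    n_clamped = int(np.sum(np.nan_to_num(neg, nan=0.0)))
    if n_clamped:
        log.info("compute_vpd: clamped %d supersaturated cells to 0", n_clamped)
    vpd = np.where(neg, 0.0, vpd)
    if return_clamped:
        return vpd, n_clamped
    return vpd


def regrid_mean(field: np.ndarray | xr.DataArray, factor: int):
    """Block-average the trailing two (lat, lon) axes by ``factor``.

    Each coarse cell is the arithmetic mean of the non-missing members of
    its ``factor x factor`` block; an all-missing block stays missing.
    """
    if factor < 1:
        raise GeometryError("factor must be >= 1")
    arr = np.asarray(field, dtype=float)
    if arr.ndim < 2:
        raise GeometryError("field must have at least 2 dimensions")
    ny, nx = arr.shape[-2], arr.shape[-1]
    if ny % factor or nx % factor:
        raise GeometryError(
            f"grid {ny}x{nx} not divisible by regrid factor {factor}"
        )
    lead = arr.shape[:-2]
    blocks = arr.reshape(*lead, ny // factor, factor, nx // factor, factor)
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmean(blocks, axis=(-3, -1))
    return out


def build_mask(
    lats: np.ndarray,
    lons: np.ndarray,
    arctic_lat: float = 66.5,
    antarctic_lat: float = -60.0,
) -> xr.DataArray:
    """Boolean (lat, lon) mask: True marks excluded cold-region cells."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    excluded = (lats > arctic_lat) | (lats < antarctic_lat)
    grid = np.broadcast_to(excluded[:, None], (len(lats), len(lons))).copy()
    return xr.DataArray(grid, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"))


def _window_stack(cube: np.ndarray, window: int) -> np.ndarray:
    """Trailing windows along axis 0: (T, C, F) -> (T-W+1, C, W, F)."""
    sw = np.lib.stride_tricks.sliding_window_view(cube, window, axis=0)
    # sw: (T-W+1, C, F, W) -> (T-W+1, C, W, F)
    return np.moveaxis(sw, -1, 2)


def upscale_grid(
    model: "EnsembleModel",
    predictors: xr.Dataset,
    stats: NormStats | None = None,
    mask: xr.DataArray | None = None,
    spinup: str = "missing",
    chunk: int = 200_000,
) -> xr.Dataset:
    """Predict the four-variable product from a gridded predictor cube.

    Predictors must carry the training feature set on dimensions
    ``(time, lat, lon)``; a missing ``VPD`` variable is derived from ``TA``
    and ``TD``.  Windowed models consume the trailing ``window`` timesteps;
    the leading edge is handled per ``spinup``: ``"missing"`` leaves the
    first ``window - 1`` steps missing, ``"pad"`` repeats the first step.
    """
    from .meta import predict_ensemble  # deferred to avoid import cycle

    if stats is None:
        stats = model.norm_stats
    ds = predictors
    if "VPD" not in ds and {"TA", "TD"} <= set(ds.data_vars):
        ds = ds.assign(VPD=(ds["TA"].dims, compute_vpd(ds["TA"].values, ds["TD"].values)))
    for feat in FEATURES:
        if feat not in ds:
            raise SchemaError(f"predictor variable {feat!r} missing from grid")
    if spinup not in ("missing", "pad"):
        raise SchemaError(f"unknown spinup mode {spinup!r}")

    lats, lons, times = ds["lat"].values, ds["lon"].values, ds["time"].values
    T, NY, NX = len(times), len(lats), len(lons)
    cube = np.stack(
        [
            (ds[f].transpose("time", "lat", "lon").values - stats.mean[f]) / stats.sd[f]
            for f in FEATURES
        ],
        axis=-1,
    ).reshape(T, NY * NX, len(FEATURES))

    if mask is not None:
        flat_mask = mask.transpose("lat", "lon").values.reshape(NY * NX)
    else:
        flat_mask = np.zeros(NY * NX, dtype=bool)
    keep = ~flat_mask

    gpp_mean = np.full((T, NY * NX), np.nan, dtype=float)
    gpp_std = np.full((T, NY * NX), np.nan, dtype=float)

    arch = model.lcfg.arch
    n_keep = int(keep.sum())
    if arch == "mlp":
        X = cube[:, keep, :].reshape(-1, len(FEATURES))
        means = np.empty(len(X))
        stds = np.empty(len(X))
        for start in range(0, len(X), chunk):
            stop = min(start + chunk, len(X))
            means[start:stop], stds[start:stop] = predict_ensemble(model, X[start:stop])
        gpp_mean[:, keep] = means.reshape(T, n_keep)
        gpp_std[:, keep] = stds.reshape(T, n_keep)
    else:
        W = model.lcfg.window
        sub = cube[:, keep, :]
        if spinup == "pad" and T >= 1:
            pad = np.repeat(sub[:1], W - 1, axis=0)
            sub_ext = np.concatenate([pad, sub], axis=0)
            first_t = 0
        else:
            if T < W:
                raise SchemaError(f"grid has {T} steps < window {W}")
            sub_ext = sub
            first_t = W - 1
        wins = _window_stack(sub_ext, W)  # (n_t, C, W, F)
        n_t, n_c = wins.shape[0], wins.shape[1]
        flatw = wins.reshape(n_t * n_c, W, len(FEATURES))
        means = np.empty(len(flatw))
        stds = np.empty(len(flatw))
        for start in range(0, len(flatw), max(chunk // W, 1)):
            stop = min(start + max(chunk // W, 1), len(flatw))
            m, s = predict_ensemble(model, flatw[start:stop])
            means[start:stop], stds[start:stop] = m, s
        means = means.reshape(n_t, n_c)
        stds = stds.reshape(n_t, n_c)
        gpp_mean[first_t:, keep] = means
        gpp_std[first_t:, keep] = stds

    data = {}
    mean_name, std_name = _target_varnames(model.target)
    data[mean_name] = gpp_mean.reshape(T, NY, NX)
    data[std_name] = gpp_std.reshape(T, NY, NX)
    out = xr.Dataset(
        {k: (("time", "lat", "lon"), v.astype(np.float32)) for k, v in data.items()},
        coords={"time": times, "lat": lats, "lon": lons},
    )
    for name in out.data_vars:
        out[name].attrs.update(units=UNITS, long_name=_LONG_NAMES[str(name)])
    return out


def _target_varnames(target: str) -> tuple[str, str]:
    if target == "GPP":
        return "GPP", "GPP_std"
    if target == "RECO":
        return "Reco", "Reco_std"
    raise SchemaError(f"unknown target {target!r}")


def combine_products(gpp: xr.Dataset, reco: xr.Dataset) -> xr.Dataset:
    """Merge the GPP and Reco halves into the four-variable product."""
    out = xr.merge([gpp, reco])
    missing = [v for v in PRODUCT_VARS if v not in out]
    if missing:
        raise SchemaError(f"product missing variables {missing}")
    return out[list(PRODUCT_VARS)]


def _encoding(ds: xr.Dataset) -> dict:
    enc = {
        v: {"dtype": "float32", "_FillValue": np.float32(np.nan)}
        for v in ds.data_vars
    }
    enc["time"] = {"dtype": "float64", "units": "days since 1900-01-01"}
    return enc


def write_product(
    field: xr.Dataset,
    out_dir: str | Path,
    timescale: str = "daily",
    engine: str = "scipy",
) -> list[Path]:
    """Write one NetCDF per month (daily) or per year (monthly).

    The time axis must cover whole months (daily) or whole years (monthly);
    a partial period raises :class:`PeriodError`.
    """
    for v in PRODUCT_VARS:
        if v not in field:
            raise SchemaError(f"product field missing variable {v!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    times = pd.DatetimeIndex(field["time"].values)
    written: list[Path] = []
    if timescale == "daily":
        periods = times.to_period("M")
        for per in sorted(set(periods)):
            idx = times[periods == per]
            if len(idx) != per.days_in_month:
                raise PeriodError(
                    f"{per}: {len(idx)} of {per.days_in_month} days present"
                )
            sub = field.sel(time=idx)
            path = out_dir / f"METAFLUX_GPP_RECO_daily_{per.year}{per.month:02d}.nc"
            sub.to_netcdf(path, engine=engine, encoding=_encoding(sub))
            written.append(path)
    elif timescale == "monthly":
        for year in sorted(set(times.year)):
            idx = times[times.year == year]
            months = sorted(pd.DatetimeIndex(idx).month.unique())
            if months != list(range(1, 13)):
                raise PeriodError(f"{year}: months {months} do not cover 01-12")
            sub = field.sel(time=idx)
            path = out_dir / f"METAFLUX_GPP_RECO_monthly_{year}.nc"
            sub.to_netcdf(path, engine=engine, encoding=_encoding(sub))
            written.append(path)
    else:
        raise SchemaError(f"unknown timescale {timescale!r}")
    return written


def read_product(path: str | Path, engine: str = "scipy") -> xr.Dataset:
    """Read a product file back into memory."""
    with xr.open_dataset(path, engine=engine) as ds:
        return ds.load()
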