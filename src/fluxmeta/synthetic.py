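"""Seeded synthetic station networks and gridded predictor fields.

The generative flux model is deliberately minimal but carries the
statistical structure the learning method assumes: a rectangular-hyperbola
light response times a Gaussian temperature response times a bucket-style
water-stress term with multi-day memory for GPP, and a Q10 temperature
response times the same water stress for Reco.  Networks mix
data-abundant zones (temperate, continental) with data-sparse target
zones (tropics, semi-arid) whose response parameters can be shifted to
create a distribution gap between base and target tasks.

Everything is a pure function of ``(params, seed)``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError, GeometryError, ParameterError
from .station_data import ZONES, StationRecord
from .upscaler import compute_vpd

#: absolute-latitude range stations are placed in (uniform, all zones).
#: Zone labels shift response parameters only; every zone draws drivers
#: from the same climatological distribution, so with zone_shift = 1 the
#: zones are statistically exchangeable.
STATION_LAT_RANGE = (0.0, 60.0)

#: synthetic plant-functional-type codes (6 levels)
PFT_LEVELS = ("ENF", "DBF", "GRA", "CRO", "SAV", "WET")

#: zone-conditional PFT pools: vegetation types track climate zones
#: (evergreen-needleleaf in cold zones, savanna in dry ones, ...)
ZONE_PFTS = {
    "tropics": ("WET", "SAV"),
    "semi-arid": ("SAV", "GRA"),
    "temperate": ("DBF", "CRO", "GRA"),
    "continental": ("ENF", "DBF"),
}

_DAYS_PER_YEAR = 365


@dataclasses.dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic network generator."""

    n_stations_per_zone: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"temperate": 10, "continental": 6, "tropics": 2, "semi-arid": 2}
    )
    years: int = 2
    timestep: str = "daily"
    zone_shift: Mapping[str, float] = dataclasses.field(default_factory=dict)
    memory_halflife: float = 15.0
    noise_sd: float = 0.3
    extreme_tail: float = 0.0
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for zone, n in self.n_stations_per_zone.items():
            if zone not in ZONES:
                raise ParameterError(f"unknown zone {zone!r}")
            if n < 0:
                raise ParameterError(f"negative station count for zone {zone!r}")
        if self.timestep not in ("daily", "monthly"):
            raise ParameterError("timestep must be 'daily' or 'monthly'")
        if not 0 <= self.gap_fraction < 1:
            raise ParameterError("gap_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.extreme_tail <= 1:
            raise ParameterError("extreme_tail must lie in [0, 1]")
        if self.memory_halflife <= 0:
            raise ParameterError("memory_halflife must be > 0")
        if self.years < 1:
            raise ParameterError("years must be >= 1")


@dataclasses.dataclass(frozen=True)
class FluxResponse:
    """Ground-truth response parameters of one station (or zone)."""

    pmax: float = 12.0          # light-saturated GPP, gC m-2 d-1
    k_light: float = 0.06       # initial slope of the light response
    t_opt: float = 22.0         # optimum temperature, degC
    t_width: float = 12.0       # temperature response width, degC
    r0: float = 3.0             # basal respiration at 10 degC, gC m-2 d-1
    q10: float = 2.0            # respiration temperature sensitivity
    w_sens: float = 0.7         # water-stress sensitivity in [0, 1]

    def __post_init__(self) -> None:
        if self.pmax <= 0 or self.r0 <= 0:
            raise ParameterError("pmax and r0 must be > 0")
        if self.q10 <= 1:
            raise ParameterError("q10 must be > 1")
        if self.t_width <= 0:
            raise ParameterError("t_width must be > 0")
        if not 0 <= self.w_sens <= 1:
            raise ParameterError("w_sens must lie in [0, 1]")


def _seasonal(doy: np.ndarray, lat) -> np.ndarray:
    """Cosine annual cycle peaking in local summer (+1) per hemisphere."""
    peak = np.where(np.asarray(lat) >= 0, 196.0, 15.0)
    return np.cos(2 * np.pi * (doy - peak) / _DAYS_PER_YEAR)


def _gen_drivers(lat, doy: np.ndarray, rng: np.random.Generator):
    """Seasonal-sinusoid drivers with noise for latitude(s) ``lat``.

    ``lat`` may be a scalar or an array of cells; outputs are shaped
    ``(len(doy), *shape(lat))``.
    """
    lat = np.asarray(lat, dtype=float)
    alat = np.abs(lat)
    doy = np.asarray(doy, dtype=float).reshape(-1, *([1] * lat.ndim))
    seas = _seasonal(doy, lat)
    shape = (len(doy),) + lat.shape

    ta = (25.0 - 0.38 * alat) + (0.35 * alat) * seas + rng.normal(0, 1.5, shape)
    sw = np.clip(
        (260.0 - 2.2 * alat) + (3.0 * alat) * seas + rng.normal(0, 25.0, shape),
        0.0, None,
    )
    p_rate = (1.5 + 6.0 * np.exp(-((alat / 18.0) ** 2))) * (1.0 + 0.6 * seas)
    p_rate = np.broadcast_to(np.clip(p_rate, 0.1, None), shape)
    p = rng.gamma(0.4, p_rate / 0.4)
    lmax = 1.0 + 4.5 * np.exp(-((alat / 40.0) ** 2))
    lai = np.clip(lmax * (0.55 + 0.45 * seas) + rng.normal(0, 0.2, shape), 0.05, None)
    dpd = np.clip(
        2.0 + 0.12 * (ta - 5.0) - 0.25 * p + rng.normal(0, 1.0, shape), 0.0, None
    )
    return p, ta, sw, lai, ta - dpd  # last is dewpoint


def water_stress(
    precip: np.ndarray, memory_halflife: float, w_sens: float
) -> np.ndarray:
    """Latent soil-water stress factor in ``[1 - w_sens, 1]``.

    A bucket is filled by precipitation and drains exponentially with the
    given half-life; the stress factor saturates at the bucket's
    equilibrium storage so the long-run factor hovers near the middle of
    its range.
    """
    decay = 0.5 ** (1.0 / memory_halflife)
    # per-cell climatological reference so the stress scale is local
    mean_p = np.maximum(np.mean(precip, axis=0), 1e-9)
    s_eq = mean_p / (1.0 - decay)
    s = np.array(s_eq, dtype=float, copy=True)
    supply = np.empty_like(np.asarray(precip, dtype=float))
    for t in range(len(precip)):
        s = s * decay + precip[t]
        supply[t] = s / (s + s_eq)
    return 1.0 - w_sens * (1.0 - supply)


def _simulate_fluxes(
    p: np.ndarray,
    ta: np.ndarray,
    sw: np.ndarray,
    lai: np.ndarray,
    response: FluxResponse,
    params: GeneratorParams,
    rng: np.random.Generator,
):
    """Clean fluxes plus Gaussian noise and (optional) heavy-tail extremes."""
    stress = water_stress(p, params.memory_halflife, response.w_sens)
    light = response.pmax * (1.0 - np.exp(-response.k_light * sw / response.pmax))
    temp = np.exp(-0.5 * ((ta - response.t_opt) / response.t_width) ** 2)
    laif = 1.0 - np.exp(-0.6 * lai)
    gpp = light * temp * stress * laif
    reco = response.r0 * response.q10 ** ((ta - 10.0) / 10.0) * stress

    shape = gpp.shape
    eps_g = rng.normal(0, 1.0, shape) * params.noise_sd
    eps_r = rng.normal(0, 1.0, shape) * params.noise_sd
    # extreme machinery draws unconditionally so the extreme set is nested
    # in extreme_tail at fixed seed
    u_ext = rng.uniform(size=shape)
    burst_g = (0.5 + np.abs(rng.standard_t(3, shape))) * 0.6 * response.pmax
    burst_r = (0.5 + np.abs(rng.standard_t(3, shape))) * 0.8 * response.r0
    is_ext = u_ext < params.extreme_tail
    gpp = gpp + eps_g + np.where(is_ext, burst_g, 0.0)
    reco = reco + eps_r + np.where(is_ext, burst_r, 0.0)
    return gpp, reco, stress


def gen_station_series(
    params: GeneratorParams,
    response: FluxResponse,
    station_seed: int,
    station_id: str | None = None,
    zone: str = "temperate",
    pft: str = "GRA",
    lat: float = 45.0,
    lon: float = 0.0,
    drivers: pd.DataFrame | None = None,
) -> StationRecord:
    """Simulate one station's daily (or monthly-averaged) flux table.

    ``drivers`` may override the generated predictor series (columns
    ``P, TA, SW_IN, LAI`` and optionally ``VPD``) for controlled
    experiments; fluxes are always computed from the generative model.
    """
    rng = np.random.default_rng([abs(int(params.seed)), abs(int(station_seed))])
    n = params.years * _DAYS_PER_YEAR
    dates = pd.date_range("2015-01-01", periods=n, freq="D")
    doy = dates.dayofyear.to_numpy()

    if drivers is None:
        p, ta, sw, lai, td = _gen_drivers(float(lat), doy, rng)
        vpd = compute_vpd(ta, td)
    else:
        n = len(drivers)
        dates = pd.to_datetime(drivers["date"]) if "date" in drivers else dates[:n]
        p = drivers["P"].to_numpy(dtype=float)
        ta = drivers["TA"].to_numpy(dtype=float)
        sw = drivers["SW_IN"].to_numpy(dtype=float)
        lai = drivers["LAI"].to_numpy(dtype=float)
        vpd = (
            drivers["VPD"].to_numpy(dtype=float)
            if "VPD" in drivers
            else np.zeros(n)
        )

    gpp, reco, stress = _simulate_fluxes(p, ta, sw, lai, response, params, rng)

    df = pd.DataFrame(
        {
            "date": pd.DatetimeIndex(dates),
            "P": p, "TA": ta, "VPD": vpd, "SW_IN": sw, "LAI": lai,
            "GPP": gpp, "RECO": reco, "W_STRESS": stress,
        }
    )
    if params.timestep == "monthly":
        df = (
            df.set_index("date")
            .resample("MS")
            .mean()
            .reset_index()
        )
    # gaps: mark targets missing
    u_gap = rng.uniform(size=len(df))
    gap = u_gap < params.gap_fraction
    df.loc[gap, ["GPP", "RECO"]] = np.nan

    sid = station_id or f"SYN{station_seed:04d}"
    return StationRecord(
        station_id=sid, data=df, zone=zone, pft=pft, lat=float(lat), lon=float(lon)
    )


@dataclasses.dataclass
class Network:
    """A synthetic station network with its generative ground truth."""

    stations: list[StationRecord]
    responses: dict[str, FluxResponse]          # per-station truth
    zone_response: dict[str, FluxResponse]      # per-zone central truth
    params: GeneratorParams

    @property
    def by_id(self) -> dict[str, StationRecord]:
        return {s.station_id: s for s in self.stations}

    def __len__(self) -> int:
        return len(self.stations)


def _shifted(base: FluxResponse, shift: float) -> FluxResponse:
    """Multiplicative amplitude shift of the flux responses (pmax, r0)."""
    return dataclasses.replace(base, pmax=base.pmax * shift, r0=base.r0 * shift)


def gen_network(
    params: GeneratorParams, response: FluxResponse | None = None
) -> Network:
    """Generate a labelled multi-zone network with seeded ground truth.

    Stations in zones named in ``params.zone_shift`` draw their response
    parameters from a multiplicatively shifted distribution, creating the
    base/target distribution gap.  Per-station parameters jitter around
    the zone's central response.
    """
    base = response or FluxResponse()
    total = sum(params.n_stations_per_zone.values())
    if total == 0:
        raise ConfigurationError("empty network: no stations requested")
    rng = np.random.default_rng([abs(int(params.seed)), 987654321])
    stations: list[StationRecord] = []
    responses: dict[str, FluxResponse] = {}
    zone_response: dict[str, FluxResponse] = {}
    counter = 0
    for zone in sorted(params.n_stations_per_zone):
        n = params.n_stations_per_zone[zone]
        shift = float(params.zone_shift.get(zone, 1.0))
        zresp = _shifted(base, shift)
        zone_response[zone] = zresp
        lo, hi = STATION_LAT_RANGE
        for _ in range(n):
            counter += 1
            jitter = rng.lognormal(0.0, 0.08, size=3)
            resp = dataclasses.replace(
                zresp,
                pmax=zresp.pmax * jitter[0],
                r0=zresp.r0 * jitter[1],
                k_light=zresp.k_light * jitter[2],
                t_opt=zresp.t_opt + rng.normal(0, 1.0),
            )
            hemi = 1.0 if rng.uniform() < 0.75 else -1.0
            lat = hemi * rng.uniform(lo, hi)
            lon = rng.uniform(-180.0, 180.0)
            pft = str(rng.choice(ZONE_PFTS[zone]))
            sid = f"{zone[:3].upper()}{counter:04d}"
            rec = gen_station_series(
                params, resp, station_seed=counter, station_id=sid,
                zone=zone, pft=pft, lat=lat, lon=lon,
            )
            stations.append(rec)
            responses[sid] = resp
    return Network(stations=stations, responses=responses,
                   zone_response=zone_response, params=params)


def gen_grid(
    extent: Sequence[float],
    resolution: float,
    params: GeneratorParams,
    response: FluxResponse | None = None,
    n_days: int | None = None,
    start: str = "2021-01-01",
) -> xr.Dataset:
    """Gridded predictor cube (P, TA, TD, SW_IN, LAI) on (time, lat, lon).

    ``extent`` is ``(lat_min, lat_max, lon_min, lon_max)``; ``resolution``
    must divide both spans.  Latitude is ordered north to south.  When a
    ``response`` is given the generative truth fluxes are included as
    ``GPP`` and ``RECO`` variables for closed-loop experiments.
    """
    lat_min, lat_max, lon_min, lon_max = map(float, extent)
    if lat_max <= lat_min or lon_max <= lon_min:
        raise GeometryError("extent must have positive spans")
    ny = (lat_max - lat_min) / resolution
    nx = (lon_max - lon_min) / resolution
    if abs(ny - round(ny)) > 1e-9 or abs(nx - round(nx)) > 1e-9:
        raise GeometryError(
            f"resolution {resolution} does not divide extent {extent}"
        )
    ny, nx = int(round(ny)), int(round(nx))
    lats = lat_max - resolution * (np.arange(ny) + 0.5)  # north -> south
    lons = lon_min + resolution * (np.arange(nx) + 0.5)

    n = n_days if n_days is not None else params.years * _DAYS_PER_YEAR
    dates = pd.date_range(start, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy()

    rng = np.random.default_rng([abs(int(params.seed)), 192837465])
    lat2d = np.broadcast_to(lats[:, None], (ny, nx))
    p, ta, sw, lai, td = _gen_drivers(lat2d, doy, rng)

    data = {
        "P": p, "TA": ta, "TD": td, "SW_IN": sw, "LAI": lai,
    }
    if response is not None:
        gpp, reco, _ = _simulate_fluxes(p, ta, sw, lai, response, params, rng)
        data["GPP"] = gpp
        data["RECO"] = reco
    return xr.Dataset(
        {k: (("time", "lat", "lon"), v) for k, v in data.items()},
        coords={"time": dates, "lat": lats, "lon": lons},
    )
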