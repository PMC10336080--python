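"""Station tables, normalization statistics, windowing and batching.

The station schema is a time-ordered table with predictor columns
``P, TA, VPD, SW_IN, LAI`` and target columns ``GPP, RECO``.  Missing
records are marked with NaN and are excluded from windows and batches
rather than imputed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateFeatureError, SchemaError

#: Predictor columns, in the order models consume them.
FEATURES = ["P", "TA", "VPD", "SW_IN", "LAI"]
#: Target flux columns.
TARGETS = ["GPP", "RECO"]
#: Recognized climate-zone labels.
ZONES = ("tropics", "semi-arid", "temperate", "continental")

_SCHEMA = ["date"] + FEATURES + TARGETS


@dataclasses.dataclass
class StationRecord:
    """One station's predictor/target table plus metadata.

    Parameters
    ----------
    station_id : str
        Unique station identifier.
    data : pandas.DataFrame
        Time-ordered table with columns ``date, P, TA, VPD, SW_IN, LAI,
        GPP, RECO``.  Dates must be strictly increasing.
    zone : str
        Climate-zone label, one of :data:`ZONES`.
    pft : str
        Plant-functional-type code.
    lat, lon : float
        Station coordinates in degrees.
    """

    station_id: str
    data: pd.DataFrame
    zone: str
    pft: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        missing = [c for c in _SCHEMA if c not in self.data.columns]
        if missing:
            raise SchemaError(f"station {self.station_id}: missing columns {missing}")
        if not self.zone or not self.pft:
            raise SchemaError(f"station {self.station_id}: empty zone or pft label")
        dates = pd.to_datetime(self.data["date"])
        if len(dates) > 1 and not dates.is_monotonic_increasing:
            raise SchemaError(f"station {self.station_id}: dates not increasing")
        if len(dates) > 1 and dates.duplicated().any():
            raise SchemaError(f"station {self.station_id}: duplicate dates")

    def __len__(self) -> int:
        return len(self.data)


@dataclasses.dataclass(frozen=True)
class NormStats:
    """Per-feature mean and sample (n-1) standard deviation."""

    mean: pd.Series
    sd: pd.Series

    @property
    def features(self) -> list[str]:
        return list(self.mean.index)


class Window(NamedTuple):
    """A contiguous gap-free input window and its final-step target."""

    inputs: np.ndarray  # (window, n_features)
    target: float
    end_index: int  # index of the final row within the source table


@dataclasses.dataclass
class Batch:
    """A mini-batch of inputs and targets.

    ``inputs`` is shaped ``(batch, features)`` for instantaneous mode or
    ``(batch, window, features)`` for windowed mode.
    """

    inputs: np.ndarray
    targets: np.ndarray
    index: int

    def __len__(self) -> int:
        return len(self.targets)


def fit_norm_stats(
    rows: pd.DataFrame, features: Sequence[str] = FEATURES
) -> NormStats:
    """Fit z-normalization statistics on training rows.

    Target columns are never included.  Missing values are ignored per
    feature.  Raises :class:`DegenerateFeatureError` if a feature has zero
    sample variance and :class:`SchemaError` if it has fewer than two
    non-missing values.
    """
    means, sds = {}, {}
    for feat in features:
        if feat in TARGETS:
            raise SchemaError(f"target column {feat!r} cannot be a feature")
        if feat not in rows.columns:
            raise SchemaError(f"feature {feat!r} absent from training rows")
        vals = pd.to_numeric(rows[feat], errors="coerce").dropna()
        if len(vals) < 2:
            raise SchemaError(f"feature {feat!r} has <2 non-missing values")
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise DegenerateFeatureError(f"feature {feat!r} has zero variance")
        means[feat], sds[feat] = mu, sd
    idx = pd.Index(features, name="feature")
    return NormStats(mean=pd.Series(means)[idx], sd=pd.Series(sds)[idx])


def z_normalize(rows: pd.DataFrame, stats: NormStats) -> pd.DataFrame:
    """Apply ``x -> (x - mean) / sd`` to every feature in ``stats``.

    Non-feature columns (dates, targets) pass through untouched.
    """
    out = rows.copy()
    for feat in stats.features:
        if feat not in out.columns:
            raise SchemaError(f"feature {feat!r} absent from rows")
        out[feat] = (out[feat] - stats.mean[feat]) / stats.sd[feat]
    return out


def denormalize(rows: pd.DataFrame, stats: NormStats) -> pd.DataFrame:
    """Invert :func:`z_normalize` given the same statistics."""
    out = rows.copy()
    for feat in stats.features:
        if feat not in out.columns:
            raise SchemaError(f"feature {feat!r} absent from rows")
        out[feat] = out[feat] * stats.sd[feat] + stats.mean[feat]
    return out


def _clean_segments(mask_ok: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True values as [start, stop) pairs."""
    segments: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(mask_ok):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            segments.append((start, i))
            start = None
    if start is not None:
        segments.append((start, len(mask_ok)))
    return segments


def make_windows(
    record: "StationRecord | pd.DataFrame",
    window: int = 30,
    stride: int = 1,
    features: Sequence[str] = FEATURES,
    target: str = "GPP",
) -> list[Window]:
    """Emit all gap-free contiguous windows with final-step targets.

    A row is usable when every feature and the target are non-missing.
    Windows are drawn only inside maximal usable segments; a series
    shorter than ``window`` yields an empty list.
    """
    if window < 1:
        raise SchemaError("window must be >= 1")
    if stride < 1:
        raise SchemaError("stride must be >= 1")
    df = record.data if isinstance(record, StationRecord) else record
    cols = list(features) + [target]
    values = df[cols].to_numpy(dtype=float)
    ok = np.isfinite(values).all(axis=1)
    X = values[:, :-1]
    y = values[:, -1]
    out: list[Window] = []
    for start, stop in _clean_segments(ok):
        for s in range(start, stop - window + 1, stride):
            e = s + window
            out.append(Window(inputs=X[s:e], target=float(y[e - 1]), end_index=e - 1))
    return out


def extract_rows(
    df: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    target: str = "GPP",
) -> tuple[np.ndarray, np.ndarray]:
    """Usable instantaneous rows as ``(X, y)`` arrays (MLP mode)."""
    cols = list(features) + [target]
    values = df[cols].to_numpy(dtype=float)
    ok = np.isfinite(values).all(axis=1)
    return values[ok, :-1], values[ok, -1]


def make_batches(
    inputs: np.ndarray | Sequence[Window],
    targets: np.ndarray | None = None,
    batch_size: int = 256,
    seed: int = 0,
) -> list[Batch]:
    """Seeded shuffle followed by chunking into :class:`Batch` objects.

    Accepts either an ``(X, y)`` array pair or a sequence of
    :class:`Window`.  The union of the batches is exactly the input: no
    duplication, no loss; the last batch may be smaller.
    """
    if targets is None:
        windows = list(inputs)  # sequence of Window
        if not windows:
            raise SchemaError("empty input to make_batches")
        X = np.stack([w.inputs for w in windows])
        y = np.array([w.target for w in windows], dtype=float)
    else:
        X = np.asarray(inputs, dtype=float)
        y = np.asarray(targets, dtype=float)
        if len(X) != len(y):
            raise SchemaError("inputs and targets length mismatch")
        if len(X) == 0:
            raise SchemaError("empty input to make_batches")
    if batch_size < 1:
        raise SchemaError("batch_size must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    batches = []
    for i, start in enumerate(range(0, len(y), batch_size)):
        sel = perm[start : start + batch_size]
        batches.append(Batch(inputs=X[sel], targets=y[sel], index=i))
    return batches


# ---------------------------------------------------------------------------
# CSV interface (schema of the synthetic network generator)
# ---------------------------------------------------------------------------

def write_station_csv(record: StationRecord, path: str | Path) -> None:
    df = record.data[_SCHEMA].copy()
    df.insert(0, "station_id", record.station_id)
    df.to_csv(path, index=False)


def read_station_csv(
    path: str | Path,
    zone: str,
    pft: str,
    lat: float,
    lon: float,
    na_values: Iterable[str] = ("", "NA", "NaN"),
) -> StationRecord:
    df = pd.read_csv(path, na_values=list(na_values), keep_default_na=True)
    if "station_id" not in df.columns:
        raise SchemaError(f"{path}: missing station_id column")
    sid = str(df["station_id"].iloc[0])
    df = df.drop(columns=["station_id"])
    df["date"] = pd.to_datetime(df["date"])
    return StationRecord(station_id=sid, data=df, zone=zone, pft=pft, lat=lat, lon=lon)


def write_network_csv(stations: Sequence[StationRecord], out_dir: str | Path) -> None:
    """Write one CSV per station plus a metadata sidecar CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for rec in stations:
        write_station_csv(rec, out / f"{rec.station_id}.csv")
        meta.append(
            {"station_id": rec.station_id, "lat": rec.lat, "lon": rec.lon,
             "zone": rec.zone, "pft": rec.pft}
        )
    pd.DataFrame(meta).to_csv(out / "stations.csv", index=False)


def read_network_csv(in_dir: str | Path) -> list[StationRecord]:
    """Read a station network written by :func:`write_network_csv`."""
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "stations.csv")
    records = []
    for row in meta.itertuples():
        records.append(
            read_station_csv(
                in_dir / f"{row.station_id}.csv",
                zone=row.zone, pft=row.pft, lat=row.lat, lon=row.lon,
            )
        )
    return records
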