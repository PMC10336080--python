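"""Meta-learning task construction.

Target tasks are the data-sparse stations: half of the tropical and half
of the semi-arid stations (seeded sample, ``floor(n/2)`` for odd counts)
plus one representative station per plant functional type not already
covered.  Base tasks are the complement.  Each station's rows are split
80:20 chronologically (earliest 80% train) to avoid temporal leakage in
windowed models.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, SchemaError
from .station_data import ZONES, StationRecord

#: zones whose stations are halved into the target set
SPARSE_ZONES = ("tropics", "semi-arid")

RowRange = tuple[int, int]  # [start, stop) row indices


@dataclasses.dataclass
class MetaSplit:
    """The four datasets of the meta-learning layout.

    Each field maps ``station_id`` to a ``[start, stop)`` row range.  Base
    and target station sets are disjoint; within a station, the train and
    test ranges are disjoint and exhaustive.
    """

    base_train: dict[str, RowRange]
    base_test: dict[str, RowRange]
    target_train: dict[str, RowRange]
    target_test: dict[str, RowRange]
    seed: int

    @property
    def base_stations(self) -> list[str]:
        return sorted(self.base_train)

    @property
    def target_stations(self) -> list[str]:
        return sorted(self.target_train)

    def validate(self) -> None:
        base = set(self.base_train)
        target = set(self.target_train)
        if base & target:
            raise ConfigurationError("base and target station sets overlap")
        if set(self.base_test) != base or set(self.target_test) != target:
            raise ConfigurationError("train/test station sets inconsistent")
        for train, test in ((self.base_train, self.base_test),
                            (self.target_train, self.target_test)):
            for sid, (a, b) in train.items():
                c, d = test[sid]
                if b != c or a != 0:
                    raise ConfigurationError(f"station {sid}: ranges not contiguous")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str | Path) -> "MetaSplit":
        p = Path(str(payload))
        text = p.read_text() if p.exists() else str(payload)
        d = json.loads(text)
        return cls(
            base_train={k: tuple(v) for k, v in d["base_train"].items()},
            base_test={k: tuple(v) for k, v in d["base_test"].items()},
            target_train={k: tuple(v) for k, v in d["target_train"].items()},
            target_test={k: tuple(v) for k, v in d["target_test"].items()},
            seed=int(d["seed"]),
        )


def _chrono_ranges(n_rows: int, train_frac: float) -> tuple[RowRange, RowRange]:
    cut = int(math.floor(train_frac * n_rows))
    return (0, cut), (cut, n_rows)


def split_tasks(
    stations: Sequence[StationRecord],
    seed: int,
    train_frac: float = 0.8,
) -> MetaSplit:
    """Partition stations into base/target tasks and rows 80:20 in time.

    Target selection: a seeded sample of ``floor(n/2)`` stations from each
    sparse zone, then one randomly chosen station per PFT level whose PFT
    is not yet represented in the target set.
    """
    if not stations:
        raise ConfigurationError("empty station network")
    ids = [s.station_id for s in stations]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate station ids")
    for s in stations:
        if s.zone not in ZONES:
            raise SchemaError(f"station {s.station_id}: unknown zone {s.zone!r}")

    rng = np.random.default_rng(seed)
    by_id = {s.station_id: s for s in stations}
    target_ids: list[str] = []
    for zone in SPARSE_ZONES:
        pool = sorted(s.station_id for s in stations if s.zone == zone)
        k = len(pool) // 2
        if k:
            target_ids.extend(rng.choice(pool, size=k, replace=False).tolist())
    covered = {by_id[sid].pft for sid in target_ids}
    for pft in sorted({s.pft for s in stations}):
        if pft in covered:
            continue
        pool = sorted(
            s.station_id for s in stations
            if s.pft == pft and s.station_id not in target_ids
        )
        if pool:
            target_ids.append(str(rng.choice(pool)))
    target_set = set(target_ids)
    base_set = set(ids) - target_set
    if not base_set:
        raise ConfigurationError("base set empty after target selection")

    split = MetaSplit({}, {}, {}, {}, seed=seed)
    for sid in sorted(ids):
        tr, te = _chrono_ranges(len(by_id[sid]), train_frac)
        if sid in target_set:
            split.target_train[sid], split.target_test[sid] = tr, te
        else:
            split.base_train[sid], split.base_test[sid] = tr, te
    split.validate()
    return split


def baseline_datasets(
    split: MetaSplit,
) -> tuple[dict[str, RowRange], dict[str, RowRange]]:
    """Pooled (train, test) row references for the non-meta baseline."""
    split.validate()
    train = {**split.base_train, **split.target_train}
    test = {**split.base_test, **split.target_test}
    return train, test


def slice_refs(
    stations: Mapping[str, StationRecord] | Sequence[StationRecord],
    refs: Mapping[str, RowRange],
):
    """Yield ``(station, rows)`` for each referenced row range."""
    if not isinstance(stations, Mapping):
        stations = {s.station_id: s for s in stations}
    for sid in sorted(refs):
        a, b = refs[sid]
        yield stations[sid], stations[sid].data.iloc[a:b]
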