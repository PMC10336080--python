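"""Station-level scoring: RMSE, per-zone breakdown, extreme-threshold sweep.

Extreme observations are selected by z-normalizing the observed target
with statistics fitted on *training* targets (globally pooled) and keeping
the high tail ``z > t``; subsets are nested as the threshold grows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .meta import EnsembleModel, predict_ensemble

DEFAULT_THRESHOLDS = (1.0, 1.25, 1.5, 1.75, 2.0)


@dataclasses.dataclass(frozen=True)
class ExtremeEvalConfig:
    """Threshold sweep plus the training-target mean/sd used for z-values."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise SchemaError("thresholds must be sorted ascending")
        if self.sd <= 0:
            raise SchemaError("target sd must be > 0")

    @classmethod
    def from_training_targets(
        cls, targets: np.ndarray, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    ) -> "ExtremeEvalConfig":
        vals = np.asarray(targets, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise SchemaError("need >= 2 training targets to fit extreme stats")
        return cls(thresholds=tuple(thresholds), mean=float(vals.mean()),
                   sd=float(vals.std(ddof=1)))


@dataclasses.dataclass
class ExtremePoint:
    rmse: float  # NaN when the subset is empty
    n_selected: int
    mean_extreme_flux: float


@dataclasses.dataclass
class ZoneScore:
    rmse: float
    member_spread: float  # std of per-member RMSEs across the ensemble
    n: int


@dataclasses.dataclass
class EvalReport:
    """Overall, per-zone and extreme-sweep RMSE summaries."""

    rmse_overall: float
    rmse_by_zone: dict[str, ZoneScore]
    extreme_curve: dict[float, ExtremePoint]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "rmse_overall": self.rmse_overall,
                "rmse_by_zone": {
                    z: dataclasses.asdict(s) for z, s in self.rmse_by_zone.items()
                },
                "extreme_curve": {
                    str(t): dataclasses.asdict(p)
                    for t, p in self.extreme_curve.items()
                },
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def extreme_curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"threshold": t, **dataclasses.asdict(p)}
             for t, p in sorted(self.extreme_curve.items())]
        )


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root-mean-square error; permutation invariant, >= 0."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise SchemaError(f"shape mismatch {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise SchemaError("rmse of empty vectors")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def extreme_eval(
    model: EnsembleModel,
    inputs: np.ndarray,
    obs: np.ndarray,
    cfg: ExtremeEvalConfig,
) -> dict[float, ExtremePoint]:
    """RMSE over increasingly extreme observation subsets (``z > t``).

    An empty subset is recorded with count 0 and missing RMSE, never an
    exception.
    """
    pred, _ = predict_ensemble(model, inputs)
    return extreme_curve_from_predictions(pred, obs, cfg)


def extreme_curve_from_predictions(
    pred: np.ndarray, obs: np.ndarray, cfg: ExtremeEvalConfig
) -> dict[float, ExtremePoint]:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    z = (obs - cfg.mean) / cfg.sd
    curve: dict[float, ExtremePoint] = {}
    for t in cfg.thresholds:
        sel = z > t
        n = int(sel.sum())
        if n == 0:
            curve[t] = ExtremePoint(rmse=float("nan"), n_selected=0,
                                    mean_extreme_flux=float("nan"))
        else:
            curve[t] = ExtremePoint(
                rmse=rmse(pred[sel], obs[sel]),
                n_selected=n,
                mean_extreme_flux=float(obs[sel].mean()),
            )
    return curve


def zone_report(
    model: EnsembleModel,
    inputs: np.ndarray,
    obs: np.ndarray,
    zones: Sequence[str],
    threshold: float | None = None,
    cfg: ExtremeEvalConfig | None = None,
) -> dict[str, ZoneScore]:
    """Per-zone RMSE with across-member spread.

    With ``threshold`` set, scoring is restricted to the extreme subset
    ``z > threshold`` (z from ``cfg``'s training-target statistics).
    """
    zones = np.asarray(zones, dtype=object)
    obs = np.asarray(obs, dtype=float)
    if len(zones) != len(obs):
        raise SchemaError("zones and observations length mismatch")
    if any(z is None or (isinstance(z, float) and np.isnan(z)) or z == ""
           for z in zones):
        raise SchemaError("unlabeled record in zone_report")
    keep = np.ones(len(obs), dtype=bool)
    if threshold is not None:
        if cfg is None:
            raise SchemaError("threshold given without extreme statistics")
        keep = (obs - cfg.mean) / cfg.sd > threshold

    member_preds = np.stack([m.forward(inputs) for m in model.members])
    mean_pred = member_preds.mean(axis=0)
    out: dict[str, ZoneScore] = {}
    for zone in sorted(set(zones.tolist())):
        sel = (zones == zone) & keep
        n = int(sel.sum())
        if n == 0:
            continue
        score = rmse(mean_pred[sel], obs[sel])
        per_member = [rmse(mp[sel], obs[sel]) for mp in member_preds]
        out[zone] = ZoneScore(
            rmse=score,
            member_spread=float(np.std(per_member, ddof=0)),
            n=n,
        )
    return out


def pooled_rmse_from_zones(report: Mapping[str, ZoneScore]) -> float:
    """Count-weighted quadratic mean of zone RMSEs (equals overall RMSE)."""
    n_total = sum(s.n for s in report.values())
    if n_total == 0:
        raise SchemaError("empty zone report")
    return float(np.sqrt(sum(s.n * s.rmse**2 for s in report.values()) / n_total))


def evaluate(
    model: EnsembleModel,
    inputs: np.ndarray,
    obs: np.ndarray,
    zones: Sequence[str],
    cfg: ExtremeEvalConfig,
) -> EvalReport:
    """Full station-level report: overall, per-zone, and extreme sweep."""
    pred, _ = predict_ensemble(model, inputs)
    return EvalReport(
        rmse_overall=rmse(pred, obs),
        rmse_by_zone=zone_report(model, inputs, obs, zones),
        extreme_curve=extreme_curve_from_predictions(pred, obs, cfg),
    )
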