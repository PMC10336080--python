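"""Optimization-based meta-learning, the non-meta baseline, and ensembles.

``meta_train`` runs the two-loop scheme: for each sampled base task the
current initialization θ is cloned and adapted by a few inner gradient
steps to task parameters φ; the outer step then updates θ from the
gradient of the meta-objective (target-task train data, held-out base
batches, or both) evaluated at φ.  The meta-gradient is first-order by
default; the exact second-order correction is available via
Hessian-vector products.  ``baseline_train`` is conventional mini-batch
descent on the pooled training data.  Both produce seeded ensembles whose
per-sample mean and spread quantify prediction uncertainty.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._optim import make_optimizer
from .errors import ConfigurationError, DivergenceError, SchemaError
from .learners import Learner, LearnerConfig, build_learner
from .station_data import (
    FEATURES,
    NormStats,
    StationRecord,
    extract_rows,
    fit_norm_stats,
    make_batches,
    make_windows,
    z_normalize,
)
from .tasks import MetaSplit, RowRange, baseline_datasets

_META_OBJECTIVES = ("target_train", "base_test", "both")


@dataclasses.dataclass(frozen=True)
class MetaConfig:
    """Hyperparameters of the two-loop trainer and its baseline."""

    inner_lr: float = 1e-2
    outer_lr: float = 1e-3
    inner_steps: int = 1
    tasks_per_meta_batch: int = 4
    epochs: int = 100
    ensemble_size: int = 5
    first_order: bool = True
    seed: int = 0
    batch_size: int = 256
    meta_objective: str = "target_train"
    outer_opt: str = "adam"
    target: str = "GPP"
    grad_clip: float = 10.0  # max gradient norm; 0 disables clipping
    lr_schedule: str = "constant"  # or "cosine" decay of the outer lr

    def __post_init__(self) -> None:
        if self.inner_lr <= 0 or self.outer_lr <= 0:
            raise ConfigurationError("learning rates must be > 0")
        if self.inner_steps < 0:
            raise ConfigurationError("inner_steps must be >= 0")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if self.ensemble_size < 1:
            raise ConfigurationError("ensemble_size must be >= 1")
        if self.meta_objective not in _META_OBJECTIVES:
            raise ConfigurationError(
                f"meta_objective must be one of {_META_OBJECTIVES}"
            )
        if self.target not in ("GPP", "RECO"):
            raise ConfigurationError("target must be 'GPP' or 'RECO'")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ConfigurationError("lr_schedule must be 'constant' or 'cosine'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetaConfig":
        return cls(**d)


@dataclasses.dataclass
class EnsembleModel:
    """Independently seeded learners plus their training provenance."""

    members: list[Learner]
    train_history: pd.DataFrame
    norm_stats: NormStats
    target: str
    lcfg: LearnerConfig
    mcfg: MetaConfig

    def save(self, path: str | Path) -> None:
        meta = {
            "lcfg": self.lcfg.to_dict(),
            "mcfg": self.mcfg.to_dict(),
            "target": self.target,
            "features": self.norm_stats.features,
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            stats_mean=self.norm_stats.mean.to_numpy(),
            stats_sd=self.norm_stats.sd.to_numpy(),
            thetas=np.stack([m.get_params() for m in self.members]),
            history=np.frombuffer(
                self.train_history.to_csv(index=False).encode(), dtype=np.uint8
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        with np.load(path) as arc:
            meta = json.loads(arc["meta"].tobytes().decode())
            lcfg = LearnerConfig.from_dict(meta["lcfg"])
            mcfg = MetaConfig.from_dict(meta["mcfg"])
            feats = meta["features"]
            stats = NormStats(
                mean=pd.Series(arc["stats_mean"], index=feats),
                sd=pd.Series(arc["stats_sd"], index=feats),
            )
            members = []
            for theta in arc["thetas"]:
                lrn = build_learner(lcfg)
                lrn.set_params(theta)
                members.append(lrn)
            history = pd.read_csv(io.BytesIO(arc["history"].tobytes()))
        return cls(members=members, train_history=history, norm_stats=stats,
                   target=meta["target"], lcfg=lcfg, mcfg=mcfg)


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------

def _as_mapping(stations) -> dict[str, StationRecord]:
    if isinstance(stations, Mapping):
        return dict(stations)
    return {s.station_id: s for s in stations}


def fit_training_stats(
    stations, refs: Mapping[str, RowRange]
) -> NormStats:
    """Fit z-normalization statistics on the referenced training rows only."""
    by_id = _as_mapping(stations)
    frames = [by_id[sid].data.iloc[a:b] for sid, (a, b) in sorted(refs.items())]
    if not frames:
        raise ConfigurationError("no training rows to fit statistics on")
    return fit_norm_stats(pd.concat(frames, ignore_index=True)[FEATURES])


def _station_arrays(
    rec: StationRecord, rng_rows: RowRange, stats: NormStats,
    lcfg: LearnerConfig, target: str,
) -> tuple[np.ndarray, np.ndarray]:
    a, b = rng_rows
    df = z_normalize(rec.data.iloc[a:b], stats)
    if lcfg.arch == "mlp":
        return extract_rows(df, target=target)
    wins = make_windows(df, window=lcfg.window, target=target)
    if not wins:
        return np.empty((0, lcfg.window, len(FEATURES))), np.empty(0)
    X = np.stack([w.inputs for w in wins])
    y = np.array([w.target for w in wins])
    return X, y


def build_task_arrays(
    stations, refs: Mapping[str, RowRange], stats: NormStats,
    lcfg: LearnerConfig, target: str,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-station (X, y) arrays; stations with no usable samples dropped."""
    by_id = _as_mapping(stations)
    out = {}
    for sid in sorted(refs):
        X, y = _station_arrays(by_id[sid], refs[sid], stats, lcfg, target)
        if len(y):
            out[sid] = (X, y)
    return out


def build_eval_arrays(
    stations, refs: Mapping[str, RowRange], stats: NormStats,
    lcfg: LearnerConfig, target: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pooled (X, y, zone, station_id) arrays for evaluation."""
    by_id = _as_mapping(stations)
    Xs, ys, zones, sids = [], [], [], []
    for sid in sorted(refs):
        X, y = _station_arrays(by_id[sid], refs[sid], stats, lcfg, target)
        if not len(y):
            continue
        Xs.append(X)
        ys.append(y)
        zones.append(np.full(len(y), by_id[sid].zone, dtype=object))
        sids.append(np.full(len(y), sid, dtype=object))
    if not Xs:
        raise ConfigurationError("no usable evaluation samples")
    return (np.concatenate(Xs), np.concatenate(ys),
            np.concatenate(zones), np.concatenate(sids))


def _pool(task_data: Mapping[str, tuple[np.ndarray, np.ndarray]]):
    Xs = [X for X, _ in task_data.values()]
    ys = [y for _, y in task_data.values()]
    if not Xs:
        raise ConfigurationError("empty task set")
    return np.concatenate(Xs), np.concatenate(ys)


def _sample_batch(X, y, batch_size, rng):
    if len(y) <= batch_size:
        return X, y
    sel = rng.choice(len(y), size=batch_size, replace=False)
    return X[sel], y[sel]


def _member_seed(mcfg_seed: int, lcfg_seed: int, member: int) -> int:
    return int(np.random.SeedSequence([mcfg_seed, lcfg_seed, member]).generate_state(1)[0])


def _lr_factor(mcfg: "MetaConfig", epoch: int) -> float:
    if mcfg.lr_schedule == "cosine" and mcfg.epochs > 1:
        return 0.5 * (1.0 + np.cos(np.pi * epoch / (mcfg.epochs - 1)))
    return 1.0


def _clip(grad: np.ndarray, max_norm: float) -> np.ndarray:
    if max_norm <= 0:
        return grad
    norm = float(np.linalg.norm(grad))
    if norm > max_norm:
        return grad * (max_norm / norm)
    return grad


def _check_finite(loss: float, epoch: int) -> None:
    if not np.isfinite(loss):
        raise DivergenceError(f"non-finite loss at epoch {epoch}")


def _rmse_of(learner: Learner, X, y, chunk: int = 65536) -> float:
    preds = np.concatenate(
        [learner.forward(X[i : i + chunk]) for i in range(0, len(y), chunk)]
    )
    return float(np.sqrt(np.mean((preds - y) ** 2)))


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------

def meta_train(
    split: MetaSplit,
    stations,
    lcfg: LearnerConfig,
    mcfg: MetaConfig,
) -> EnsembleModel:
    """Two-loop meta-training of an ensemble on a task split."""
    by_id = _as_mapping(stations)
    stats = fit_training_stats(by_id, {**split.base_train, **split.target_train})
    target = mcfg.target
    base_train = build_task_arrays(by_id, split.base_train, stats, lcfg, target)
    base_test = build_task_arrays(by_id, split.base_test, stats, lcfg, target)
    target_train = build_task_arrays(by_id, split.target_train, stats, lcfg, target)
    target_test = build_task_arrays(by_id, split.target_test, stats, lcfg, target)
    if not base_train:
        raise ConfigurationError("no usable base_train tasks")
    if not target_train and mcfg.meta_objective in ("target_train", "both"):
        raise ConfigurationError("no usable target_train data")
    tt_X, tt_y = _pool(target_train) if target_train else (None, None)
    val_X, val_y = _pool(target_test) if target_test else (None, None)
    task_ids = sorted(base_train)

    members: list[Learner] = []
    rows = []
    for m in range(mcfg.ensemble_size):
        lrn = build_learner(
            dataclasses.replace(lcfg, seed=_member_seed(mcfg.seed, lcfg.seed, m))
        )
        rng = np.random.default_rng([mcfg.seed, 71, m])
        opt = make_optimizer(mcfg.outer_opt, mcfg.outer_lr)
        theta = lrn.get_params()
        # an epoch covers every base-train batch: a task occurs once per
        # batch it owns, so large tasks are visited proportionally often
        occurrences = np.repeat(
            np.arange(len(task_ids)),
            [max(1, -(-len(base_train[t][1]) // mcfg.batch_size)) for t in task_ids],
        )
        for epoch in range(mcfg.epochs):
            opt.lr = mcfg.outer_lr * _lr_factor(mcfg, epoch)
            order = rng.permutation(occurrences)
            for g0 in range(0, len(order), mcfg.tasks_per_meta_batch):
                group = order[g0 : g0 + mcfg.tasks_per_meta_batch]
                grads = []
                for ti in group:
                    tid = task_ids[ti]
                    phi = theta
                    traj = []
                    for _ in range(mcfg.inner_steps):
                        Xb, yb = _sample_batch(*base_train[tid], mcfg.batch_size, rng)
                        lrn.set_params(phi)
                        loss, g = lrn.loss_and_grad(Xb, yb)
                        _check_finite(loss, epoch)
                        traj.append((phi, Xb, yb))
                        phi = phi - mcfg.inner_lr * _clip(g, mcfg.grad_clip)
                    Xo, yo = _meta_objective_batch(
                        mcfg, rng, tid, base_test, tt_X, tt_y
                    )
                    lrn.set_params(phi)
                    loss, g_out = lrn.loss_and_grad(Xo, yo)
                    _check_finite(loss, epoch)
                    if not mcfg.first_order:
                        g_out = _second_order_correction(
                            lrn, traj, g_out, mcfg.inner_lr
                        )
                    grads.append(g_out)
                theta = opt.step(theta, _clip(np.mean(grads, axis=0), mcfg.grad_clip))
            if val_y is not None:
                lrn.set_params(theta)
                rows.append(
                    {"epoch": epoch, "member": m, "split": "target_test",
                     "rmse": _rmse_of(lrn, val_X, val_y)}
                )
        lrn.set_params(theta)
        members.append(lrn)
    history = pd.DataFrame(rows, columns=["epoch", "member", "split", "rmse"])
    return EnsembleModel(members=members, train_history=history,
                         norm_stats=stats, target=target, lcfg=lcfg, mcfg=mcfg)


def _meta_objective_batch(mcfg, rng, tid, base_test, tt_X, tt_y):
    parts = []
    if mcfg.meta_objective in ("target_train", "both") and tt_y is not None:
        parts.append(_sample_batch(tt_X, tt_y, mcfg.batch_size, rng))
    if mcfg.meta_objective in ("base_test", "both"):
        if tid in base_test:
            parts.append(_sample_batch(*base_test[tid], mcfg.batch_size, rng))
    if not parts:
        raise ConfigurationError(
            f"no meta-objective data for task {tid!r} "
            f"(objective={mcfg.meta_objective})"
        )
    X = np.concatenate([p[0] for p in parts])
    y = np.concatenate([p[1] for p in parts])
    return X, y


def _second_order_correction(lrn, traj, g_out, inner_lr, eps=1e-5):
    """Back-chain (I - lr*H) factors via central-difference HVPs."""
    v = g_out
    for phi_s, Xb, yb in reversed(traj):
        nv = float(np.linalg.norm(v))
        if nv == 0:
            break
        h = eps / nv
        lrn.set_params(phi_s + h * v)
        _, gp = lrn.loss_and_grad(Xb, yb)
        lrn.set_params(phi_s - h * v)
        _, gm = lrn.loss_and_grad(Xb, yb)
        hvp = (gp - gm) / (2 * h)
        v = v - inner_lr * hvp
    return v


def baseline_train(
    train_refs: Mapping[str, RowRange],
    test_refs: Mapping[str, RowRange],
    stations,
    lcfg: LearnerConfig,
    mcfg: MetaConfig,
) -> EnsembleModel:
    """Standard mini-batch MSE training on the pooled training data."""
    by_id = _as_mapping(stations)
    stats = fit_training_stats(by_id, train_refs)
    target = mcfg.target
    train = build_task_arrays(by_id, train_refs, stats, lcfg, target)
    if not train:
        raise ConfigurationError("no usable training data")
    X, y = _pool(train)
    test = build_task_arrays(by_id, test_refs, stats, lcfg, target) if test_refs else {}
    val_X, val_y = _pool(test) if test else (None, None)

    members: list[Learner] = []
    rows = []
    for m in range(mcfg.ensemble_size):
        lrn = build_learner(
            dataclasses.replace(lcfg, seed=_member_seed(mcfg.seed, lcfg.seed, m))
        )
        rng = np.random.default_rng([mcfg.seed, 72, m])
        opt = make_optimizer(mcfg.outer_opt, mcfg.outer_lr)
        theta = lrn.get_params()
        for epoch in range(mcfg.epochs):
            opt.lr = mcfg.outer_lr * _lr_factor(mcfg, epoch)
            batches = make_batches(
                X, y, batch_size=mcfg.batch_size,
                seed=int(rng.integers(2**31)),
            )
            for batch in batches:
                lrn.set_params(theta)
                loss, g = lrn.loss_and_grad(batch.inputs, batch.targets)
                _check_finite(loss, epoch)
                theta = opt.step(theta, _clip(g, mcfg.grad_clip))
            if val_y is not None:
                lrn.set_params(theta)
                rows.append(
                    {"epoch": epoch, "member": m, "split": "test",
                     "rmse": _rmse_of(lrn, val_X, val_y)}
                )
        lrn.set_params(theta)
        members.append(lrn)
    history = pd.DataFrame(rows, columns=["epoch", "member", "split", "rmse"])
    return EnsembleModel(members=members, train_history=history,
                         norm_stats=stats, target=target, lcfg=lcfg, mcfg=mcfg)


def train_from_split(
    mode: str, split: MetaSplit, stations, lcfg: LearnerConfig, mcfg: MetaConfig
) -> EnsembleModel:
    """Dispatch ``meta`` / ``baseline`` training from one task split."""
    if mode == "meta":
        return meta_train(split, stations, lcfg, mcfg)
    if mode == "baseline":
        train_refs, test_refs = baseline_datasets(split)
        return baseline_train(train_refs, test_refs, stations, lcfg, mcfg)
    raise ConfigurationError(f"unknown training mode {mode!r}")


def predict_ensemble(model: EnsembleModel, inputs: np.ndarray):
    """Per-sample ensemble mean and population standard deviation."""
    if not model.members:
        raise ConfigurationError("empty ensemble")
    preds = np.stack([m.forward(inputs) for m in model.members])
    return preds.mean(axis=0), preds.std(axis=0, ddof=0)


# ---------------------------------------------------------------------------
# k-fold hyperparameter selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KFoldResult:
    best: tuple[LearnerConfig, MetaConfig]
    best_index: int
    scores: pd.DataFrame  # columns: candidate, fold, rmse


def kfold_select(
    candidates: Sequence[tuple[LearnerConfig, MetaConfig]],
    stations,
    train_refs: Mapping[str, RowRange],
    k: int = 5,
    seed: int = 0,
) -> KFoldResult:
    """Pick the candidate minimizing mean held-out RMSE over station folds."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if not candidates:
        raise ConfigurationError("no candidates")
    by_id = _as_mapping(stations)
    sids = sorted(train_refs)
    if len(sids) < k:
        raise ConfigurationError(f"{len(sids)} stations < k={k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sids))
    folds = np.array_split(perm, k)
    rows = []
    for ci, (lcfg, mcfg) in enumerate(candidates):
        for fi, fold in enumerate(folds):
            held = {sids[i] for i in fold}
            fit_refs = {s: r for s, r in train_refs.items() if s not in held}
            val_refs = {s: r for s, r in train_refs.items() if s in held}
            model = baseline_train(fit_refs, {}, by_id, lcfg, mcfg)
            Xv, yv, _, _ = build_eval_arrays(
                by_id, val_refs, model.norm_stats, lcfg, mcfg.target
            )
            pred, _ = predict_ensemble(model, Xv)
            rows.append(
                {"candidate": ci, "fold": fi,
                 "rmse": float(np.sqrt(np.mean((pred - yv) ** 2)))}
            )
    scores = pd.DataFrame(rows)
    means = scores.groupby("candidate")["rmse"].mean()
    best_index = int(means.idxmin())
    return KFoldResult(best=tuple(candidates[best_index]), best_index=best_index,
                       scores=scores)
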