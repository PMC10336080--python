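"""Differentiable regressors (MLP, LSTM, BiLSTM) in pure numpy.

All three architectures share one contract: a deterministic forward pass,
a mean-squared-error loss with an analytic gradient with respect to a flat
parameter vector, and exact parameter get/set for inner-loop adaptation.
Gradients are pinned by central finite-difference tests at toy size.

The MLP is a stack of ``n_layers`` fully connected weight layers with
LeakyReLU activations between them and a scalar output.  The recurrent
variants replace the first dense layer with an (bi)LSTM cell that consumes
a ``(window, features)`` sequence; the remaining dense layers read out the
final hidden state (forward direction) or the concatenated final states of
both directions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, SchemaError

ARCHS = ("mlp", "lstm", "bilstm")


def leaky_relu(x, alpha: float = 0.01):
    """LeakyReLU: ``x`` if ``x > 0`` else ``alpha * x``."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x, alpha * x)
    return out if out.ndim else float(out)


def _sigmoid(x):
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclasses.dataclass(frozen=True)
class LearnerConfig:
    """Architecture hyperparameters.

    ``n_layers`` counts weight layers; the default 3 gives two hidden
    transitions plus the scalar output layer.
    """

    arch: str = "mlp"
    hidden_size: int = 350
    n_layers: int = 3
    alpha: float = 0.01
    input_dim: int = 5
    window: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ConfigurationError(f"unknown arch {self.arch!r}; choose from {ARCHS}")
        if self.hidden_size < 1:
            raise ConfigurationError("hidden_size must be >= 1")
        if not 0 < self.alpha <= 1:
            # alpha = 1 is allowed: the activation becomes the identity
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.n_layers < 2:
            raise ConfigurationError("n_layers must be >= 2")
        if self.input_dim < 1:
            raise ConfigurationError("input_dim must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LearnerConfig":
        return cls(**d)


def _param_shapes(cfg: LearnerConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Ordered (name, shape) table defining the flat parameter layout."""
    H, F, L = cfg.hidden_size, cfg.input_dim, cfg.n_layers
    shapes: list[tuple[str, tuple[int, ...]]] = []
    if cfg.arch == "mlp":
        dims = [F] + [H] * (L - 1) + [1]
    elif cfg.arch == "lstm":
        shapes += [("Wx", (4 * H, F)), ("Wh", (4 * H, H)), ("b", (4 * H,))]
        dims = [H] + [H] * (L - 2) + [1]
    else:  # bilstm: two independent directions, concatenated readout
        for d in ("f", "b"):
            shapes += [(f"Wx_{d}", (4 * H, F)), (f"Wh_{d}", (4 * H, H)), (f"b_{d}", (4 * H,))]
        dims = [2 * H] + [H] * (L - 2) + [1]
    for i in range(len(dims) - 1):
        shapes.append((f"W{i}", (dims[i + 1], dims[i])))
        shapes.append((f"b{i}", (dims[i + 1],)))
    return shapes


class Learner:
    """A differentiable regressor with a flat parameter vector θ."""

    def __init__(self, config: LearnerConfig):
        self.config = config
        self._shapes = _param_shapes(config)
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        for name, shape in self._shapes:
            # uniform fan-in init; recurrent weights scale with hidden size
            if name.startswith(("Wx", "Wh", "b_")) or name == "b":
                bound = 1.0 / np.sqrt(config.hidden_size)
            else:
                fan_in = shape[1] if len(shape) == 2 else shape[0]
                bound = 1.0 / np.sqrt(max(fan_in, 1))
            self.params[name] = rng.uniform(-bound, bound, size=shape)

    # -- flat parameter contract -------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(int(np.prod(s)) for _, s in self._shapes)

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.params[n].ravel() for n, _ in self._shapes])

    def set_params(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise SchemaError(
                f"theta has shape {theta.shape}, expected ({self.n_params},)"
            )
        pos = 0
        for name, shape in self._shapes:
            size = int(np.prod(shape))
            self.params[name] = theta[pos : pos + size].reshape(shape).copy()
            pos += size

    def _flatten_grads(self, grads: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([grads[n].ravel() for n, _ in self._shapes])

    # -- forward -----------------------------------------------------------
    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.config.arch == "mlp":
            if X.ndim != 2 or X.shape[1] != self.config.input_dim:
                raise SchemaError(
                    f"mlp expects (batch, {self.config.input_dim}), got {X.shape}"
                )
        else:
            if X.ndim != 3 or X.shape[2] != self.config.input_dim:
                raise SchemaError(
                    f"{self.config.arch} expects (batch, window, "
                    f"{self.config.input_dim}), got {X.shape}"
                )
        return X

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Predict a scalar per sample; deterministic given θ."""
        X = self._check_input(X)
        readout, _ = self._readout(X)
        pred, _ = self._dense_forward(readout)
        return pred

    def _readout(self, X):
        """First-layer output: identity for MLP, final hidden state(s) else."""
        if self.config.arch == "mlp":
            return X, None
        if self.config.arch == "lstm":
            h, cache = _lstm_forward(X, self.params["Wx"], self.params["Wh"], self.params["b"])
            return h, cache
        hf, cf = _lstm_forward(X, self.params["Wx_f"], self.params["Wh_f"], self.params["b_f"])
        hb, cb = _lstm_forward(X[:, ::-1, :], self.params["Wx_b"], self.params["Wh_b"], self.params["b_b"])
        return np.concatenate([hf, hb], axis=1), (cf, cb)

    def _dense_names(self):
        i = 0
        while f"W{i}" in self.params:
            yield f"W{i}", f"b{i}"
            i += 1

    def _dense_forward(self, x):
        alpha = self.config.alpha
        caches = []
        names = list(self._dense_names())
        for j, (wn, bn) in enumerate(names):
            a = x @ self.params[wn].T + self.params[bn]
            last = j == len(names) - 1
            out = a if last else leaky_relu(a, alpha)
            caches.append((x, a))
            x = out
        return x[:, 0], caches

    # -- loss and gradient -------------------------------------------------
    def loss_and_grad(self, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        """MSE over the batch and its gradient w.r.t. the flat θ."""
        X = self._check_input(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise SchemaError(f"targets shape {y.shape} does not match batch {X.shape[0]}")
        readout, rcache = self._readout(X)
        pred, dcaches = self._dense_forward(readout)
        resid = pred - y
        mse = float(np.mean(resid**2))

        grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        dout = (2.0 * resid / len(y))[:, None]  # (B, 1)
        dx = self._dense_backward(dout, dcaches, grads)
        if self.config.arch == "lstm":
            _lstm_backward(dx, rcache, self.params["Wh"], grads, "Wx", "Wh", "b")
        elif self.config.arch == "bilstm":
            H = self.config.hidden_size
            cf, cb = rcache
            _lstm_backward(dx[:, :H], cf, self.params["Wh_f"], grads, "Wx_f", "Wh_f", "b_f")
            _lstm_backward(dx[:, H:], cb, self.params["Wh_b"], grads, "Wx_b", "Wh_b", "b_b")
        return mse, self._flatten_grads(grads)

    def _dense_backward(self, dout, caches, grads):
        alpha = self.config.alpha
        names = list(self._dense_names())
        d = dout
        for j in range(len(names) - 1, -1, -1):
            wn, bn = names[j]
            x_in, a = caches[j]
            if j < len(names) - 1:  # undo the activation of this layer's output
                pass
            grads[wn] += d.T @ x_in
            grads[bn] += d.sum(axis=0)
            d = d @ self.params[wn]
            if j > 0:
                _, a_prev = caches[j - 1]
                d = d * np.where(a_prev > 0, 1.0, alpha)
        return d  # gradient w.r.t. the readout / input

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Portable checkpoint: JSON config + flat θ in one .npz archive."""
        np.savez(
            path,
            config=np.frombuffer(json.dumps(self.config.to_dict()).encode(), dtype=np.uint8),
            theta=self.get_params(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Learner":
        with np.load(path) as arc:
            cfg = LearnerConfig.from_dict(json.loads(arc["config"].tobytes().decode()))
            learner = cls(cfg)
            learner.set_params(arc["theta"])
        return learner


def build_learner(config: LearnerConfig) -> Learner:
    """Construct a seeded-random learner for the given architecture."""
    return Learner(config)


# ---------------------------------------------------------------------------
# LSTM cell forward / backward-through-time
# ---------------------------------------------------------------------------

def _lstm_forward(X, Wx, Wh, b):
    """Run an LSTM over (B, T, F); returns final hidden state and caches."""
    B, T, _ = X.shape
    H = Wh.shape[1]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    caches = []
    for t in range(T):
        x_t = X[:, t, :]
        a = x_t @ Wx.T + h @ Wh.T + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        caches.append((x_t, h, c, i, f, g, o, c_new))
        h, c = h_new, c_new
    return h, caches


def _lstm_backward(dh_T, caches, Wh, grads, kx, kh, kb):
    """Backprop-through-time given the gradient at the final hidden state.

    Accumulates into ``grads[kx]``, ``grads[kh]``, ``grads[kb]``.
    """
    dh = dh_T
    dc = np.zeros_like(dh)
    for x_t, h_prev, c_prev, i, f, g, o, c_new in reversed(caches):
        tc = np.tanh(c_new)
        do = dh * tc
        dct = dc + dh * o * (1.0 - tc**2)
        di = dct * g
        dg = dct * i
        df = dct * c_prev
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        grads[kx] += da.T @ x_t
        grads[kh] += da.T @ h_prev
        grads[kb] += da.sum(axis=0)
        dh = da @ Wh
        dc = dct * f
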