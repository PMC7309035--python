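"""CNN-LSTM saccade classifier with a Monte Carlo dropout head.

The architecture is two 1-D convolutional blocks (kernel 3, 128 filters,
ReLU, max-pool 2/2) feeding an LSTM with 100 units, a dropout layer (rate
0.5) on the LSTM output, and a 3-unit softmax dense layer — one class
probability vector per saccade, class order C, P, S.

Dropout is the single stochastic layer and sits after the LSTM.  In Monte
Carlo dropout (MCD) mode it stays active at inference, with a fresh 0-1 mask
on every forward pass; repeated passes then sample the model's predictive
distribution.  With dropout disabled the model is the plain deterministic
CNN-LSTM baseline.  Because everything below the dropout layer is
deterministic at inference, the conv+LSTM feature map of a saccade can be
computed once and reused across MCD passes; the stochastic part of each pass
is only mask x dense x softmax.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn_ops as ops
from .data import DataSet

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "SaccadeNet",
    "build_model",
    "train",
    "stochastic_forward",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Network hyperparameters; the defaults are the reference architecture."""

    n_conv_layers: int = 2
    kernel_size: int = 3
    n_filters: int = 128
    pool_size: int = 2
    pool_stride: int = 2
    lstm_units: int = 100
    dropout_rate: float = 0.5
    n_classes: int = 3

    def __post_init__(self) -> None:
        for name in ("n_conv_layers", "kernel_size", "n_filters", "pool_size",
                     "pool_stride", "lstm_units", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.pool_size != self.pool_stride:
            raise ValueError("only non-overlapping pooling (size == stride) is supported")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (adaptive-moment gradient descent, cross-entropy)."""

    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class SaccadeNet:
    """The CNN-LSTM model: parameters, forward/backward, training state."""

    def __init__(self, cfg: ArchitectureConfig, dtype=np.float32, init_seed: int = 0):
        self.cfg = cfg
        self.dtype = np.dtype(dtype).type
        self.trained = False
        self.training_log: list[dict] = []
        self.initialize(init_seed)

    # -- parameters ---------------------------------------------------------

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        cfg = self.cfg
        p: dict[str, np.ndarray] = {}
        c_in = 1
        for i in range(cfg.n_conv_layers):
            k = cfg.kernel_size
            p[f"conv{i}_w"] = ops.glorot_uniform(
                rng, (k, c_in, cfg.n_filters), k * c_in, cfg.n_filters, self.dtype
            )
            p[f"conv{i}_b"] = np.zeros(cfg.n_filters, dtype=self.dtype)
            c_in = cfg.n_filters
        h = cfg.lstm_units
        p["lstm_wx"] = ops.glorot_uniform(rng, (c_in, 4 * h), c_in, h, self.dtype)
        p["lstm_wh"] = ops.glorot_uniform(rng, (h, 4 * h), h, h, self.dtype)
        b = np.zeros(4 * h, dtype=self.dtype)
        b[h : 2 * h] = 1.0  # forget-gate bias
        p["lstm_b"] = b
        p["dense_w"] = ops.glorot_uniform(
            rng, (h, cfg.n_classes), h, cfg.n_classes, self.dtype
        )
        p["dense_b"] = np.zeros(cfg.n_classes, dtype=self.dtype)
        self.params = p

    def describe(self) -> dict:
        """Architecture introspection: layer sequence with sizes."""
        cfg = self.cfg
        layers = []
        for i in range(cfg.n_conv_layers):
            layers.append(
                {"layer": "conv1d", "filters": cfg.n_filters,
                 "kernel_size": cfg.kernel_size, "activation": "relu"}
            )
            layers.append({"layer": "maxpool1d", "size": cfg.pool_size,
                           "stride": cfg.pool_stride})
        layers.append({"layer": "lstm", "units": cfg.lstm_units})
        layers.append({"layer": "dropout", "rate": cfg.dropout_rate,
                       "monte_carlo": True})
        layers.append({"layer": "dense", "units": cfg.n_classes,
                       "activation": "softmax"})
        return {"layers": layers,
                "n_parameters": int(sum(v.size for v in self.params.values()))}

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim != 2:
            raise ValueError(f"expected (batch, time) input, got shape {x.shape}")
        return x

    def features(self, x, return_cache: bool = False):
        """Deterministic conv+LSTM trunk: (B, T) -> LSTM final state (B, H)."""
        x = self._check_input(x)
        h = x[:, :, None]
        caches = []
        for i in range(self.cfg.n_conv_layers):
            h, c_conv = ops.conv1d_forward(
                h, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"]
            )
            h, c_relu = ops.relu_forward(h)
            h, c_pool = ops.maxpool1d_forward(h, self.cfg.pool_size)
            caches.append((c_conv, c_relu, c_pool))
        h, c_lstm = ops.lstm_forward(
            h, self.params["lstm_wx"], self.params["lstm_wh"], self.params["lstm_b"]
        )
        if return_cache:
            return h, (caches, c_lstm)
        return h

    def head(self, feats, rng: np.random.Generator | None = None,
             dropout_active: bool = False):
        """Dropout + dense + softmax on trunk features: (B, H) -> (B, n_classes)."""
        if dropout_active and self.cfg.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("dropout_active requires an rng")
            mask = ops.dropout_mask(rng, feats.shape, self.cfg.dropout_rate, self.dtype)
            feats = feats * mask
        logits, _ = ops.dense_forward(
            feats, self.params["dense_w"], self.params["dense_b"]
        )
        return ops.softmax(logits)

    def forward(self, x, rng: np.random.Generator | None = None,
                dropout_active: bool = False):
        """Full forward pass: class probabilities, one row per saccade."""
        return self.head(self.features(x), rng=rng, dropout_active=dropout_active)

    def predict_proba(self, x, batch_size: int = 512) -> np.ndarray:
        """Deterministic (dropout-off) probabilities — the plain CNN-LSTM mode."""
        x = self._check_input(x)
        out = [self.forward(x[i : i + batch_size])
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0) if out else np.empty((0, self.cfg.n_classes))

    def loss_and_grads(self, x, y_index, rng: np.random.Generator):
        """Cross-entropy loss and gradients with dropout active (training mode)."""
        feats, (conv_caches, c_lstm) = self.features(x, return_cache=True)
        mask = ops.dropout_mask(rng, feats.shape, self.cfg.dropout_rate, self.dtype)
        dropped = feats * mask
        logits, c_dense = ops.dense_forward(
            dropped, self.params["dense_w"], self.params["dense_b"]
        )
        loss, dlogits = ops.softmax_cross_entropy(logits, y_index)
        grads: dict[str, np.ndarray] = {}
        dfeat, grads["dense_w"], grads["dense_b"] = ops.dense_backward(dlogits, c_dense)
        dfeat = dfeat * mask
        dh, grads["lstm_wx"], grads["lstm_wh"], grads["lstm_b"] = ops.lstm_backward(
            dfeat, c_lstm
        )
        for i in range(self.cfg.n_conv_layers - 1, -1, -1):
            c_conv, c_relu, c_pool = conv_caches[i]
            dh = ops.maxpool1d_backward(dh, c_pool)
            dh = ops.relu_backward(dh, c_relu)
            dh, grads[f"conv{i}_w"], grads[f"conv{i}_b"] = ops.conv1d_backward(dh, c_conv)
        n_correct = int((np.argmax(logits, axis=1) == y_index).sum())
        return loss, grads, n_correct


def build_model(cfg: ArchitectureConfig | None = None, dtype=np.float32) -> SaccadeNet:
    """Construct an untrained CNN-LSTM with the given (default: reference) config."""
    return SaccadeNet(cfg or ArchitectureConfig(), dtype=dtype)


def train(model: SaccadeNet, train_set: DataSet, cfg: TrainConfig | None = None,
          verbose: bool = False) -> SaccadeNet:
    """Train in place on all saccades of ``train_set``.

    Every saccade inherits its parent register's label.  Dropout is active
    throughout training.  The per-epoch mean loss and accuracy (computed over
    the training batches as seen) are appended to ``model.training_log``.
    Fixed seed => identical parameter trajectory.
    """
    cfg = cfg or TrainConfig()
    x, y, _ = train_set.saccade_matrix()
    if x.shape[0] == 0:
        raise ValueError("training set contains no saccades")
    x = x.astype(model.dtype)
    model.initialize(cfg.seed)
    model.training_log = []
    rng = np.random.default_rng(cfg.seed)
    opt = ops.AdamOptimizer(model.params, lr=cfg.learning_rate)
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss, total_correct = 0.0, 0
        t0 = time.perf_counter()
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads, n_correct = model.loss_and_grads(x[idx], y[idx], rng)
            opt.step(model.params, grads)
            total_loss += loss * len(idx)
            total_correct += n_correct
        entry = {
            "epoch": epoch + 1,
            "loss": total_loss / n,
            "accuracy": total_correct / n,
            "seconds": time.perf_counter() - t0,
        }
        model.training_log.append(entry)
        if verbose:
            print(f"epoch {entry['epoch']:3d}  loss {entry['loss']:.4f}  "
                  f"acc {entry['accuracy']:.4f}  ({entry['seconds']:.1f}s)")
    model.trained = True
    return model


def stochastic_forward(model: SaccadeNet, saccades, rng: np.random.Generator,
                       batch_size: int = 512) -> np.ndarray:
    """One MCD pass: a fresh dropout mask, one probability row per saccade."""
    if not model.trained:
        raise RuntimeError("model is untrained; call train() first")
    x = np.asarray(saccades, dtype=model.dtype)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] == 0:
        return np.empty((0, model.cfg.n_classes))
    out = []
    for i in range(0, x.shape[0], batch_size):
        feats = model.features(x[i : i + batch_size])
        out.append(model.head(feats, rng=rng, dropout_active=True))
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# persistence: parameters in .npz, config + training log in a text sidecar

def save_model(model: SaccadeNet, path) -> Path:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    sidecar = {
        "architecture": asdict(model.cfg),
        "dtype": np.dtype(model.dtype).name,
        "trained": model.trained,
        "training_log": model.training_log,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_model(path) -> SaccadeNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ArchitectureConfig(**sidecar["architecture"])
    model = SaccadeNet(cfg, dtype=np.dtype(sidecar["dtype"]).type)
    with np.load(path.with_suffix(".npz")) as npz:
        model.params = {k: npz[k] for k in npz.files}
    model.trained = sidecar["trained"]
    model.training_log = sidecar["training_log"]
    return model
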