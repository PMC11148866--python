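"""Parallel stacked 2D CNN for ictal/interictal window classification.

The classifier consumes N x 1024 windows (N channels, 4 s at 256 Hz) and
runs two parallel convolutional branches that differ only in kernel length
(1 x 3 and 1 x 5).  Each branch stacks three blocks of
[convolution -> batch norm -> ReLU -> max-pool(3)] with 32, 64 and 128
filters and temporal strides 2, 2, 1.  Kernels span a single electrode row,
so channels are mixed only by the global average pooling and dense head:
branch outputs are concatenated on the feature axis, globally average-pooled
over rows and time, passed through a 64-unit ReLU layer and a 2-way softmax.
Training uses RMSprop (3e-4), cross-entropy on the two classes, and early
stopping on validation loss with best-weight restore.

The network is implemented directly in NumPy (see ``_nnlayers``): forward,
backprop and the optimizer are all explicit, which keeps inference and
training deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._nnlayers import (
    BatchNorm, Conv1D, Dense, GlobalAvgPool, MaxPool1D, ReLU, RMSProp,
    softmax,
)
from .errors import MonoseizeError
from .preprocess import BalancedBatchStream, BatchPlan, SegmentSet

__all__ = [
    "ModelConfig", "ParallelCNN", "TrainedModel",
    "build_model", "train_model", "predict_proba",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters."""

    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel_lengths: tuple[int, int] = (3, 5)    # the two parallel branches
    conv_strides: tuple[int, int, int] = (2, 2, 1)
    pool_size: int = 3
    dense_units: int = 64
    learning_rate: float = 3e-4
    loss: str = "binary_crossentropy"
    optimizer: str = "rmsprop"
    early_stop_patience: int = 15
    max_epochs: int = 100
    batch_size: int = 32
    epoch_batches: int = 50
    input_samples: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.conv_filters
        if len(f) != 3 or not (f[0] < f[1] < f[2]):
            raise MonoseizeError("conv_filters must be a strictly increasing triple")
        if len(self.conv_strides) != 3:
            raise MonoseizeError("conv_strides must have length 3")
        if self.early_stop_patience < 1:
            raise MonoseizeError("early_stop_patience must be >= 1")
        if self.max_epochs < 1:
            raise MonoseizeError("max_epochs must be >= 1")


class ParallelCNN:
    """The two-branch convolutional classifier (see module docstring)."""

    def __init__(self, cfg: ModelConfig, n_channels: int) -> None:
        if n_channels < 1:
            raise MonoseizeError("n_channels must be >= 1")
        self.cfg = cfg
        self.n_channels = n_channels
        rng = np.random.default_rng(cfg.seed)
        self.branches: dict[int, list] = {}
        for k in cfg.kernel_lengths:
            layers, c_in = [], 1
            for c_out, stride in zip(cfg.conv_filters, cfg.conv_strides):
                layers += [
                    Conv1D(k, c_in, c_out, stride, rng),
                    BatchNorm(c_out),
                    ReLU(),
                    MaxPool1D(cfg.pool_size),
                ]
                c_in = c_out
            self.branches[k] = layers
        feat = cfg.conv_filters[-1] * len(cfg.kernel_lengths)
        self.head = [
            GlobalAvgPool(),
            Dense(feat, cfg.dense_units, rng),
            ReLU(),
            Dense(cfg.dense_units, 2, rng),
        ]

    # -- plumbing ----------------------------------------------------------
    @property
    def layers(self) -> list:
        out = []
        for k in self.cfg.kernel_lengths:
            out.extend(self.branches[k])
        out.extend(self.head)
        return out

    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())

    def temporal_trace(self, input_samples: int | None = None) -> dict[int, list[int]]:
        """Per-branch temporal lengths after every conv/pool layer, measured
        by running a dummy forward pass."""
        t = input_samples or self.cfg.input_samples
        x = np.zeros((1, self.n_channels, t, 1), dtype=np.float32)
        trace: dict[int, list[int]] = {}
        for k in self.cfg.kernel_lengths:
            h, lens = x, []
            for layer in self.branches[k]:
                h = layer.forward(h, train=False)
                if isinstance(layer, (Conv1D, MaxPool1D)):
                    lens.append(h.shape[2])
            trace[k] = lens
        return trace

    # -- forward / backward ------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != self.n_channels:
            raise MonoseizeError(
                f"expected windows of shape (M, {self.n_channels}, T), got {x.shape}"
            )
        h = x[:, :, :, None]
        outs = []
        for k in self.cfg.kernel_lengths:
            b = h
            for layer in self.branches[k]:
                b = layer.forward(b, train)
            outs.append(b)
        z = np.concatenate(outs, axis=-1)
        self._branch_feat = [o.shape[-1] for o in outs]
        for layer in self.head:
            z = layer.forward(z, train)
        return z  # logits (M, 2)

    def _backward(self, glogits: np.ndarray) -> None:
        g = glogits
        for layer in reversed(self.head):
            g = layer.backward(g)
        splits = np.cumsum(self._branch_feat)[:-1]
        parts = np.split(g, splits, axis=-1)
        for k, gk in zip(self.cfg.kernel_lengths, parts):
            for layer in reversed(self.branches[k]):
                gk = layer.backward(gk)

    def train_step(self, x: np.ndarray, y: np.ndarray,
                   opt: RMSProp) -> tuple[float, float]:
        logits = self._forward(x, train=True)
        probs = softmax(logits)
        m = len(y)
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(m), y] + eps).mean())
        if not np.isfinite(loss):
            raise MonoseizeError("non-finite training loss")
        onehot = np.zeros_like(probs)
        onehot[np.arange(m), y] = 1.0
        self._backward((probs - onehot) / m)
        opt.step(self.layers)
        acc = float((probs[:, 1] >= 0.5).astype(int).__eq__(y).mean())
        return loss, acc

    def predict(self, windows: np.ndarray, batch: int = 256) -> np.ndarray:
        """Softmax probabilities (M, 2) in inference mode."""
        windows = np.asarray(windows, dtype=np.float32)
        out = []
        for i in range(0, len(windows), batch):
            logits = self._forward(windows[i:i + batch], train=False)
            out.append(softmax(logits))
        return np.concatenate(out) if out else np.empty((0, 2))

    def evaluate(self, segs: SegmentSet) -> tuple[float, float]:
        probs = self.predict(segs.windows)
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(len(segs)), segs.labels] + eps).mean())
        acc = float(((probs[:, 1] >= 0.5).astype(int) == segs.labels).mean())
        return loss, acc

    # -- state -------------------------------------------------------------
    def snapshot(self) -> list:
        state = []
        for layer in self.layers:
            entry = {n: p.copy() for n, p in layer.params.items()}
            if isinstance(layer, BatchNorm):
                entry["_rm"] = layer.running_mean.copy()
                entry["_rv"] = layer.running_var.copy()
            state.append(entry)
        return state

    def restore(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            for n in layer.params:
                layer.params[n][...] = entry[n]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = entry["_rm"]
                layer.running_var[...] = entry["_rv"]


@dataclass
class TrainedModel:
    """A trained classifier plus its training history."""

    model: ParallelCNN
    history: pd.DataFrame
    n_channels: int
    input_samples: int = 1024

    def export_history(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)


def build_model(cfg: ModelConfig, n_channels: int) -> ParallelCNN:
    """Construct the untrained two-branch CNN for ``n_channels`` rows."""
    return ParallelCNN(cfg, n_channels)


def train_model(
    model: ParallelCNN,
    train: SegmentSet,
    val: SegmentSet,
    cfg: ModelConfig,
    _val_loss_hook: Callable[[int], float] | None = None,
) -> TrainedModel:
    """Train with balanced batches and early stopping on validation loss.

    Stops when validation loss has not improved for ``early_stop_patience``
    epochs (or at ``max_epochs``) and restores the best-validation weights.
    ``_val_loss_hook`` optionally replaces the monitored quantity (testing
    scaffold for the stopping rule).
    """
    for name, part in (("train", train), ("val", val)):
        if part.n_ictal == 0 or part.n_interictal == 0:
            raise MonoseizeError(f"{name} set must contain both classes")
    stream = BalancedBatchStream(
        train, BatchPlan(cfg.batch_size, cfg.seed, cfg.epoch_batches)
    )
    opt = RMSProp(cfg.learning_rate)
    rows = []
    best_loss, best_state, best_epoch = np.inf, None, -1
    for epoch in range(cfg.max_epochs):
        losses, accs = [], []
        for x, y in stream.epoch(epoch):
            loss, acc = model.train_step(x, y, opt)
            losses.append(loss)
            accs.append(acc)
        val_loss, val_acc = model.evaluate(val)
        monitored = _val_loss_hook(epoch) if _val_loss_hook else val_loss
        rows.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "train_acc": float(np.mean(accs)),
            "val_acc": val_acc,
        })
        if monitored < best_loss:
            best_loss, best_state, best_epoch = monitored, model.snapshot(), epoch
        elif epoch - best_epoch >= cfg.early_stop_patience:
            break
    if best_state is not None:
        model.restore(best_state)
    history = pd.DataFrame(rows)
    return TrainedModel(
        model=model,
        history=history,
        n_channels=model.n_channels,
        input_samples=cfg.input_samples,
    )


def predict_proba(model: TrainedModel | ParallelCNN, windows: np.ndarray) -> np.ndarray:
    """Ictal probability per window; windows shaped (M, N, input_samples).

    The decision rule downstream is ictal iff probability >= 0.5.
    """
    net = model.model if isinstance(model, TrainedModel) else model
    windows = np.asarray(windows, dtype=np.float32)
    if windows.ndim != 3:
        raise MonoseizeError("windows must be (M, N, W)")
    if windows.shape[1] != net.n_channels:
        raise MonoseizeError(
            f"model expects {net.n_channels} channels, got {windows.shape[1]}"
        )
    if windows.shape[2] != net.cfg.input_samples:
        raise MonoseizeError(
            f"model expects {net.cfg.input_samples} samples, got {windows.shape[2]}"
        )
    return net.predict(windows)[:, 1]


# ---------------------------------------------------------------------------
# Checkpoints (NumPy .npz with a JSON sidecar blob inside)
# ---------------------------------------------------------------------------

def save_model(tm: TrainedModel, path: str | Path) -> None:
    net = tm.model
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(net.layers):
        for n, p in layer.params.items():
            arrays[f"{i}:{n}"] = p
        if isinstance(layer, BatchNorm):
            arrays[f"{i}:_rm"] = layer.running_mean
            arrays[f"{i}:_rv"] = layer.running_var
    meta = {
        "config": asdict(tm.model.cfg),
        "n_channels": tm.n_channels,
        "history": tm.history.to_dict(orient="list"),
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_d = meta["config"]
    for key in ("conv_filters", "kernel_lengths", "conv_strides"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = ModelConfig(**cfg_d)
    net = ParallelCNN(cfg, meta["n_channels"])
    for i, layer in enumerate(net.layers):
        for n in layer.params:
            layer.params[n][...] = data[f"{i}:{n}"]
        if isinstance(layer, BatchNorm):
            layer.running_mean[...] = data[f"{i}:_rm"]
            layer.running_var[...] = data[f"{i}:_rv"]
    return TrainedModel(
        model=net,
        history=pd.DataFrame(meta["history"]),
        n_channels=meta["n_channels"],
        input_samples=cfg.input_samples,
    )
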