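"""1D VGG16 activity classifier with a global-average-pooling head.

The network is the standard VGG16 convolutional plan transposed to one
dimension — 13 kernel-3, stride-1 convolutions in five blocks
(64,64 | 128,128 | 256,256,256 | 512,512,512 | 512,512,512), each block
followed by size-2 max pooling — with the fully-connected stack replaced
by global average pooling and a single linear classification layer, so
the head stays shallow and independent of temporal length.  A ``tiny``
scale divides every channel width by 8 for desk-scale experiments.

With ``padding='none'`` every convolution shortens the sequence by
(kernel-1) samples and every pooling halves it (floor); construction
fails fast with the offending layer named if the temporal length hits
zero.  ``padding='same'`` keeps convolutions length-preserving, which
short windows need to survive five blocks.

Implemented directly on numpy (see :mod:`freqhar._nn`): forward/backward
passes are explicit, the optimiser is Adam, and a fixed seed gives
bitwise-reproducible training on a given machine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .dataio import stack_windows
from .spectral import Window

__all__ = [
    "VGG_CONV_PLAN",
    "ModelConfig",
    "TrainConfig",
    "ActivityClassifier",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]

# 13-layer VGG16 convolutional plan, grouped into the five pooled blocks.
VGG_CONV_PLAN: tuple[tuple[int, ...], ...] = (
    (64, 64),
    (128, 128),
    (256, 256, 256),
    (512, 512, 512),
    (512, 512, 512),
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the 1D VGG classifier."""

    n_classes: int
    in_axes: int = 3
    kernel: int = 3
    stride: int = 1
    padding: str = "none"  # 'none' (valid) or 'same'
    pool: int = 2
    conv_plan: tuple[tuple[int, ...], ...] = VGG_CONV_PLAN
    batch_norm: bool = False
    scale: str = "full"  # 'full' or 'tiny' (channel widths / 8)

    def __post_init__(self) -> None:
        if self.padding not in ("none", "valid", "same"):
            raise ValueError(f"padding must be 'none' or 'same', got {self.padding!r}")
        if self.scale not in ("full", "tiny"):
            raise ValueError(f"scale must be 'full' or 'tiny', got {self.scale!r}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    @property
    def channels(self) -> tuple[tuple[int, ...], ...]:
        if self.scale == "tiny":
            return tuple(
                tuple(max(1, c // 8) for c in block) for block in self.conv_plan
            )
        return self.conv_plan

    @property
    def conv_padding(self) -> str:
        return "same" if self.padding == "same" else "valid"


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters; defaults follow common VGG practice."""

    batch_size: int = 256
    learning_rate: float = 0.001
    epochs: int = 200
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    select: str = "final"  # 'final' or 'best_valid'

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("batch size, epochs and learning rate must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.select not in ("final", "best_valid"):
            raise ValueError(f"select must be 'final' or 'best_valid'")


class ActivityClassifier:
    """A built (possibly trained) network bound to one window length."""

    def __init__(self, cfg: ModelConfig, input_length: int, seed: int = 0):
        self.cfg = cfg
        self.input_length = input_length
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = []
        length = input_length
        in_ch = cfg.in_axes
        for b, block in enumerate(cfg.channels, start=1):
            for i, out_ch in enumerate(block, start=1):
                conv = _nn.Conv1d(in_ch, out_ch, cfg.kernel, cfg.conv_padding, rng)
                length = conv.out_length(length)
                if length <= 0:
                    raise ValueError(
                        f"temporal length exhausted at block {b}, conv {i} "
                        f"(input length {input_length}, padding "
                        f"{cfg.padding!r}); use padding='same' for short windows"
                    )
                layers.append(conv)
                if cfg.batch_norm:
                    layers.append(_nn.BatchNorm1d(out_ch))
                layers.append(_nn.ReLU())
                in_ch = out_ch
            pool = _nn.MaxPool1d(cfg.pool)
            length = pool.out_length(length)
            if length <= 0:
                raise ValueError(
                    f"temporal length exhausted at block {b} pooling "
                    f"(input length {input_length}, padding {cfg.padding!r})"
                )
            layers.append(pool)
        self.pre_gap_length = length
        layers.append(_nn.GlobalAvgPool1d())
        self.head = _nn.Dense(in_ch, cfg.n_classes, rng)
        layers.append(self.head)
        self.net = _nn.Sequential(layers)

    def logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (self.cfg.in_axes, self.input_length):
            raise ValueError(
                f"expected input of shape (N, {self.cfg.in_axes}, "
                f"{self.input_length}), got {X.shape}"
            )
        return self.net.forward(X, train=train)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        out = [
            _nn.softmax(self.logits(X[i : i + batch_size]))
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(out)

    def state(self) -> list[np.ndarray]:
        arrays = [p.copy() for p, _ in self.net.parameters()]
        for layer in self.net.layers:
            if isinstance(layer, _nn.BatchNorm1d):
                arrays.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return arrays

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        arrays = list(arrays)
        pg = self.net.parameters()
        for (p, _), a in zip(pg, arrays[: len(pg)]):
            p[...] = a
        rest = arrays[len(pg) :]
        i = 0
        for layer in self.net.layers:
            if isinstance(layer, _nn.BatchNorm1d):
                layer.running_mean[...] = rest[i]
                layer.running_var[...] = rest[i + 1]
                i += 2


def build_model(
    cfg: ModelConfig, input_length: int, seed: int = 0
) -> ActivityClassifier:
    """Instantiate the classifier, validating the length arithmetic."""
    return ActivityClassifier(cfg, input_length, seed=seed)


def train(
    model: ActivityClassifier,
    windows: Sequence[Window] | tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    class_set: Sequence[str] | None = None,
    valid_windows: Sequence[Window] | tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[ActivityClassifier, pd.DataFrame]:
    """Train in place; returns the model and a per-epoch metrics log.

    ``windows`` is either a list of :class:`Window` (then ``class_set``
    maps labels to class indices) or a pre-stacked ``(X, y)`` pair.
    With ``epochs=0`` the initialised model is returned unchanged.
    """
    X, y = _as_arrays(windows, class_set)
    if y.max(initial=0) >= model.cfg.n_classes:
        raise ValueError(
            f"label index {y.max()} out of range for {model.cfg.n_classes} classes"
        )
    valid = _as_arrays(valid_windows, class_set) if valid_windows is not None else None

    rng = np.random.default_rng(cfg.seed)
    optimizer = _nn.Adam(model.net.parameters(), lr=cfg.learning_rate)
    rows = []
    best: tuple[float, list[np.ndarray]] | None = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.logits(X[idx], train=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, batch starting "
                    f"{start}: lr={cfg.learning_rate}, batch={len(idx)}"
                )
            model.net.backward(dlogits)
            optimizer.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        row = {
            "epoch": epoch + 1,
            "loss": sum(losses) / len(X),
            "train_acc": correct / len(X),
        }
        if valid is not None:
            va = float(
                (model.predict_proba(valid[0]).argmax(axis=1) == valid[1]).mean()
            )
            row["valid_acc"] = va
            if cfg.select == "best_valid" and (best is None or va >= best[0]):
                best = (va, model.state())
        rows.append(row)
    if cfg.select == "best_valid" and best is not None:
        model.load_state(best[1])
    return model, pd.DataFrame(rows)


def predict(
    model: ActivityClassifier,
    windows: Sequence[Window] | np.ndarray,
    class_set: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-probability scores and argmax labels for a batch of windows.

    Returns ``(probs, labels)`` where ``probs`` rows sum to 1 and
    ``labels`` are integer class indices (or strings when ``class_set``
    is given).
    """
    if isinstance(windows, np.ndarray):
        X = windows
    else:
        X = np.stack([w.values for w in windows])
    probs = model.predict_proba(X)
    idx = probs.argmax(axis=1)
    if class_set is not None:
        return probs, np.asarray(class_set, dtype=object)[idx]
    return probs, idx


def _as_arrays(
    data: Sequence[Window] | tuple[np.ndarray, np.ndarray],
    class_set: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple) and len(data) == 2 and isinstance(data[0], np.ndarray):
        return np.asarray(data[0], dtype=float), np.asarray(data[1], dtype=int)
    if class_set is None:
        raise ValueError("class_set is required when passing Window lists")
    return stack_windows(data, class_set)  # type: ignore[arg-type]


def save_model(model: ActivityClassifier, path: str | Path) -> None:
    """Persist weights plus enough config to rebuild the network."""
    cfg = model.cfg
    meta = dict(
        n_classes=cfg.n_classes, in_axes=cfg.in_axes, kernel=cfg.kernel,
        padding=cfg.padding, pool=cfg.pool, batch_norm=int(cfg.batch_norm),
        scale=cfg.scale, input_length=model.input_length, seed=model.seed,
    )
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state())}
    np.savez(path, _meta=np.array([repr(meta)]), **arrays)


def load_model(path: str | Path) -> ActivityClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = eval(str(data["_meta"][0]), {"__builtins__": {}})  # trusted file
        cfg = ModelConfig(
            n_classes=meta["n_classes"], in_axes=meta["in_axes"],
            kernel=meta["kernel"], padding=meta["padding"], pool=meta["pool"],
            batch_norm=bool(meta["batch_norm"]), scale=meta["scale"],
        )
        model = ActivityClassifier(cfg, meta["input_length"], seed=meta["seed"])
        n = len([k for k in data.files if k.startswith("arr_")])
        model.load_state([data[f"arr_{i}"] for i in range(n)])
    return model
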