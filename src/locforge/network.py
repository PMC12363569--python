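"""The hybrid multi-label localization network and its training loop.

Two branches encode a protein: a CNN branch over the similarity-organized
descriptor image (two 3x3 stride-2 valid convolutions, each followed by a
2x2 stride-2 max pool, then two FC layers) and an FC branch over the
pooled global embedding (two FC layers).  ReLU activates all CNN/FC
layers.  The two branch embeddings are concatenated into a fused vector,
zero-padded to a multiple of the token count and reshaped into a short
token sequence, refined by a two-layer bidirectional LSTM whose output
passes through a tanh, and finally mapped by a linear head to per-label
sigmoid scores.

Training minimizes focal loss (down-weighting easy examples to counter
the heavy class imbalance of localization corpora) with Adam, batch
size 32 and learning rate 2e-4 by default, monitoring a validation
metric each epoch with early stopping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluation import confusion_from_decisions, decide_matrix, f1_score
from .nn import Adam, BiLSTM, Conv2d, Linear, MaxPool2d, Module, Tensor, concat

__all__ = [
    "ModelSpec",
    "FocalLossConfig",
    "TrainConfig",
    "ArrayDataset",
    "propagate_shapes",
    "focal_loss",
    "LocalizationNet",
    "train",
    "save_model",
    "load_model",
]

_EPS = 1e-7


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters (defaults follow the published constants)."""

    image_dims: tuple[int, int]
    embedding_dim: int
    n_labels: int
    cnn_channels: tuple[int, int] = (16, 32)
    conv_kernel: int = 3
    conv_stride: int = 2
    pool_size: int = 2
    pool_stride: int = 2
    cnn_fc: tuple[int, int] = (512, 256)
    emb_fc: tuple[int, int] = (512, 256)
    bilstm_hidden: int = 256
    bilstm_layers: int = 2
    n_tokens: int = 16

    def __post_init__(self) -> None:
        if self.n_labels < 1:
            raise ValueError("need at least one label")
        if self.n_tokens < 1:
            raise ValueError("n_tokens must be positive")

    @property
    def fusion_dim(self) -> int:
        return self.cnn_fc[-1] + self.emb_fc[-1]

    @property
    def token_dim(self) -> int:
        return math.ceil(self.fusion_dim / self.n_tokens)


def propagate_shapes(spec: ModelSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Layer-by-layer output shapes under valid (unpadded) arithmetic.

    Convolution: ``floor((n - k) / s) + 1``; pooling: ``floor((n - p) / s) + 1``.
    Raises naming the first layer whose output dimension is nonpositive.
    """
    h, w = spec.image_dims
    shapes: list[tuple[str, tuple[int, ...]]] = [("input", (1, h, w))]

    def shrink(n: int, k: int, s: int) -> int:
        return (n - k) // s + 1

    dims = (h, w)
    for i, channels in enumerate(spec.cnn_channels, start=1):
        dims = tuple(shrink(n, spec.conv_kernel, spec.conv_stride) for n in dims)
        if min(dims) < 1:
            raise ValueError(f"layer conv_{i}: output shape {dims} is degenerate")
        shapes.append((f"conv_{i}", (channels, *dims)))
        dims = tuple(shrink(n, spec.pool_size, spec.pool_stride) for n in dims)
        if min(dims) < 1:
            raise ValueError(f"layer max_pool_{i}: output shape {dims} is degenerate")
        shapes.append((f"max_pool_{i}", (channels, *dims)))
    flat = spec.cnn_channels[-1] * dims[0] * dims[1]
    shapes.append(("cnn_flatten", (flat,)))
    for i, width in enumerate(spec.cnn_fc, start=1):
        shapes.append((f"cnn_fc_{i}", (width,)))
    for i, width in enumerate(spec.emb_fc, start=1):
        shapes.append((f"emb_fc_{i}", (width,)))
    shapes.append(("fusion", (spec.fusion_dim,)))
    shapes.append(("tokens", (spec.n_tokens, spec.token_dim)))
    shapes.append(("bilstm", (2 * spec.bilstm_hidden,)))
    shapes.append(("head", (spec.n_labels,)))
    return shapes


@dataclass(frozen=True)
class FocalLossConfig:
    """Focal loss parameters; alpha=0.25, gamma=2 are the classical defaults."""

    alpha: float = 0.25
    gamma: float = 2.0
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def focal_loss(
    probabilities: np.ndarray,
    targets: np.ndarray,
    config: FocalLossConfig = FocalLossConfig(),
) -> float:
    """Focal loss ``-alpha * (1 - p_t)^gamma * log(p_t)`` on probabilities.

    ``p_t`` is the probability assigned to the true class; probabilities
    are clamped to ``[1e-7, 1 - 1e-7]``.  With gamma=0 and alpha=1 this is
    exactly binary cross-entropy.
    """
    p = np.clip(np.asarray(probabilities, dtype=float), _EPS, 1 - _EPS)
    y = np.asarray(targets, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and targets must be aligned")
    p_t = p * y + (1 - p) * (1 - y)
    fl = -config.alpha * (1 - p_t) ** config.gamma * np.log(p_t)
    return float(fl.mean() if config.reduction == "mean" else fl.sum())


def _focal_loss_graph(probs: Tensor, targets: np.ndarray, config: FocalLossConfig) -> Tensor:
    y = np.asarray(targets, dtype=float)
    p = probs.clip(_EPS, 1 - _EPS)
    p_t = p * y + (1.0 - p) * (1.0 - y)
    fl = (1.0 - p_t) ** config.gamma * p_t.log() * (-config.alpha)
    return fl.mean() if config.reduction == "mean" else fl.sum()


class LocalizationNet(Module):
    """Dual-branch CNN + FC network fused through a BiLSTM multi-label head."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        shapes = propagate_shapes(spec)  # validates the spec
        flat = dict(shapes)["cnn_flatten"][0]
        rng = np.random.default_rng(seed)
        self.spec = spec
        c1, c2 = spec.cnn_channels
        self.conv1 = Conv2d(1, c1, spec.conv_kernel, spec.conv_stride, rng)
        self.conv2 = Conv2d(c1, c2, spec.conv_kernel, spec.conv_stride, rng)
        self.pool = MaxPool2d(spec.pool_size, spec.pool_stride)
        self.cnn_fc1 = Linear(flat, spec.cnn_fc[0], rng)
        self.cnn_fc2 = Linear(spec.cnn_fc[0], spec.cnn_fc[1], rng)
        self.emb_fc1 = Linear(spec.embedding_dim, spec.emb_fc[0], rng)
        self.emb_fc2 = Linear(spec.emb_fc[0], spec.emb_fc[1], rng)
        self.bilstm = BiLSTM(spec.token_dim, spec.bilstm_hidden, spec.bilstm_layers, rng)
        self.head = Linear(2 * spec.bilstm_hidden, spec.n_labels, rng)

    def forward(self, images: np.ndarray, embeddings: np.ndarray) -> Tensor:
        """Per-label sigmoid scores for a batch.

        ``images``: (N, H, W) or (N, 1, H, W); ``embeddings``: (N, E).
        """
        spec = self.spec
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:
            images = images[:, None, :, :]
        if images.shape[2:] != spec.image_dims:
            raise ValueError(
                f"image dims {images.shape[2:]} do not match spec {spec.image_dims}"
            )
        embeddings = np.asarray(embeddings, dtype=float)
        if embeddings.shape[1] != spec.embedding_dim:
            raise ValueError(
                f"embedding dim {embeddings.shape[1]} does not match spec "
                f"{spec.embedding_dim}"
            )
        n = images.shape[0]
        x = Tensor(images)
        x = self.pool(self.conv1(x).relu())
        x = self.pool(self.conv2(x).relu())
        x = x.reshape(n, -1)
        x = self.cnn_fc1(x).relu()
        x = self.cnn_fc2(x).relu()
        e = Tensor(embeddings)
        e = self.emb_fc1(e).relu()
        e = self.emb_fc2(e).relu()
        fused = concat([x, e], axis=1)
        pad = spec.n_tokens * spec.token_dim - spec.fusion_dim
        if pad:
            fused = concat([fused, Tensor(np.zeros((n, pad)))], axis=1)
        tokens = fused.reshape(n, spec.n_tokens, spec.token_dim)
        seq_repr = self.bilstm(tokens).tanh()
        return self.head(seq_repr).sigmoid()

    def predict(self, images: np.ndarray, embeddings: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode scores as a plain array."""
        return self.forward(images, embeddings).data


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 2e-4
    max_epochs: int = 100
    patience: int = 5
    monitor_metric: str = "macro_f1"  # or "val_loss"
    focal: FocalLossConfig = FocalLossConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.monitor_metric not in ("macro_f1", "val_loss"):
            raise ValueError("monitor_metric must be 'macro_f1' or 'val_loss'")


@dataclass
class ArrayDataset:
    """In-memory (images, embeddings, labels) arrays for one split."""

    images: np.ndarray
    embeddings: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.embeddings) == len(self.labels)):
            raise ValueError("dataset arrays misaligned")

    def __len__(self) -> int:
        return len(self.labels)


def _macro_f1(scores: np.ndarray, truth: np.ndarray) -> float:
    decided = decide_matrix(scores, 0.5)
    counts = confusion_from_decisions(decided, truth.astype(bool))
    return float(np.mean([f1_score(c) for c in counts]))


def train(
    model_spec: ModelSpec,
    train_set: ArrayDataset,
    val_set: ArrayDataset,
    config: TrainConfig = TrainConfig(),
) -> tuple[LocalizationNet, list[dict]]:
    """Mini-batch focal-loss training with early stopping.

    After every epoch the monitor metric is computed on the validation
    set; training stops once ``patience`` epochs pass without improvement
    and the best epoch's weights are restored.  All randomness
    (initialization, shuffling) flows from ``config.seed``.  Returns the
    trained model and a per-epoch history of train loss and monitor value.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    if train_set.labels.shape[1] != val_set.labels.shape[1]:
        raise ValueError("train/val label spaces differ")
    model = LocalizationNet(model_spec, seed=config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    maximize = config.monitor_metric == "macro_f1"
    best_value = -np.inf if maximize else np.inf
    best_epoch = 0
    best_state = model.state_arrays()
    history: list[dict] = []

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            probs = model.forward(train_set.images[idx], train_set.embeddings[idx])
            loss = _focal_loss_graph(probs, train_set.labels[idx], config.focal)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item()
            n_batches += 1
        val_scores = model.predict(val_set.images, val_set.embeddings)
        if config.monitor_metric == "macro_f1":
            monitor = _macro_f1(val_scores, val_set.labels)
        else:
            monitor = focal_loss(val_scores, val_set.labels, config.focal)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n_batches,
                config.monitor_metric: monitor,
            }
        )
        improved = monitor > best_value if maximize else monitor < best_value
        if improved:
            best_value = monitor
            best_epoch = epoch
            best_state = model.state_arrays()
        elif epoch - best_epoch >= config.patience:
            break
    model.load_state_arrays(best_state)
    return model, history


def save_model(model: LocalizationNet, out_dir: str | Path) -> None:
    """Persist architecture (JSON) and weights (NPZ) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec_dict = asdict(model.spec)
    (out / "architecture.json").write_text(json.dumps(spec_dict, indent=1))
    np.savez(out / "weights.npz", *[p.data for p in model.parameters()])


def load_model(model_dir: str | Path) -> LocalizationNet:
    path = Path(model_dir)
    raw = json.loads((path / "architecture.json").read_text())
    for key in ("image_dims", "cnn_channels", "cnn_fc", "emb_fc"):
        raw[key] = tuple(raw[key])
    model = LocalizationNet(ModelSpec(**raw))
    with np.load(path / "weights.npz") as npz:
        model.load_state_arrays([npz[k] for k in npz.files])
    return model
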