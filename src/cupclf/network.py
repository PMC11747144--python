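"""The feed-forward organ-of-origin classifier.

Architecture: fully connected layers (default 20000 -> 1024 -> 512 -> 6)
with ReLU activations and 0.5 dropout after each hidden layer, a softmax
over the six organ classes, cross-entropy loss, Adam, mini-batches of 16
for 50 epochs. The model is small enough that a compact NumPy
implementation trains in seconds at desk scale; every stochastic element
(weight init, shuffling, dropout) draws from one seeded generator, so runs
are bit-reproducible on the same platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    CLASSES,
    PredictionReport,
    TrainedClassifier,
    ValidationError,
)


@dataclass
class NetworkConfig:
    layer_dims: tuple[int, ...] = (20000, 1024, 512, 6)
    dropout_rate: float = 0.5
    batch_size: int = 16
    epochs: int = 50
    learning_rate: float = 1e-3
    seed: int = 0
    class_weighting: str = "none"  # "none" | "inverse-frequency"
    #: keep the weights from the epoch with the lowest validation loss
    #: instead of the final epoch (off by default: fixed-epoch training).
    checkpoint_best: bool = False

    def __post_init__(self) -> None:
        if len(self.layer_dims) < 2:
            raise ValidationError("layer_dims needs at least input and output layers")
        if any(d < 1 for d in self.layer_dims):
            raise ValidationError("layer dimensions must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValidationError("batch_size, epochs and learning_rate must be positive")
        if self.class_weighting not in {"none", "inverse-frequency"}:
            raise ValidationError(f"unknown class_weighting {self.class_weighting!r}")


@dataclass
class ClassifierSpec:
    """Shape of the network before training."""

    layer_dims: tuple[int, ...]
    dropout_rate: float

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims) - 1

    @property
    def parameter_count(self) -> int:
        # each fully connected layer has (in + 1 bias) * out parameters
        return sum(
            (self.layer_dims[i] + 1) * self.layer_dims[i + 1]
            for i in range(self.n_layers)
        )


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_acc": self.train_acc,
                "val_acc": self.val_acc,
            }
        )


def build_network(cfg: NetworkConfig) -> ClassifierSpec:
    """Validate the configuration and return the network shape."""
    return ClassifierSpec(tuple(cfg.layer_dims), cfg.dropout_rate)


def _init_weights(
    dims: Sequence[int], rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    # He-style uniform fan-in scaling, suited to the ReLU stack
    weights = []
    for i in range(len(dims) - 1):
        limit = np.sqrt(6.0 / dims[i])
        w = rng.uniform(-limit, limit, size=(dims[i], dims[i + 1]))
        b = np.zeros(dims[i + 1])
        weights.append((w, b))
    return weights


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    weights: Sequence[tuple[np.ndarray, np.ndarray]], x: np.ndarray
) -> np.ndarray:
    """Inference-mode forward pass (dropout disabled): class probabilities."""
    h = x
    last = len(weights) - 1
    for i, (w, b) in enumerate(weights):
        h = h @ w + b
        if i < last:
            h = np.maximum(h, 0.0)
    return _softmax(h)


def _eval_loss_acc(weights, x, y_idx, class_weights) -> tuple[float, float]:
    p = forward(weights, x)
    eps = 1e-12
    ce = -np.log(np.clip(p[np.arange(len(y_idx)), y_idx], eps, None))
    w = class_weights[y_idx]
    loss = float((w * ce).sum() / w.sum())
    acc = float((p.argmax(axis=1) == y_idx).mean())
    return loss, acc


def train_network(
    spec: ClassifierSpec,
    x: np.ndarray,
    y: Sequence[str],
    cfg: NetworkConfig,
    x_val: np.ndarray | None = None,
    y_val: Sequence[str] | None = None,
    class_order: Sequence[str] = CLASSES,
    selected_probes: Sequence[str] | None = None,
    preprocessing_state: dict | None = None,
) -> tuple[TrainedClassifier, TrainingHistory]:
    """Train by mini-batch cross-entropy with Adam.

    ``x`` is samples x features and must match the spec's input width;
    ``y`` holds labels from ``class_order``. Per-epoch losses/accuracies are
    measured in evaluation mode (dropout off) on the full training set and,
    when supplied, the validation set. The returned model carries float32
    weights so that persistence is bit-stable.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != spec.layer_dims[0]:
        raise ValidationError(
            f"X has {x.shape[1] if x.ndim == 2 else '?'} features but the input "
            f"layer expects {spec.layer_dims[0]}"
        )
    if np.isnan(x).any():
        raise ValidationError("training matrix contains missing values; impute upstream")
    class_order = list(class_order)
    idx_of = {c: i for i, c in enumerate(class_order)}
    try:
        y_idx = np.array([idx_of[l] for l in y], dtype=np.intp)
    except KeyError as e:
        raise ValidationError(f"label {e.args[0]!r} not in class_order") from None
    if len(y_idx) != x.shape[0]:
        raise ValidationError("X and y length mismatch")
    n_classes = spec.layer_dims[-1]
    if len(class_order) != n_classes:
        raise ValidationError("class_order length does not match the output layer")

    counts = np.bincount(y_idx, minlength=n_classes).astype(float)
    if cfg.class_weighting == "inverse-frequency":
        if (counts == 0).any():
            absent = [class_order[i] for i in np.flatnonzero(counts == 0)]
            raise ValidationError(
                f"inverse-frequency weighting with classes absent from y: {absent}"
            )
        class_weights = counts.sum() / (n_classes * counts)
    else:
        class_weights = np.ones(n_classes)

    yv_idx = None
    if x_val is not None and y_val is not None:
        x_val = np.asarray(x_val, dtype=np.float64)
        yv_idx = np.array([idx_of[l] for l in y_val], dtype=np.intp)

    rng = np.random.default_rng(cfg.seed)
    weights = _init_weights(spec.layer_dims, rng)
    # Adam state
    m_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    v_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0

    n = x.shape[0]
    keep_p = 1.0 - cfg.dropout_rate
    history = TrainingHistory()
    best = (np.inf, None)

    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = x[batch], y_idx[batch]
            # forward with inverted dropout on hidden activations
            acts = [xb]
            masks = []
            h = xb
            last = len(weights) - 1
            for li, (w, b) in enumerate(weights):
                z = h @ w + b
                if li < last:
                    h = np.maximum(z, 0.0)
                    if keep_p < 1.0:
                        mask = (rng.random(h.shape) < keep_p) / keep_p
                        h = h * mask
                    else:
                        mask = None
                    masks.append(mask)
                    acts.append(h)
                else:
                    h = z
            p = _softmax(h)
            wvec = class_weights[yb]
            wsum = wvec.sum()
            # d(weighted CE)/dz at the softmax input
            grad = p * wvec[:, None]
            grad[np.arange(len(yb)), yb] -= wvec
            grad /= wsum
            # backprop
            grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(weights)
            for li in range(last, -1, -1):
                w, b = weights[li]
                grads[li] = (acts[li].T @ grad, grad.sum(axis=0))
                if li > 0:
                    grad = grad @ w.T
                    if masks[li - 1] is not None:
                        grad = grad * masks[li - 1]
                    grad = grad * (acts[li] > 0)
            # Adam update
            step += 1
            corr1 = 1.0 - beta1 ** step
            corr2 = 1.0 - beta2 ** step
            for li, (w, b) in enumerate(weights):
                gw, gb = grads[li]
                mw, mb = m_state[li]
                vw, vb = v_state[li]
                mw = beta1 * mw + (1 - beta1) * gw
                mb = beta1 * mb + (1 - beta1) * gb
                vw = beta2 * vw + (1 - beta2) * gw * gw
                vb = beta2 * vb + (1 - beta2) * gb * gb
                m_state[li], v_state[li] = (mw, mb), (vw, vb)
                w = w - cfg.learning_rate * (mw / corr1) / (np.sqrt(vw / corr2) + adam_eps)
                b = b - cfg.learning_rate * (mb / corr1) / (np.sqrt(vb / corr2) + adam_eps)
                weights[li] = (w, b)

        tl, ta = _eval_loss_acc(weights, x, y_idx, class_weights)
        history.train_loss.append(tl)
        history.train_acc.append(ta)
        if yv_idx is not None:
            vl, va = _eval_loss_acc(weights, x_val, yv_idx, class_weights)
            history.val_loss.append(vl)
            history.val_acc.append(va)
            if cfg.checkpoint_best and vl < best[0]:
                best = (vl, [(w.copy(), b.copy()) for w, b in weights])
        else:
            history.val_loss.append(float("nan"))
            history.val_acc.append(float("nan"))

    if cfg.checkpoint_best and best[1] is not None:
        weights = best[1]

    if selected_probes is None:
        selected_probes = [f"feature_{i}" for i in range(spec.layer_dims[0])]
    model = TrainedClassifier(
        layer_dims=list(spec.layer_dims),
        dropout_rate=cfg.dropout_rate,
        weights=[(w.astype(np.float32), b.astype(np.float32)) for w, b in weights],
        class_order=class_order,
        selected_probes=list(selected_probes),
        preprocessing_state=preprocessing_state or {},
    )
    return model, history


def _second_labels(p: np.ndarray, class_order: Sequence[str]) -> list[str]:
    # stable argsort on (-p, class index): ties resolve by class_order position
    order = np.argsort(-p, axis=1, kind="stable")
    return [class_order[order[i, 1]] for i in range(p.shape[0])]


def predict_probabilities(
    model: TrainedClassifier,
    bm: BetaMatrix,
    impute_missing_probes: bool = False,
) -> PredictionReport:
    """Class probabilities for every sample in ``bm`` (dropout disabled).

    All of ``model.selected_probes`` must be present; with
    ``impute_missing_probes`` absent probes are filled with the frozen
    training means instead of raising. Missing *values* in present probes
    are always imputed with the frozen means.
    """
    have = set(bm.probe_ids)
    missing = [p for p in model.selected_probes if p not in have]
    means = model.preprocessing_state.get("impute_means")
    if missing and not impute_missing_probes:
        shown = ", ".join(missing[:20])
        raise ValidationError(
            f"{len(missing)} model probes absent from the input matrix "
            f"(first {min(20, len(missing))}: {shown}); pass "
            f"impute_missing_probes=True to substitute training means"
        )
    if (missing or np.isnan(bm.values).any()) and means is None:
        raise ValidationError("model has no frozen imputation means")

    row_of = {p: i for i, p in enumerate(bm.probe_ids)}
    n = bm.n_samples
    x = np.empty((n, len(model.selected_probes)), dtype=np.float64)
    for k, probe in enumerate(model.selected_probes):
        if probe in row_of:
            col = bm.values[row_of[probe]]
            if np.isnan(col).any():
                col = np.where(np.isnan(col), float(means[k]), col)
            x[:, k] = col
        else:
            x[:, k] = float(means[k])

    # float32 end to end so saved/loaded models predict identically
    p = forward(
        [(w.astype(np.float32), b.astype(np.float32)) for w, b in model.weights],
        x.astype(np.float32),
    ).astype(np.float64)
    p = p / p.sum(axis=1, keepdims=True)

    pred_idx = p.argmax(axis=1)
    frame = pd.DataFrame({"sample_id": bm.sample_ids})
    for ci, c in enumerate(model.class_order):
        frame[f"p_{c}"] = p[:, ci]
    frame["predicted_label"] = [model.class_order[i] for i in pred_idx]
    frame["second_label"] = _second_labels(p, model.class_order)
    frame["confidence"] = p.max(axis=1)
    return PredictionReport(frame, list(model.class_order))
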