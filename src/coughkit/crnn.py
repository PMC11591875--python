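"""Residual convolutional-recurrent cough classifier.

Architecture: the (1, 128, 22) Mel grid passes through four residual
convolution blocks.  Each block adds a width-1 projection of its input to
the output of a 3x3 convolution, normalizes and rectifies, applies a second
3x3 convolution + normalization + rectification, then halves the frequency
axis with 2x max pooling; channel counts run 1 → 128 → 256 → 512 → 1024 at
the default width.  The remaining frequency rows are mean-pooled away,
yielding a 22-step sequence of 1024-dim features that feeds a 4-layer LSTM
(hidden 512); the final step's top-layer hidden state passes through a fully
connected layer to a single cough logit.

Class imbalance is handled by a weighted binary cross-entropy: with n_true
positive and n_false negative training segments, the positive term is scaled
by w_true = n_false / n_true, so missing a cough costs proportionally more
than a false alarm.  During training, the model parameters at three epochs
are kept: best validation accuracy, best validation sensitivity, and best
mixed score (accuracy + sensitivity), exposing the accuracy-sensitivity
trade-off rather than hiding it.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autograd import Adam, Tensor, conv2d, max_pool_axis2
from .evaluation import MetricsReport, _stratified_split, compute_metrics

PROB_CLAMP = 1e-7


# ---------------------------------------------------------------------------
# loss and class weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassWeight:
    """Positive-class loss weight derived from training-set class counts."""

    n_true: int
    n_false: int

    def __post_init__(self) -> None:
        if self.n_true <= 0 or self.n_false <= 0:
            raise ValueError("class weighting needs both classes present "
                             f"(n_true={self.n_true}, n_false={self.n_false})")

    @property
    def w_true(self) -> float:
        return self.n_false / self.n_true


def class_weight(n_true: int, n_false: int) -> ClassWeight:
    """Weight for the positive class: w_true = n_false / n_true.

    Up-weights the minority (cough) class whenever negatives dominate, so the
    optimizer cannot profitably collapse to the all-negative predictor.
    """
    return ClassWeight(n_true=n_true, n_false=n_false)


def weighted_loss(y, p, w_true: float = 1.0) -> float:
    """Class-weighted binary cross-entropy, averaged over the batch.

    L = −mean[ w_true · y · log p + (1 − y) · log(1 − p) ], with p clamped
    to [1e-7, 1 − 1e-7].  Reduces to ordinary binary cross-entropy at
    w_true = 1; the weight touches only the positive term.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(p, dtype=np.float64), PROB_CLAMP, 1.0 - PROB_CLAMP)
    return float(-np.mean(w_true * y * np.log(p) + (1.0 - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv2d:
    def __init__(self, rng, c_in, c_out, k=3, dtype=np.float64):
        std = np.sqrt(2.0 / (c_in * k * k))          # He initialization
        self.weight = Tensor((rng.standard_normal((c_out, c_in, k, k)) * std
                              ).astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)

    @property
    def params(self):
        return [self.weight, self.bias]


class _BatchNorm2d:
    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=np.float64):
        self.gamma = Tensor(np.ones((1, c, 1, 1), dtype=dtype),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), dtype=dtype),
                           requires_grad=True)
        self.running_mean = np.zeros((1, c, 1, 1), dtype=dtype)
        self.running_var = np.ones((1, c, 1, 1), dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = centered / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) \
                / Tensor(np.sqrt(self.running_var + self.eps))
        return self.gamma * xhat + self.beta

    @property
    def params(self):
        return [self.gamma, self.beta]


class _ResidualBlock:
    """Projected-skip residual convolution block with frequency pooling."""

    def __init__(self, rng, c_in, c_out, dtype=np.float64):
        self.proj = _Conv2d(rng, c_in, c_out, k=1, dtype=dtype)  # "simple layer"
        self.conv1 = _Conv2d(rng, c_in, c_out, k=3, dtype=dtype)
        self.bn1 = _BatchNorm2d(c_out, dtype=dtype)
        self.conv2 = _Conv2d(rng, c_out, c_out, k=3, dtype=dtype)
        self.bn2 = _BatchNorm2d(c_out, dtype=dtype)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = self.conv1(x) + self.proj(x)             # residual add
        h = self.bn1(h, training).relu()
        h = self.bn2(self.conv2(h), training).relu()
        return max_pool_axis2(h, 2)                  # halve frequency only

    @property
    def params(self):
        return (self.proj.params + self.conv1.params + self.bn1.params
                + self.conv2.params + self.bn2.params)


class _LSTM:
    """Stacked LSTM; gate weights stored as (input, 4*hidden) matrices."""

    def __init__(self, rng, input_size, hidden_size, num_layers,
                 dtype=np.float64):
        self.hidden = hidden_size
        self.layers = []
        for layer in range(num_layers):
            i = input_size if layer == 0 else hidden_size
            k = 1.0 / np.sqrt(hidden_size)
            w_ih = Tensor(rng.uniform(-k, k, (i, 4 * hidden_size)
                                      ).astype(dtype), requires_grad=True)
            w_hh = Tensor(rng.uniform(-k, k, (hidden_size, 4 * hidden_size)
                                      ).astype(dtype), requires_grad=True)
            b = np.zeros(4 * hidden_size, dtype=dtype)
            b[hidden_size:2 * hidden_size] = 1.0     # open forget gates
            bias = Tensor(b, requires_grad=True)
            self.layers.append((w_ih, w_hh, bias))

    def __call__(self, x: Tensor) -> list[Tensor]:
        """x: (B, T, I) → top-layer hidden states, one (B, H) per step."""
        batch, T = x.shape[0], x.shape[1]
        H = self.hidden
        inputs = [x[:, t, :] for t in range(T)]
        dtype = x.data.dtype
        for w_ih, w_hh, bias in self.layers:
            h = Tensor(np.zeros((batch, H), dtype=dtype))
            c = Tensor(np.zeros((batch, H), dtype=dtype))
            outputs = []
            for x_t in inputs:
                gates = x_t @ w_ih + h @ w_hh + bias
                i_g = gates[:, 0 * H:1 * H].sigmoid()
                f_g = gates[:, 1 * H:2 * H].sigmoid()
                g_g = gates[:, 2 * H:3 * H].tanh()
                o_g = gates[:, 3 * H:4 * H].sigmoid()
                c = f_g * c + i_g * g_g
                h = o_g * c.tanh()
                outputs.append(h)
            inputs = outputs
        return inputs

    @property
    def params(self):
        return [p for layer in self.layers for p in layer]


class _Linear:
    def __init__(self, rng, n_in, n_out, dtype=np.float64):
        k = 1.0 / np.sqrt(n_in)
        self.weight = Tensor(rng.uniform(-k, k, (n_in, n_out)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    @property
    def params(self):
        return [self.weight, self.bias]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class CRNNConfig:
    """Architecture and training hyperparameters.

    The recurrent input width is tied to the encoder: after ``n_conv_blocks``
    channel doublings from ``base_filters``, lstm_input must equal
    base_filters × 2^(n_conv_blocks − 1) (1024 at the default width).
    """

    base_filters: int = 128
    n_conv_blocks: int = 4
    lstm_layers: int = 4
    lstm_hidden: int = 512
    lstm_input: int = 1024
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    n_mels: int = 128
    n_frames: int = 22
    head: str = "last"           # "last" or "mean" over time steps
    input_db_range: float = 80.0
    dtype: str = "float32"       # parameter/activation precision

    def __post_init__(self) -> None:
        expected = self.base_filters * 2 ** (self.n_conv_blocks - 1)
        if self.lstm_input != expected:
            raise ValueError(
                f"lstm_input={self.lstm_input} inconsistent with "
                f"base_filters × 2^(n_conv_blocks−1) = {expected}"
            )
        if self.n_mels % (2 ** self.n_conv_blocks):
            raise ValueError(
                f"n_mels={self.n_mels} must be divisible by "
                f"2^{self.n_conv_blocks} for the frequency pooling"
            )
        if self.head not in ("last", "mean"):
            raise ValueError("head must be 'last' or 'mean'")


class CRNNModel:
    """The network itself: residual conv encoder → stacked LSTM → FC head."""

    def __init__(self, config: CRNNConfig):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        self.blocks = []
        c_in = 1
        for k in range(config.n_conv_blocks):
            c_out = config.base_filters * 2 ** k
            self.blocks.append(_ResidualBlock(rng, c_in, c_out,
                                              dtype=self.dtype))
            c_in = c_out
        self.lstm = _LSTM(rng, config.lstm_input, config.lstm_hidden,
                          config.lstm_layers, dtype=self.dtype)
        self.fc = _Linear(rng, config.lstm_hidden, 1, dtype=self.dtype)

    @property
    def params(self) -> list[Tensor]:
        ps = [p for b in self.blocks for p in b.params]
        return ps + self.lstm.params + self.fc.params

    def encode(self, x: Tensor, training: bool) -> Tensor:
        """(B, 1, F, T) → (B, T, channels) sequence for the recurrent block."""
        for block in self.blocks:
            x = block(x, training)
        x = x.mean(axis=2)                           # collapse residual freq rows
        b, c, t = x.shape
        return x.transpose((0, 2, 1))                # (B, T, C)

    def forward(self, X: np.ndarray, training: bool = False) -> Tensor:
        """Batch of Mel grids (B, n_mels, n_frames) → logits (B,)."""
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1:] != (cfg.n_mels, cfg.n_frames):
            raise ValueError(
                f"expected input (batch, {cfg.n_mels}, {cfg.n_frames}), "
                f"got {X.shape}"
            )
        # map dB values in [-range, 0] onto [0, 1]
        Xs = (X / cfg.input_db_range + 1.0).astype(self.dtype)
        x = Tensor(Xs[:, None, :, :])
        seq = self.encode(x, training)
        hidden = self.lstm(seq)
        if cfg.head == "last":
            feat = hidden[-1]
        else:
            acc = hidden[0]
            for h in hidden[1:]:
                acc = acc + h
            feat = acc * (1.0 / len(hidden))
        return self.fc(feat).reshape(-1)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            z = self.forward(X[i:i + batch_size], training=False)
            out.append(1.0 / (1.0 + np.exp(-z.data)))
        return np.concatenate(out) if out else np.empty(0)

    # -- state --------------------------------------------------------------

    def state(self) -> dict:
        arrays = {f"p{i}": p.data.copy() for i, p in enumerate(self.params)}
        bns = [bn for b in self.blocks for bn in (b.bn1, b.bn2)]
        for i, bn in enumerate(bns):
            arrays[f"rm{i}"] = bn.running_mean.copy()
            arrays[f"rv{i}"] = bn.running_var.copy()
        return arrays

    def load_state(self, arrays: dict) -> None:
        for i, p in enumerate(self.params):
            p.data = np.array(arrays[f"p{i}"], dtype=self.dtype)
        bns = [bn for b in self.blocks for bn in (b.bn1, b.bn2)]
        for i, bn in enumerate(bns):
            bn.running_mean = np.array(arrays[f"rm{i}"])
            bn.running_var = np.array(arrays[f"rv{i}"])


def build_model(config: CRNNConfig) -> CRNNModel:
    """Construct the residual CRNN for the given configuration."""
    return CRNNModel(config)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    epoch: int
    metrics: dict
    state: dict


@dataclass
class CheckpointTriple:
    """Model snapshots at the best-accuracy, best-sensitivity and best
    mixed-score (accuracy + sensitivity) validation epochs."""

    best_accuracy: Checkpoint | None = None
    best_sensitivity: Checkpoint | None = None
    best_mixed: Checkpoint | None = None

    def update(self, epoch: int, metrics: dict, state: dict) -> None:
        def val(cp, key):
            if cp is None or cp.metrics.get(key) is None:
                return -np.inf
            return cp.metrics[key]

        for attr, key in (("best_accuracy", "accuracy"),
                          ("best_sensitivity", "sensitivity"),
                          ("best_mixed", "mixed")):
            new = metrics.get(key)
            if new is not None and new > val(getattr(self, attr), key):
                setattr(self, attr, Checkpoint(epoch, dict(metrics), state))


def _epoch_metrics(y: np.ndarray, p: np.ndarray, loss: float) -> dict:
    rep = compute_metrics(y, p >= 0.5)
    return {"loss": loss, "accuracy": rep.accuracy,
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "mixed": rep.mixed}


def train(model: CRNNModel, train_set: tuple[np.ndarray, np.ndarray],
          test_set: tuple[np.ndarray, np.ndarray],
          config: CRNNConfig | None = None, weighted: bool = True,
          ) -> tuple[CheckpointTriple, pd.DataFrame]:
    """Train a model, tracking per-epoch metrics on both splits.

    Returns the checkpoint triple and a tidy history frame with one row per
    (epoch, split) carrying loss, accuracy, sensitivity and specificity.
    Train-split metrics are accumulated from the training batches themselves;
    test-split metrics come from a full forward pass in evaluation mode after
    each epoch.  All randomness (shuffling) flows from the config seed.
    """
    cfg = config or model.config
    X_tr, y_tr = np.asarray(train_set[0]), np.asarray(train_set[1], dtype=bool)
    X_te, y_te = np.asarray(test_set[0]), np.asarray(test_set[1], dtype=bool)
    if y_tr.all() or not y_tr.any():
        raise ValueError("training set must contain both classes")
    w_true = class_weight(int(y_tr.sum()), int((~y_tr).sum())).w_true \
        if weighted else 1.0

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, lr=cfg.learning_rate)
    checkpoints = CheckpointTriple()
    rows = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X_tr))
        losses, probs, labels = [], [], []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            yb = y_tr[idx].astype(model.dtype)
            z = model.forward(X_tr[idx], training=True)
            # weighted BCE on logits: w·y·softplus(−z) + (1−y)·softplus(z)
            yt = Tensor(yb)
            loss = (Tensor((w_true * yb).astype(model.dtype)) * (-z).softplus()
                    + (1.0 - yt) * z.softplus()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.data.item() * len(idx))
            probs.append(1.0 / (1.0 + np.exp(-z.data)))
            labels.append(yb)
        train_m = _epoch_metrics(np.concatenate(labels).astype(bool),
                                 np.concatenate(probs),
                                 sum(losses) / len(X_tr))
        rows.append({"epoch": epoch, "split": "train", **train_m})

        p_te = model.predict_proba(X_te)
        test_loss = weighted_loss(y_te.astype(float), p_te, w_true)
        test_m = _epoch_metrics(y_te, p_te, test_loss)
        rows.append({"epoch": epoch, "split": "test", **test_m})
        checkpoints.update(epoch, test_m, model.state())

    history = pd.DataFrame(rows).drop(columns=["mixed"])
    return checkpoints, history


def predict(model: "CRNNModel | CRNNClassifier", X: np.ndarray,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment cough probabilities and thresholded labels."""
    proba = model.predict_proba(X)
    if proba.ndim == 2:                              # sklearn-style (n, 2)
        proba = proba[:, 1]
    return proba, proba >= threshold


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class CRNNClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style wrapper around the residual CRNN.

    ``fit`` expects X of shape (n, n_mels, n_frames) holding dB Mel grids and
    boolean/0-1 labels y.  A validation split (stratified, default 10%) is
    carved out internally unless ``fit`` is given one explicitly; per-epoch
    history and the checkpoint triple are exposed as fitted attributes.
    After training, the weights named by ``restore`` ("mixed", "accuracy",
    "sensitivity", or "last") are loaded for prediction.
    """

    def __init__(self, base_filters: int = 128, n_conv_blocks: int = 4,
                 lstm_layers: int = 4, lstm_hidden: int = 512,
                 epochs: int = 50, batch_size: int = 64,
                 learning_rate: float = 1e-3, seed: int = 0,
                 n_mels: int = 128, n_frames: int = 22, head: str = "last",
                 weighted: bool = True, validation_fraction: float = 0.10,
                 restore: str = "mixed", input_db_range: float = 80.0):
        self.base_filters = base_filters
        self.n_conv_blocks = n_conv_blocks
        self.lstm_layers = lstm_layers
        self.lstm_hidden = lstm_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.n_mels = n_mels
        self.n_frames = n_frames
        self.head = head
        self.weighted = weighted
        self.validation_fraction = validation_fraction
        self.restore = restore
        self.input_db_range = input_db_range

    def _config(self) -> CRNNConfig:
        return CRNNConfig(
            base_filters=self.base_filters, n_conv_blocks=self.n_conv_blocks,
            lstm_layers=self.lstm_layers, lstm_hidden=self.lstm_hidden,
            lstm_input=self.base_filters * 2 ** (self.n_conv_blocks - 1),
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, seed=self.seed,
            n_mels=self.n_mels, n_frames=self.n_frames, head=self.head,
            input_db_range=self.input_db_range,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(bool)
        if y.all() or not y.any():
            raise ValueError("training data must contain both classes")
        cfg = self._config()
        if X_val is None:
            rng = np.random.default_rng(cfg.seed + 2)
            tr, te = _stratified_split(y, self.validation_fraction, rng)
            X, X_val = X[tr], X[te]
            y, y_val = y[tr], y[te]
        else:
            X_val = np.asarray(X_val, dtype=np.float64)
            y_val = np.asarray(y_val).astype(bool)

        self.model_ = build_model(cfg)
        self.class_weight_ = (class_weight(int(y.sum()), int((~y).sum()))
                              if self.weighted else None)
        self.checkpoints_, self.history_ = train(
            self.model_, (X, y), (X_val, y_val), cfg, weighted=self.weighted)
        if self.restore != "last":
            cp = {"mixed": self.checkpoints_.best_mixed,
                  "accuracy": self.checkpoints_.best_accuracy,
                  "sensitivity": self.checkpoints_.best_sensitivity}[self.restore]
            if cp is not None:
                self.model_.load_state(cp.state)
        self.classes_ = np.array([False, True])
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        p = self.model_.predict_proba(np.asarray(X, dtype=np.float64))
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.model_.predict_proba(np.asarray(X, dtype=np.float64))

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X) >= 0.5

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize config + weights + running stats to a single .npz file."""
        cfg = json.dumps(self.get_params())
        np.savez(Path(path), __config__=np.array(cfg), **self.model_.state())

    @classmethod
    def load(cls, path: str | Path) -> "CRNNClassifier":
        with np.load(Path(path), allow_pickle=False) as data:
            params = json.loads(str(data["__config__"]))
            est = cls(**params)
            est.model_ = build_model(est._config())
            est.model_.load_state({k: data[k] for k in data.files
                                   if k != "__config__"})
        est.classes_ = np.array([False, True])
        return est
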