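"""Neural baselines: a fully connected net on the 7 engineered features and
a one-dimensional convolutional net on the raw photon-count series.

Both are small rectified networks trained with minibatch AdamW on a mean
squared error loss, with early stopping on a validation split and
best-weight restoration.  The output neuron is rectified too, so
predictions are non-negative by construction — the targets (exposure,
concentration, dosage) are physical non-negative quantities.

The trainer is a compact, fully deterministic numpy implementation: all
randomness (weight init, shuffling, validation split, dropout) flows from
one seeded generator, so a fixed seed reproduces runs bit-for-bit on a
fixed numpy version.

Architectures:

* FCNN — input (7 standardized features) → dense(80, ReLU) → dense(1, ReLU).
  Standardization of the inputs is required for the net to train well and
  is checked at entry.
* CNN  — per-time-point standardized series → conv1d(16 filters, kernel 32,
  stride 4, ReLU) → flatten → dense(80, ReLU) → dense(1, ReLU).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import _bin_target
from .regression import CVResult, _score

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configs and history


@dataclass
class _TrainConfig:
    learning_rate: float = 0.0035
    weight_decay: float = 0.004
    max_epochs: int = 3000
    early_stopping: bool = True
    patience: int = 100
    batch_size: int = 32
    val_fraction: float = 0.2
    dropout: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class FCNNConfig(_TrainConfig):
    """Fully connected net: 7 standardized features → 80 ReLU → 1 ReLU."""

    input_dim: int = 7
    hidden_units: int = 80
    strict_standardization: bool = False


@dataclass
class CNNConfig(_TrainConfig):
    """1-D convolutional net on raw count series (one conv, one dense layer)."""

    input_length: int = 1643
    filters: int = 16
    kernel_size: int = 32
    stride: int = 4
    dense_units: int = 80


@dataclass
class TrainingHistory:
    """Per-epoch loss and R² curves plus the early-stopping epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_r2: list[float] = field(default_factory=list)
    val_r2: list[float] = field(default_factory=list)
    stopped_epoch: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_r2": self.train_r2,
                "val_r2": self.val_r2,
            }
        )


# --------------------------------------------------------------------------
# layers


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class _MLPCore:
    """dense(hidden, ReLU) → dense(1, ReLU) with MSE gradients.

    The output bias starts at the training-target mean so the rectified
    output neuron begins in its active region instead of dead at zero.
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator,
                 y_mean: float, dropout: float = 0.0):
        self.W1 = _he_init(rng, input_dim, (input_dim, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = _he_init(rng, hidden, (hidden, 1))
        self.b2 = np.full(1, max(y_mean, 1e-3))
        self.dropout = dropout

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    # weight decay applies to weights only, not biases
    decay_mask = (True, False, True, False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        h = _relu(X @ self.W1 + self.b1)
        return _relu(h @ self.W2 + self.b2).ravel()

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None):
        z1 = X @ self.W1 + self.b1
        h = _relu(z1)
        if self.dropout > 0 and rng is not None:
            mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h = h * mask
        z2 = h @ self.W2 + self.b2
        out = _relu(z2).ravel()
        resid = out - y
        loss = float(np.mean(resid**2))
        n = len(y)
        dz2 = (2.0 / n) * resid[:, None] * (z2 > 0)
        dW2 = h.T @ dz2
        db2 = dz2.sum(axis=0)
        dh = dz2 @ self.W2.T
        if self.dropout > 0 and rng is not None:
            dh = dh * mask
        dz1 = dh * (z1 > 0)
        dW1 = X.T @ dz1
        db1 = dz1.sum(axis=0)
        return loss, [dW1, db1, dW2, db2]


class _CNNCore:
    """conv1d(ReLU) → flatten → dense(ReLU) → dense(1, ReLU).

    The convolution is evaluated as a matmul over pre-extracted strided
    windows (im2col); windows are views, so memory stays modest.
    """

    def __init__(self, cfg: CNNConfig, rng: np.random.Generator, y_mean: float):
        self.cfg = cfg
        self.out_len = (cfg.input_length - cfg.kernel_size) // cfg.stride + 1
        if self.out_len < 1:
            raise ValueError("kernel longer than input series")
        self.Wc = _he_init(rng, cfg.kernel_size, (cfg.kernel_size, cfg.filters))
        self.bc = np.zeros(cfg.filters)
        flat = self.out_len * cfg.filters
        self.W1 = _he_init(rng, flat, (flat, cfg.dense_units))
        self.b1 = np.zeros(cfg.dense_units)
        self.W2 = _he_init(rng, cfg.dense_units, (cfg.dense_units, 1))
        self.b2 = np.full(1, max(y_mean, 1e-3))
        self.dropout = cfg.dropout

    @property
    def params(self):
        return [self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2]

    decay_mask = (True, False, True, False, True, False)

    def _windows(self, X: np.ndarray) -> np.ndarray:
        k, s = self.cfg.kernel_size, self.cfg.stride
        return np.lib.stride_tricks.sliding_window_view(X, k, axis=1)[:, ::s, :]

    def predict(self, X: np.ndarray) -> np.ndarray:
        w = self._windows(X)
        conv = _relu(w @ self.Wc + self.bc)
        flat = conv.reshape(len(X), -1)
        h = _relu(flat @ self.W1 + self.b1)
        return _relu(h @ self.W2 + self.b2).ravel()

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None):
        w = self._windows(X)
        zc = w @ self.Wc + self.bc
        conv = _relu(zc)
        flat = conv.reshape(len(X), -1)
        z1 = flat @ self.W1 + self.b1
        h = _relu(z1)
        if self.dropout > 0 and rng is not None:
            mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h = h * mask
        z2 = h @ self.W2 + self.b2
        out = _relu(z2).ravel()
        resid = out - y
        loss = float(np.mean(resid**2))
        n = len(y)
        dz2 = (2.0 / n) * resid[:, None] * (z2 > 0)
        dW2 = h.T @ dz2
        db2 = dz2.sum(axis=0)
        dh = dz2 @ self.W2.T
        if self.dropout > 0 and rng is not None:
            dh = dh * mask
        dz1 = dh * (z1 > 0)
        dW1 = flat.T @ dz1
        db1 = dz1.sum(axis=0)
        dflat = dz1 @ self.W1.T
        dconv = dflat.reshape(zc.shape) * (zc > 0)
        k, f = self.cfg.kernel_size, self.cfg.filters
        dWc = w.reshape(-1, k).T @ dconv.reshape(-1, f)
        dbc = dconv.sum(axis=(0, 1))
        return loss, [dWc, dbc, dW1, db1, dW2, db2]


class _AdamW:
    """Adam with decoupled weight decay (decay skipped on bias terms)."""

    def __init__(self, params, lr: float, weight_decay: float, decay_mask,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.decay_mask = decay_mask
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.decay_mask[i]:
                p -= self.lr * self.wd * p


# --------------------------------------------------------------------------
# training loop


def _check_standardized(X: np.ndarray, strict: bool) -> None:
    means = np.abs(X.mean(axis=0))
    stds = np.abs(X.std(axis=0) - 1.0)
    if means.max() > 0.1 or stds.max() > 0.5:
        msg = (
            "input does not look standardized "
            f"(max |mean| = {means.max():.3g}, max |std-1| = {stds.max():.3g})"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=3)


def _fit(model, X: np.ndarray, y: np.ndarray, cfg: _TrainConfig,
         validation: tuple[np.ndarray, np.ndarray] | None,
         rng: np.random.Generator) -> TrainingHistory:
    n = len(X)
    if validation is None:
        n_val = max(1, int(round(cfg.val_fraction * n)))
        perm = rng.permutation(n)
        Xv, yv = X[perm[:n_val]], y[perm[:n_val]]
        Xt, yt = X[perm[n_val:]], y[perm[n_val:]]
    else:
        Xt, yt = X, y
        Xv, yv = validation

    opt = _AdamW(model.params, cfg.learning_rate, cfg.weight_decay, model.decay_mask)
    hist = TrainingHistory()
    best_loss = np.inf
    best_weights = [p.copy() for p in model.params]
    best_epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(Xt))
        for start in range(0, len(Xt), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            _, grads = model.loss_and_grads(Xt[batch], yt[batch], rng=rng)
            opt.step(model.params, grads)
        pred_t = model.predict(Xt)
        pred_v = model.predict(Xv)
        tl = float(np.mean((pred_t - yt) ** 2))
        vl = float(np.mean((pred_v - yv) ** 2))
        hist.train_loss.append(tl)
        hist.val_loss.append(vl)
        hist.train_r2.append(_score(yt, pred_t)[0])
        hist.val_r2.append(_score(yv, pred_v)[0])
        if vl < best_loss:
            best_loss = vl
            best_weights = [p.copy() for p in model.params]
            best_epoch = epoch
        if cfg.early_stopping and epoch - best_epoch >= cfg.patience:
            break
    hist.stopped_epoch = epoch
    for p, w in zip(model.params, best_weights):
        p[...] = w
    logger.info("training stopped at epoch %d (best val loss %.4g at %d)",
                epoch, best_loss, best_epoch)
    return hist


def train_fcnn(
    X: np.ndarray,
    y: np.ndarray,
    config: FCNNConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[_MLPCore, TrainingHistory]:
    """Train the fully connected net on standardized features.

    ``X`` must be standardized (zero mean, unit std per column); a
    non-standardized matrix triggers a warning, or an error when
    ``config.strict_standardization`` is set.  ``validation`` overrides the
    internal seeded validation split.
    """
    config = config or FCNNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != config.input_dim:
        raise ValueError(f"expected {config.input_dim} features, got {X.shape[1]}")
    if np.any(y < 0):
        raise ValueError("target must be non-negative")
    _check_standardized(X, config.strict_standardization)
    rng = np.random.default_rng(config.seed)
    model = _MLPCore(config.input_dim, config.hidden_units, rng,
                     y_mean=float(y.mean()), dropout=config.dropout)
    hist = _fit(model, X, y, config, validation, rng)
    return model, hist


class SeriesStandardizer:
    """Per-time-point standardization for raw count series.

    Fitted on training rows only; time points with zero variance are left
    unscaled (scale 1) so flat pre-pulse regions do not blow up.
    """

    def fit(self, X: np.ndarray) -> "SeriesStandardizer":
        self.means_ = X.mean(axis=0)
        scales = X.std(axis=0)
        scales[scales == 0] = 1.0
        self.scales_ = scales
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means_) / self.scales_


def train_cnn(
    X: np.ndarray,
    y: np.ndarray,
    config: CNNConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple["_CNNPipeline", TrainingHistory]:
    """Train the 1-D CNN on raw count series.

    Rows must all have ``config.input_length`` points.  Per-time-point
    standardization is fitted on the training rows and applied inside the
    returned pipeline, so ``predict`` takes raw series.
    """
    config = config or CNNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != config.input_length:
        raise ValueError(
            f"series must be a matrix with {config.input_length} columns, got {X.shape}"
        )
    if np.any(y < 0):
        raise ValueError("target must be non-negative")
    rng = np.random.default_rng(config.seed)
    std = SeriesStandardizer().fit(X)
    Xs = std.transform(X)
    val = None
    if validation is not None:
        val = (std.transform(np.asarray(validation[0], dtype=float)),
               np.asarray(validation[1], dtype=float))
    core = _CNNCore(config, rng, y_mean=float(y.mean()))
    hist = _fit(core, Xs, y, config, val, rng)
    return _CNNPipeline(std, core), hist


@dataclass
class _CNNPipeline:
    """Standardizer + trained CNN core; ``predict`` takes raw series."""

    standardizer: SeriesStandardizer
    core: _CNNCore

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.core.predict(self.standardizer.transform(np.asarray(X, dtype=float)))


def cross_validate_nn(
    X: np.ndarray,
    y: np.ndarray,
    config: FCNNConfig | CNNConfig,
    n_splits: int = 5,
    seed: int = 1,
) -> tuple[CVResult, list[TrainingHistory]]:
    """K-fold cross-validation of a neural model (strata from the binned target).

    For the FCNN, standardization statistics are refitted on each fold's
    training rows.  Returns the usual CV score bundle plus one training
    history per fold.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = _bin_target(y, 5)
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < n_splits:
        warnings.warn("a stratum is smaller than n_splits; unstratified K-fold",
                      stacklevel=2)
        folds = KFold(n_splits=n_splits, shuffle=True, random_state=seed).split(X)
    else:
        folds = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                random_state=seed).split(X, strata)

    is_cnn = isinstance(config, CNNConfig)
    per_fold = []
    histories = []
    for k, (tr, va) in enumerate(folds):
        if is_cnn:
            model, hist = train_cnn(X[tr], y[tr], config, validation=(X[va], y[va]))
        else:
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            model, hist = train_fcnn((X[tr] - mu) / sd, y[tr], config,
                                     validation=((X[va] - mu) / sd, y[va]))
            pred = model.predict((X[va] - mu) / sd)
            r2, mae = _score(y[va], pred)
            per_fold.append((0, k, r2, mae))
            histories.append(hist)
            continue
        pred = model.predict(X[va])
        r2, mae = _score(y[va], pred)
        per_fold.append((0, k, r2, mae))
        histories.append(hist)

    r2s = np.array([f[2] for f in per_fold])
    maes = np.array([f[3] for f in per_fold])
    result = CVResult(
        r2_mean=float(np.nanmean(r2s)),
        r2_std=float(np.nanstd(r2s)),
        mae_mean=float(maes.mean()),
        mae_std=float(maes.std()),
        per_fold=per_fold,
        n_splits=n_splits,
        n_repeats=1,
    )
    return result, histories
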