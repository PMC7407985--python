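"""The three silent-speech decoders and their training harness.

Three architecture families share one training recipe (categorical
cross-entropy, batch size 32, initial learning rate 1e-3, ReLU activations,
batch normalization) but differ in topology, optimizer and dropout:

=======  =========  =======  ====================================
family   optimizer  dropout  topology
=======  =========  =======  ====================================
mlp      adam       0.2      dense 1024 -> 256 -> softmax
cnn      adadelta   0.5      conv 32@3x7 -> pool -> conv 64@3x5 ->
                             pool -> dense 256 -> softmax
blstm    rmsprop    0.2      3 bidirectional LSTM layers (128 units),
                             2 dense layers (128, 64) -> softmax
=======  =========  =======  ====================================

The MLP and CNN consume the 6000-long concatenated feature vector (the CNN
reshapes it to a 6 x 1000 single-channel map); the bLSTM consumes the 6-step
sequence of 1000-dim channel features.  Training uses a
reduce-on-plateau learning-rate schedule (factor 0.2, patience 20, floor
0.5e-6 on validation loss) with early stopping (patience 80) and restores
the best-validation-loss weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .features import FeatureBundle
from .synthetic import ParameterError

__all__ = [
    "DecoderConfig",
    "TrainingSchedule",
    "ScheduleState",
    "SplitSpec",
    "TrainingReport",
    "DecoderModel",
    "ConfigurationError",
    "TrainingError",
    "build_decoder",
    "split_dataset",
    "split_indices",
    "bundles_to_arrays",
    "train",
    "predict",
    "save_decoder",
    "load_decoder",
    "FAMILY_DEFAULTS",
]

CONCAT_VIEW = "concat_6000"
SEQUENCE_VIEW = "sequence_6x1000"

#: per-family (optimizer, dropout) pairs
FAMILY_DEFAULTS = {
    "mlp": ("adam", 0.2),
    "cnn": ("adadelta", 0.5),
    "blstm": ("rmsprop", 0.2),
}


class ConfigurationError(ValueError):
    """Decoder family, view and hyperparameters are inconsistent."""


class TrainingError(RuntimeError):
    """Training diverged; carries the epoch index."""

    def __init__(self, message: str, epoch: int) -> None:
        super().__init__(message)
        self.epoch = epoch


@dataclass(frozen=True)
class DecoderConfig:
    """Architecture family plus its training hyperparameters.

    ``hidden_spec`` is family specific: dense widths for the MLP
    (default ``(1024, 256)``); for the CNN a dict with conv filter counts,
    kernel sizes, pool widths and dense width; for the bLSTM the recurrent
    width, layer count and dense widths.  Leaving it ``None`` selects the
    defaults above.
    """

    family: str = "mlp"
    optimizer: str | None = None
    dropout: float | None = None
    init_lr: float = 1e-3
    batch_size: int = 32
    n_classes: int = 10
    batch_norm: bool = True
    hidden_spec: tuple | dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILY_DEFAULTS:
            raise ConfigurationError(
                f"family: unknown decoder family {self.family!r}; choose from {sorted(FAMILY_DEFAULTS)}"
            )
        opt, drop = FAMILY_DEFAULTS[self.family]
        if self.optimizer is None:
            object.__setattr__(self, "optimizer", opt)
        if self.dropout is None:
            object.__setattr__(self, "dropout", drop)
        if not (0 <= self.dropout < 1):
            raise ConfigurationError(f"dropout: must lie in [0, 1), got {self.dropout}")
        if self.init_lr <= 0:
            raise ConfigurationError(f"init_lr: must be > 0, got {self.init_lr}")
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes: must be >= 2, got {self.n_classes}")


@dataclass(frozen=True)
class TrainingSchedule:
    """Reduce-on-plateau plus early stopping, both on validation loss."""

    lr_factor: float = 0.2
    lr_patience: int = 20
    min_lr: float = 0.5e-6
    early_stop_patience: int = 80
    max_epochs: int = 400
    min_delta: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.lr_factor < 1):
            raise ParameterError(f"lr_factor: must lie in (0, 1), got {self.lr_factor}")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ParameterError("patience values must be >= 1")


class ScheduleState:
    """Epoch-by-epoch schedule bookkeeping (shared by training and tests).

    ``update`` is called once per epoch with the validation loss and returns
    ``(lr, stop)``.  The plateau counter resets on improvement *and* on a
    reduction; the early-stop counter resets only on improvement.
    """

    def __init__(self, schedule: TrainingSchedule, init_lr: float) -> None:
        self.schedule = schedule
        self.lr = init_lr
        self.best = np.inf
        self.best_epoch = 0
        self._plateau_wait = 0
        self._stop_wait = 0
        self.epoch = 0

    def update(self, val_loss: float) -> tuple[float, bool]:
        s = self.schedule
        self.epoch += 1
        if val_loss < self.best - s.min_delta:
            self.best = val_loss
            self.best_epoch = self.epoch
            self._plateau_wait = 0
            self._stop_wait = 0
            return self.lr, False
        self._plateau_wait += 1
        self._stop_wait += 1
        if self._plateau_wait >= s.lr_patience:
            self.lr = max(self.lr * s.lr_factor, s.min_lr)
            self._plateau_wait = 0
        return self.lr, self._stop_wait >= s.early_stop_patience


@dataclass(frozen=True)
class SplitSpec:
    """Train/validate/test ratios (normalized), seeded, stratified by class."""

    ratios: tuple[float, float, float] = (7.0, 2.0, 1.0)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ParameterError(f"ratios: must be positive, got {self.ratios}")

    @property
    def fractions(self) -> np.ndarray:
        r = np.asarray(self.ratios, dtype=float)
        return r / r.sum()


@dataclass
class TrainingReport:
    """Per-epoch curves plus where and why training stopped."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""
    best_epoch: int = 0
    best_val_loss: float = np.inf

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "lr": self.lr_trace,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_acc": self.train_acc,
                "val_acc": self.val_acc,
            }
        )


@dataclass
class DecoderModel:
    """A built decoder: the network plus its configuration and input view."""

    network: nn.Network
    config: DecoderConfig
    input_view: str

    def describe(self) -> dict:
        layers = self.network.layers
        dense_idx = [i for i, l in enumerate(layers) if isinstance(l, nn.Dense)]
        return {
            "family": self.config.family,
            "input_view": self.input_view,
            "bidirectional_layers": sum(isinstance(l, nn.BiLSTM) for l in layers),
            "conv_layers": sum(isinstance(l, nn.Conv2D) for l in layers),
            "dense_layers_before_softmax": len(dense_idx) - 1,
            "n_parameters": sum(
                int(np.prod(p.shape)) for l in layers for p in l.params.values()
            ),
        }


def _mlp_layers(cfg: DecoderConfig, rng, drop_rng) -> list[nn.Layer]:
    widths = cfg.hidden_spec or (1024, 256)
    layers: list[nn.Layer] = []
    d_in = 6000
    for w in widths:
        layers.append(nn.Dense(d_in, w, rng))
        if cfg.batch_norm:
            layers.append(nn.BatchNorm(w))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(cfg.dropout, drop_rng))
        d_in = w
    layers.append(nn.Dense(d_in, cfg.n_classes, rng))
    return layers


def _cnn_layers(cfg: DecoderConfig, rng, drop_rng) -> list[nn.Layer]:
    spec = cfg.hidden_spec or {}
    f1, k1 = spec.get("conv1", (32, (3, 7)))
    f2, k2 = spec.get("conv2", (64, (3, 5)))
    pool = spec.get("pool", (1, 2))
    dense_w = spec.get("dense", 256)
    n_ch, step = spec.get("input_hw", (6, 1000))

    layers: list[nn.Layer] = [nn.Reshape((n_ch, step, 1))]
    h, w = n_ch, step
    layers.append(nn.Conv2D(1, f1, k1[0], k1[1], rng))
    h, w = h - k1[0] + 1, w - k1[1] + 1
    if cfg.batch_norm:
        layers.append(nn.BatchNorm(f1))
    layers.append(nn.ReLU())
    layers.append(nn.MaxPool2D(*pool))
    h, w = h // pool[0], w // pool[1]
    layers.append(nn.Conv2D(f1, f2, k2[0], k2[1], rng))
    h, w = h - k2[0] + 1, w - k2[1] + 1
    if cfg.batch_norm:
        layers.append(nn.BatchNorm(f2))
    layers.append(nn.ReLU())
    layers.append(nn.MaxPool2D(*pool))
    h, w = h // pool[0], w // pool[1]
    layers.append(nn.Flatten())
    layers.append(nn.Dropout(cfg.dropout, drop_rng))
    layers.append(nn.Dense(h * w * f2, dense_w, rng))
    if cfg.batch_norm:
        layers.append(nn.BatchNorm(dense_w))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(cfg.dropout, drop_rng))
    layers.append(nn.Dense(dense_w, cfg.n_classes, rng))
    return layers


def _blstm_layers(cfg: DecoderConfig, rng, drop_rng) -> list[nn.Layer]:
    spec = cfg.hidden_spec or {}
    units = spec.get("units", 128)
    n_bi = spec.get("n_bidirectional", 3)
    dense_ws = spec.get("dense", (128, 64))
    step_dim = spec.get("step_dim", 1000)

    layers: list[nn.Layer] = []
    d_in = step_dim
    for i in range(n_bi):
        layers.append(nn.BiLSTM(d_in, units, rng, return_sequences=(i < n_bi - 1)))
        d_in = 2 * units
    layers.append(nn.Dropout(cfg.dropout, drop_rng))
    for w in dense_ws:
        layers.append(nn.Dense(d_in, w, rng))
        if cfg.batch_norm:
            layers.append(nn.BatchNorm(w))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(cfg.dropout, drop_rng))
        d_in = w
    layers.append(nn.Dense(d_in, cfg.n_classes, rng))
    return layers


def build_decoder(cfg: DecoderConfig, input_view: str | None = None) -> DecoderModel:
    """Construct a trainable classifier for the requested family and view."""
    expected_view = SEQUENCE_VIEW if cfg.family == "blstm" else CONCAT_VIEW
    if input_view is None:
        input_view = expected_view
    if input_view != expected_view:
        raise ConfigurationError(
            f"input_view {input_view!r} is inconsistent with family {cfg.family!r} "
            f"(expected {expected_view!r})"
        )
    rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(cfg.seed + 1)
    builders = {"mlp": _mlp_layers, "cnn": _cnn_layers, "blstm": _blstm_layers}
    layers = builders[cfg.family](cfg, rng, drop_rng)
    return DecoderModel(network=nn.Network(layers), config=cfg, input_view=input_view)


def split_indices(labels: np.ndarray, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, covering train/validate/test index sets.

    Stratified mode allocates per class with largest-remainder rounding, so
    a 7:2:1 split of 100 balanced samples gives exactly 70/20/10.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 10:
        raise ParameterError(f"split: need at least 10 samples, got {n}")
    rng = np.random.default_rng(spec.seed)
    frac = spec.fractions

    def allocate(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = rng.permutation(idx)
        m = len(idx)
        raw = frac * m
        base = np.floor(raw).astype(int)
        for k in np.argsort(-(raw - base))[: m - base.sum()]:
            base[k] += 1
        # with >= 3 samples every part gets at least one
        while m >= 3 and base.min() == 0:
            base[int(base.argmin())] += 1
            base[int(base.argmax())] -= 1
        c1, c2 = base[0], base[0] + base[1]
        return idx[:c1], idx[c1:c2], idx[c2:]

    if not spec.stratified:
        return allocate(np.arange(n))
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        if len(cls_idx) < 3:
            raise ParameterError(
                f"split: class {cls} has only {len(cls_idx)} samples, fewer than the 3 split parts"
            )
        for part, chunk in zip(parts, allocate(cls_idx)):
            part.append(chunk)
    return tuple(np.sort(np.concatenate(p)) for p in parts)  # type: ignore[return-value]


def split_dataset(
    bundles: list[FeatureBundle], spec: SplitSpec = SplitSpec()
) -> tuple[list[FeatureBundle], list[FeatureBundle], list[FeatureBundle]]:
    """Split a labeled bundle collection into (train, validate, test) lists."""
    labels = np.array([b.label for b in bundles])
    tr, va, te = split_indices(labels, spec)
    pick = lambda idx: [bundles[i] for i in idx]
    return pick(tr), pick(va), pick(te)


def bundles_to_arrays(bundles: list[FeatureBundle], view: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack bundles into (X, y) in the requested input view, float32."""
    y = np.array([b.label for b in bundles], dtype=np.int64)
    if view == CONCAT_VIEW:
        x = np.stack([b.concat for b in bundles])
    elif view == SEQUENCE_VIEW:
        x = np.stack([b.sequence for b in bundles])
    else:
        raise ConfigurationError(f"unknown input view {view!r}")
    return x.astype(np.float32), y


def train(
    model: DecoderModel,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    schedule: TrainingSchedule = TrainingSchedule(),
    seed: int = 0,
) -> TrainingReport:
    """Minibatch training with plateau LR decay, early stopping and
    best-validation-weight restoration."""
    x_tr, y_tr = train_data
    x_va, y_va = val_data
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ParameterError("train: empty training or validation split")
    cfg = model.config
    net = model.network
    optimizer = nn.make_optimizer(cfg.optimizer, cfg.init_lr)
    state = ScheduleState(schedule, cfg.init_lr)
    rng = np.random.default_rng(seed)
    report = TrainingReport()
    best_weights = net.get_weights()

    for epoch in range(1, schedule.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        # training metrics are running averages over the epoch's minibatches,
        # computed from the training-mode forward passes themselves
        loss_sum, hit_sum = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            loss, hits = net.train_step(x_tr[sel], y_tr[sel], optimizer)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}", epoch)
            loss_sum += loss * len(sel)
            hit_sum += hits
        tr_loss, tr_acc = loss_sum / len(order), hit_sum / len(order)
        va_loss, va_acc = net.evaluate(x_va, y_va)
        if not np.isfinite(va_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}", epoch)
        report.lr_trace.append(optimizer.lr)
        report.train_loss.append(tr_loss)
        report.val_loss.append(va_loss)
        report.train_acc.append(tr_acc)
        report.val_acc.append(va_acc)

        new_lr, stop = state.update(va_loss)
        if state.best_epoch == state.epoch:
            best_weights = net.get_weights()
        optimizer.lr = new_lr
        if stop:
            report.stop_reason = "early_stop"
            report.stop_epoch = epoch
            break
    else:
        report.stop_reason = "max_epochs"
        report.stop_epoch = schedule.max_epochs

    report.best_epoch = state.best_epoch
    report.best_val_loss = state.best
    net.set_weights(best_weights)
    return report


def predict(model: DecoderModel, bundle: FeatureBundle | np.ndarray) -> tuple[int, np.ndarray]:
    """(argmax label, probability vector) for one sample; deterministic."""
    if isinstance(bundle, FeatureBundle):
        x = bundle.concat if model.input_view == CONCAT_VIEW else bundle.sequence
    else:
        x = np.asarray(bundle)
    probs = model.network.predict_proba(x[None].astype(np.float32))[0]
    return int(probs.argmax()), probs


def save_decoder(model: DecoderModel, out_dir: str) -> None:
    """Persist weights (NPZ) plus a JSON sidecar with the configuration."""
    import json
    import os
    from dataclasses import asdict

    os.makedirs(out_dir, exist_ok=True)
    arrays = {}
    for i, entry in enumerate(model.network.get_weights()):
        for key, val in entry.items():
            arrays[f"{i}:{key}"] = val
    np.savez(os.path.join(out_dir, "weights.npz"), **arrays)
    sidecar = {
        "config": asdict(model.config),
        "input_view": model.input_view,
        "topology": model.describe(),
    }
    with open(os.path.join(out_dir, "decoder.json"), "w") as f:
        json.dump(sidecar, f, indent=2)


def load_decoder(out_dir: str) -> DecoderModel:
    """Rebuild a decoder from :func:`save_decoder` output."""
    import json
    import os

    with open(os.path.join(out_dir, "decoder.json")) as f:
        sidecar = json.load(f)
    raw_cfg = sidecar["config"]
    if isinstance(raw_cfg.get("hidden_spec"), list):
        raw_cfg["hidden_spec"] = tuple(raw_cfg["hidden_spec"])
    cfg = DecoderConfig(**raw_cfg)
    model = build_decoder(cfg, sidecar["input_view"])
    data = np.load(os.path.join(out_dir, "weights.npz"))
    snapshot: list[dict] = [{} for _ in model.network.layers]
    for name in data.files:
        idx, key = name.split(":", 1)
        snapshot[int(idx)][key] = data[name]
    model.network.set_weights(snapshot)
    return model


def predict_batch(model: DecoderModel, bundles: list[FeatureBundle]) -> np.ndarray:
    """Predicted labels for a bundle collection."""
    if not bundles:
        return np.empty(0, dtype=np.int64)
    x, _ = bundles_to_arrays(bundles, model.input_view)
    out = []
    for start in range(0, len(x), 64):
        out.append(model.network.predict_proba(x[start:start + 64]).argmax(axis=1))
    return np.concatenate(out)
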