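"""CNN count regression: dataset preparation, training, inference, metrics.

A small convolutional network maps a homogenized single-nucleus patch to a
continuous micronucleus (CIN) count, trained with mean squared error; at
inference the raw output is rounded half-away-from-zero and clamped at zero
to give an integer count.  The module also provides the dataset balancing
used before training (drop counts above 3, downsample zero-count patches to
match the non-zero total), stratified splitting / k-fold cross-validation,
the standard classification metrics on rounded counts, and class-activation
saliency maps.

Training recipe (defaults): Adam at 1e-3, reduce-on-plateau LR decay
(factor 0.2, patience 10 epochs), early stopping on validation loss
(patience 30), at most 300 epochs, dropout 0.2 before the fully connected
head, mini-batches of 64, inputs mapped from [0, 1] to [-1, 1], and random
augmentations: vertical/horizontal flips, rotation up to +/-30 degrees and a
3x3 Gaussian blur applied with probability 0.3.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.transform import resize as _sk_resize
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .patches import NucleusPatch


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Architecture description.  ``small_cnn`` is a stack of 3x3
    conv(+batch-norm)+ReLU blocks (widths ``conv_channels``, 2x2 max pooling
    after the first ``n_pools`` blocks, optional 2x2 average-pool stem)
    followed by global average pooling, dropout and a single-output linear
    regression head — small enough to train on a CPU."""

    backbone: str = "small_cnn"
    conv_channels: tuple[int, ...] = (24, 48, 64, 64)
    n_pools: int = 2
    stem_pool: int = 2
    batch_norm: bool = True

    def validate(self) -> None:
        if self.backbone == "efficientnet_family":
            raise NotImplementedError(
                "EfficientNet backbones require a GPU deep-learning framework; "
                "this build ships the small_cnn backbone only"
            )
        if self.backbone != "small_cnn":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if len(self.conv_channels) < 1:
            raise ValueError("need at least one conv block")
        if self.stem_pool not in (1, 2):
            raise ValueError("stem_pool must be 1 (off) or 2")
        if not (0 <= self.n_pools <= len(self.conv_channels)):
            raise ValueError("n_pools must be between 0 and the number of conv blocks")

    @property
    def downsampling(self) -> int:
        """Total spatial downsampling factor (stem + max pools)."""
        return self.stem_pool * 2**self.n_pools


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    initial_learning_rate: float = 1e-3
    lr_factor: float = 0.2
    lr_patience: int = 10
    early_stopping_patience: int = 30
    max_epochs: int = 300
    dropout: float = 0.2
    batch_size: int = 64
    augment: bool = True
    rotation_degrees: float = 30.0
    blur_probability: float = 0.3
    max_grad_norm: float | None = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not (0.0 < self.lr_factor < 1.0):
            raise ValueError("lr_factor must be in (0, 1)")
        for name in ("dropout", "blur_probability"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} out of range")
        if self.batch_size < 1 or self.lr_patience < 1:
            raise ValueError("batch_size and lr_patience must be >= 1")
        if self.max_grad_norm is not None and self.max_grad_norm <= 0:
            raise ValueError("max_grad_norm must be positive or None")


@dataclasses.dataclass(frozen=True)
class PredictionRecord:
    """Per-patch prediction: raw regression output and the integer count
    (rounded half-away-from-zero, clamped at zero, never clipped above)."""

    patch_id: str
    raw_count: float
    count: int


# ---------------------------------------------------------------------------
# dataset preparation
# ---------------------------------------------------------------------------

def balance_indices(labels: np.ndarray, max_count: int = 3,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Indices of a balanced subset of ``labels``.

    Removes patches with a count above ``max_count`` (outliers), keeps every
    remaining non-zero patch, and downsamples zero-count patches without
    replacement to exactly the non-zero total, so the output is 50% zeros
    whenever zeros were in excess.  The returned index array is shuffled.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be 1D")
    if np.any(labels < 0):
        raise ValueError("labels must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    valid = np.flatnonzero(labels <= max_count)
    nonzero = valid[labels[valid] > 0]
    zero = valid[labels[valid] == 0]
    if nonzero.size == 0:
        raise ValueError("balancing undefined: no patches with a non-zero count")
    if zero.size < nonzero.size:
        warnings.warn(
            f"only {zero.size} zero-count patches for {nonzero.size} non-zero; "
            "keeping all zeros (set will not be 50/50)"
        )
        chosen_zero = zero
    else:
        chosen_zero = rng.choice(zero, size=nonzero.size, replace=False)
    out = np.concatenate([nonzero, chosen_zero])
    rng.shuffle(out)
    return out


def balance_dataset(patches, labels, max_count: int = 3, seed: int = 0):
    """Apply :func:`balance_indices` to a (patches, labels) pair."""
    idx = balance_indices(np.asarray(labels), max_count=max_count, seed=seed)
    labels = np.asarray(labels)[idx]
    if isinstance(patches, np.ndarray):
        return patches[idx], labels
    return [patches[i] for i in idx], labels


def split_dataset(labels: np.ndarray, val_fraction: float = 0.10,
                  k_folds: int | None = None, seed: int = 0):
    """Stratified train/validation split, or ``k_folds`` stratified folds.

    Returns ``(train_idx, val_idx)`` or, with ``k_folds``, a list of
    ``(train_idx, val_idx)`` tuples in which every sample appears in exactly
    one validation fold.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if k_folds is not None:
        smallest = int(np.unique(labels, return_counts=True)[1].min())
        if k_folds > smallest:
            raise ValueError(
                f"k_folds={k_folds} exceeds the smallest class size {smallest}; "
                "stratified folds would be empty for that class"
            )
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros(labels.size), labels))
    idx = np.arange(labels.size)
    stratify = labels
    if np.unique(labels, return_counts=True)[1].min() < 2:
        warnings.warn(
            "some classes have fewer than 2 members; falling back to an "
            "unstratified split"
        )
        stratify = None
    train_idx, val_idx = train_test_split(
        idx, test_size=val_fraction, random_state=seed, stratify=stratify
    )
    return train_idx, val_idx


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class CountingCNN:
    """Convolutional feature extractor + GAP + dropout + linear head.

    Exposes the final convolutional feature maps (for class-activation maps)
    and a flat parameter list (for the optimizer)."""

    def __init__(self, spec: ModelSpec, dropout: float, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        if spec.stem_pool == 2:
            layers.append(nn.AvgPool2d())
        in_ch = 1
        for block, ch in enumerate(spec.conv_channels):
            layers.append(nn.Conv2d(in_ch, ch, 3, rng))
            if spec.batch_norm:
                layers.append(nn.BatchNorm2d(ch))
            layers.append(nn.ReLU())
            if block < spec.n_pools:
                layers.append(nn.MaxPool2d())
            in_ch = ch
        self.features = nn.Sequential(layers)
        self.head = nn.Sequential([
            nn.GlobalAvgPool(),
            nn.Dropout(dropout, rng),
            nn.Linear(in_ch, 1, rng),
        ])
        self.last_feature_maps: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        fmap = self.features.forward(x, train)
        self.last_feature_maps = fmap
        return self.head.forward(fmap, train)[:, 0]

    def backward(self, grad_out: np.ndarray) -> None:
        g = self.head.backward(grad_out[:, None])
        self.features.backward(g)

    def parameters(self):
        return self.features.parameters() + self.head.parameters()

    def gradients(self):
        return self.features.gradients() + self.head.gradients()

    def state(self):
        arrays = self.parameters() + self.features.buffers() + self.head.buffers()
        return [a.copy() for a in arrays]

    def load_state(self, state):
        arrays = self.parameters() + self.features.buffers() + self.head.buffers()
        for a, s in zip(arrays, state, strict=True):
            a[...] = s

    @property
    def head_weights(self) -> np.ndarray:
        """Linear-head weight vector over feature channels (for CAM)."""
        return self.head.layers[-1].params[0][0]


def to_model_input(patches: np.ndarray) -> np.ndarray:
    """Map [0, 1] patches of shape (N, S, S) to the model's [-1, 1] NCHW."""
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    return (x * 2.0 - 1.0)[:, None, :, :]


def _augment_batch(batch: np.ndarray, cfg: TrainingConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(batch)
    for i, img in enumerate(batch):
        if rng.random() < 0.5:
            img = img[::-1, :]
        if rng.random() < 0.5:
            img = img[:, ::-1]
        angle = rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees)
        img = ndi.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
        if rng.random() < cfg.blur_probability:
            # sigma 0.8 with truncate=1.25 gives a 3x3 kernel
            img = ndi.gaussian_filter(img, sigma=0.8, truncate=1.25)
        out[i] = img
    return out


@dataclasses.dataclass
class TrainedModel:
    model: CountingCNN
    spec: ModelSpec
    config: TrainingConfig
    input_size: int

    def predict_raw(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = to_model_input(patches)
        if x.shape[2] != self.input_size or x.shape[3] != self.input_size:
            raise ValueError(
                f"patches are {x.shape[2]}x{x.shape[3]} but the model was "
                f"trained on {self.input_size}x{self.input_size}"
            )
        chunks = [
            self.model.forward(x[i : i + batch_size], train=False)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(chunks)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz",
                 **{f"p{i}": p for i, p in enumerate(self.model.state())})
        sidecar = {
            "model_spec": dataclasses.asdict(self.spec),
            "training_config": dataclasses.asdict(self.config),
            "input_size": self.input_size,
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        spec_d = dict(sidecar["model_spec"])
        spec_d["conv_channels"] = tuple(spec_d["conv_channels"])
        spec = ModelSpec(**spec_d)
        config = TrainingConfig(**sidecar["training_config"])
        model = CountingCNN(spec, config.dropout, seed=config.seed)
        with np.load(directory / "weights.npz") as data:
            model.load_state([data[f"p{i}"] for i in range(len(data.files))])
        return cls(model=model, spec=spec, config=config,
                   input_size=int(sidecar["input_size"]))


def train(
    train_patches: np.ndarray,
    train_labels: np.ndarray,
    val_patches: np.ndarray,
    val_labels: np.ndarray,
    model_spec: ModelSpec | None = None,
    config: TrainingConfig | None = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Train the count regressor; returns the best-validation-loss weights.

    ``train_patches``/``val_patches`` are (N, S, S) arrays in [0, 1] (the
    [-1, 1] mapping is applied internally); labels are per-patch integer
    counts cast to float for regression.  The history frame records per-epoch
    mean training loss, validation loss and learning rate.
    """
    model_spec = model_spec or ModelSpec()
    config = config or TrainingConfig()
    config.validate()
    model_spec.validate()
    size = np.asarray(train_patches).shape[-1]
    if size % model_spec.downsampling != 0:
        raise ValueError(
            f"patch size {size} must be divisible by {model_spec.downsampling}"
        )

    rng = np.random.default_rng(config.seed)
    model = CountingCNN(model_spec, config.dropout, seed=int(rng.integers(2**31)))
    # start the regression head at the mean label so early epochs are spent
    # on features, not on finding the output offset
    model.head.layers[-1].params[1][0] = float(np.mean(train_labels))
    optimizer = nn.Adam(model.parameters(), lr=config.initial_learning_rate)
    scheduler = nn.ReduceLROnPlateau(optimizer, config.lr_factor, config.lr_patience)

    x_train = np.asarray(train_patches, dtype=np.float32)
    y_train = np.asarray(train_labels, dtype=np.float32)
    x_val = to_model_input(val_patches)
    y_val = np.asarray(val_labels, dtype=np.float32)

    best_val, best_state, bad_epochs = np.inf, model.state(), 0
    history = []
    for epoch in range(config.max_epochs):
        perm = rng.permutation(x_train.shape[0])
        epoch_losses = []
        for start in range(0, perm.size, config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch = x_train[idx]
            if config.augment:
                batch = _augment_batch(batch, config, rng)
            pred = model.forward(to_model_input(batch), train=True)
            loss, dloss = nn.mse_loss(pred, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            model.backward(dloss.astype(np.float32))
            grads = model.gradients()
            if config.max_grad_norm is not None:
                total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if total > config.max_grad_norm:
                    scale = config.max_grad_norm / total
                    for g in grads:
                        g *= scale
            optimizer.step(grads)
            epoch_losses.append(loss)

        val_pred = np.concatenate([
            model.forward(x_val[i : i + 256], train=False)
            for i in range(0, x_val.shape[0], 256)
        ])
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "learning_rate": optimizer.lr,
        })
        if val_loss < best_val:
            best_val, best_state, bad_epochs = val_loss, model.state(), 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stopping_patience:
                break
        scheduler.step(val_loss)

    model.load_state(best_state)
    _recalibrate_batch_norm(model, to_model_input(x_train), config.batch_size)
    trained = TrainedModel(model=model, spec=model_spec, config=config, input_size=size)
    return trained, pd.DataFrame(history)


def _recalibrate_batch_norm(model: CountingCNN, x: np.ndarray, batch_size: int) -> None:
    """Recompute batch-norm running statistics with the final weights.

    The exponential estimates accumulated during training lag behind the
    restored best-epoch weights and carry augmentation noise; replacing them
    with the cumulative average of per-batch statistics over the unaugmented
    training set removes that mismatch.  Deterministic: fixed batch order,
    and dropout only sits downstream of every normalization layer.
    """
    bns = [layer for layer in model.features.layers
           if isinstance(layer, nn.BatchNorm2d)]
    if not bns:
        return
    saved_momentum = [b.momentum for b in bns]
    for b in bns:
        b.buffers[0][...] = 0.0
        b.buffers[1][...] = 1.0
    for i, start in enumerate(range(0, x.shape[0], batch_size)):
        for b in bns:
            b.momentum = 1.0 / (i + 1)  # cumulative average of batch stats
        model.forward(x[start : start + batch_size], train=True)
    for b, momentum in zip(bns, saved_momentum):
        b.momentum = momentum


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def round_half_away_from_zero(x: np.ndarray) -> np.ndarray:
    """Round to nearest with .5 going away from zero (so 1.5 -> 2)."""
    x = np.asarray(x)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def predict_counts(model: TrainedModel, patches, patch_ids=None) -> list[PredictionRecord]:
    """Predict integer CIN counts for patches (no augmentation at inference).

    Counts above the training range are flagged via a warning but not
    clipped — the regression head may extrapolate.
    """
    if isinstance(patches, list) and patches and isinstance(patches[0], NucleusPatch):
        if patch_ids is None:
            patch_ids = [f"{p.source_image_id}:{p.label}" for p in patches]
        patches = np.stack([p.pixels for p in patches])
    patches = np.asarray(patches)
    if patch_ids is None:
        patch_ids = [str(i) for i in range(patches.shape[0])]
    raw = model.predict_raw(patches)
    counts = np.maximum(0, round_half_away_from_zero(raw))
    if np.any(counts > 3):
        warnings.warn(f"{int(np.sum(counts > 3))} predictions above count 3 (extrapolation)")
    return [
        PredictionRecord(patch_id=str(pid), raw_count=float(r), count=int(c))
        for pid, r, c in zip(patch_ids, raw, counts)
    ]


def predictions_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patch_id, r.raw_count, r.count) for r in records],
        columns=["patch_id", "raw_count", "count"],
    )


def evaluate_classification(
    true_counts, predicted_counts, raw_scores=None
) -> dict:
    """Classification metrics on integer counts.

    Returns weighted F1, multiclass Matthews correlation (0 with a warning on
    degenerate single-class input), per-class precision/recall, the confusion
    matrix, and — when ``raw_scores`` is given — average precision for the
    binary task "count >= 1" computed from the raw regression outputs.
    """
    y_true = np.asarray(true_counts, dtype=np.int64)
    y_pred = np.asarray(predicted_counts, dtype=np.int64)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("inputs must be equal-length non-empty integer vectors")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    out: dict = {
        "f1_weighted": float(_skm.f1_score(y_true, y_pred, average="weighted",
                                           zero_division=0)),
        "confusion_matrix": _skm.confusion_matrix(y_true, y_pred, labels=classes),
        "classes": classes,
    }
    if classes.size < 2:
        warnings.warn("single-class inputs: MCC undefined, reported as 0 by convention")
        out["mcc"] = 0.0
    else:
        out["mcc"] = float(_skm.matthews_corrcoef(y_true, y_pred))
    out["precision_per_class"] = _skm.precision_score(
        y_true, y_pred, labels=classes, average=None, zero_division=0
    )
    out["recall_per_class"] = _skm.recall_score(
        y_true, y_pred, labels=classes, average=None, zero_division=0
    )
    if raw_scores is not None:
        out["average_precision_binary"] = float(
            _skm.average_precision_score((y_true >= 1).astype(int), np.asarray(raw_scores))
        )
    return out


def saliency_map(model: TrainedModel, patch: np.ndarray) -> np.ndarray:
    """Class-activation map: linear-head-weighted sum of the final feature
    maps, rectified, upsampled to the patch size and max-normalized to [0, 1]
    (all-zero if no channel activates)."""
    patch = np.asarray(patch, dtype=np.float32)
    if patch.ndim != 2:
        raise ValueError("patch must be 2D")
    model.model.forward(to_model_input(patch[None]), train=False)
    fmap = model.model.last_feature_maps[0]  # (C, h, w)
    cam = np.tensordot(model.model.head_weights, fmap, axes=(0, 0))
    cam = np.maximum(cam, 0.0)
    cam = _sk_resize(cam, patch.shape, order=1, preserve_range=True)
    peak = cam.max()
    return (cam / peak) if peak > 0 else np.zeros_like(cam)
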