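"""Small 3D CNN binary classifier with optional encoder-weight transfer.

Architecture: 1-3 convolution layers (3x3x3 kernels, stride 1, same padding,
ReLU) -> flatten -> one fully connected ReLU layer -> a single sigmoid output
unit trained with binary cross-entropy.  The probability p of the "unhealthy"
class carries an implicit complement 1 - p, so the model's confidence is the
disparity |p - (1 - p)| = |2p - 1|.

Transfer initialization copies pretrained encoder convolution weights into
the classifier's convolution stack layer by layer (prefix rule): where the
shapes match exactly the tensors are copied bitwise; where the filter counts
differ, the leading sub-tensor of matching shape is copied and the rest keeps
its random initialization.  All layers remain trainable.

Training holds out a stratified inner-validation split and checkpoints the
epoch with the highest inner-validation accuracy (earliest epoch on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .autoencoder import EncoderWeights
from .types import LabeledVolume, Prediction, as_volume

__all__ = [
    "ClassifierConfig",
    "Model",
    "TrainedModel",
    "build_classifier",
    "initialize_from_encoder",
    "train_classifier",
    "predict",
    "predict_batch",
    "stratified_split",
]

_GRID_CHOICES = (16, 32, 64)


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the classifier; width/depth from the search grid."""

    n_conv_layers: int = 2
    filters_per_layer: int = 32
    fc_nodes: int = 16
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_conv_layers <= 3:
            raise ValueError(f"n_conv_layers must be 1-3, got {self.n_conv_layers}")
        if self.filters_per_layer not in _GRID_CHOICES:
            raise ValueError(f"filters_per_layer must be in {_GRID_CHOICES}, got {self.filters_per_layer}")
        if self.fc_nodes not in _GRID_CHOICES:
            raise ValueError(f"fc_nodes must be in {_GRID_CHOICES}, got {self.fc_nodes}")
        if not 0.0 < self.validation_fraction <= 0.5:
            raise ValueError(f"validation_fraction must lie in (0, 0.5], got {self.validation_fraction}")


@dataclass
class Model:
    """An (un)trained network plus the metadata needed to use it."""

    net: nn.Sequential
    config: ClassifierConfig
    input_shape: Tuple[int, int, int]
    init_mode: str = "random"

    def conv_layers(self) -> List[nn.Conv3D]:
        return [l for l in self.net.layers if isinstance(l, nn.Conv3D)]

    def n_params(self) -> int:
        return self.net.n_params()


@dataclass
class TrainedModel:
    """A checkpointed model and its training history."""

    model: Model
    train_losses: List[float]
    val_accuracies: List[float]
    checkpoint_epoch: int  # 1-based
    checkpoint_val_accuracy: float
    init_mode: str = "random"


def build_classifier(config: ClassifierConfig, input_shape: Tuple[int, int, int]) -> Model:
    """Assemble the network with seeded random initialization."""
    h, w, d = (int(s) for s in input_shape)
    if min(h, w, d) < 1:
        raise ValueError(f"invalid input shape {input_shape}")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC1F]))
    layers: List = []
    cin = 1
    for _ in range(config.n_conv_layers):
        layers.append(nn.Conv3D(cin, config.filters_per_layer, rng))
        layers.append(nn.ReLU())
        cin = config.filters_per_layer
    layers.append(nn.Flatten())
    layers.append(nn.Dense(h * w * d * cin, config.fc_nodes, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(config.fc_nodes, 1, rng))
    return Model(net=nn.Sequential(layers), config=config, input_shape=(h, w, d))


def initialize_from_encoder(model: Model, weights: EncoderWeights) -> Model:
    """Copy pretrained encoder convolutions into the classifier (prefix rule).

    For classifier conv layer i, if encoder layer i exists: on exact shape
    match the kernel and bias are copied bitwise; otherwise the leading
    sub-tensor of matching shape is copied (both channel axes) and the
    remainder keeps its random values.  Non-convolution layers are untouched
    and everything stays trainable.
    """
    convs = model.conv_layers()
    if not convs:
        raise ValueError("model has no convolution layers")
    for conv, (kernel, bias) in zip(convs, weights.layers):
        if kernel.shape[:3] != conv.kernel.shape[:3]:
            raise ValueError(
                f"encoder kernel spatial shape {kernel.shape[:3]} incompatible with "
                f"classifier kernels {conv.kernel.shape[:3]}"
            )
        ci = min(kernel.shape[3], conv.kernel.shape[3])
        co = min(kernel.shape[4], conv.kernel.shape[4])
        conv.kernel[:, :, :, :ci, :co] = kernel[:, :, :, :ci, :co]
        conv.bias[:co] = bias[:co]
    model.init_mode = "transfer"
    return model


def stratified_split(
    labels: Sequence[int], val_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Class-balanced validation split: the same count from every class.

    The count is ``ceil(val_fraction * smallest class)`` (at least 1 when a
    class has more than one member).  Equal per-class validation counts
    matter in leave-one-out settings: a proportionally stratified split
    mirrors the training fold's imbalance, whose majority class is always
    the complement of the held-out sample, and checkpointing on such a
    validation set systematically selects models biased against the held-out
    label.  The residual training imbalance is handled by the class-weighted
    loss instead.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    min_count = min(np.sum(labels == cls) for cls in classes)
    n_val = max(1, int(np.ceil(val_fraction * min_count))) if min_count > 1 else 0
    train_idx, val_idx = [], []
    for cls in classes:
        idx = rng.permutation(np.flatnonzero(labels == cls))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx, dtype=int)), np.sort(np.asarray(val_idx, dtype=int))


def _stratified_order(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Interleave shuffled per-class indices so every minibatch is near-balanced.

    With a handful of near-identical volumes per class, label-unbalanced
    minibatches exert a large common-mode pull on the logit that can saturate
    and then kill the ReLU stack before any class-differential gradient
    accumulates; class-interleaved ordering removes that failure mode.
    """
    i0 = rng.permutation(np.flatnonzero(y == 0))
    i1 = rng.permutation(np.flatnonzero(y == 1))
    longer, shorter = (i0, i1) if i0.size >= i1.size else (i1, i0)
    # alternate classes while both remain, then append the surplus
    seq: List[int] = []
    a, b = list(longer), list(shorter)
    while a or b:
        if a:
            seq.append(a.pop())
        if b:
            seq.append(b.pop())
    return np.asarray(seq, dtype=int)


def _stack(samples: Sequence[LabeledVolume]) -> Tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.volume for s in samples]).astype(np.float32)[..., None]
    y = np.array([s.label for s in samples], dtype=np.float32)
    return x, y


def predict_batch(model: Model, volumes: np.ndarray) -> np.ndarray:
    """Probabilities for a (n, H, W, D, 1) batch."""
    z = model.net.forward(volumes, train=False)
    return nn.sigmoid(z).ravel()


def predict(model: Model, volume: np.ndarray) -> Prediction:
    """Probability, hard label (ties at 0.5 -> class 1) and confidence |2p-1|."""
    vol = as_volume(volume)
    if vol.shape != model.input_shape:
        raise ValueError(f"volume shape {vol.shape} does not match training shape {model.input_shape}")
    p = float(predict_batch(model, vol[None, ..., None])[0])
    return Prediction.from_probability(p)


def train_classifier(
    model: Model,
    train_samples: Sequence[LabeledVolume],
    config: Optional[ClassifierConfig] = None,
    augmented: Optional[Sequence[LabeledVolume]] = None,
    val_samples: Optional[Sequence[LabeledVolume]] = None,
) -> TrainedModel:
    """Optimize binary cross-entropy; checkpoint on inner-validation accuracy.

    If ``val_samples`` is not supplied, a stratified ``validation_fraction``
    of ``train_samples`` is held out (before any augmentation is added).
    ``augmented`` samples, if given, join only the optimization set.  The
    loss weights samples by inverse class frequency so a majority class is
    not a learnable shortcut.  The returned model carries the weights of the
    epoch with the highest validation accuracy (accuracy ties broken by
    lower validation loss, then the earlier epoch); seeded end to end.
    """
    config = config or model.config
    labels = [s.label for s in train_samples]
    if len(set(labels)) < 2:
        raise ValueError("training fold must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x7A]))
    if val_samples is None:
        tr_idx, va_idx = stratified_split(labels, config.validation_fraction, rng)
        inner_train = [train_samples[i] for i in tr_idx]
        inner_val = [train_samples[i] for i in va_idx]
    else:
        inner_train = list(train_samples)
        inner_val = list(val_samples)
    if augmented:
        inner_train = inner_train + list(augmented)
    if len({s.label for s in inner_train}) < 2:
        raise ValueError("inner training split lost a class; lower validation_fraction")

    x_tr, y_tr = _stack(inner_train)
    x_va, y_va = _stack(inner_val)
    # inverse-class-frequency weights: leaving one sample out of a balanced
    # set leaves a majority prior, and an unweighted learner that follows it
    # gets every held-out prediction wrong; weighting removes the prior as a
    # learnable shortcut
    n1 = float(y_tr.sum())
    n0 = float(y_tr.size - n1)
    cls_w = {0.0: y_tr.size / (2.0 * n0), 1.0: y_tr.size / (2.0 * n1)}
    w_tr = np.array([cls_w[float(v)] for v in y_tr])
    opt = nn.Adam(model.net.params(), lr=config.learning_rate)
    n = x_tr.shape[0]
    train_losses: List[float] = []
    val_accuracies: List[float] = []
    # checkpoint = argmax validation accuracy; exact-accuracy ties broken by
    # lower validation loss, then by the earlier epoch — with a handful of
    # validation samples the accuracy is coarse and flat stretches are
    # common, and loss is the informative secondary signal
    best: Dict = {"acc": -1.0, "loss": np.inf, "epoch": 0, "state": model.net.state_dict()}
    for epoch in range(1, config.epochs + 1):
        order = _stratified_order(y_tr, rng)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            z = model.net.forward(x_tr[idx], train=True)
            loss, dz = nn.bce_with_logits(z, y_tr[idx], sample_weight=w_tr[idx])
            model.net.backward(dz)
            opt.step(model.net.grads())
            losses.append(loss)
        train_losses.append(float(np.mean(losses)))
        z_va = model.net.forward(x_va, train=False)
        val_loss, _ = nn.bce_with_logits(z_va, y_va)
        p_va = nn.sigmoid(z_va).ravel()
        acc = float(np.mean((p_va >= 0.5).astype(int) == y_va.astype(int)))
        val_accuracies.append(acc)
        if acc > best["acc"] or (acc == best["acc"] and val_loss < best["loss"]):
            best = {"acc": acc, "loss": val_loss, "epoch": epoch, "state": model.net.state_dict()}
    model.net.load_state_dict(best["state"])
    return TrainedModel(
        model=model,
        train_losses=train_losses,
        val_accuracies=val_accuracies,
        checkpoint_epoch=best["epoch"],
        checkpoint_val_accuracy=best["acc"],
        init_mode=model.init_mode,
    )
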