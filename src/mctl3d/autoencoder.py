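"""Patch-based 3D convolutional autoencoder pretraining on an unlabeled corpus.

Small sub-volumes (default 25 x 25 x 4 voxels, 20000 per volume) are sampled
uniformly with replacement from each source volume, and an encoder-decoder
network is trained to reconstruct them under mean-squared error.  The encoder
is a stack of 3x3x3 stride-1 same-padding convolutions with ReLU; the decoder
mirrors it with a linear final layer, so all shapes are preserved end to end.
The learned encoder convolution kernels ("layer 1", "layer 2", "layer 3") are
exported for use as the initialization of a classifier's convolution stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .types import as_volume

__all__ = [
    "PatchSet",
    "AutoencoderConfig",
    "EncoderWeights",
    "extract_patches",
    "extract_corpus_patches",
    "build_autoencoder",
    "train_autoencoder",
    "reconstruction_error",
]


@dataclass
class PatchSet:
    """Fixed-shape sub-volumes plus where they came from."""

    patches: np.ndarray  # (n, ph, pw, pd) float32
    corners: np.ndarray  # (n, 3) int — (y, x, z) of each patch's origin
    source_ids: np.ndarray  # (n,) int — index of the source volume
    seed: int

    def __post_init__(self) -> None:
        if self.patches.ndim != 4:
            raise ValueError("patches must be a (n, ph, pw, pd) array")

    @property
    def n(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_shape(self) -> Tuple[int, int, int]:
        return tuple(self.patches.shape[1:])


@dataclass(frozen=True)
class AutoencoderConfig:
    """Encoder depth/width and optimization settings.

    1-3 encoder layers with filter counts from {16, 32, 64}, 3x3x3 kernels,
    stride 1; trained with Adam on mean-squared reconstruction error.
    """

    encoder_filters: Tuple[int, ...] = (16, 32, 64)
    epochs: int = 20
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.encoder_filters) <= 3:
            raise ValueError(f"1-3 encoder layers supported, got {len(self.encoder_filters)}")
        if any(f not in (16, 32, 64) for f in self.encoder_filters):
            raise ValueError(f"filter counts must be from {{16, 32, 64}}, got {self.encoder_filters}")


@dataclass
class EncoderWeights:
    """Ordered encoder convolution kernels/biases exported after pretraining.

    ``layers[i]`` holds (kernel of shape 3x3x3 x in x out, bias) for encoder
    layer i+1.  The mirrored decoder layers are kept as training metadata so
    reconstruction error remains computable from the container alone.
    """

    layers: List[Tuple[np.ndarray, np.ndarray]]
    decoder_layers: List[Tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    config: Optional[AutoencoderConfig] = None
    final_loss: float = float("nan")
    epoch_losses: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i in range(1, len(self.layers)):
            prev_out = self.layers[i - 1][0].shape[4]
            cur_in = self.layers[i][0].shape[3]
            if prev_out != cur_in:
                raise ValueError(f"encoder layer {i + 1} expects {cur_in} input channels, layer {i} emits {prev_out}")


def extract_patches(
    volume: np.ndarray,
    patch_shape: Tuple[int, int, int] = (25, 25, 4),
    n: int = 20000,
    seed: int = 0,
) -> PatchSet:
    """Sample ``n`` patches with corners uniform over all valid positions.

    Sampling is with replacement and deterministic under ``seed``; every patch
    lies fully inside the volume.
    """
    vol = as_volume(volume)
    ph, pw, pd = (int(s) for s in patch_shape)
    h, w, d = vol.shape
    if h < ph or w < pw or d < pd:
        raise ValueError(f"volume shape {vol.shape} smaller than patch shape {tuple(patch_shape)}")
    if n < 0:
        raise ValueError("patch count must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A7C]))
    ys = rng.integers(0, h - ph + 1, size=n)
    xs = rng.integers(0, w - pw + 1, size=n)
    zs = rng.integers(0, d - pd + 1, size=n)
    patches = np.empty((n, ph, pw, pd), dtype=np.float32)
    for i, (y, x, z) in enumerate(zip(ys, xs, zs)):
        patches[i] = vol[y : y + ph, x : x + pw, z : z + pd]
    corners = np.stack([ys, xs, zs], axis=1).astype(np.int64)
    return PatchSet(patches=patches, corners=corners, source_ids=np.zeros(n, dtype=np.int64), seed=int(seed))


def extract_corpus_patches(
    volumes: Sequence[np.ndarray],
    patch_shape: Tuple[int, int, int] = (25, 25, 4),
    per_volume: int = 20000,
    seed: int = 0,
) -> PatchSet:
    """Concatenate per-volume patch sets over a corpus, tracking source ids."""
    sets = []
    for i, v in enumerate(volumes):
        ps = extract_patches(v, patch_shape=patch_shape, n=per_volume, seed=int(seed) * 100003 + i)
        ps.source_ids[:] = i
        sets.append(ps)
    if not sets:
        raise ValueError("empty corpus")
    return PatchSet(
        patches=np.concatenate([s.patches for s in sets]),
        corners=np.concatenate([s.corners for s in sets]),
        source_ids=np.concatenate([s.source_ids for s in sets]),
        seed=int(seed),
    )


def build_autoencoder(config: AutoencoderConfig, rng: np.random.Generator) -> nn.Sequential:
    """Encoder convs (ReLU) then a mirrored decoder with a linear final conv."""
    layers: List = []
    cin = 1
    for f in config.encoder_filters:
        layers.append(nn.Conv3D(cin, f, rng))
        layers.append(nn.ReLU())
        cin = f
    mirror = list(config.encoder_filters[:-1][::-1]) + [1]
    for j, f in enumerate(mirror):
        layers.append(nn.Conv3D(cin, f, rng))
        if j < len(mirror) - 1:
            layers.append(nn.ReLU())
        cin = f
    return nn.Sequential(layers)


def _conv_layers(model: nn.Sequential) -> List[nn.Conv3D]:
    return [l for l in model.layers if isinstance(l, nn.Conv3D)]


def train_autoencoder(patches: PatchSet, config: AutoencoderConfig) -> EncoderWeights:
    """Minimize mean-squared reconstruction error over the patch set.

    Seeded end to end: initialization, batch order and therefore the final
    weights are identical across runs with the same inputs.
    """
    if patches.n == 0:
        raise ValueError("cannot train on an empty PatchSet")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xAE]))
    model = build_autoencoder(config, rng)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    x_all = patches.patches[..., None]  # (n, ph, pw, pd, 1)
    n = patches.n
    epoch_losses: List[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_all[idx]
            recon = model.forward(xb, train=True)
            loss, dpred = nn.mse_loss(recon, xb)
            model.backward(dpred)
            opt.step(model.grads())
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
    n_enc = len(config.encoder_filters)
    convs = _conv_layers(model)
    return EncoderWeights(
        layers=[(c.kernel.copy(), c.bias.copy()) for c in convs[:n_enc]],
        decoder_layers=[(c.kernel.copy(), c.bias.copy()) for c in convs[n_enc:]],
        config=config,
        final_loss=epoch_losses[-1],
        epoch_losses=epoch_losses,
    )


def _assemble(weights: EncoderWeights) -> nn.Sequential:
    """Rebuild the full autoencoder network from an exported container."""
    rng = np.random.default_rng(0)
    layers: List = []
    n_total = len(weights.layers) + len(weights.decoder_layers)
    for i, (k, b) in enumerate([*weights.layers, *weights.decoder_layers]):
        conv = nn.Conv3D(k.shape[3], k.shape[4], rng)
        conv.kernel[...] = k
        conv.bias[...] = b
        layers.append(conv)
        if i < n_total - 1:
            layers.append(nn.ReLU())
    return nn.Sequential(layers)


def reconstruction_error(weights: EncoderWeights, patches: PatchSet) -> float:
    """Mean squared reconstruction error per voxel over a patch set."""
    if not weights.decoder_layers:
        raise ValueError("container has no decoder layers; reconstruction undefined")
    if weights.layers[0][0].shape[3] != 1:
        raise ValueError("encoder expects single-channel patches")
    model = _assemble(weights)
    x = patches.patches[..., None]
    errs = []
    for start in range(0, patches.n, 256):
        xb = x[start : start + 256]
        recon = model.forward(xb, train=False)
        errs.append(np.mean((recon.astype(np.float64) - xb) ** 2) * xb.size)
    return float(np.sum(errs) / x.size)
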