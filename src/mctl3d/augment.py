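"""Label-preserving rigid augmentation: in-plane rotation plus translation.

Each augmented volume is produced by one composed affine transform applied
identically to every depth slice: the slice is rotated about its center into
enlarged boundary dimensions computed from the sine and cosine of the rotation
matrix (so no content is clipped), then translated.  Exposed voxels take a
configurable fill value.  Because the perturbation is rigid, the class of the
image is unchanged, which is the premise that lets a small labeled set be
expanded k-fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .types import LabeledVolume, as_volume

__all__ = [
    "RigidTransform",
    "AugmentationConfig",
    "rotated_bounds",
    "apply_rigid_transform",
    "augment_sample",
    "center_crop_pad",
]


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rotation (degrees, about the slice center) then (dy, dx) shift."""

    angle: float
    shift: Tuple[float, float] = (0.0, 0.0)
    fill_value: float = 0.0
    order: int = 1  # 1 = bilinear, 0 = nearest


@dataclass(frozen=True)
class AugmentationConfig:
    """How many random rigid operations to draw per image, and their ranges."""

    k: int = 14
    max_angle: float = 25.0
    max_shift_fraction: float = 0.1
    seed: int = 0
    fill_value: float = 0.0
    order: int = 1

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be nonnegative, got {self.k}")
        if self.max_angle < 0:
            raise ValueError(f"max_angle must be nonnegative, got {self.max_angle}")
        if not 0.0 <= self.max_shift_fraction < 0.5:
            raise ValueError(f"max_shift_fraction must lie in [0, 0.5), got {self.max_shift_fraction}")


def rotated_bounds(height: int, width: int, angle: float) -> Tuple[int, int]:
    """Boundary dimensions of a (height, width) frame rotated by ``angle`` degrees.

    new_height = ceil(h|cos| + w|sin|), new_width = ceil(h|sin| + w|cos|); the
    rotated footprint always fits inside these bounds.
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    theta = math.radians(angle)
    c, s = abs(math.cos(theta)), abs(math.sin(theta))
    # round before ceil so exact quarter turns are not inflated by fp dust
    new_h = math.ceil(round(height * c + width * s, 6))
    new_w = math.ceil(round(height * s + width * c, 6))
    return int(new_h), int(new_w)


def _affine_inverse(h: int, w: int, t: RigidTransform) -> Tuple[np.ndarray, np.ndarray]:
    """Matrix/offset mapping output voxel coords back to input coords."""
    new_h, new_w = rotated_bounds(h, w, t.angle)
    theta = math.radians(t.angle)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])  # input <- output rotation (inverse of forward)
    c_in = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    c_out = np.array([(new_h - 1) / 2.0, (new_w - 1) / 2.0])
    shift = np.asarray(t.shift, dtype=float)
    # forward: out = R^T (in - c_in) + c_out + shift  =>  in = R (out - c_out - shift) + c_in
    offset = c_in - rot @ (c_out + shift)
    return rot, offset


def apply_rigid_transform(volume: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Rotate every depth slice about its center into the enlarged bounds, then shift.

    A single composed affine (one interpolation pass) is applied; all slices
    share the transform, so the output shape is (new_h, new_w, depth).
    """
    vol = as_volume(volume)
    h, w, d = vol.shape
    new_h, new_w = rotated_bounds(h, w, t.angle)
    rot2, offset2 = _affine_inverse(h, w, t)
    mat = np.eye(3)
    mat[:2, :2] = rot2
    offset = np.array([offset2[0], offset2[1], 0.0])
    return ndimage.affine_transform(
        vol,
        mat,
        offset=offset,
        output_shape=(new_h, new_w, d),
        order=t.order,
        mode="constant",
        cval=t.fill_value,
    ).astype(np.float32)


def center_crop_pad(volume: np.ndarray, shape: Tuple[int, int, int], fill_value: float = 0.0) -> np.ndarray:
    """Center-crop or pad a volume to ``shape`` so augmented tensors stack."""
    vol = as_volume(volume)
    out = np.full(shape, fill_value, dtype=np.float32)
    src_slices, dst_slices = [], []
    for axis in range(3):
        n_in, n_out = vol.shape[axis], shape[axis]
        if n_in >= n_out:
            start = (n_in - n_out) // 2
            src_slices.append(slice(start, start + n_out))
            dst_slices.append(slice(0, n_out))
        else:
            start = (n_out - n_in) // 2
            src_slices.append(slice(0, n_in))
            dst_slices.append(slice(start, start + n_in))
    out[tuple(dst_slices)] = vol[tuple(src_slices)]
    return out


def sample_transform(rng: np.random.Generator, shape: Tuple[int, int, int], config: AugmentationConfig) -> RigidTransform:
    """Draw one random rigid operation within the configured ranges."""
    angle = float(rng.uniform(-config.max_angle, config.max_angle))
    dy = float(rng.uniform(-1.0, 1.0) * config.max_shift_fraction * shape[0])
    dx = float(rng.uniform(-1.0, 1.0) * config.max_shift_fraction * shape[1])
    return RigidTransform(angle=angle, shift=(dy, dx), fill_value=config.fill_value, order=config.order)


def augment_sample(sample: LabeledVolume, config: AugmentationConfig) -> List[LabeledVolume]:
    """Exactly k independently perturbed copies, every one keeping the label.

    Outputs are cropped/padded back to the input shape (centered) so a batch
    of augmented volumes stacks into one tensor.  Deterministic under seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xA06]))
    shape = sample.volume.shape
    out: List[LabeledVolume] = []
    for _ in range(config.k):
        t = sample_transform(rng, shape, config)
        warped = apply_rigid_transform(sample.volume, t)
        out.append(LabeledVolume(volume=center_crop_pad(warped, shape, config.fill_value), label=sample.label))
    return out
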