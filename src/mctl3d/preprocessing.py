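"""Slice stacking, intensity windowing and training-set brightness normalization.

The window for each image is chosen to contain at least a requested fraction
(default 95%) of its voxel intensities, by central symmetric trimming: the
interpolated (1-c)/2 and 1-(1-c)/2 quantiles are snapped outward to observed
intensities and then widened order statistic by order statistic until the
realized coverage reaches the request.  Windows are per-image; brightness
normalization uses pooled statistics of the *training* volumes only, so a
held-out volume can never influence the transform applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np

from .types import as_volume

__all__ = [
    "WindowParams",
    "NormalizerParams",
    "stack_slices",
    "compute_window",
    "apply_window",
    "fit_normalizer",
    "apply_normalizer",
]


@dataclass(frozen=True)
class WindowParams:
    """An intensity interval [lower, upper] and the coverage it was asked for."""

    lower: float
    upper: float
    coverage: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"window lower {self.lower} exceeds upper {self.upper}")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError(f"coverage must lie in (0, 1], got {self.coverage}")


@dataclass(frozen=True)
class NormalizerParams:
    """Pooled brightness statistics of a training fold."""

    train_mean: float
    train_min: float
    train_max: float

    def __post_init__(self) -> None:
        if not self.train_min <= self.train_mean <= self.train_max:
            raise ValueError(
                f"require train_min <= train_mean <= train_max, got "
                f"({self.train_min}, {self.train_mean}, {self.train_max})"
            )


def stack_slices(slices: Sequence[np.ndarray]) -> np.ndarray:
    """Stack 2D slices into a (H, W, n_slices) volume, slice k at depth k."""
    if len(slices) == 0:
        raise ValueError("need at least one slice")
    first = np.asarray(slices[0])
    if first.ndim != 2:
        raise ValueError("slices must be 2D arrays")
    for k, s in enumerate(slices):
        s = np.asarray(s)
        if s.shape != first.shape:
            raise ValueError(f"slice {k} has shape {s.shape}, expected {first.shape}")
    return as_volume(np.stack([np.asarray(s) for s in slices], axis=-1))


def compute_window(volume: np.ndarray, coverage: float = 0.95) -> WindowParams:
    """Window containing at least ``coverage`` of the volume's intensities."""
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must lie in (0, 1], got {coverage}")
    vol = as_volume(volume)
    vals = np.sort(vol.ravel())
    n = vals.size
    if n == 0:
        raise ValueError("empty volume")
    alpha = (1.0 - coverage) / 2.0
    q_lo, q_hi = np.quantile(vals, [alpha, 1.0 - alpha])
    # snap outward to observed intensities
    lo_idx = int(np.searchsorted(vals, q_lo, side="right")) - 1
    lo_idx = max(lo_idx, 0)
    hi_idx = int(np.searchsorted(vals, q_hi, side="left"))
    hi_idx = min(hi_idx, n - 1)
    # widen until the realized in-window fraction meets the request
    need = int(np.ceil(coverage * n - 1e-9))
    while True:
        lower, upper = float(vals[lo_idx]), float(vals[hi_idx])
        inside = int(np.searchsorted(vals, upper, side="right")) - int(np.searchsorted(vals, lower, side="left"))
        if inside >= need:
            break
        below = int(np.searchsorted(vals, lower, side="left"))
        above = n - int(np.searchsorted(vals, upper, side="right"))
        if below >= above and lo_idx > 0:
            lo_idx -= 1
        elif hi_idx < n - 1:
            hi_idx += 1
        else:
            lo_idx = max(lo_idx - 1, 0)
    return WindowParams(lower=lower, upper=upper, coverage=coverage)


def apply_window(volume: np.ndarray, window: WindowParams) -> np.ndarray:
    """Clip to [lower, upper] and rescale linearly to [0, 1]; shape unchanged."""
    vol = as_volume(volume)
    span = window.upper - window.lower
    if span == 0:
        return np.zeros_like(vol)
    return ((np.clip(vol, window.lower, window.upper) - window.lower) / span).astype(np.float32)


def fit_normalizer(training_volumes: Iterable[np.ndarray]) -> NormalizerParams:
    """Pool all training voxels and record their mean, min and max."""
    vols: List[np.ndarray] = [as_volume(v) for v in training_volumes]
    if not vols:
        raise ValueError("need at least one training volume")
    total = sum(float(v.sum(dtype=np.float64)) for v in vols)
    count = sum(v.size for v in vols)
    return NormalizerParams(
        train_mean=total / count,
        train_min=min(float(v.min()) for v in vols),
        train_max=max(float(v.max()) for v in vols),
    )


def apply_normalizer(volume: np.ndarray, norm: NormalizerParams) -> np.ndarray:
    """Center on the training mean and scale by the training range.

    Applied identically to training and held-out volumes.  A degenerate
    training range (max == min) maps everything to zero.
    """
    vol = as_volume(volume)
    span = norm.train_max - norm.train_min
    if span <= 0:
        return np.zeros_like(vol)
    return ((vol - norm.train_mean) / span).astype(np.float32)
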