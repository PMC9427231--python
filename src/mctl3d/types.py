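"""Core containers shared across the pipeline.

A volume is a plain 3D :class:`numpy.ndarray` of voxel intensities with axes
ordered (height, width, depth) and 0-based voxel indices.  Geometry operations
may change the shape; intensity operations never do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LabeledVolume", "Prediction", "as_volume"]


def as_volume(arr: np.ndarray, name: str = "volume") -> np.ndarray:
    """Validate and return a 3D float array of finite intensities."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError(f"{name} must be 3D (H, W, D); got rank {arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite intensities")
    return arr


@dataclass(frozen=True)
class LabeledVolume:
    """A volume plus its binary class: 0 = healthy, 1 = unhealthy."""

    volume: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class Prediction:
    """Per-sample model output.

    ``probability`` is P(unhealthy); ``label`` applies the 0.5 threshold with
    ties (p == 0.5 exactly) mapped to class 1; ``confidence`` is the disparity
    between the two implicit class scores, |p - (1 - p)| = |2p - 1|.
    """

    probability: float
    label: int
    confidence: float

    @classmethod
    def from_probability(cls, p: float) -> "Prediction":
        p = float(p)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability must lie in [0, 1], got {p}")
        return cls(probability=p, label=1 if p >= 0.5 else 0, confidence=abs(2.0 * p - 1.0))
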