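"""Synthetic 3D brain-phantom volumes with Rician magnitude noise.

Every downstream stage (windowing, augmentation, patch pretraining, LOOCV)
is exercised on these seeded phantoms, so no image download is ever needed.
A phantom is an ellipsoidal "head" of uniform tissue intensity on a dark
background; an unhealthy phantom additionally carries one bright spherical
lesion fully inside the tissue.  Magnitude noise follows the Rician model of
MR images: each voxel v becomes sqrt((v + n1)^2 + n2^2) with n1, n2
independent zero-mean Gaussians of standard deviation sigma.  At v = 0 this
reduces to a Rayleigh distribution (mean sigma*sqrt(pi/2)); at high SNR it
approaches additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np

from .types import LabeledVolume, as_volume

__all__ = [
    "PhantomParams",
    "make_phantom",
    "add_rician_noise",
    "generate_labeled_dataset",
    "generate_source_corpus",
]

# Fraction of each half-axis occupied by the tissue ellipsoid.
_TISSUE_FRACTION = 0.84


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, contrast and noise settings of the synthetic generator.

    Attributes
    ----------
    shape : (H, W, D) voxel counts; each axis must admit the downstream
        patch shape (>= 25, 25, 4 for the default autoencoder patches).
    background_level, tissue_level : intensities in [0, 1] of the dark
        surround and of the ellipsoidal head region.
    lesion_radius_range : (min, max) lesion radius in voxels.
    lesion_contrast : additive intensity of the lesion over tissue_level.
    noise_sigma : Rician channel standard deviation, intensity units.
    seed : master seed for dataset-level generation.
    """

    shape: Tuple[int, int, int] = (64, 64, 16)
    background_level: float = 0.05
    tissue_level: float = 0.60
    lesion_radius_range: Tuple[float, float] = (3.0, 6.0)
    lesion_contrast: float = 0.30
    noise_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive axis sizes, got {self.shape}")
        if not 0.0 <= self.background_level < self.tissue_level <= 1.0:
            raise ValueError(
                "require 0 <= background_level < tissue_level <= 1; got "
                f"background_level={self.background_level}, tissue_level={self.tissue_level}"
            )
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError(f"lesion_radius_range must satisfy 0 < min <= max, got {self.lesion_radius_range}")
        if self.lesion_contrast < 0:
            # zero contrast is allowed: it yields label-bearing volumes with
            # no visible lesion, the no-signal control condition
            raise ValueError(f"lesion_contrast must be nonnegative, got {self.lesion_contrast}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be nonnegative, got {self.noise_sigma}")


def _semi_axes(shape: Sequence[int]) -> np.ndarray:
    return _TISSUE_FRACTION * (np.asarray(shape, dtype=float) / 2.0)


def _scaled_grid(shape: Sequence[int]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    axes = [np.arange(s, dtype=float) - c for s, c in zip(shape, center)]
    return np.ix_(*axes)


def make_phantom(params: PhantomParams, with_lesion: bool, rng_seed: int) -> LabeledVolume:
    """Build one noiseless phantom; identical seed gives identical voxels.

    The lesion center is rejection-sampled so the whole sphere stays inside
    the tissue ellipsoid; if no radius in ``lesion_radius_range`` can fit, a
    ``ValueError`` names the offending radius.
    """
    shape = tuple(int(s) for s in params.shape)
    semi = _semi_axes(shape)
    vol = np.full(shape, params.background_level, dtype=np.float32)
    gy, gx, gz = _scaled_grid(shape)
    tissue = (gy / semi[0]) ** 2 + (gx / semi[1]) ** 2 + (gz / semi[2]) ** 2 <= 1.0
    vol[tissue] = params.tissue_level

    label = 0
    if with_lesion:
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0x1E51]))
        r = float(rng.uniform(*params.lesion_radius_range))
        # conservative containment: the lesion sphere fits if its center lies
        # inside the ellipsoid shrunk by r on every semi-axis
        margin = 1.0 - r / float(semi.min())
        if margin <= 0:
            raise ValueError(
                f"lesion of radius {r:.2f} voxels cannot fit inside tissue semi-axes {tuple(np.round(semi, 2))}"
            )
        while True:
            u = rng.uniform(-margin, margin, size=3)
            if float(np.sum((u / margin) ** 2)) <= 1.0:
                break
        center = (np.asarray(shape, dtype=float) - 1.0) / 2.0 + u * semi
        dy = np.arange(shape[0], dtype=float)[:, None, None] - center[0]
        dx = np.arange(shape[1], dtype=float)[None, :, None] - center[1]
        dz = np.arange(shape[2], dtype=float)[None, None, :] - center[2]
        lesion = dy * dy + dx * dx + dz * dz <= r * r
        vol[lesion] = params.tissue_level + params.lesion_contrast
        label = 1

    return LabeledVolume(volume=as_volume(vol), label=label)


def add_rician_noise(volume: np.ndarray, sigma: float, rng_seed: int) -> np.ndarray:
    """Apply Rician magnitude noise: sqrt((v + n1)^2 + n2^2), n_i ~ N(0, sigma).

    sigma = 0 returns the input unchanged (exact identity).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma}")
    vol = as_volume(volume)
    if sigma == 0:
        return vol.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0x71C3]))
    n1 = rng.normal(0.0, sigma, size=vol.shape)
    n2 = rng.normal(0.0, sigma, size=vol.shape)
    return np.sqrt((vol + n1) ** 2 + n2 ** 2).astype(np.float32)


def _derived_seed(master: int, *tags: int) -> int:
    """Stable sub-seed < 2**31 from a master seed and integer tags."""
    ss = np.random.SeedSequence([int(master), *[int(t) for t in tags]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_labeled_dataset(n_healthy: int, n_lesion: int, params: PhantomParams) -> List[LabeledVolume]:
    """n_healthy lesion-free then n_lesion lesion-bearing noisy phantoms.

    Noise is applied once, after phantom construction.  Fully determined by
    ``params.seed``.
    """
    if n_healthy < 0 or n_lesion < 0:
        raise ValueError("counts must be nonnegative")
    out: List[LabeledVolume] = []
    for i in range(n_healthy + n_lesion):
        with_lesion = i >= n_healthy
        seed_i = _derived_seed(params.seed, 1, i)
        sample = make_phantom(params, with_lesion=with_lesion, rng_seed=seed_i)
        noisy = add_rician_noise(sample.volume, params.noise_sigma, rng_seed=_derived_seed(params.seed, 2, i))
        out.append(LabeledVolume(volume=noisy, label=sample.label))
    return out


def generate_source_corpus(n: int, params: PhantomParams) -> List[np.ndarray]:
    """Unlabeled pretraining corpus from a shifted anatomy distribution.

    The corpus differs from the target set in a stated way: lesion radii are
    drawn from a range widened by 50% (clipped to fit the tissue region) and
    lesion prevalence is 50%, so encoder features transferred from it are
    informative but not a copy of the target distribution.
    """
    if n < 0:
        raise ValueError("corpus size must be nonnegative")
    lo, hi = params.lesion_radius_range
    max_fit = 0.95 * float(_semi_axes(params.shape).min())
    wide = (min(lo * 0.75, max_fit), min(hi * 1.5, max_fit))
    src_params = replace(params, lesion_radius_range=wide)
    out: List[np.ndarray] = []
    for i in range(n):
        seed_i = _derived_seed(params.seed, 3, i)
        with_lesion = i % 2 == 1  # 50% prevalence, deterministic
        sample = make_phantom(src_params, with_lesion=with_lesion, rng_seed=seed_i)
        noisy = add_rician_noise(sample.volume, params.noise_sigma, rng_seed=_derived_seed(params.seed, 4, i))
        out.append(noisy)
    return out
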