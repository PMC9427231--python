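"""Readers and writers: NIfTI volumes, HDF5 weight containers, YAML run configs.

Volumes are written as float32 NIfTI with an identity affine; weight
containers use a documented HDF5 layout (``/encoder/layer_{i}/kernel`` and
``/bias``, mirrored under ``/decoder``, metadata attributes on the root)
with a version field that is checked on load so stale files fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Tuple, Union

import h5py
import nibabel as nib
import numpy as np
import yaml

from .augment import AugmentationConfig
from .autoencoder import AutoencoderConfig, EncoderWeights
from .classifier import ClassifierConfig
from .preprocessing import NormalizerParams
from .synthetic import PhantomParams
from .types import as_volume

__all__ = [
    "read_volume",
    "write_volume",
    "save_weights",
    "load_weights",
    "save_normalizer",
    "load_normalizer",
    "RunConfig",
]

WEIGHTS_FORMAT_VERSION = "mctl3d-weights-1"


def read_volume(path: Union[str, Path]) -> np.ndarray:
    """Load a 3D NIfTI volume as float32 (H, W, D)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got rank {data.ndim}")
    return as_volume(data)


def write_volume(volume: np.ndarray, path: Union[str, Path]) -> None:
    """Write float32 NIfTI (.nii or .nii.gz) with an identity affine."""
    vol = as_volume(volume)
    img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))


def _write_layers(grp: h5py.Group, layers: List[Tuple[np.ndarray, np.ndarray]]) -> None:
    for i, (kernel, bias) in enumerate(layers, start=1):
        sub = grp.create_group(f"layer_{i}")
        sub.create_dataset("kernel", data=kernel)
        sub.create_dataset("bias", data=bias)


def _read_layers(grp: h5py.Group) -> List[Tuple[np.ndarray, np.ndarray]]:
    out = []
    for i in range(1, len(grp) + 1):
        sub = grp[f"layer_{i}"]
        out.append((np.asarray(sub["kernel"], dtype=np.float32), np.asarray(sub["bias"], dtype=np.float32)))
    return out


def save_weights(weights: EncoderWeights, path: Union[str, Path]) -> None:
    """Store an encoder-weight container in the documented HDF5 layout."""
    with h5py.File(str(path), "w", track_order=True) as f:
        f.attrs["format_version"] = WEIGHTS_FORMAT_VERSION
        f.attrs["final_loss"] = weights.final_loss
        f.attrs["epoch_losses"] = json.dumps(list(weights.epoch_losses))
        if weights.config is not None:
            f.attrs["config"] = json.dumps(dataclasses.asdict(weights.config))
        _write_layers(f.create_group("encoder"), weights.layers)
        _write_layers(f.create_group("decoder"), weights.decoder_layers)


def load_weights(path: Union[str, Path]) -> EncoderWeights:
    """Load an encoder-weight container; the version field must match."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    with h5py.File(str(path), "r") as f:
        version = f.attrs.get("format_version")
        if version != WEIGHTS_FORMAT_VERSION:
            raise ValueError(f"weight container version mismatch: expected {WEIGHTS_FORMAT_VERSION!r}, found {version!r}")
        config = None
        if "config" in f.attrs:
            raw = json.loads(f.attrs["config"])
            raw["encoder_filters"] = tuple(raw["encoder_filters"])
            config = AutoencoderConfig(**raw)
        return EncoderWeights(
            layers=_read_layers(f["encoder"]),
            decoder_layers=_read_layers(f["decoder"]),
            config=config,
            final_loss=float(f.attrs["final_loss"]),
            epoch_losses=list(json.loads(f.attrs["epoch_losses"])),
        )


def save_normalizer(norm: NormalizerParams, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(norm), indent=2))


def load_normalizer(path: Union[str, Path]) -> NormalizerParams:
    return NormalizerParams(**json.loads(Path(path).read_text()))


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable to one YAML file."""

    phantom: PhantomParams = PhantomParams()
    coverage: float = 0.95
    augmentation: AugmentationConfig = AugmentationConfig()
    autoencoder: AutoencoderConfig = AutoencoderConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    repeats: int = 15
    master_seed: int = 0

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = self.to_dict()
        # tuples -> lists for clean YAML; restored on load
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(d)), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        phantom = d.get("phantom", {})
        for key in ("shape", "lesion_radius_range"):
            if key in phantom:
                phantom[key] = tuple(phantom[key])
        ae = d.get("autoencoder", {})
        if "encoder_filters" in ae:
            ae["encoder_filters"] = tuple(ae["encoder_filters"])
        return cls(
            phantom=PhantomParams(**phantom),
            coverage=float(d.get("coverage", 0.95)),
            augmentation=AugmentationConfig(**d.get("augmentation", {})),
            autoencoder=AutoencoderConfig(**ae),
            classifier=ClassifierConfig(**d.get("classifier", {})),
            repeats=int(d.get("repeats", 15)),
            master_seed=int(d.get("master_seed", 0)),
        )
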