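"""Volume container and NIfTI / CSV / YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml


@dataclass
class ImageVolume:
    """A 3D scalar grid with anisotropic voxel spacing in mm."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"invalid voxel spacing: {self.spacing_mm}")
        self.spacing_mm = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def save_nifti(volume: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        import warnings

        warnings.warn(f"{path}: missing/invalid spacing metadata, assuming 1 mm isotropic")
        zooms = (1.0, 1.0, 1.0)
    return ImageVolume(data=np.asarray(img.dataobj), spacing_mm=tuple(float(z) for z in zooms))


def save_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
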