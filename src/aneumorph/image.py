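"""3D scalar image volumes with anisotropic spacing (the synthetic "scan").

Voxel coordinates are cell-centered: ``world = origin + index * spacing``.
Volumes round-trip through NIfTI (nibabel) and MetaImage (SimpleITK).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class ImageVolume:
    data: np.ndarray          # (nx, ny, nz) scalar intensities
    spacing: np.ndarray       # mm per axis
    origin: np.ndarray        # world mm of voxel (0, 0, 0) center
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, float).reshape(3)
        self.origin = np.asarray(self.origin, float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self):
        return self.data.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, float) * self.spacing

    # ---------------------------------------------------------------- I/O
    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.data, np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "ImageVolume":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float32),
            spacing=np.abs(np.diag(affine)[:3]),
            origin=affine[:3, 3].copy(),
        )

    def to_mha(self, path) -> None:
        import SimpleITK as sitk

        # SimpleITK arrays are (z, y, x)
        img = sitk.GetImageFromArray(np.asarray(self.data, np.float32).transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        sitk.WriteImage(img, str(path))

    @classmethod
    def from_mha(cls, path) -> "ImageVolume":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        return cls(
            data=sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float32),
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
        )

    @classmethod
    def load(cls, path) -> "ImageVolume":
        path = str(path)
        if path.endswith((".mha", ".mhd")):
            return cls.from_mha(path)
        return cls.from_nifti(path)
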