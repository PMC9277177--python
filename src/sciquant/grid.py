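"""Minimal 3D volume container with voxel spacing and NIfTI round-trip.

All images handled by the pipeline (FLAIR, T1, tissue masks, distance maps,
ROI label volumes) live on one shared voxel grid.  Voxel indices are 0-based;
world coordinates follow the NIfTI affine; distances are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "load_volume", "save_volume", "save_mask", "save_labels"]


@dataclass
class VolumeGrid:
    """A 3D scalar image together with its per-axis voxel spacing in mm."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        vs = tuple(float(s) for s in self.voxel_size_mm)
        if len(vs) != 3 or any(s <= 0 for s in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive lengths, got {vs}")
        self.voxel_size_mm = vs
        if self.affine is None:
            aff = np.diag(list(vs) + [1.0])
            self.affine = aff

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )


def load_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI-1 volume, taking spacing from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(np.asarray(data), tuple(float(z) for z in zooms), affine=img.affine)


def save_volume(vol: VolumeGrid, path: str | Path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    """Binary mask written as uint8 NIfTI."""
    save_volume(VolumeGrid(mask.astype(np.uint8), voxel_size_mm), path, dtype=np.uint8)


def save_labels(labels: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    """Integer label volume (one label per candidate lesion) as int32 NIfTI."""
    save_volume(VolumeGrid(labels.astype(np.int32), voxel_size_mm), path, dtype=np.int32)
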