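"""Cortex-referenced intensity thresholding of candidate lesion ROIs.

A lesion is hyperintense on FLAIR relative to the cortical mean and,
under the restrictive reading, additionally iso/hypo-intense on T1.
Both criteria are operationalised as a single multiplier applied to the
participant's mean cortical intensity:

    lower FLAIR threshold = multiplier * mean FLAIR over cortex
    upper T1 threshold    = multiplier * mean T1   over cortex

with multiplier 1.02 by default.  FLAIR voxels inside a candidate ROI at
or above the lower threshold form the lesion mask; of those, voxels at
or below the T1 upper threshold form the T1-surviving subset.  The T1
criterion is evaluated only within FLAIR-surviving voxels, so T1
hypo-intensities outside the FLAIR mask are never captured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid

__all__ = [
    "ThresholdSet",
    "CandidateROI",
    "LesionMask",
    "compute_thresholds",
    "extract_lesion_masks",
    "connectivity_structure",
]

DEFAULT_MULTIPLIER = 1.02


@dataclass(frozen=True)
class ThresholdSet:
    """Cortex means and derived thresholds for one participant."""

    mean_flair_cortex: float
    mean_t1_cortex: float
    multiplier: float = DEFAULT_MULTIPLIER

    @property
    def lower_thr_flair(self) -> float:
        return self.multiplier * self.mean_flair_cortex

    @property
    def upper_thr_t1(self) -> float:
        return self.multiplier * self.mean_t1_cortex


@dataclass
class CandidateROI:
    """A manually identified lesion candidate: voxel set plus a lobe label."""

    roi_id: int
    voxels: np.ndarray  # (N, 3) int voxel indices
    lobe: str

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.intp))
        if self.voxels.size == 0:
            raise ValueError(f"ROI {self.roi_id}: empty voxel set")
        if self.voxels.shape[1] != 3:
            raise ValueError(f"ROI {self.roi_id}: voxels must be (N, 3)")


@dataclass
class LesionMask:
    """Voxels of one identified lesion surviving the intensity thresholds.

    ``flair_voxels`` may be empty when no ROI voxel survived the FLAIR
    threshold; such lesions are recorded but count toward no definition.
    """

    lesion_id: int
    roi_id: int
    lobe: str
    flair_voxels: np.ndarray  # (N, 3)
    t1_voxels: np.ndarray  # (M, 3), subset of flair_voxels
    voxel_size_mm: tuple[float, float, float]
    n_components: int = 0  # connected components inside the ROI (diagnostic)

    @property
    def n_flair_voxels(self) -> int:
        return int(self.flair_voxels.shape[0])

    @property
    def n_t1_voxels(self) -> int:
        return int(self.t1_voxels.shape[0])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def volume_mm3(self) -> float:
        return self.n_flair_voxels * self.voxel_volume_mm3

    @property
    def t1_volume_mm3(self) -> float:
        return self.n_t1_voxels * self.voxel_volume_mm3


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D structuring element for 6-, 18- or 26-connectivity."""
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    return ndimage.generate_binary_structure(3, rank[connectivity])


def compute_thresholds(
    flair: VolumeGrid,
    t1: VolumeGrid,
    cortex_mask: np.ndarray,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> ThresholdSet:
    """Mean cortical intensities and the derived lesion thresholds.

    Raises if the cortex mask is empty, lies outside the grid, or covers
    non-finite intensities.
    """
    cortex_mask = np.asarray(cortex_mask, dtype=bool)
    if cortex_mask.shape != flair.shape or not flair.same_grid(t1):
        raise ValueError("cortex mask, FLAIR and T1 must share one voxel grid")
    if not cortex_mask.any():
        raise ValueError("cortex mask is empty")
    fvals = flair.data[cortex_mask].astype(float)
    tvals = t1.data[cortex_mask].astype(float)
    if not (np.isfinite(fvals).all() and np.isfinite(tvals).all()):
        raise ValueError("non-finite intensities inside the cortex mask")
    return ThresholdSet(
        mean_flair_cortex=float(fvals.mean()),
        mean_t1_cortex=float(tvals.mean()),
        multiplier=float(multiplier),
    )


def _roi_label_volume(shape, rois: list[CandidateROI]) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    for roi in rois:
        idx = tuple(roi.voxels.T)
        if (roi.voxels < 0).any() or any(
            (roi.voxels[:, a] >= shape[a]).any() for a in range(3)
        ):
            raise ValueError(f"ROI {roi.roi_id} lies outside the voxel grid")
        if (labels[idx] != 0).any():
            other = int(labels[idx][labels[idx] != 0][0])
            raise ValueError(f"ROIs {other} and {roi.roi_id} overlap")
        labels[idx] = roi.roi_id
    return labels


def extract_lesion_masks(
    flair: VolumeGrid,
    t1: VolumeGrid,
    rois: list[CandidateROI],
    thr: ThresholdSet,
    connectivity: int = 26,
    min_voxels: int = 1,
) -> list[LesionMask]:
    """Apply the FLAIR and T1 thresholds within each candidate ROI.

    All connected components within one ROI are merged into a single
    lesion mask (one mask per identified lesion); the component count is
    kept as a diagnostic.  Threshold comparisons are inclusive.
    ``min_voxels`` is the minimum number of surviving FLAIR voxels for a
    lesion to be retained as surviving (smaller yields an empty mask).
    """
    if not flair.same_grid(t1):
        raise ValueError("FLAIR and T1 grids do not match")
    ids = [r.roi_id for r in rois]
    if len(set(ids)) != len(ids):
        raise ValueError("roi_ids must be unique within a subject")
    _roi_label_volume(flair.shape, rois)  # validates bounds + overlap

    structure = connectivity_structure(connectivity)
    flair_ok = flair.data >= thr.lower_thr_flair
    t1_ok = t1.data <= thr.upper_thr_t1

    lesions: list[LesionMask] = []
    for lesion_id, roi in enumerate(rois, start=1):
        roi_mask = np.zeros(flair.shape, dtype=bool)
        roi_mask[tuple(roi.voxels.T)] = True
        surviving = roi_mask & flair_ok
        n_surv = int(surviving.sum())
        if n_surv < max(1, min_voxels):
            lesions.append(
                LesionMask(
                    lesion_id=lesion_id,
                    roi_id=roi.roi_id,
                    lobe=roi.lobe,
                    flair_voxels=np.empty((0, 3), dtype=np.intp),
                    t1_voxels=np.empty((0, 3), dtype=np.intp),
                    voxel_size_mm=flair.voxel_size_mm,
                    n_components=0,
                )
            )
            continue
        _, n_comp = ndimage.label(surviving, structure=structure)
        fvox = np.argwhere(surviving)
        t1_sub = surviving & t1_ok
        tvox = np.argwhere(t1_sub)
        lesions.append(
            LesionMask(
                lesion_id=lesion_id,
                roi_id=roi.roi_id,
                lobe=roi.lobe,
                flair_voxels=fvox,
                t1_voxels=tvox,
                voxel_size_mm=flair.voxel_size_mm,
                n_components=int(n_comp),
            )
        )
    return lesions
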