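"""Periventricular / deep / juxta-cortical parcellation and bullseye zones.

White matter is partitioned per participant using percentile thresholds
on Euclidean distance maps rather than fixed millimetre rules (which
derive from older adults and transfer poorly to a paediatric/young-adult
sample):

* periventricular — white-matter voxels whose distance to the ventricles
  is at or below the 5th percentile of that distance over white matter;
* juxta-cortical — of the remaining white matter, voxels whose distance
  to the cortex is at or below the 75th percentile of that distance over
  the remaining white matter;
* deep — everything else.

The three masks are pairwise disjoint and partition white matter by
construction.  Distance transforms are anisotropy-aware (mm, not
voxels).  Lesions are assigned to the region holding the strict majority
of their FLAIR voxels; ties are surfaced, never silently broken.
Crossing the 3 regions with 4 lobes (frontal, parietal, temporal,
occipital; lobe labels travel with the candidate ROI) yields the 12-zone
bullseye summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .definitions import DEFINITIONS, SubjectProfile
from .thresholds import LesionMask

__all__ = [
    "RegionalConfig",
    "RegionalParcellation",
    "TissueMasks",
    "distance_map",
    "build_parcellation",
    "assign_region",
    "regional_volumes",
    "bullseye",
    "REGIONS",
    "LOBES",
]

REGIONS = ("periventricular", "deep", "juxta-cortical")
LOBES = ("frontal", "parietal", "temporal", "occipital")


@dataclass
class TissueMasks:
    """Binary tissue masks on the shared grid."""

    brain: np.ndarray
    cortex: np.ndarray
    white_matter: np.ndarray
    ventricles: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def validate(self) -> None:
        for name in ("cortex", "white_matter", "ventricles"):
            m = getattr(self, name)
            if m.shape != self.brain.shape:
                raise ValueError(f"{name} mask shape mismatch")
            if (m & ~self.brain).any():
                raise ValueError(f"{name} extends outside the brain mask")
        overlap = (
            (self.cortex & self.white_matter)
            | (self.cortex & self.ventricles)
            | (self.white_matter & self.ventricles)
        )
        if overlap.any():
            raise ValueError("tissue classes overlap")


@dataclass(frozen=True)
class RegionalConfig:
    pv_percentile: float = 5.0
    jc_percentile: float = 75.0
    #: compute the juxta-cortical quantile over WM minus the periventricular
    #: mask (the stated exclusion order) or over all WM (sensitivity check)
    quantile_domain: str = "post_exclusion"

    def __post_init__(self) -> None:
        for p in (self.pv_percentile, self.jc_percentile):
            if not 0 < p < 100:
                raise ValueError(f"percentiles must lie in (0, 100), got {p}")
        if self.quantile_domain not in ("post_exclusion", "all_wm"):
            raise ValueError("quantile_domain must be post_exclusion or all_wm")


@dataclass
class RegionalParcellation:
    pv_mask: np.ndarray
    deep_mask: np.ndarray
    jc_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def mask(self, region: str) -> np.ndarray:
        return {
            "periventricular": self.pv_mask,
            "deep": self.deep_mask,
            "juxta-cortical": self.jc_mask,
        }[region]

    @property
    def white_matter(self) -> np.ndarray:
        return self.pv_mask | self.deep_mask | self.jc_mask


def distance_map(
    target_mask: np.ndarray,
    voxel_size_mm,
    domain: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel Euclidean distance in mm to the nearest target voxel.

    Distances are computed with anisotropic sampling; outside ``domain``
    (when given) values are NaN.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if not target_mask.any():
        raise ValueError("target mask is empty")
    dist = ndimage.distance_transform_edt(~target_mask, sampling=voxel_size_mm)
    if domain is not None:
        dist = np.where(np.asarray(domain, dtype=bool), dist, np.nan)
    return dist


def build_parcellation(
    segmentation: TissueMasks, cfg: RegionalConfig = RegionalConfig()
) -> RegionalParcellation:
    """Percentile-thresholded distance-map parcellation of white matter."""
    segmentation.validate()
    wm = segmentation.white_matter.astype(bool)
    if not wm.any():
        raise ValueError("white matter mask is empty")
    if not segmentation.ventricles.any() or not segmentation.cortex.any():
        raise ValueError("ventricle and cortex masks must be non-empty")
    vs = segmentation.voxel_size_mm

    d_vent = distance_map(segmentation.ventricles, vs)
    pv_thr = np.quantile(d_vent[wm], cfg.pv_percentile / 100.0)
    pv = wm & (d_vent <= pv_thr)

    remaining = wm & ~pv
    d_cort = distance_map(segmentation.cortex, vs)
    jc_domain = remaining if cfg.quantile_domain == "post_exclusion" else wm
    jc_thr = np.quantile(d_cort[jc_domain], cfg.jc_percentile / 100.0)
    jc = remaining & (d_cort <= jc_thr)

    deep = remaining & ~jc
    for name, m in (("periventricular", pv), ("juxta-cortical", jc), ("deep", deep)):
        if not m.any():
            warnings.warn(f"{name} mask is empty (degenerate geometry)", stacklevel=2)
    return RegionalParcellation(pv_mask=pv, deep_mask=deep, jc_mask=jc, voxel_size_mm=vs)


def _region_counts(lesion: LesionMask, parc: RegionalParcellation) -> dict[str, int]:
    idx = tuple(lesion.flair_voxels.T)
    return {r: int(parc.mask(r)[idx].sum()) for r in REGIONS}


def assign_region(
    lesion: LesionMask, parc: RegionalParcellation
) -> tuple[str | None, bool, tuple[str, ...]]:
    """Region holding the strict maximum of the lesion's FLAIR voxels.

    Returns ``(region, tie_flag, tied_regions)``.  On a tie the region is
    None and the tied candidates are returned for human adjudication.
    """
    if lesion.n_flair_voxels == 0:
        raise ValueError(f"lesion {lesion.lesion_id} has no FLAIR voxels")
    counts = _region_counts(lesion, parc)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(
            f"lesion {lesion.lesion_id} has no overlap with white matter "
            f"(voxels: {lesion.n_flair_voxels})"
        )
    best = max(counts.values())
    tied = tuple(r for r in REGIONS if counts[r] == best)
    if len(tied) > 1:
        return None, True, tied
    return tied[0], False, tied


def regional_volumes(
    lesion: LesionMask, parc: RegionalParcellation, use_t1_voxels: bool = False
) -> dict[str, float]:
    """Lesion volume (mm^3) falling in each region, allowing within-lesion
    overlap between regions; the values sum to the lesion's white-matter
    volume."""
    voxels = lesion.t1_voxels if use_t1_voxels else lesion.flair_voxels
    if voxels.shape[0] == 0:
        return {r: 0.0 for r in REGIONS}
    idx = tuple(voxels.T)
    vv = lesion.voxel_volume_mm3
    return {r: float(parc.mask(r)[idx].sum()) * vv for r in REGIONS}


def _zone_frame() -> pd.DataFrame:
    return pd.DataFrame(0.0, index=list(REGIONS), columns=list(LOBES))


def bullseye(
    profiles: list[SubjectProfile],
    definition: str = "liberal",
    metric: str = "participants",
) -> pd.DataFrame:
    """Group-level 12-zone bullseye table (regions x lobes).

    Metrics: ``participants`` — percent of the group with lesion voxels in
    the zone; ``count_share`` — percent of the group's lesion count
    attributed to the zone (majority region x ROI lobe; unresolved ties
    excluded); ``volume_share`` — percent of the group's lesion voxel
    volume in the zone.  Shares are percentages summing to 100 when any
    lesion exists; the frame carries ``n_ties_excluded`` in ``attrs``.
    """
    if definition not in DEFINITIONS:
        raise ValueError(f"unknown definition {definition!r}")
    if metric not in ("participants", "count_share", "volume_share"):
        raise ValueError(f"unknown metric {metric!r}")
    if not profiles:
        raise ValueError("need at least one subject profile")
    use_t1 = definition == "restrictive"
    table = _zone_frame()
    ties_excluded = 0

    if metric == "participants":
        for prof in profiles:
            hit = _zone_frame()
            for les in prof.lesions:
                if not getattr(les.flags, definition):
                    continue
                vols = (
                    les.t1_regional_volumes_mm3 if use_t1 else les.regional_volumes_mm3
                )
                for region, v in vols.items():
                    if v > 0 and les.lobe in LOBES:
                        hit.loc[region, les.lobe] = 1.0
            table += hit
        return _finish(100.0 * table / len(profiles), 0)

    for prof in profiles:
        for les in prof.lesions:
            if not getattr(les.flags, definition):
                continue
            if metric == "count_share":
                if les.region_tie or les.region is None:
                    ties_excluded += 1
                    continue
                if les.lobe in LOBES:
                    table.loc[les.region, les.lobe] += 1.0
            else:
                vols = (
                    les.t1_regional_volumes_mm3 if use_t1 else les.regional_volumes_mm3
                )
                for region, v in vols.items():
                    if les.lobe in LOBES:
                        table.loc[region, les.lobe] += v
    total = table.values.sum()
    if total > 0:
        table = 100.0 * table / total
    return _finish(table, ties_excluded)


def _finish(table: pd.DataFrame, ties_excluded: int) -> pd.DataFrame:
    table.attrs["n_ties_excluded"] = ties_excluded
    return table
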