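"""Lesion size measurement, nested radiological definitions, subject metrics.

Three nested definitions of silent cerebral infarction are applied to each
thresholded lesion mask:

* liberal       — any FLAIR-surviving voxels, no size requirement;
* traditional   — liberal and greatest dimension >= 3 mm (the SIT-trial
                  criterion, inclusive at the boundary);
* restrictive   — traditional and at least one T1-surviving voxel.

Greatest dimension is a caliper (edge-to-edge) measurement: the maximum
Euclidean distance between corner vertices of the lesion's voxels, which
mirrors an on-screen manual measurement and keeps a 5-voxel row of
0.65 mm voxels above the 3 mm cut where a centre-to-centre rule would
not.  The default mode restricts the measurement to single coronal
slices (the plane the source measurement was made in), projecting out
the through-slice extent; a full 3D mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thresholds import LesionMask

__all__ = [
    "DefinitionFlags",
    "SubjectProfile",
    "LesionRecord",
    "greatest_dimension",
    "classify_definitions",
    "per_decade_abnormal",
    "aggregate_subject",
    "DEFINITIONS",
]

DEFINITIONS = ("liberal", "traditional", "restrictive")

#: axis index held fixed by a coronal slice (anterior-posterior axis)
CORONAL_AXIS = 1

_CORNER_OFFSETS = np.array(
    [[dx, dy, dz] for dx in (-0.5, 0.5) for dy in (-0.5, 0.5) for dz in (-0.5, 0.5)]
)


@dataclass(frozen=True)
class DefinitionFlags:
    liberal: bool
    traditional: bool
    restrictive: bool
    greatest_dimension_mm: float

    def __post_init__(self) -> None:
        if self.restrictive and not self.traditional:
            raise ValueError("restrictive implies traditional")
        if self.traditional and not self.liberal:
            raise ValueError("traditional implies liberal")

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (self.liberal, self.traditional, self.restrictive)


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Maximum Euclidean distance over a point cloud (uses the convex hull
    for large clouds; exact either way)."""
    if points.shape[0] > 400:
        from scipy.spatial import ConvexHull

        uniq = np.unique(points, axis=0)
        try:
            hull = ConvexHull(uniq)
            points = uniq[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) clouds
            points = uniq
    diffs = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diffs**2).sum(axis=-1)).max())


def greatest_dimension(
    lesion: LesionMask | np.ndarray,
    voxel_size_mm=None,
    mode: str = "coronal_in_plane",
    coronal_axis: int = CORONAL_AXIS,
) -> float:
    """Caliper greatest dimension of a lesion in mm.

    Accepts a LesionMask (using its FLAIR voxels and spacing) or a raw
    (N, 3) voxel index array plus ``voxel_size_mm``.
    """
    if isinstance(lesion, LesionMask):
        voxels = lesion.flair_voxels
        voxel_size_mm = lesion.voxel_size_mm
    else:
        voxels = np.atleast_2d(np.asarray(lesion))
    if voxels.shape[0] == 0:
        raise ValueError("cannot measure an empty lesion")
    spacing = np.asarray(voxel_size_mm, dtype=float)
    if mode == "3d":
        corners = (voxels[:, None, :] + _CORNER_OFFSETS[None, :, :]).reshape(-1, 3)
        return _max_pairwise_distance(corners * spacing)
    if mode != "coronal_in_plane":
        raise ValueError(f"unknown mode {mode!r}")
    in_plane = [a for a in range(3) if a != coronal_axis]
    best = 0.0
    for s in np.unique(voxels[:, coronal_axis]):
        sl = voxels[voxels[:, coronal_axis] == s][:, in_plane]
        off2 = np.array([[dx, dz] for dx in (-0.5, 0.5) for dz in (-0.5, 0.5)])
        corners = (sl[:, None, :] + off2[None, :, :]).reshape(-1, 2)
        corners = np.unique(corners, axis=0) * spacing[in_plane]
        pad = np.zeros((corners.shape[0], 3))
        pad[:, :2] = corners
        best = max(best, _max_pairwise_distance(pad))
    return best


def classify_definitions(
    lesion: LesionMask,
    min_dimension_mm: float = 3.0,
    mode: str = "coronal_in_plane",
) -> DefinitionFlags:
    """Nested liberal/traditional/restrictive flags for one lesion."""
    liberal = lesion.n_flair_voxels >= 1
    if not liberal:
        return DefinitionFlags(False, False, False, 0.0)
    dim = greatest_dimension(lesion, mode=mode)
    traditional = dim >= min_dimension_mm
    restrictive = traditional and lesion.n_t1_voxels >= 1
    return DefinitionFlags(liberal, traditional, restrictive, dim)


def per_decade_abnormal(n_lesions: int, age_years: float) -> bool:
    """Abnormal lesion burden for age: more than one lesion per decade of
    life, with the current (partially elapsed) decade counting."""
    if n_lesions < 0 or age_years < 0:
        raise ValueError("n_lesions and age_years must be non-negative")
    decades = int(age_years // 10) + 1
    return n_lesions > decades


@dataclass
class LesionRecord:
    """One lesion with its flags and (optional) regional attribution."""

    lesion_id: int
    roi_id: int
    lobe: str
    flags: DefinitionFlags
    volume_mm3: float
    t1_volume_mm3: float
    n_flair_voxels: int
    n_t1_voxels: int
    region: str | None = None
    region_tie: bool = False
    regional_volumes_mm3: dict[str, float] = field(default_factory=dict)
    t1_regional_volumes_mm3: dict[str, float] = field(default_factory=dict)


@dataclass
class SubjectProfile:
    """Per-subject global lesion metrics under each definition, plus
    demographics and cognition where supplied."""

    subject_id: str
    group: str | None = None
    age_years: float | None = None
    n_lesions: dict[str, int] = field(default_factory=dict)
    volume_mm3: dict[str, float] = field(default_factory=dict)
    n_voxels: dict[str, int] = field(default_factory=dict)
    presence: dict[str, bool] = field(default_factory=dict)
    per_decade_abnormal: dict[str, bool] = field(default_factory=dict)
    lesions: list[LesionRecord] = field(default_factory=list)
    cognition: dict[str, float] = field(default_factory=dict)
    impaired: bool | None = None
    covariates: dict[str, float] = field(default_factory=dict)


def aggregate_subject(
    subject_id: str,
    lesions: list[tuple[LesionMask, DefinitionFlags]],
    group: str | None = None,
    age_years: float | None = None,
    cognition: dict[str, float] | None = None,
    covariates: dict[str, float] | None = None,
) -> SubjectProfile:
    """Aggregate one subject's lesions into per-definition global metrics.

    Counts sum lesions whose flag is true; volumes sum the FLAIR mask
    volume for the liberal and traditional definitions and the
    T1-surviving volume for the restrictive definition.  Cognitive
    impairment is any of IQ/WMI/PSI below 70.
    """
    ids = [m.lesion_id for m, _ in lesions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lesion_ids within one subject")
    profile = SubjectProfile(subject_id=subject_id, group=group, age_years=age_years)
    for d in DEFINITIONS:
        profile.n_lesions[d] = 0
        profile.volume_mm3[d] = 0.0
        profile.n_voxels[d] = 0
    for mask, flags in lesions:
        rec = LesionRecord(
            lesion_id=mask.lesion_id,
            roi_id=mask.roi_id,
            lobe=mask.lobe,
            flags=flags,
            volume_mm3=mask.volume_mm3,
            t1_volume_mm3=mask.t1_volume_mm3,
            n_flair_voxels=mask.n_flair_voxels,
            n_t1_voxels=mask.n_t1_voxels,
        )
        profile.lesions.append(rec)
        for d in DEFINITIONS:
            if getattr(flags, d):
                profile.n_lesions[d] += 1
                if d == "restrictive":
                    profile.volume_mm3[d] += mask.t1_volume_mm3
                    profile.n_voxels[d] += mask.n_t1_voxels
                else:
                    profile.volume_mm3[d] += mask.volume_mm3
                    profile.n_voxels[d] += mask.n_flair_voxels
    for d in DEFINITIONS:
        profile.presence[d] = profile.n_lesions[d] >= 1
        if age_years is not None:
            profile.per_decade_abnormal[d] = per_decade_abnormal(
                profile.n_lesions[d], age_years
            )
    if cognition:
        profile.cognition = dict(cognition)
        scores = [cognition.get(k) for k in ("iq", "wmi", "psi")]
        scores = [s for s in scores if s is not None]
        if scores:
            profile.impaired = min(scores) < 70
    if covariates:
        profile.covariates = dict(covariates)
    return profile
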