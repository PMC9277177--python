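"""Synthetic brain phantoms with ground-truth white-matter lesions.

The phantom stands in for a scanned, segmented and co-registered
participant: aligned FLAIR and T1 volumes on one voxel grid, tissue
masks (brain, cortical ribbon, white matter, ventricles) built from
nested ellipsoids, and a set of planted lesions, each paired with a
candidate ROI of the kind a neuroradiologist would draw around it.

Lesions are spherical intensity perturbations: inside the lesion the
FLAIR value is ``flair_multiplier`` x the cortical FLAIR base intensity
and the T1 value is ``t1_multiplier`` x the cortical T1 base intensity.
The profile is a uniform plateau by default so that threshold behaviour
is analytically predictable (a multiplier of 1.5 survives a 1.02x
cortical-mean threshold on a noise-free phantom by construction); a
smooth-edge option exists but is off by default.  Phantom lobes are
assigned by quadrant of the white-matter bounding box (anterior/
posterior x superior/inferior), standing in for the neuroradiologist's
lobe label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .definitions import greatest_dimension
from .grid import VolumeGrid
from .regional import REGIONS, RegionalConfig, TissueMasks, build_parcellation
from .thresholds import CandidateROI

__all__ = ["PhantomSpec", "TruthLesion", "generate_phantom", "sample_truth_lesions"]

#: quadrant -> lobe mapping on (anterior?, superior?) relative to the
#: white-matter bounding-box centre
_QUADRANT_LOBE = {
    (True, True): "frontal",
    (False, True): "parietal",
    (True, False): "temporal",
    (False, False): "occipital",
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic participant."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (0.65, 0.65, 1.0)
    #: ellipsoid semi-axes as fractions of the half field of view
    brain_frac: float = 0.92
    cortex_thickness_mm: float = 3.0
    ventricle_semi_axes_mm: tuple[float, float, float] = (6.0, 10.0, 8.0)
    #: base intensities per tissue class, FLAIR then T1
    flair_intensity: dict = field(
        default_factory=lambda: {"cortex": 100.0, "wm": 80.0, "csf": 25.0, "bg": 0.0}
    )
    t1_intensity: dict = field(
        default_factory=lambda: {"cortex": 100.0, "wm": 130.0, "csf": 40.0, "bg": 0.0}
    )
    noise_sd: float = 0.0
    smooth_edges: bool = False
    roi_margin_voxels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be strictly positive")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small for a nested-ellipsoid phantom")


@dataclass
class TruthLesion:
    """A planted lesion and, after generation, its realised ground truth."""

    center_voxel: tuple[int, int, int]
    target_diameter_mm: float
    flair_multiplier: float = 1.5
    t1_multiplier: float = 1.1
    intended_region: str | None = None
    intended_lobe: str | None = None
    # realised after generation
    voxels: np.ndarray | None = None
    realized_diameter_mm: float | None = None
    expect_liberal: bool | None = None
    expect_traditional: bool | None = None
    expect_restrictive: bool | None = None

    def __post_init__(self) -> None:
        if self.target_diameter_mm <= 0:
            raise ValueError("target_diameter_mm must be positive")
        if self.intended_region is not None and self.intended_region not in REGIONS:
            raise ValueError(f"unknown region {self.intended_region!r}")


def _ellipsoid(shape, voxel_size, center_mm, semi_axes_mm) -> np.ndarray:
    coords = [
        (np.arange(n) * s - c) / a
        for n, s, c, a in zip(shape, voxel_size, center_mm, semi_axes_mm)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= 1.0


def _segmentation(spec: PhantomSpec) -> TissueMasks:
    shape = spec.grid_shape
    vs = np.asarray(spec.voxel_size_mm)
    fov = np.asarray(shape) * vs
    center = fov / 2.0
    brain_axes = spec.brain_frac * fov / 2.0
    wm_axes = brain_axes - spec.cortex_thickness_mm
    if (wm_axes <= 0).any():
        raise ValueError("cortex_thickness_mm too large for the grid")
    brain = _ellipsoid(shape, vs, center, brain_axes)
    wm_outer = _ellipsoid(shape, vs, center, wm_axes)
    vent = _ellipsoid(shape, vs, center, np.asarray(spec.ventricle_semi_axes_mm))
    cortex = brain & ~wm_outer
    wm = wm_outer & ~vent
    seg = TissueMasks(
        brain=brain,
        cortex=cortex,
        white_matter=wm,
        ventricles=vent,
        voxel_size_mm=spec.voxel_size_mm,
    )
    seg.validate()
    return seg


def _lesion_voxels(spec: PhantomSpec, lesion: TruthLesion, wm: np.ndarray) -> np.ndarray:
    vs = np.asarray(spec.voxel_size_mm)
    c = np.asarray(lesion.center_voxel, dtype=float)
    r = lesion.target_diameter_mm / 2.0
    half = np.ceil(r / vs).astype(int) + 1
    lo = np.maximum(np.round(c).astype(int) - half, 0)
    hi = np.minimum(np.round(c).astype(int) + half + 1, np.asarray(spec.grid_shape))
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    d2 = (((pts - c) * vs) ** 2).sum(axis=1)
    inside = pts[d2 <= r**2]
    keep = inside[wm[tuple(inside.T)]]
    return keep


def _lobe_of(center_voxel, wm: np.ndarray) -> str:
    idx = np.argwhere(wm)
    mid = (idx.min(axis=0) + idx.max(axis=0)) / 2.0
    anterior = center_voxel[1] >= mid[1]
    superior = center_voxel[2] >= mid[2]
    return _QUADRANT_LOBE[(anterior, superior)]


def generate_phantom(
    spec: PhantomSpec, lesions: list[TruthLesion]
) -> tuple[VolumeGrid, VolumeGrid, TissueMasks, list[CandidateROI], list[TruthLesion]]:
    """Build aligned FLAIR/T1 volumes, tissue masks, candidate ROIs and
    realised ground truth for the requested lesions.

    Raises when a lesion centre falls outside white matter or when two
    lesions (or their ROIs) overlap: phantoms must have separable ground
    truth.
    """
    rng = np.random.default_rng(spec.seed)
    seg = _segmentation(spec)
    wm = seg.white_matter
    flair = np.full(spec.grid_shape, spec.flair_intensity["bg"], dtype=float)
    t1 = np.full(spec.grid_shape, spec.t1_intensity["bg"], dtype=float)
    for tissue, mask in (
        ("cortex", seg.cortex),
        ("wm", wm),
        ("csf", seg.ventricles),
    ):
        flair[mask] = spec.flair_intensity[tissue]
        t1[mask] = spec.t1_intensity[tissue]

    occupied = np.zeros(spec.grid_shape, dtype=bool)
    roi_labels = np.zeros(spec.grid_shape, dtype=np.int32)
    rois: list[CandidateROI] = []
    truth: list[TruthLesion] = []
    for i, lesion in enumerate(lesions, start=1):
        cv = tuple(int(v) for v in lesion.center_voxel)
        if not wm[cv]:
            raise ValueError(
                f"lesion {i} centre {cv} lies outside white matter; "
                "plant lesions inside the white-matter mask"
            )
        vox = _lesion_voxels(spec, lesion, wm)
        if vox.shape[0] == 0:
            raise ValueError(f"lesion {i} realises no voxels at this diameter")
        idx = tuple(vox.T)
        if occupied[idx].any():
            raise ValueError(f"lesion {i} overlaps a previously planted lesion")
        occupied[idx] = True

        fl_val = lesion.flair_multiplier * spec.flair_intensity["cortex"]
        t1_val = lesion.t1_multiplier * spec.t1_intensity["cortex"]
        if spec.smooth_edges:
            bump = np.zeros(spec.grid_shape)
            bump[idx] = 1.0
            bump = ndimage.gaussian_filter(bump, sigma=1.0)
            bump /= bump.max()
            flair += bump * (fl_val - flair)
            t1 += bump * (t1_val - t1)
        else:
            flair[idx] = fl_val
            t1[idx] = t1_val

        # candidate ROI: bounding box dilated by the margin, clipped to brain
        m = spec.roi_margin_voxels
        lo = np.maximum(vox.min(axis=0) - m, 0)
        hi = np.minimum(vox.max(axis=0) + m + 1, np.asarray(spec.grid_shape))
        box = np.zeros(spec.grid_shape, dtype=bool)
        box[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        box &= seg.brain
        if (roi_labels[box] != 0).any():
            raise ValueError(
                f"candidate ROI of lesion {i} overlaps another ROI; "
                "increase lesion separation"
            )
        roi_labels[box] = i
        lobe = lesion.intended_lobe or _lobe_of(cv, wm)
        rois.append(CandidateROI(roi_id=i, voxels=np.argwhere(box), lobe=lobe))

        realized = replace(lesion)
        realized.intended_lobe = lobe
        realized.voxels = vox
        realized.realized_diameter_mm = greatest_dimension(vox, spec.voxel_size_mm)
        realized.expect_liberal = lesion.flair_multiplier >= 1.02
        realized.expect_traditional = (
            realized.expect_liberal and realized.realized_diameter_mm >= 3.0
        )
        realized.expect_restrictive = (
            realized.expect_traditional and lesion.t1_multiplier <= 1.02
        )
        truth.append(realized)

    if spec.noise_sd > 0:
        flair += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        t1 += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    vs = spec.voxel_size_mm
    return VolumeGrid(flair, vs), VolumeGrid(t1, vs), seg, rois, truth


def sample_truth_lesions(
    spec: PhantomSpec,
    rng: np.random.Generator,
    requests: list[dict] | None = None,
    n_lesions: int = 3,
    regional_config: RegionalConfig = RegionalConfig(),
    min_margin_mm: float = 2.0,
    min_separation_mm: float = 12.0,
) -> list[TruthLesion]:
    """Sample lesion placements with guaranteed region ground truth.

    Each request may fix ``intended_region``, ``target_diameter_mm``,
    ``flair_multiplier`` and ``t1_multiplier``; unset fields are drawn at
    random.  Centres are drawn as deep inside the requested regional band
    as the band allows (preferring at least lesion radius +
    ``min_margin_mm`` from the band boundary), and every placement is
    verified to give the intended region a strict majority of the
    realised lesion voxels, so the majority-overlap assignment is
    unambiguous ground truth.  Thin bands (the periventricular shell)
    accept lesions that spill over, as long as the majority holds.
    """
    seg = _segmentation(spec)
    parc = build_parcellation(seg, regional_config)
    wm = seg.white_matter
    vs = np.asarray(spec.voxel_size_mm)
    if requests is None:
        requests = [{} for _ in range(n_lesions)]

    depth = {
        r: ndimage.distance_transform_edt(parc.mask(r), sampling=vs) for r in REGIONS
    }
    chosen: list[TruthLesion] = []
    centers_mm: list[np.ndarray] = []
    for req in requests:
        region = req.get("intended_region") or str(rng.choice(REGIONS))
        diam = float(req.get("target_diameter_mm") or rng.uniform(3.6, 6.0))
        fmul = float(req.get("flair_multiplier", 1.5))
        tmul = float(req.get("t1_multiplier", 1.1))
        radius = diam / 2.0
        max_depth = depth[region].max()
        levels = [
            need
            for need in (radius + min_margin_mm, radius, 0.5 * radius, 0.8 * max_depth)
            if need <= max_depth
        ] or [0.8 * max_depth]
        placed = None
        for need in levels:
            cand = np.argwhere(depth[region] >= need)
            if cand.shape[0] == 0:
                continue
            for _ in range(500):
                c = cand[rng.integers(cand.shape[0])]
                c_mm = c * vs
                if any(
                    np.linalg.norm(c_mm - prev) < min_separation_mm
                    for prev in centers_mm
                ):
                    continue
                probe = TruthLesion(
                    center_voxel=tuple(int(v) for v in c), target_diameter_mm=diam
                )
                vox = _lesion_voxels(spec, probe, wm)
                if vox.shape[0] == 0:
                    continue
                idx = tuple(vox.T)
                counts = {r: int(parc.mask(r)[idx].sum()) for r in REGIONS}
                if counts[region] > max(v for r, v in counts.items() if r != region):
                    placed = c
                    break
            if placed is not None:
                break
        if placed is None:
            raise ValueError(
                f"could not place a {diam:.1f} mm {region} lesion with the "
                "required separation and an unambiguous majority region"
            )
        c, c_mm = placed, placed * vs
        centers_mm.append(c_mm)
        chosen.append(
            TruthLesion(
                center_voxel=tuple(int(v) for v in c),
                target_diameter_mm=diam,
                flair_multiplier=fmul,
                t1_multiplier=tmul,
                intended_region=region,
            )
        )
    return chosen
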