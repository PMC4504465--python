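"""SAT / IMAT / muscle / bone compartments and the intramuscular fat fraction.

Given the fitted limb and fascia contours plus the raw tissue clustering of
a slice, the slice is partitioned into subcutaneous adipose tissue (SAT =
fat-class pixels between the two contours), intramuscular adipose tissue
(IMAT = fat-class pixels inside the fascia, excluding bone), muscle
(muscle-class pixels inside the fascia, excluding bone), bone (cortical
ring plus marrow), and outside.  The quantitative outcome is the
intramuscular fat fraction

    fat fraction = |IMAT| / (|IMAT| + |muscle|)

by pixel count, computed per slice and aggregated as the mean over the 20
middle slices of the volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .active_contour import Contour
from .errors import GeometryError, UndefinedFractionError
from .tissue_clustering import BACKGROUND, FAT, MUSCLE, TissueLabelMap

# compartment codes
OUTSIDE = 0
SAT = 1
IMAT = 2
MUSCLE_C = 3
BONE = 4

COMPARTMENT_NAMES = {
    OUTSIDE: "outside",
    SAT: "SAT",
    IMAT: "IMAT",
    MUSCLE_C: "muscle",
    BONE: "bone",
}


@dataclass
class CompartmentMasks:
    labels: np.ndarray  # (H, W) int in {OUTSIDE, SAT, IMAT, MUSCLE_C, BONE}
    source: str = "automatic"  # or "manual_corrected"

    def count(self, code: int) -> int:
        return int((self.labels == code).sum())

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class FatFractionResult:
    per_slice_fraction: list[float]
    aggregate_fraction: float | None = None
    slices_used: list[int] = field(default_factory=list)
    failure_flags: list[list[str]] = field(default_factory=list)
    source: str = "automatic"
    warnings: list[str] = field(default_factory=list)


def detect_bone(
    image: np.ndarray, tmap: TissueLabelMap, muscle_contour: Contour
) -> np.ndarray:
    """Locate the femur inside the fascia contour.

    Cortical bone clusters with the dark background class; marrow is bright
    and clusters with fat.  The femur is therefore the dark connected
    component inside the muscle contour whose filled interior contains a
    bright (fat-class) marrow core.  The returned mask is the filled bone
    (cortical + marrow).  When no candidate qualifies an empty mask is
    returned with a warning (lower-leg anatomy, or a segmentation problem).
    """
    inside = muscle_contour.to_mask(tmap.labels.shape)
    dark_inside = (tmap.labels == BACKGROUND) & inside
    cc, m = ndi.label(dark_inside)
    best: np.ndarray | None = None
    best_size = 0
    for j in range(1, m + 1):
        comp = cc == j
        filled = ndi.binary_fill_holes(comp)
        core = filled & ~comp
        if core.any() and (tmap.labels[core] == FAT).mean() > 0.5:
            size = int(filled.sum())
            if size > best_size:
                best, best_size = filled, size
    if best is None:
        warnings.warn(
            "no bone candidate found inside the muscle contour", stacklevel=2
        )
        return np.zeros(tmap.labels.shape, dtype=bool)
    return best


def partition_compartments(
    tmap: TissueLabelMap,
    limb: Contour,
    muscle: Contour,
    bone: np.ndarray | None = None,
) -> CompartmentMasks:
    """Combine contours and (raw) tissue classes into compartment masks.

    SAT is the fat class between the limb and fascia contours; IMAT and
    muscle are the fat and muscle classes inside the fascia minus bone.
    Pixels that fit no compartment (skin rim, noise specks outside the fat
    and muscle classes) are coded ``outside``.
    """
    shape = tmap.labels.shape
    limb_mask = limb.to_mask(shape)
    fascia_mask = muscle.to_mask(shape)
    protruding = (fascia_mask & ~limb_mask).sum()
    if protruding > 0.02 * max(fascia_mask.sum(), 1):
        raise GeometryError("muscle contour is not inside the limb contour")
    if bone is None:
        bone = np.zeros(shape, dtype=bool)

    out = np.full(shape, OUTSIDE, dtype=np.int16)
    between = limb_mask & ~fascia_mask
    out[between & (tmap.labels == FAT)] = SAT
    interior = fascia_mask & ~bone
    out[interior & (tmap.labels == FAT)] = IMAT
    out[interior & (tmap.labels == MUSCLE)] = MUSCLE_C
    out[bone & limb_mask] = BONE
    return CompartmentMasks(labels=out, source="automatic")


def fat_fraction(masks: CompartmentMasks) -> float:
    """Intramuscular fat fraction |IMAT| / (|IMAT| + |muscle|)."""
    imat = masks.count(IMAT)
    musc = masks.count(MUSCLE_C)
    if imat + musc == 0:
        raise UndefinedFractionError(
            "IMAT and muscle masks both empty — fraction undefined"
        )
    return imat / (imat + musc)


def middle_slice_indices(n_slices: int, n_middle: int = 20) -> list[int]:
    """Indices of the ``n_middle`` slices centered on the stack midpoint,
    shifted toward the proximal end when the split is uneven."""
    if n_slices <= n_middle:
        return list(range(n_slices))
    start = (n_slices - n_middle) // 2
    return list(range(start, start + n_middle))


def aggregate_fraction(
    per_slice: FatFractionResult, n_middle: int = 20
) -> FatFractionResult:
    """Aggregate per-slice fractions as the mean over the middle slices.

    Flagged slices are excluded; when fewer than ``n_middle`` unflagged
    slices are available inside the central window, all unflagged slices
    are used and a warning is recorded.
    """
    n = len(per_slice.per_slice_fraction)
    flags = per_slice.failure_flags or [[] for _ in range(n)]
    valid = [i for i in range(n) if not flags[i]]
    if not valid:
        raise UndefinedFractionError("no valid slice to aggregate")
    window = middle_slice_indices(n, n_middle)
    used = [i for i in window if i in set(valid)]
    warn = list(per_slice.warnings)
    if len(used) < min(n_middle, n):
        used = valid
        warn.append(
            f"fewer than {n_middle} valid middle slices; aggregated over "
            f"all {len(valid)} valid slices"
        )
    agg = float(np.mean([per_slice.per_slice_fraction[i] for i in used]))
    return FatFractionResult(
        per_slice_fraction=list(per_slice.per_slice_fraction),
        aggregate_fraction=agg,
        slices_used=used,
        failure_flags=flags,
        source=per_slice.source,
        warnings=warn,
    )


def flag_failure(
    masks: CompartmentMasks,
    tmap: TissueLabelMap,
    min_fascia_fraction: float = 0.2,
    max_touch_fraction: float = 0.02,
    boundary_support_radius_px: int = 5,
    max_unsupported_fraction: float = 0.2,
) -> tuple[bool, list[str]]:
    """Heuristics for slices where the automatic SAT/IMAT delimitation is
    untrustworthy (typically severe infiltration merging SAT with deep fat).

    Flags when (a) the fascia-enclosed area is implausibly small relative
    to the limb, (b) the SAT ring is non-annular (the fascia touches the
    limb boundary), or (c) too much of the fascia boundary runs through
    fat with no muscle-class pixel within ``boundary_support_radius_px``
    — i.e. fat bridges SAT and intramuscular fat across the fascia with no
    local evidence of where the boundary should sit.  Moth-eaten speckle
    at ordinary levels keeps muscle pixels close to the whole boundary and
    is not flagged; confluent infiltration merging with the SAT ring is.
    """
    reasons: list[str] = []
    lab = masks.labels
    fascia = (lab == IMAT) | (lab == MUSCLE_C) | (lab == BONE)
    limb_area = fascia.sum() + (lab == SAT).sum()
    if (lab == MUSCLE_C).sum() == 0:
        reasons.append("empty muscle compartment")
    if limb_area == 0:
        return True, reasons + ["empty limb"]
    if fascia.sum() < min_fascia_fraction * limb_area:
        reasons.append("muscle compartment too small relative to limb")

    outside = lab == OUTSIDE
    boundary = fascia & ndi.binary_dilation(~fascia)
    touching = fascia & ndi.binary_dilation(outside & _border_connected(outside))
    if boundary.any() and touching.sum() > max_touch_fraction * boundary.sum():
        reasons.append("muscle contour touches limb contour (no SAT ring)")

    from skimage.morphology import disk

    muscle_near = ndi.binary_dilation(
        tmap.labels == MUSCLE, structure=disk(boundary_support_radius_px)
    )
    if boundary.any():
        unsupported = (boundary & ~muscle_near).sum() / boundary.sum()
        if unsupported > max_unsupported_fraction:
            reasons.append("SAT/IMAT delimitation (fat bridge across fascia)")
    return bool(reasons), reasons


def _border_connected(mask: np.ndarray) -> np.ndarray:
    cc, m = ndi.label(mask)
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    ids = np.unique(cc[border & mask])
    return np.isin(cc, ids[ids > 0])


def apply_manual_contours(
    image: np.ndarray,
    tmap: TissueLabelMap,
    manual_limb: Contour,
    manual_muscle: Contour,
) -> FatFractionResult:
    """Fallback when automatic segmentation fails: recompute the fat
    fraction of the mid-portion slice from manually drawn contours.

    The supplied contours replace the snake output; bone detection and the
    compartment partition run unchanged.  The result covers this single
    slice only (no multi-slice aggregation).
    """
    from shapely.geometry import Polygon

    p_limb = Polygon(manual_limb.points)
    p_musc = Polygon(manual_muscle.points)
    if not (p_limb.is_valid and p_musc.is_valid):
        raise GeometryError("manual contour is not a simple closed polygon")
    if p_limb.within(p_musc):
        raise GeometryError("manual limb contour lies inside the muscle contour")
    if not p_musc.within(p_limb.buffer(1.0)):
        raise GeometryError("manual muscle contour is not inside the limb contour")

    bone = detect_bone(image, tmap, manual_muscle)
    masks = partition_compartments(tmap, manual_limb, manual_muscle, bone)
    masks.source = "manual_corrected"
    frac = fat_fraction(masks)
    return FatFractionResult(
        per_slice_fraction=[frac],
        aggregate_fraction=frac,
        slices_used=[0],
        failure_flags=[[]],
        source="manual_corrected",
    )
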