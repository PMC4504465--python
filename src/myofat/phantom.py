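"""Synthetic thigh MR phantoms and synthetic cohort score tables.

The phantom emulates the T1-weighted contrast of an axial thigh slice:
subcutaneous fat and bone marrow are bright, muscle is mid-gray, skin is
slightly darker than muscle, and cortical bone and background are dark.
Geometry is a set of nested circles — skin rim, SAT ring, fascia-enclosed
muscle compartment, femur (cortical ring + marrow) — with "moth-eaten"
intramuscular fat speckle at a controllable fraction, an optional
proximal-to-distal infiltration gradient, Rician noise and a smooth
multiplicative intensity-inhomogeneity (bias) field.

Every phantom carries its exact ground truth: a per-pixel compartment label
map, the per-slice true fat fraction IMAT/(IMAT+muscle) computed from the
labels, and the true limb and fascia contours as polygons.

Coordinate convention (used package-wide): pixels are centered, 0-based,
row-major; polygon points are (x, y) = (column, row).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import InvalidSpecError

# ground-truth compartment codes
GT_OUTSIDE = 0
GT_SKIN = 1
GT_SAT = 2
GT_MUSCLE = 3
GT_IMAT = 4
GT_CORTICAL_BONE = 5
GT_MARROW = 6
GT_VESSEL = 7

GT_NAMES = {
    GT_OUTSIDE: "outside",
    GT_SKIN: "skin",
    GT_SAT: "SAT",
    GT_MUSCLE: "muscle",
    GT_IMAT: "IMAT",
    GT_CORTICAL_BONE: "cortical_bone",
    GT_MARROW: "marrow",
    GT_VESSEL: "vessel",
}

DEFAULT_INTENSITY_MEANS = {
    "fat": 230.0,
    "marrow": 215.0,
    "muscle": 110.0,
    "skin": 70.0,
    "cortical_bone": 12.0,
    "background": 8.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic thigh volume.

    ``gradient``, when given, is a ``(proximal_fraction, distal_fraction)``
    pair; the per-slice IMAT target is linearly interpolated between the two
    endpoints and overrides ``imat_fraction_target``.  The defaults for that
    gradient elsewhere in the package are the proximal/distal infiltration
    levels typical of fatty-infiltrated thighs (≈ 12% proximal, ≈ 27% distal).
    """

    image_size: int = 160
    limb_radius: float = 70.0
    sat_thickness: float = 12.0
    skin_thickness: float = 2.0
    bone_center: tuple[float, float] | None = None  # (x, y); default = slice center
    bone_outer_radius: float = 13.0
    marrow_radius: float = 7.0
    imat_fraction_target: float = 0.2
    speckle_grain: float = 2.5
    n_slices: int = 1
    gradient: tuple[float, float] | None = None
    intensity_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS)
    )
    noise_sigma: float = 0.0
    bias_field_amplitude: float = 0.0
    n_vessels: int = 0
    vessel_radius: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sat_thickness + self.bone_outer_radius >= self.limb_radius:
            raise InvalidSpecError(
                "geometry does not nest: sat_thickness + bone_outer_radius "
                f"({self.sat_thickness} + {self.bone_outer_radius}) must be "
                f"< limb_radius ({self.limb_radius})"
            )
        if self.marrow_radius >= self.bone_outer_radius:
            raise InvalidSpecError(
                f"marrow_radius ({self.marrow_radius}) must be < "
                f"bone_outer_radius ({self.bone_outer_radius})"
            )
        targets = [self.imat_fraction_target]
        if self.gradient is not None:
            targets = list(self.gradient)
        for t in targets:
            if not (0.0 <= t <= 0.95):
                raise InvalidSpecError(
                    f"imat fraction target {t} outside [0, 0.95]"
                )
        if 2 * self.limb_radius >= self.image_size:
            raise InvalidSpecError(
                f"limb (diameter {2 * self.limb_radius}) does not fit in a "
                f"{self.image_size}-px slice"
            )
        m = self.intensity_means
        order = ["fat", "marrow", "muscle", "skin", "cortical_bone"]
        vals = [m[k] for k in order]
        if not all(a > b for a, b in zip(vals, vals[1:])):
            raise InvalidSpecError(
                "intensity means must be strictly ordered "
                "fat > marrow > muscle > skin > cortical_bone; got "
                + ", ".join(f"{k}={m[k]}" for k in order)
            )
        if self.n_slices < 1:
            raise InvalidSpecError("n_slices must be >= 1")
        if self.speckle_grain <= 0:
            raise InvalidSpecError("speckle_grain must be > 0")

    def slice_targets(self) -> np.ndarray:
        """Per-slice IMAT fraction targets (proximal = slice 0)."""
        if self.gradient is None:
            return np.full(self.n_slices, self.imat_fraction_target)
        lo, hi = self.gradient
        if self.n_slices == 1:
            return np.array([(lo + hi) / 2.0])
        return np.linspace(lo, hi, self.n_slices)


@dataclass
class GroundTruth:
    """Exact per-pixel truth for a rendered phantom volume."""

    label_volume: np.ndarray            # (n_slices, H, W) int codes GT_*
    true_fat_fraction_per_slice: np.ndarray
    true_limb_contour: np.ndarray       # (n_points, 2) float (x, y)
    true_muscle_contour: np.ndarray     # fascia boundary polygon

    def fraction_from_labels(self) -> np.ndarray:
        imat = (self.label_volume == GT_IMAT).sum(axis=(1, 2))
        muscle = (self.label_volume == GT_MUSCLE).sum(axis=(1, 2))
        denom = imat + muscle
        return np.where(denom > 0, imat / np.maximum(denom, 1), 0.0)


def _circle_polygon(cx: float, cy: float, r: float, n: int = 50) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _speckle_mask(
    muscle_mask: np.ndarray, fraction: float, grain: float, rng: np.random.Generator
) -> np.ndarray:
    """'Moth-eaten' infiltration: threshold a smoothed random field at the
    quantile that converts exactly the requested fraction of the muscle
    compartment into fat speckle (up to grain quantization)."""
    if fraction <= 0:
        return np.zeros_like(muscle_mask)
    noise = rng.standard_normal(muscle_mask.shape)
    fld = gaussian_filter(noise, sigma=grain)
    vals = fld[muscle_mask]
    thr = np.quantile(vals, 1.0 - fraction)
    return muscle_mask & (fld > thr)


def make_thigh_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic thigh volume with its ground truth.

    Returns
    -------
    volume : (n_slices, H, W) float array of noisy T1-like intensities.
    truth : GroundTruth consistent with the pre-noise rendering.

    Same spec (including seed) gives bit-identical output.
    """
    n = spec.image_size
    c = (n - 1) / 2.0
    bx, by = spec.bone_center if spec.bone_center is not None else (c, c)
    yy, xx = np.mgrid[0:n, 0:n]
    r_limb = np.hypot(xx - c, yy - c)
    r_bone = np.hypot(xx - bx, yy - by)

    fascia_radius = spec.limb_radius - spec.skin_thickness - spec.sat_thickness
    sat_outer = spec.limb_radius - spec.skin_thickness

    base = np.full((n, n), GT_OUTSIDE, dtype=np.int16)
    base[r_limb <= spec.limb_radius] = GT_SKIN
    base[r_limb <= sat_outer] = GT_SAT
    base[r_limb <= fascia_radius] = GT_MUSCLE
    base[r_bone <= spec.bone_outer_radius] = GT_CORTICAL_BONE
    base[r_bone <= spec.marrow_radius] = GT_MARROW

    if spec.n_vessels > 0:
        # bright vessel lumina placed deterministically on a mid-muscle ring
        ring = (fascia_radius + spec.bone_outer_radius) / 2.0
        angles = np.linspace(0, 2 * np.pi, spec.n_vessels, endpoint=False) + 0.3
        for a in angles:
            vx, vy = c + ring * np.cos(a), c + ring * np.sin(a)
            dot = np.hypot(xx - vx, yy - vy) <= spec.vessel_radius
            base[dot & (base == GT_MUSCLE)] = GT_VESSEL

    means = spec.intensity_means
    intensity_of = {
        GT_OUTSIDE: means["background"],
        GT_SKIN: means["skin"],
        GT_SAT: means["fat"],
        GT_MUSCLE: means["muscle"],
        GT_IMAT: means["fat"],
        GT_CORTICAL_BONE: means["cortical_bone"],
        GT_MARROW: means["marrow"],
        GT_VESSEL: means["fat"],
    }

    rng = np.random.default_rng(spec.seed)
    targets = spec.slice_targets()
    labels = np.empty((spec.n_slices, n, n), dtype=np.int16)
    volume = np.empty((spec.n_slices, n, n), dtype=float)

    for s in range(spec.n_slices):
        lab = base.copy()
        imat = _speckle_mask(lab == GT_MUSCLE, targets[s], spec.speckle_grain, rng)
        lab[imat] = GT_IMAT
        labels[s] = lab

        img = np.zeros((n, n), dtype=float)
        for code, mean in intensity_of.items():
            img[lab == code] = mean

        if spec.bias_field_amplitude > 0:
            # one broad multiplicative Gaussian bump, off-center
            gx, gy = c + 0.3 * spec.limb_radius, c - 0.2 * spec.limb_radius
            bump = np.exp(-((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * (0.8 * n) ** 2))
            bump = (bump - bump.min()) / (bump.max() - bump.min())
            img = img * (1.0 + spec.bias_field_amplitude * (bump - 0.5))

        if spec.noise_sigma > 0:
            # magnitude-MRI (Rician) noise: modulus of a complex Gaussian
            re = img + rng.normal(0.0, spec.noise_sigma, img.shape)
            im = rng.normal(0.0, spec.noise_sigma, img.shape)
            img = np.hypot(re, im)
        volume[s] = img

    imat_n = (labels == GT_IMAT).sum(axis=(1, 2)).astype(float)
    musc_n = (labels == GT_MUSCLE).sum(axis=(1, 2)).astype(float)
    denom = imat_n + musc_n
    frac = np.where(denom > 0, imat_n / np.maximum(denom, 1.0), 0.0)

    truth = GroundTruth(
        label_volume=labels,
        true_fat_fraction_per_slice=frac,
        true_limb_contour=_circle_polygon(c, c, spec.limb_radius),
        true_muscle_contour=_circle_polygon(c, c, fascia_radius),
    )
    return volume, truth


# --------------------------------------------------------------------------
# cohort score tables
# --------------------------------------------------------------------------

THIGH_MUSCLES = ["VM", "VL", "VI", "RF", "Add", "G", "S", "SM", "ST", "BF"]
LEG_MUSCLES = ["TA", "TP", "Sol", "GL", "GM", "P"]
ALL_MUSCLES = THIGH_MUSCLES + LEG_MUSCLES
SIDES = ["L", "R"]

_POSTERIOR_THIGH = {"Add", "G", "SM", "ST", "BF"}

# Imaging-pattern archetypes: near-normal, posterior-dominant (selective),
# and diffuse infiltration — mean per-muscle grades on the 1–4 visual scale.
THIGH_ARCHETYPES = {
    1: {m: 1.7 for m in THIGH_MUSCLES},
    2: {m: (3.7 if m in _POSTERIOR_THIGH else 2.5) for m in THIGH_MUSCLES},
    3: {m: 3.4 for m in THIGH_MUSCLES},
}
LEG_ARCHETYPES = {
    1: {m: 1.2 for m in LEG_MUSCLES},
    2: {m: (3.0 if m == "GM" else 1.8) for m in LEG_MUSCLES},
    3: {m: (1.5 if m == "TP" else 2.8) for m in LEG_MUSCLES},
}

DEFAULT_ARCHETYPES = {
    k: {**THIGH_ARCHETYPES[k], **LEG_ARCHETYPES[k]} for k in (1, 2, 3)
}


def grade_columns(region: str = "all") -> list[str]:
    """Column names of the bilateral grade table for a region
    ('thigh', 'leg' or 'all')."""
    muscles = {"thigh": THIGH_MUSCLES, "leg": LEG_MUSCLES, "all": ALL_MUSCLES}[region]
    return [f"{m}_{s}" for m in muscles for s in SIDES]


def stir_columns(region: str = "all") -> list[str]:
    return [f"stir_{c}" for c in grade_columns(region)]


def make_cohort_scores(
    n_per_cluster: tuple[int, ...] = (16, 10, 9),
    archetype_means: dict[int, dict[str, float]] | None = None,
    score_noise_sd: float = 0.4,
    stir_rate: float = 0.031,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic cohort visual-score table with known clusters.

    Each patient belongs to one archetype; every muscle is graded on both
    sides as ``round(clip(archetype mean + Gaussian noise, 1, 4))``.  STIR
    hyperintensity flags are independent Bernoulli draws at ``stir_rate``
    (the observed cohort rate of abnormal STIR signal is ≈ 3%).

    Returns a wide DataFrame with columns ``patient_id``, ``true_cluster``,
    one integer grade column per muscle × side, and one 0/1 ``stir_*``
    column per muscle × side.
    """
    if archetype_means is None:
        archetype_means = DEFAULT_ARCHETYPES
    if len(n_per_cluster) != len(archetype_means):
        raise InvalidSpecError(
            f"{len(n_per_cluster)} cluster sizes for "
            f"{len(archetype_means)} archetypes"
        )
    for cid, means in archetype_means.items():
        for m, v in means.items():
            if not (1.0 <= v <= 4.0):
                raise InvalidSpecError(
                    f"archetype {cid} mean for {m} is {v}, outside [1, 4]"
                )
    if any(nc < 1 for nc in n_per_cluster):
        raise InvalidSpecError("every cluster must have at least one patient")

    rng = np.random.default_rng(seed)
    muscles = list(next(iter(archetype_means.values())).keys())
    rows = []
    pid = 0
    for (cid, means), nc in zip(sorted(archetype_means.items()), n_per_cluster):
        for _ in range(nc):
            row: dict[str, object] = {"patient_id": f"P{pid:03d}", "true_cluster": cid}
            for m in muscles:
                for s in SIDES:
                    g = means[m] + rng.normal(0.0, score_noise_sd)
                    row[f"{m}_{s}"] = int(np.clip(np.rint(g), 1, 4))
                    row[f"stir_{m}_{s}"] = int(rng.random() < stir_rate)
            rows.append(row)
            pid += 1
    cols = ["patient_id", "true_cluster"]
    cols += [f"{m}_{s}" for m in muscles for s in SIDES]
    cols += [f"stir_{m}_{s}" for m in muscles for s in SIDES]
    return pd.DataFrame(rows, columns=cols)


def spec_with(spec: PhantomSpec, **updates) -> PhantomSpec:
    """Return a copy of ``spec`` with fields replaced (re-validated)."""
    return dataclasses.replace(spec, **updates)
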