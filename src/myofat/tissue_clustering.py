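"""Per-pixel tissue classification of a T1-weighted slice.

Stage 1 of the segmentation pipeline clusters the raw pixel intensities of a
slice into three groups with k-means.  Under T1 contrast the darkest cluster
collects background, cortical bone and flow voids; the middle cluster is
muscle; the brightest cluster is adipose tissue (subcutaneous fat, marrow,
fat infiltration, and bright vessel lumina).  Stage 2 is a morphological
cleanup: small bright vessel lumina are closed out of the fat class and the
thin skin rim is removed from the muscle class, keeping the morphology of
the muscle compartment intact for the contour-fitting stage.

The cleaned map is what the active-contour stage fits boundaries on; the
IMAT/muscle separation itself is taken from the *raw* clustering result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from ._kmeans import LloydResult, lloyd_kmeans
from .errors import AmbiguousAssignmentError, InvalidParameterError

# tissue class codes
BACKGROUND = 0  # background, cortical bone, flow voids
MUSCLE = 1
FAT = 2

TISSUE_NAMES = {BACKGROUND: "background_bone_vessel", MUSCLE: "muscle", FAT: "fat"}


@dataclass
class IntensityClustering:
    """Result of k-means on the pixel intensities of one slice.

    Centroids are sorted ascending and labels relabeled accordingly, so
    label 0 is always the darkest cluster.
    """

    labels: np.ndarray      # flat (n,) cluster indices, centroid-ascending
    centroids: np.ndarray   # (k,) ascending intensity means
    inertia: float
    n_iter: int
    inertia_history: list[float]
    shape: tuple[int, int] | None = None


@dataclass
class TissueLabelMap:
    """Per-pixel tissue classes for one slice."""

    labels: np.ndarray  # (H, W) int in {BACKGROUND, MUSCLE, FAT}
    provenance: str     # "raw_kmeans" or "cleaned"

    def mask(self, tissue: int) -> np.ndarray:
        return self.labels == tissue


def kmeans_1d(
    values: np.ndarray,
    k: int = 3,
    n_restarts: int = 8,
    seed: int = 0,
    tol: float = 1e-8,
) -> IntensityClustering:
    """Cluster scalar intensities with Lloyd k-means (k-means++ seeding,
    best of ``n_restarts`` by inertia).

    Ties (a value equidistant from two centroids) go to the darker centroid.
    Raises :class:`DegenerateInputError` when there are fewer than ``k``
    distinct values.
    """
    values = np.asarray(values, dtype=float)
    shape = values.shape if values.ndim == 2 else None
    flat = values.ravel()
    res: LloydResult = lloyd_kmeans(flat, k, n_restarts=n_restarts, seed=seed, tol=tol)
    order = np.argsort(res.centers[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return IntensityClustering(
        labels=relabel[res.labels],
        centroids=res.centers[order, 0],
        inertia=res.inertia,
        n_iter=res.n_iter,
        inertia_history=res.inertia_history,
        shape=shape,
    )


def assign_tissues(clustering: IntensityClustering) -> TissueLabelMap:
    """Map the three intensity clusters onto tissue classes.

    T1 contrast fixes the semantics: darkest centroid → background/bone/
    vessel, middle → muscle, brightest → fat.  The mapping depends only on
    the centroid ordering, so it is invariant to cluster permutation.
    """
    cents = np.asarray(clustering.centroids, dtype=float)
    if cents.size != 3:
        raise AmbiguousAssignmentError(
            f"tissue assignment needs exactly 3 centroids, got {cents.size}"
        )
    if np.unique(cents).size != 3:
        raise AmbiguousAssignmentError(
            f"centroids not distinct: {cents.tolist()}"
        )
    order = np.argsort(cents)
    tissue_of_cluster = np.empty(3, dtype=int)
    tissue_of_cluster[order] = [BACKGROUND, MUSCLE, FAT]
    labels = tissue_of_cluster[clustering.labels]
    if clustering.shape is not None:
        labels = labels.reshape(clustering.shape)
    return TissueLabelMap(labels=labels, provenance="raw_kmeans")


def clean_tissue_map(tmap: TissueLabelMap, closing_radius_px: int = 3) -> TissueLabelMap:
    """Morphological cleanup: close vessels out of the fat class and strip
    the skin rim from the muscle class.

    Vessel removal closes the muscle mask with a disk; bright specks inside
    muscle smaller than the structuring element are absorbed back into
    muscle.  Skin removal drops muscle-class connected components that touch
    the outer background and are thinner than the closing radius (they
    vanish under erosion).  Pixels farther than twice the closing radius
    from any class boundary are never altered.
    """
    if closing_radius_px <= 0:
        raise InvalidParameterError(
            f"closing radius must be positive, got {closing_radius_px}"
        )
    labels = tmap.labels.copy()
    selem = disk(closing_radius_px)

    # vessels: fat pixels swallowed when the muscle mask is closed
    muscle = labels == MUSCLE
    closed = ndi.binary_closing(muscle, structure=selem)
    swallowed = closed & (labels == FAT)
    labels[swallowed] = MUSCLE

    # skin: thin muscle components in contact with the outer background
    outside = _outer_background(labels)
    touching = ndi.binary_dilation(outside)
    muscle = labels == MUSCLE
    cc, n = ndi.label(muscle)
    if n:
        surviving = ndi.binary_erosion(muscle, structure=selem)
        for j in range(1, n + 1):
            comp = cc == j
            if (comp & touching).any() and not (comp & surviving).any():
                labels[comp] = BACKGROUND
    return TissueLabelMap(labels=labels, provenance="cleaned")


def _outer_background(labels: np.ndarray) -> np.ndarray:
    """Background region connected to the image border (outside the limb)."""
    bg = labels == BACKGROUND
    cc, n = ndi.label(bg)
    border = np.zeros_like(bg)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = np.unique(cc[border & bg])
    out = np.isin(cc, border_ids[border_ids > 0])
    return out


def classify_slice(
    image: np.ndarray,
    n_restarts: int = 8,
    seed: int = 0,
    closing_radius_px: int = 3,
) -> tuple[TissueLabelMap, TissueLabelMap, IntensityClustering]:
    """Convenience: k-means → tissue assignment → cleanup for one slice.

    Returns ``(raw_map, cleaned_map, clustering)``.
    """
    clus = kmeans_1d(image, k=3, n_restarts=n_restarts, seed=seed)
    raw = assign_tissues(clus)
    cleaned = clean_tissue_map(raw, closing_radius_px=closing_radius_px)
    return raw, cleaned, clus
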