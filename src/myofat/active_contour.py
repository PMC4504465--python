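"""Greedy polygonal active contour ("snake") on binary target images.

A closed polygon of N control points :math:`p_0 \\dots p_{N-1}` is evolved
to minimize the discrete contour energy

    ε = Σ_i  α·E_cont(i) + β·E_curv(i) + γ·E_image(i)

with cyclic indexing, where

    E_cont(i) = ||p_i − p_{i−1}||²          (contour tension)
    E_curv(i) = ||p_{i−1} − 2 p_i + p_{i+1}||²   (rigidity)
    E_image(i)                               (data attachment)

E_image is the squared Euclidean distance (in pixels) from p_i to the
nearest boundary pixel of the binary target, so edges are energy minima and
the attraction basin extends across the whole frame.  By default the two
internal terms are divided by the mean squared point spacing of the current
polygon, which makes them scale-free (independent of contour size and N)
and lets the default weights (α, β, γ) = (0.1, 0.6, 0.3) act as meaningful
relative weights against the px²-scaled image term; set
``normalize_internal=False`` for the raw px² internal terms.

Minimization is greedy: each point in turn is moved to the lowest-energy
position in a small square search window, counting every energy term that
involves that point; a sweep visits all N points, after which the polygon
is resampled to N equally spaced points along its arc length.  Each greedy
move can only lower the total energy with the other points held fixed, so
the total energy is non-increasing within a sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidParameterError, OutOfBoundsError, SegmentationFailure


@dataclass(frozen=True)
class SnakeConfig:
    alpha: float = 0.1          # continuity (tension) weight
    beta: float = 0.6           # curvature (rigidity) weight
    gamma: float = 0.3          # image (data-attachment) weight
    n_points: int = 50
    search_window_px: int = 7   # odd side of the greedy search window
    max_iter: int = 200
    move_tol: float = 0.02      # stop when < this fraction of points moved
    normalize_internal: bool = True  # scale E_cont/E_curv by mean spacing²

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0 or (
            self.alpha == self.beta == self.gamma == 0
        ):
            raise InvalidParameterError(
                "weights must be >= 0 and not all zero; got "
                f"({self.alpha}, {self.beta}, {self.gamma})"
            )
        if self.n_points < 4:
            raise InvalidParameterError(f"n_points must be >= 4, got {self.n_points}")
        if self.search_window_px < 3 or self.search_window_px % 2 == 0:
            raise InvalidParameterError(
                f"search window must be odd and >= 3, got {self.search_window_px}"
            )


@dataclass
class Contour:
    """Closed polygon in pixel coordinates, points as (x, y) = (col, row)."""

    points: np.ndarray  # (N, 2) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 3:
            raise InvalidParameterError("contour needs an (N>=3, 2) point array")

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def area(self) -> float:
        return abs(self.signed_area())

    def normalized(self) -> "Contour":
        """Counterclockwise orientation (positive shoelace area)."""
        if self.signed_area() < 0:
            return Contour(self.points[::-1].copy())
        return self

    def is_simple(self) -> bool:
        from shapely.geometry import Polygon

        return Polygon(self.points).is_valid

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the enclosed region; boundary pixels count as interior."""
        from skimage.draw import polygon2mask

        return polygon2mask(shape, self.points[:, ::-1])


@dataclass
class EvolveResult:
    contour: Contour
    converged: bool
    n_sweeps: int
    energy_trace: list[tuple[float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Redistribute points of a closed polygon to equal arc length,
    anchoring the first output point at the first input point."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return np.repeat(pts[:1], n, axis=0)
    s = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return np.column_stack([x, y])


def edge_distance_field(target: np.ndarray) -> np.ndarray:
    """Distance (px) from each pixel to the nearest boundary pixel of the
    binary target.  Zero exactly on the edge; grows monotonically away."""
    t = np.asarray(target).astype(bool)
    if not t.any() or t.all():
        raise InvalidParameterError("binary target must contain an edge")
    eroded = ndi.binary_erosion(t)
    edge = t & ~eroded
    return ndi.distance_transform_edt(~edge)


def _sample(field: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear sampling of field at (x, y) float points."""
    return ndi.map_coordinates(
        field, [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
    )


def _check_in_frame(pts: np.ndarray, shape: tuple[int, int]) -> None:
    h, w = shape
    if (
        (pts[:, 0] < 0).any()
        or (pts[:, 0] > w - 1).any()
        or (pts[:, 1] < 0).any()
        or (pts[:, 1] > h - 1).any()
    ):
        bad = pts[
            (pts[:, 0] < 0)
            | (pts[:, 0] > w - 1)
            | (pts[:, 1] < 0)
            | (pts[:, 1] > h - 1)
        ]
        raise OutOfBoundsError(f"contour points outside {h}x{w} frame: {bad[:3]}")


def mean_sq_spacing(pts: np.ndarray) -> float:
    """Mean squared segment length of a closed polygon."""
    seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.mean(np.sum(seg**2, axis=1)))


def snake_energy(
    contour: Contour | np.ndarray,
    target: np.ndarray,
    config: SnakeConfig = SnakeConfig(),
    _field: np.ndarray | None = None,
    _s2: float | None = None,
) -> float:
    """Total contour energy Σ α·E_cont + β·E_curv + γ·E_image (cyclic).

    With ``config.normalize_internal`` (the default) the continuity and
    curvature sums are divided by the polygon's mean squared point spacing;
    otherwise the raw px² terms enter directly.
    """
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    if len(pts) < 4:
        raise InvalidParameterError("energy needs at least 4 contour points")
    _check_in_frame(pts, target.shape)
    prev = np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0)
    e_cont = np.sum((pts - prev) ** 2, axis=1)
    e_curv = np.sum((prev - 2 * pts + nxt) ** 2, axis=1)
    fld = edge_distance_field(target) if _field is None else _field
    e_img = _sample(fld, pts) ** 2
    scale = 1.0
    if config.normalize_internal:
        scale = 1.0 / max(_s2 if _s2 is not None else mean_sq_spacing(pts), 1e-9)
    return float(
        (config.alpha * e_cont.sum() + config.beta * e_curv.sum()) * scale
        + config.gamma * e_img.sum()
    )


def _local_energy(
    cand: np.ndarray,  # (m, 2) candidate positions for point i
    p_im2: np.ndarray,
    p_im1: np.ndarray,
    p_ip1: np.ndarray,
    p_ip2: np.ndarray,
    d_cand: np.ndarray,  # (m,) edge distance at candidates
    cfg: SnakeConfig,
    scale: float,
) -> np.ndarray:
    """All energy terms of the global sum that involve point i, evaluated
    for each candidate position with the neighbors fixed."""
    cont = np.sum((cand - p_im1) ** 2, axis=1) + np.sum((p_ip1 - cand) ** 2, axis=1)
    curv = (
        np.sum((p_im2 - 2 * p_im1 + cand) ** 2, axis=1)
        + np.sum((p_im1 - 2 * cand + p_ip1) ** 2, axis=1)
        + np.sum((cand - 2 * p_ip1 + p_ip2) ** 2, axis=1)
    )
    return (cfg.alpha * cont + cfg.beta * curv) * scale + cfg.gamma * d_cand**2


def evolve_contour(
    init: Contour | np.ndarray,
    target: np.ndarray,
    config: SnakeConfig = SnakeConfig(),
) -> EvolveResult:
    """Greedy snake evolution on a binary target image.

    Each sweep visits the points in order and moves each to the integer
    offset in the search window minimizing its local energy (ties keep the
    current position); the polygon is then resampled to equal arc length.
    Terminates when the moved fraction drops below ``move_tol``, when the
    per-sweep energy change becomes negligible, or at ``max_iter`` (the
    last sets a non-convergence warning instead of raising).
    """
    pts = init.points.copy() if isinstance(init, Contour) else np.asarray(init, float)
    pts = resample_closed(pts, config.n_points)
    h, w = target.shape
    pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
    fld = edge_distance_field(target)
    half = config.search_window_px // 2
    offs = np.array(
        [(dx, dy) for dy in range(-half, half + 1) for dx in range(-half, half + 1)],
        dtype=float,
    )
    stay = np.where((offs == 0).all(axis=1))[0][0]
    n = config.n_points

    trace: list[tuple[float, float]] = []
    warnings_: list[str] = []
    converged = False
    flat_sweeps = 0
    sweep = 0
    for sweep in range(1, config.max_iter + 1):
        # freeze the internal-term scale for the whole sweep so that every
        # greedy move minimizes the same energy function (monotone trace)
        s2 = mean_sq_spacing(pts)
        scale = 1.0 / max(s2, 1e-9) if config.normalize_internal else 1.0
        e_pre = snake_energy(pts, target, config, _field=fld, _s2=s2)
        moved = 0
        for i in range(n):
            cand = pts[i] + offs
            ok = (
                (cand[:, 0] >= 0)
                & (cand[:, 0] <= w - 1)
                & (cand[:, 1] >= 0)
                & (cand[:, 1] <= h - 1)
            )
            d = np.full(len(offs), np.inf)
            d[ok] = _sample(fld, cand[ok])
            e = _local_energy(
                cand,
                pts[(i - 2) % n],
                pts[(i - 1) % n],
                pts[(i + 1) % n],
                pts[(i + 2) % n],
                d,
                config,
                scale,
            )
            j = int(np.argmin(e))
            if j != stay and e[j] < e[stay] - 1e-9:
                pts[i] = cand[j]
                moved += 1
        e_post = snake_energy(pts, target, config, _field=fld, _s2=s2)
        trace.append((e_pre, e_post))
        if moved / n < config.move_tol:
            converged = True
            break
        if abs(e_pre - e_post) <= 1e-4 * max(abs(e_pre), 1.0):
            flat_sweeps += 1
            if flat_sweeps >= 3:
                converged = True
                break
        else:
            flat_sweeps = 0
        pts = resample_closed(pts, n)
    if not converged:
        warnings_.append("max_iter reached without convergence")

    out = Contour(pts).normalized()
    if not out.is_simple():
        warnings_.append("self-intersecting contour after convergence")
    return EvolveResult(out, converged, sweep, trace, warnings_)


def _hull_init(mask: np.ndarray, n_points: int, pad: float = 4.0) -> np.ndarray:
    """Initial contour: boundary of the convex hull of the mask, pushed
    outward by ``pad`` pixels from the hull centroid."""
    from skimage.measure import find_contours
    from skimage.morphology import convex_hull_image

    hull = convex_hull_image(mask)
    cs = find_contours(hull.astype(float), 0.5)
    boundary = max(cs, key=len)[:, ::-1]  # (row, col) -> (x, y)
    pts = resample_closed(boundary, n_points)
    cen = pts.mean(axis=0)
    vec = pts - cen
    r = np.linalg.norm(vec, axis=1, keepdims=True)
    return cen + vec * (1.0 + pad / np.maximum(r, 1e-9))


def muscle_support_mask(
    muscle_mask: np.ndarray,
    base_closing_px: int = 3,
    max_closing_px: int = 15,
    convex: bool = True,
) -> np.ndarray:
    """Fascia-enclosed support: close the muscle class, keep the largest
    component, fill interior (fat and bone) holes, and take the convex
    hull.

    The closing radius is grown adaptively: heavy fat speckle fragments
    the muscle class, so the radius is increased until the filled support
    stops growing (< 2% area change), which reconnects moth-eaten muscle
    without inflating an already-compact compartment.  The convex hull
    then bridges fat pockets that open onto the subcutaneous ring and can
    never be closed morphologically; muscle touches the fascia densely
    enough that the hull chords hug the true boundary (the thigh fascia
    cross-section is treated as approximately convex).
    """
    from skimage.morphology import convex_hull_image, disk

    prev_area = 0
    sup = muscle_mask
    r = base_closing_px
    while r <= max_closing_px:
        closed = ndi.binary_closing(muscle_mask, structure=disk(r), border_value=0)
        s = ndi.binary_fill_holes(_largest_component(closed))
        area = int(s.sum())
        sup = s
        if prev_area and area < 1.02 * prev_area:
            break
        prev_area = area
        r += base_closing_px
    if convex:
        sup = convex_hull_image(sup)
    return sup


def fit_limb_and_muscle_contours(
    tmap,
    config: SnakeConfig = SnakeConfig(),
    support_closing_px: int = 3,
    raw_tmap=None,
) -> tuple[Contour, Contour]:
    """Fit the outer limb boundary and the fascia (muscle-compartment)
    boundary on a cleaned tissue map.

    The limb snake targets the filled fat ∪ muscle support — taken from
    the *raw* map when one is supplied, because the cleanup stage strips
    the skin rim from the muscle class and the rim is part of the leg
    outline.  The muscle snake targets the muscle-class support of the
    cleaned map (interior fat and bone are holes and get filled, so the
    target is the fascia-enclosed region).  Raises
    :class:`SegmentationFailure` when the muscle class is empty — the
    caller should route the slice to the manual-contour fallback.
    """
    from .tissue_clustering import FAT, MUSCLE

    labels = tmap.labels
    muscle_mask = labels == MUSCLE
    if not muscle_mask.any():
        raise SegmentationFailure("muscle class is empty")

    limb_labels = raw_tmap.labels if raw_tmap is not None else labels
    limb_support = ndi.binary_fill_holes(
        (limb_labels == FAT) | (limb_labels == MUSCLE)
    )
    limb_support = _largest_component(limb_support)
    muscle_support = muscle_support_mask(
        muscle_mask, support_closing_px, 5 * support_closing_px
    )

    shape = labels.shape
    limb_res = evolve_contour(
        Contour(_clip_frame(_hull_init(limb_support, config.n_points), shape)),
        limb_support,
        config,
    )
    muscle_res = evolve_contour(
        Contour(_clip_frame(_hull_init(muscle_support, config.n_points), shape)),
        muscle_support,
        config,
    )
    return limb_res.contour, muscle_res.contour


def _clip_frame(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    out = pts.copy()
    out[:, 0] = np.clip(out[:, 0], 0, w - 1)
    out[:, 1] = np.clip(out[:, 1], 0, h - 1)
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    cc, m = ndi.label(mask)
    if m <= 1:
        return mask
    sizes = ndi.sum_labels(mask, cc, index=np.arange(1, m + 1))
    return cc == (1 + int(np.argmax(sizes)))
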