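"""Shared Lloyd k-means core.

Both the per-pixel intensity clustering and the patient-pattern clustering
use the same alternating scheme: assign each point to its nearest center,
recompute each center as the mean of its members, repeat until the centers
stop moving.  The implementation is deliberately self-contained so that the
per-iteration inertia trace can be asserted against (inertia never increases
across Lloyd iterations) and so ties are broken deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError


@dataclass
class LloydResult:
    labels: np.ndarray          # (n,) int cluster index in [0, k)
    centers: np.ndarray         # (k, d) float
    inertia: float              # within-cluster sum of squared distances
    n_iter: int
    inertia_history: list[float] = field(default_factory=list)


def _kpp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread the initial centers proportionally to
    squared distance from the centers already chosen."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]), dtype=float)
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining mass at chosen centers; pick any distinct point
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # argmin breaks distance ties toward the lower center index
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _assign_1d(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment for 1-D data via sorted midpoints.

    A point exactly on a midpoint is assigned to the lower (darker) center,
    matching the package-wide deterministic tie-break.
    """
    order = np.argsort(centers)
    c = centers[order]
    mids = (c[:-1] + c[1:]) / 2.0
    idx_sorted = np.searchsorted(mids, x, side="left")
    return order[idx_sorted]


def lloyd_kmeans(
    X: np.ndarray,
    k: int,
    n_restarts: int = 8,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> LloydResult:
    """Best-of-restarts Lloyd k-means with k-means++ seeding.

    Parameters
    ----------
    X : (n, d) array. For d == 1 the fast sorted-midpoint assignment is used.
    tol : stop when inertia improves by less than ``tol`` (absolute).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if k < 1:
        raise DegenerateInputError(f"k must be >= 1, got {k}")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise DegenerateInputError(
            f"need at least k={k} distinct points, got {n_distinct}"
        )
    rng = np.random.default_rng(seed)
    best: LloydResult | None = None
    one_d = d == 1
    x_flat = X[:, 0] if one_d else None

    for _ in range(max(1, n_restarts)):
        centers = _kpp_init(X, k, rng)
        history: list[float] = []
        prev_inertia = np.inf
        labels = np.zeros(n, dtype=int)
        for it in range(1, max_iter + 1):
            if one_d:
                labels = _assign_1d(x_flat, centers[:, 0])
            else:
                labels = _assign(X, centers)
            new_centers = centers.copy()
            for j in range(k):
                members = labels == j
                if members.any():
                    new_centers[j] = X[members].mean(axis=0)
                else:
                    # reseed an empty cluster at the point farthest from its center
                    d2 = ((X - centers[labels]) ** 2).sum(axis=1)
                    new_centers[j] = X[np.argmax(d2)]
            centers = new_centers
            inertia = float(((X - centers[labels]) ** 2).sum())
            history.append(inertia)
            if prev_inertia - inertia < tol:
                break
            prev_inertia = inertia
        # final assignment consistent with final centers (Lloyd fixed point)
        if one_d:
            labels = _assign_1d(x_flat, centers[:, 0])
        else:
            labels = _assign(X, centers)
        inertia = float(((X - centers[labels]) ** 2).sum())
        if best is None or inertia < best.inertia - 1e-12:
            best = LloydResult(labels, centers, inertia, len(history), history)
    assert best is not None
    return best
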