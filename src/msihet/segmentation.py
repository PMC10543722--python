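"""Pixel-wise k-means segmentation into metabolic subpopulations.

Pixels are clustered on their (RMS-normalized) spectra with squared
Euclidean distance; a cluster is a metabolic subpopulation — spectrally
similar pixels that need not be spatially adjacent.  The implementation is
plain Lloyd iteration with distance-weighted (k-means++-style) seeding and a
best-of-``n_init`` restart policy, and it records the within-cluster sum of
squares after every iteration so the monotone descent of the objective is
checkable.  An empty cluster is re-seeded at the pixel farthest from its
current centroid, which keeps k clusters alive deterministically.

Cluster ids are renumbered 1..k by decreasing overall pixel share so that
"cluster 1" is always the most abundant subpopulation, giving stable
reporting across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import PixelTable

__all__ = [
    "SegmentationResult",
    "PresenceMatrix",
    "lloyd_kmeans",
    "kmeans_segment",
    "presence_matrix",
    "pixel_distribution",
]


@dataclass
class SegmentationResult:
    """A fitted segmentation: labels in 1..k, centroids, and the objective."""

    k: int
    labels: pd.Series  # pixel_id -> cluster in 1..k
    centroids: np.ndarray  # k × F
    wcss: float
    seed: int
    n_init: int
    converged: bool
    n_iter: int
    wcss_history: list = field(default_factory=list, repr=False)


@dataclass
class PresenceMatrix:
    """Patient × cluster fractional composition p_ic (rows sum to 1).

    ``overall_shares`` is the cohort-level pixel share of each cluster.
    """

    frame: pd.DataFrame  # index patient_id, columns 1..k
    overall_shares: pd.Series

    @property
    def k(self) -> int:
        return self.frame.shape[1]

    def binarize(self, tau: float) -> pd.DataFrame:
        """Presence indicators 1[p_ic >= tau]."""
        return (self.frame >= tau).astype(int)


def _pp_seed(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted random seeding (k-means++)."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-center labels and squared distances (ties -> lowest index)."""
    # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; ||x||^2 constant for argmin
    cross = X @ centers.T
    c2 = (centers**2).sum(axis=1)
    scores = c2[None, :] - 2.0 * cross
    labels = np.argmin(scores, axis=1)
    x2 = (X**2).sum(axis=1)
    d2 = x2 + scores[np.arange(len(labels)), labels]
    return labels, np.maximum(d2, 0.0)


def lloyd_kmeans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
):
    """Best-of-``n_init`` Lloyd k-means on the rows of ``X``.

    Returns ``(labels, centers, wcss, history, converged, n_iter)`` with
    0-based labels; ``history`` is the WCSS after each update of the winning
    restart (non-increasing).  ``tol`` is the relative WCSS change declaring
    convergence.  Deterministic given ``(seed, n_init, max_iter)``.
    """
    X = np.ascontiguousarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n pixels, got k={k}, n={n}")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"k={k} exceeds the number of distinct pixels")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        centers = _pp_seed(X, k, rng)
        prev = np.inf
        history = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            labels, d2 = _assign(X, centers)
            for j in range(k):
                mask = labels == j
                if mask.any():
                    centers[j] = X[mask].mean(axis=0)
                else:
                    # re-seed an empty cluster at the farthest pixel
                    far = int(np.argmax(d2))
                    centers[j] = X[far]
                    d2[far] = 0.0
            labels, d2 = _assign(X, centers)
            wcss = float(d2.sum())
            history.append(wcss)
            if prev - wcss <= tol * max(prev, 1e-300) and np.isfinite(prev):
                converged = True
                break
            prev = wcss
        if best is None or history[-1] < best[2]:
            best = (labels, centers.copy(), history[-1], history, converged, it)
    return best


def kmeans_segment(
    table: PixelTable,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> SegmentationResult:
    """Segment the pixels of ``table`` into ``k`` metabolic subpopulations.

    The table is expected to be RMS-normalized (see
    :func:`msihet.dataio.rms_normalize`) so that clustering acts on spectral
    shape; this is not enforced, allowing deliberately constructed inputs.
    Clusters are renumbered by decreasing overall pixel share.
    """
    X = table.intensities()
    labels0, centers, wcss, history, converged, n_iter = lloyd_kmeans(
        X, k, seed=seed, n_init=n_init, max_iter=max_iter, tol=tol
    )
    counts = np.bincount(labels0, minlength=k)
    order = np.argsort(-counts, kind="stable")  # old label -> rank
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[labels0], index=table.pixel_ids.to_numpy(), name="cluster")
    return SegmentationResult(
        k=k,
        labels=labels,
        centroids=centers[order],
        wcss=wcss,
        seed=seed,
        n_init=n_init,
        converged=converged,
        n_iter=n_iter,
        wcss_history=history,
    )


def presence_matrix(seg: SegmentationResult, table: PixelTable) -> PresenceMatrix:
    """Per-patient fractional composition over the k subpopulations."""
    df = table.frame[["pixel_id", "patient_id"]].copy()
    lab = seg.labels.reindex(df["pixel_id"].to_numpy())
    if lab.isna().any():
        raise ValueError("segmentation labels do not cover the pixel table")
    df["cluster"] = lab.to_numpy()
    counts = (
        df.groupby(["patient_id", "cluster"], sort=True).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=range(1, seg.k + 1), fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("patient with zero pixels")
    frame = counts.div(totals, axis=0)
    overall = counts.sum(axis=0) / counts.to_numpy().sum()
    return PresenceMatrix(frame=frame, overall_shares=overall)


def pixel_distribution(seg: SegmentationResult, table: PixelTable | None = None) -> pd.DataFrame:
    """Overall pixel count and percentage per subpopulation (empty ones kept)."""
    counts = seg.labels.value_counts().reindex(range(1, seg.k + 1), fill_value=0)
    out = pd.DataFrame(
        {
            "cluster": counts.index,
            "n_pixels": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / counts.sum(),
        }
    ).reset_index(drop=True)
    return out
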