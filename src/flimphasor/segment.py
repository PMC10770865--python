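"""Unsupervised fluorophore separation by K-means on the phasor cloud.

Clustering operates on the per-pixel (g, s) coordinates (not on the binned
histogram) so every cloud entry keeps its 1:1 pixel back-mapping.  Lloyd's
algorithm with k-means++ seeding and multiple restarts is run in-package:
the per-iteration inertia trajectory is asserted non-increasing on every
run, and labels are canonically renumbered by ascending centroid g (ties
broken by s) so the result is restart-order independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .phasor import PhasorCloud

__all__ = [
    "Segmentation",
    "kmeans_phasor",
    "labels_to_image",
    "overlay_segments",
    "segmentation_accuracy",
]


@dataclass
class Segmentation:
    """K-means result: centroids in (g, s) space and per-entry labels 1..K."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    seed: int

    def __post_init__(self) -> None:
        if self.centroids.shape != (self.k, 2):
            raise ValueError("centroids must be (k, 2)")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.labels.size and not (
            self.labels.min() >= 1 and self.labels.max() <= self.k
        ):
            raise ValueError("labels must lie in 1..k")


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centers = np.empty((k, 2))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[i] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centers[i] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centers[i]) ** 2, axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple:
    prev_inertia = np.inf
    k = len(centers)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(X)), labels].sum())
        # Lloyd monotonicity holds analytically; asserted on every run
        assert inertia <= prev_inertia + 1e-9 * max(1.0, prev_inertia if np.isfinite(prev_inertia) else 1.0)
        new_centers = centers.copy()
        for j in range(k):
            sel = labels == j
            if np.any(sel):
                new_centers[j] = X[sel].mean(axis=0)
        if np.allclose(new_centers, centers) and inertia == prev_inertia:
            break
        centers = new_centers
        prev_inertia = inertia
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    return centers, labels, inertia


def kmeans_phasor(
    cloud: PhasorCloud,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> Segmentation:
    """Cluster the phasor cloud into K fluorophore groups.

    Best of ``n_init`` k-means++-seeded Lloyd restarts by inertia;
    deterministic given ``seed``.  Returned labels are 1..K after the
    canonical g-ascending renumbering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(cloud) < k:
        raise ValueError(f"cloud size {len(cloud)} < k = {k}")
    X = np.column_stack([cloud.g_coord, cloud.s_coord]).astype(float)
    best = None
    rng = np.random.default_rng(seed)
    for restart in range(n_init):
        if restart % 2 == 0:
            centers = _kmeanspp_init(X, k, rng)
        else:
            # plain random restarts escape the local optimum k-means++
            # repeatedly lands in when one far point dominates the d^2 draw
            centers = X[rng.choice(len(X), size=k, replace=False)]
        centers, labels, inertia = _lloyd(X, centers, max_iter)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia)
    centers, labels, inertia = best
    order = np.lexsort((centers[:, 1], centers[:, 0]))  # ascending g, tie s
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return Segmentation(
        k=k,
        centroids=centers[order],
        labels=remap[labels],
        inertia=inertia,
        seed=seed,
    )


def labels_to_image(seg: Segmentation, cloud: PhasorCloud, shape: tuple[int, ...]) -> np.ndarray:
    """Map cluster labels back onto an image; 0 at invalid/background pixels."""
    idx = cloud.pixel_index
    if idx.shape[1] != len(shape):
        raise ValueError("pixel_index dimensionality does not match shape")
    if idx.size and np.any(idx.max(axis=0) >= np.asarray(shape)):
        raise ValueError("pixel_index outside image shape")
    out = np.zeros(shape, dtype=np.uint8)
    out[tuple(idx.T)] = seg.labels
    return out


def overlay_segments(
    label_image: np.ndarray,
    base_intensity: np.ndarray,
    palette: list[tuple[float, float, float]],
) -> np.ndarray:
    """Render clusters as colors modulated by normalized intensity.

    ``palette[i]`` colors label i+1; label 0 (background) renders black.
    """
    label_image = np.asarray(label_image)
    if label_image.max() > len(palette):
        raise ValueError("palette too short for label image")
    inten = np.asarray(base_intensity, dtype=float)
    if inten.shape != label_image.shape:
        raise ValueError("shape mismatch")
    rng_ = inten.max() - inten.min()
    norm = (inten - inten.min()) / rng_ if rng_ > 0 else np.zeros_like(inten)
    colors = np.concatenate([[(0.0, 0.0, 0.0)], np.asarray(palette, dtype=float)])
    rgb = colors[label_image] * norm[..., None]
    return rgb


def segmentation_accuracy(seg_labels: np.ndarray, truth_labels: np.ndarray) -> float:
    """Best-over-label-permutations pixel accuracy on valid (truth > 0) pixels.

    The optimal label matching is found with the Hungarian algorithm on the
    contingency table, which equals the best permutation.
    """
    seg_labels = np.asarray(seg_labels)
    truth_labels = np.asarray(truth_labels)
    if seg_labels.shape != truth_labels.shape:
        raise ValueError("shape mismatch")
    valid = truth_labels > 0
    n = int(valid.sum())
    if n == 0:
        raise ValueError("truth has no valid pixels")
    s = seg_labels[valid]
    t = truth_labels[valid]
    s_ids = np.unique(s)
    t_ids = np.unique(t)
    cont = np.zeros((len(s_ids), len(t_ids)))
    for i, si in enumerate(s_ids):
        for j, tj in enumerate(t_ids):
            cont[i, j] = np.count_nonzero((s == si) & (t == tj))
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / n)
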