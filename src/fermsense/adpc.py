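"""Adaptive density-peak clustering (ADPC).

Classic density-peak clustering ranks every point by a local density
``rho`` and a relative distance ``delta`` (distance to the nearest point
of higher density); cluster centers are the points where both are
large.  The variant implemented here sharpens the gap between centers
and non-centers with a logarithmic decision parameter

    D_i = rho_i * log10(delta_tilde_i),

where ``delta_tilde`` is ``delta`` monotonically rescaled to [1, 10] so
the base-10 logarithm stays non-negative and order-preserving.  Sorting
D descending gives the profile ``gamma``; the relative-drop statistic

    gamma*_i = (gamma_{i-1} - gamma_i) / (gamma_i - gamma_{i+1})

peaks at the position where the profile falls off the "center plateau"
into the noise tail, which locates the number of clusters without a
user-supplied k.  The point at the peak position itself sits on the low
side of the drop, so by default centers are the positions *before* the
peak; ``include_drop_point=True`` additionally counts the peak position
itself as a center.

Remaining points are assigned, in decreasing-density order, to the
cluster of their nearest neighbor of higher density (the standard DPC
assignment rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DensityProfile",
    "Partition",
    "pairwise_distances",
    "truncation_distance",
    "local_density",
    "relative_distance",
    "decision_parameters",
    "select_centers",
    "assign_points",
    "cluster",
    "merge_small_clusters",
]

_EPS = 1e-12


@dataclass
class DensityProfile:
    """Per-point diagnostics of the center-selection stage.

    Attributes
    ----------
    dist : (n, n) symmetric Euclidean distance matrix.
    dist_c : truncation distance (Gaussian density bandwidth).
    rho : local densities.
    delta : distance to nearest higher-density point (max row distance
        for the globally densest point).
    D : decision parameters ``rho * log10(delta_tilde)``.
    order : indices sorting D descending (ties by index).
    gamma : D sorted descending.
    gamma_star : relative-drop statistic at interior sorted positions;
        NaN at the two boundary positions where it is undefined.
    """

    dist: np.ndarray
    dist_c: float
    rho: np.ndarray
    delta: np.ndarray
    D: np.ndarray
    order: np.ndarray
    gamma: np.ndarray
    gamma_star: np.ndarray

    @property
    def n(self) -> int:
        return self.rho.shape[0]

    def diagnostics(self) -> dict:
        """JSON-ready per-point diagnostics (rho, delta, D)."""
        return {
            "dist_c": self.dist_c,
            "rho": self.rho.tolist(),
            "delta": self.delta.tolist(),
            "D": self.D.tolist(),
        }


@dataclass
class Partition:
    """Cluster labels in 1..k plus the center row indices."""

    labels: np.ndarray
    center_indices: np.ndarray

    @property
    def k(self) -> int:
        return len(self.center_indices)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def to_frame(self):
        """(row_index, label) table, writable as CSV."""
        import pandas as pd

        return pd.DataFrame({"row_index": np.arange(len(self.labels)),
                             "label": self.labels})


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return squareform(pdist(X)) if X.shape[0] > 1 else np.zeros((1, 1))


def truncation_distance(dist: np.ndarray, percentile: float = 2.0) -> float:
    """p-th percentile of the off-diagonal pairwise distances.

    Falls back to the smallest positive distance when the percentile
    lands on zero (duplicated points).
    """
    n = dist.shape[0]
    if n < 2:
        return 1.0
    vals = dist[np.triu_indices(n, k=1)]
    dc = float(np.percentile(vals, percentile))
    if dc <= 0.0:
        pos = vals[vals > 0]
        dc = float(pos.min()) if pos.size else 1.0
    return dc


def local_density(dist: np.ndarray, dist_c: float) -> np.ndarray:
    """Gaussian-kernel local density rho_i = sum_{j!=i} exp(-(d_ij/d_c)^2)."""
    if dist_c <= 0:
        raise ValueError("dist_c must be positive")
    dist = np.asarray(dist, dtype=float)
    k = np.exp(-((dist / dist_c) ** 2))
    np.fill_diagonal(k, 0.0)
    return k.sum(axis=1)


def _delta_and_neighbor(dist: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """delta_i and the index of the nearest strictly-higher-density point.

    Density ties are broken by index order: j outranks i when
    rho_j > rho_i, or rho_j == rho_i and j < i.  The unique top-ranked
    point gets delta = max distance in its row and neighbor -1.
    """
    n = rho.shape[0]
    # rank by (-rho, index): rank[i] = position in the density ordering
    order = np.lexsort((np.arange(n), -rho))
    delta = np.empty(n)
    neighbor = np.full(n, -1, dtype=int)
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = dist[i].max() if n > 1 else 0.0
            continue
        higher = order[:pos]
        j = higher[np.argmin(dist[i, higher])]
        delta[i] = dist[i, j]
        neighbor[i] = j
    return delta, neighbor


def relative_distance(dist: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Minimum distance to a point of higher density (DPC delta)."""
    return _delta_and_neighbor(np.asarray(dist, float), np.asarray(rho, float))[0]


def decision_parameters(
    rho: np.ndarray, delta: np.ndarray, dist: np.ndarray | None = None, dist_c: float = 1.0
) -> DensityProfile:
    """Compute D, the descending profile gamma, and the drop statistic gamma*."""
    rho = np.asarray(rho, dtype=float)
    delta = np.asarray(delta, dtype=float)
    n = rho.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to form the drop statistic")
    dmin, dmax = delta.min(), delta.max()
    if dmax > dmin:
        delta_tilde = 1.0 + 9.0 * (delta - dmin) / (dmax - dmin)
    else:
        delta_tilde = np.ones_like(delta)
    D = rho * np.log10(delta_tilde)
    order = np.lexsort((np.arange(n), -D))
    gamma = D[order]
    gamma_star = np.full(n, np.nan)
    num = gamma[:-2] - gamma[1:-1]
    den = np.maximum(gamma[1:-1] - gamma[2:], _EPS)
    gamma_star[1:-1] = num / den
    if dist is None:
        dist = np.zeros((n, n))
    return DensityProfile(
        dist=np.asarray(dist, float),
        dist_c=float(dist_c),
        rho=rho,
        delta=delta,
        D=D,
        order=order,
        gamma=gamma,
        gamma_star=gamma_star,
    )


def select_centers(
    profile: DensityProfile, k_max: int | None = None, include_drop_point: bool = False
) -> np.ndarray:
    """Locate the center/noise boundary from the gamma* peak.

    The search for the maximal relative drop runs over interior sorted
    positions 2..k_max+1 (1-based), so at most ``k_max`` centers are
    returned.  ``include_drop_point`` switches to counting the peak
    position itself as a center.
    """
    n = profile.n
    if k_max is None:
        k_max = max(2, min(10, n // 10))
    if not 2 <= k_max < n:
        raise ValueError("need 2 <= k_max < n")
    # Selection uses the drop ratio with its denominator floored at the
    # mean gamma gap: near-tied consecutive tail values otherwise blow
    # the ratio up and put the peak deep in the noise tail.
    gamma = profile.gamma
    floor = max((gamma[0] - gamma[-1]) / (n - 1), _EPS)
    num = gamma[:-2] - gamma[1:-1]
    den = np.maximum(gamma[1:-1] - gamma[2:], floor)
    score = num / den
    hi = min(k_max + 1, n - 1)          # 1-based inclusive upper position
    window = score[: hi - 1]            # score[j] sits at 1-based position j+2
    istar = 2 + int(np.argmax(window))  # 1-based peak position, ties -> smallest
    k = istar if include_drop_point else istar - 1
    k = int(np.clip(k, 1, k_max))
    return profile.order[:k].copy()


def assign_points(profile: DensityProfile, center_indices: np.ndarray) -> Partition:
    """Standard DPC assignment: inherit the label of the nearest
    higher-density neighbor, processed in decreasing-density order."""
    center_indices = np.asarray(center_indices, dtype=int)
    if center_indices.size == 0:
        raise ValueError("need at least one center")
    n = profile.n
    _, neighbor = _delta_and_neighbor(profile.dist, profile.rho)
    labels = np.zeros(n, dtype=int)
    for c_label, c_idx in enumerate(center_indices, start=1):
        labels[c_idx] = c_label
    order = np.lexsort((np.arange(n), -profile.rho))
    for i in order:
        if labels[i] == 0:
            labels[i] = labels[neighbor[i]]
    return Partition(labels=labels, center_indices=center_indices)


def cluster(
    X: np.ndarray,
    dist_c_percentile: float = 2.0,
    k_max: int | None = None,
    include_drop_point: bool = False,
) -> tuple[Partition, DensityProfile]:
    """Full ADPC pipeline on a feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dist = pairwise_distances(X)
    dc = truncation_distance(dist, dist_c_percentile)
    rho = local_density(dist, dc)
    delta = relative_distance(dist, rho)
    profile = decision_parameters(rho, delta, dist=dist, dist_c=dc)
    centers = select_centers(profile, k_max=k_max, include_drop_point=include_drop_point)
    return assign_points(profile, centers), profile


def merge_small_clusters(X: np.ndarray, part: Partition, min_size: int) -> Partition:
    """Merge clusters with fewer than ``min_size`` members into the
    cluster with the nearest centroid; labels are re-packed to 1..k'."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = part.labels.copy()
    centers = list(part.center_indices)
    while True:
        uniq = np.unique(labels)
        sizes = {int(u): int((labels == u).sum()) for u in uniq}
        small = [u for u in uniq if sizes[int(u)] < min_size]
        if not small or len(uniq) == 1:
            break
        u = min(small, key=lambda v: sizes[int(v)])
        cent = {int(v): X[labels == v].mean(axis=0) for v in uniq}
        others = [int(v) for v in uniq if v != u]
        tgt = min(others, key=lambda v: float(np.linalg.norm(cent[int(u)] - cent[v])))
        labels[labels == u] = tgt
    # re-pack labels and keep the surviving centers in label order
    uniq = np.unique(labels)
    remap = {int(old): new for new, old in enumerate(uniq, start=1)}
    new_labels = np.array([remap[int(v)] for v in labels], dtype=int)
    keep = [c for c in centers if remap.get(int(part.labels[c])) is not None]
    new_centers = []
    seen = set()
    for c in keep:
        lbl = new_labels[c]
        if lbl not in seen:
            seen.add(lbl)
            new_centers.append(c)
    # a merged-away center may leave a cluster without one; fall back to densest row
    for lbl in range(1, len(uniq) + 1):
        if lbl not in seen:
            rows = np.flatnonzero(new_labels == lbl)
            new_centers.append(int(rows[0]))
            seen.add(lbl)
    new_centers.sort(key=lambda c: new_labels[c])
    return Partition(labels=new_labels, center_indices=np.asarray(new_centers, dtype=int))
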