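"""Ensemble analysis: structure distances, clustering, reliable subsets.

The structure metric compares intra-structure distance matrices, so it is
invariant to translation, rotation and reflection — mirror-image
conformations (which interaction data cannot distinguish) have distance
exactly zero.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .core import Conformation, InteractionDataset
from .sampler import Ensemble

__all__ = [
    "structure_distance",
    "ensemble_distance_matrix",
    "ClusteringResult",
    "ward_cluster",
    "kmeans_check",
    "label_agreement",
    "Representative",
    "representatives",
    "ReliableSubset",
    "reliable_subset",
    "superpose",
    "genomic_distance_profile",
]


def _points(x) -> np.ndarray:
    return x.points if isinstance(x, Conformation) else np.asarray(x, float)


def structure_distance(s, t) -> float:
    """Root of the summed squared differences of intra-structure distances.

    ``sqrt(sum_{i<j} (D_S(i,j) - D_T(i,j))**2)`` — a pseudometric on
    conformations modulo rigid motions and reflections.
    """
    ps, pt = _points(s), _points(t)
    if ps.shape != pt.shape:
        raise ValueError(f"shape mismatch: {ps.shape} vs {pt.shape}")
    return float(np.sqrt(np.sum((pdist(ps) - pdist(pt)) ** 2)))


def ensemble_distance_matrix(ens: Ensemble) -> np.ndarray:
    """N x N matrix of pairwise structure distances over an ensemble."""
    if len(ens) < 2:
        raise ValueError("need at least 2 structures")
    v = ens.distance_vectors()
    return squareform(pdist(v))  # euclidean on condensed vectors == metric


@dataclasses.dataclass
class ClusteringResult:
    """Ward linkage over a structure distance matrix plus a flat cut."""

    linkage: np.ndarray  # scipy linkage matrix (merge heights)
    labels: np.ndarray  # 0-based flat labels
    n_clusters: int

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    @property
    def weights(self) -> np.ndarray:
        return self.sizes / self.sizes.sum()


def ward_cluster(dm: np.ndarray, n_clusters: int) -> ClusteringResult:
    """Agglomerative Ward clustering of a precomputed distance matrix."""
    dm = np.asarray(dm, float)
    n = dm.shape[0]
    if dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    z = linkage(squareform(dm, checks=False), method="ward")
    labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    return ClusteringResult(z, labels, int(labels.max()) + 1)


def kmeans_check(ens: Ensemble, n_clusters: int, seed: int = 0) -> np.ndarray:
    """k-means labels for a cross-method agreement check.

    Operates on the flattened upper-triangle intra-structure distance
    vectors (rotation/reflection-invariant "structure space").
    """
    from sklearn.cluster import KMeans

    v = ens.distance_vectors()
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(v)


def label_agreement(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Fraction of items agreeing after best-match label alignment."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label arrays must have equal length")
    ua, ub = np.unique(a), np.unique(b)
    conf = np.zeros((len(ua), len(ub)), dtype=np.int64)
    for i, la in enumerate(ua):
        for j, lb in enumerate(ub):
            conf[i, j] = np.sum((a == la) & (b == lb))
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / len(a))


@dataclasses.dataclass
class Representative:
    label: int
    index: int
    weight: float
    log_posterior: float


def representatives(ens: Ensemble, labels: Sequence[int]) -> List[Representative]:
    """Per-cluster representative: the member with the highest posterior,
    weighted by the cluster's share of the ensemble."""
    labels = np.asarray(labels)
    if len(labels) != len(ens) or len(labels) == 0:
        raise ValueError("labels must cover the ensemble")
    out = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        best = idx[np.argmax(ens.log_posteriors[idx])]  # first max = earliest
        out.append(Representative(int(lab), int(best), len(idx) / len(ens),
                                  float(ens.log_posteriors[best])))
    return out


@dataclasses.dataclass
class ReliableSubset:
    fragments: List[int]  # in greedy addition order, 0-based
    score: float  # total pairwise distance-sd within the subset


def reliable_subset(ens: Ensemble, k: int) -> ReliableSubset:
    """Greedy search for the k fragments whose pairwise distances vary
    least across the ensemble.

    ``s(i, j)`` is the standard deviation of the (i, j) intra-structure
    distance across members.  The greedy run starts from the pair with
    the smallest s and repeatedly adds the fragment with the smallest
    added cost; ties break to the lowest fragment index.
    """
    n = ens.n_points
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    if len(ens) < 2:
        raise ValueError("need at least 2 ensemble members")
    s_cond = ens.distance_vectors().std(axis=0, ddof=0)
    s = squareform(s_cond)
    # condensed ordering scans (0,1),(0,2),... so argmin = lexicographic tie-break
    best_pair = int(np.argmin(s_cond))
    iu, ju = np.triu_indices(n, k=1)
    subset = [int(iu[best_pair]), int(ju[best_pair])]
    while len(subset) < k:
        best_c, best_cost = -1, np.inf
        for c in range(n):
            if c in subset:
                continue
            cost = float(s[c, subset].sum())
            if cost < best_cost:
                best_c, best_cost = c, cost
        subset.append(best_c)
    idx = np.asarray(subset)
    score = float(s[np.ix_(idx, idx)].sum() / 2.0)
    return ReliableSubset(subset, score)


def superpose(s, t, allow_reflection: bool = False) -> Tuple[Conformation, float]:
    """Least-squares rigid superposition of ``s`` onto ``t`` (Kabsch).

    With ``allow_reflection`` the better of the proper and improper
    alignment is returned (interaction data cannot tell enantiomers
    apart, so mirrored structures are legitimately aligned this way).
    """
    ps, pt = _points(s), _points(t)
    if ps.shape != pt.shape:
        raise ValueError("shape mismatch")
    if ps.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    cs, ct = ps.mean(0), pt.mean(0)
    p0, q0 = ps - cs, pt - ct
    u, _, vt = np.linalg.svd(p0.T @ q0)
    d = np.sign(np.linalg.det(u @ vt))
    rot_proper = (u @ np.diag([1.0, 1.0, d]) @ vt)
    candidates = [rot_proper]
    if allow_reflection and d < 0:
        candidates.append(u @ vt)  # unconstrained optimum is improper here
    best = None
    for rot in candidates:
        aligned = p0 @ rot + ct
        rmsd = float(np.sqrt(np.mean(np.sum((aligned - pt) ** 2, axis=1))))
        if best is None or rmsd < best[1]:
            best = (aligned, rmsd)
    return Conformation(best[0]), best[1]


def genomic_distance_profile(data: InteractionDataset,
                             bins: Sequence[float]) -> pd.DataFrame:
    """Mean measured IF grouped by linear genomic separation.

    Separation is the fragment-midpoint distance in bp.  Bins are given
    by their edges; empty bins report NaN means (missing, not zero).
    """
    bins = np.asarray(bins, float)
    if len(bins) < 2 or np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be at least two increasing edges")
    mids = data.fragment_map.midpoints
    sep = np.abs(mids[data.pair_j] - mids[data.pair_i])
    which = np.digitize(sep, bins) - 1  # bin b covers [bins[b], bins[b+1])
    rows = []
    for b in range(len(bins) - 1):
        mask = which == b
        mean_if = float(data.values[mask].mean()) if mask.any() else np.nan
        rows.append((bins[b], bins[b + 1], int(mask.sum()), mean_if))
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "n_pairs",
                                       "mean_if"])
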