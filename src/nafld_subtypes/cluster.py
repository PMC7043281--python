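"""Patient clustering: Manhattan distances + Ward-criterion agglomeration.

The pipeline clusters patients on a binary feature matrix using the
Manhattan (city-block) distance and Ward's minimum-variance criterion in
its "D2" form: the Lance-Williams recurrence with Ward coefficients is
applied to *squared* input dissimilarities and reported merge heights are
the square roots of the updated squared dissimilarities.  This matches R's
``hclust(..., method="ward.D2")``, the convention used in the clinical
clustering literature this package follows, even though Ward's variance
interpretation is only exact for Euclidean input.

Ties (common with integer-valued Manhattan distances on binary data) are
broken deterministically by the smallest (left, right) cluster-id pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class Dendrogram:
    """Merge tree in scipy linkage convention.

    ``merges`` has one row per merge: (left id, right id, height, new size).
    Leaves are numbered 0..n-1 in the order of ``leaf_ids``; the cluster
    created by merge ``t`` has id ``n + t``.
    """

    merges: np.ndarray  # (n-1, 4) float
    leaf_ids: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1


@dataclass
class ClusterAssignment:
    """A k-cut of a dendrogram: per-patient labels in 1..k.

    Label 1 is the largest cluster (ties broken by smallest member leaf),
    so downstream analyses can use cluster 1 as the reference subtype.
    """

    labels: np.ndarray  # (n,) int, values 1..k
    k: int
    patient_ids: list = field(default_factory=list)

    def to_mapping(self) -> dict:
        return dict(zip(self.patient_ids, (int(v) for v in self.labels)))


def manhattan_distances(values: np.ndarray) -> np.ndarray:
    """Condensed pairwise Manhattan distance matrix.

    On binary rows this is the Hamming count of disagreeing features.
    Returns the usual condensed (upper-triangle, row-major) vector of
    length n*(n-1)/2.
    """
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("feature matrix must be a non-empty 2-D array")
    return pdist(values.astype(np.float64), metric="cityblock")


def ward_linkage(d: np.ndarray, n: int | None = None) -> Dendrogram:
    """Agglomerate with Ward's criterion in the D2 convention.

    Parameters
    ----------
    d : condensed or square dissimilarity matrix.
    n : number of observations (inferred when omitted).

    The Lance-Williams recurrence is applied to squared dissimilarities
    with Ward coefficients alpha_i=(n_i+n_k)/(n_i+n_j+n_k),
    beta=-n_k/(n_i+n_j+n_k), gamma=0; heights are square roots of the
    merged squared dissimilarity.  At every step the minimal-height pair
    with the lexicographically smallest (left, right) cluster-id pair is
    merged.
    """
    d = np.asarray(d, dtype=np.float64)
    if d.ndim == 1:
        sq = squareform(d, checks=False)
    else:
        sq = d.copy()
    m = sq.shape[0]
    if n is not None and n != m:
        raise ValueError(f"n={n} inconsistent with distance matrix of size {m}")
    n = m
    if n < 2:
        raise ValueError("need at least 2 observations to cluster")

    d2 = sq**2
    np.fill_diagonal(d2, np.inf)
    active = np.ones(n, dtype=bool)
    # slot -> current cluster id; ids n..2n-2 are created by merges
    cluster_id = np.arange(n)
    sizes = np.ones(n, dtype=np.int64)
    merges = np.empty((n - 1, 4), dtype=np.float64)

    for step in range(n - 1):
        sub = d2[np.ix_(active, active)]
        best = sub.min()
        # candidate slot pairs achieving the minimum (within fp noise,
        # so ties resolve identically across computation orders); pick
        # the smallest (left,right) cluster-id pair
        idx = np.flatnonzero(active)
        ii, jj = np.where(sub <= best + 1e-9 * max(1.0, best))
        pairs = [
            (*sorted((int(cluster_id[idx[a]]), int(cluster_id[idx[b]]))), idx[a], idx[b])
            for a, b in zip(ii, jj)
            if a < b
        ]
        left, right, si, sj = min(pairs)
        ni, nj = sizes[si], sizes[sj]
        h2 = d2[si, sj]

        # Lance-Williams Ward update against every other active cluster
        others = active.copy()
        others[si] = others[sj] = False
        nk = sizes[others]
        denom = ni + nj + nk
        new_d2 = ((ni + nk) * d2[si, others] + (nj + nk) * d2[sj, others] - nk * h2) / denom
        d2[si, others] = new_d2
        d2[others, si] = new_d2
        active[sj] = False
        sizes[si] = ni + nj
        cluster_id[si] = n + step
        merges[step] = (left, right, np.sqrt(h2), ni + nj)

    return Dendrogram(merges=merges)


def cut_tree(dend: Dendrogram, k: int, patient_ids=None) -> ClusterAssignment:
    """Cut a dendrogram into k clusters by undoing the last k-1 merges.

    Clusters are labeled 1..k in decreasing size order, ties broken by the
    smallest member leaf id.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent = np.arange(2 * n - 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b = int(dend.merges[t, 0]), int(dend.merges[t, 1])
        parent[find(a)] = parent[find(b)] = n + t

    roots = np.array([find(i) for i in range(n)])
    uniq = {}
    for i, r in enumerate(roots):
        uniq.setdefault(r, []).append(i)
    # order: decreasing size, then smallest leaf id
    ordered = sorted(uniq.values(), key=lambda mem: (-len(mem), mem[0]))
    labels = np.empty(n, dtype=np.int64)
    for lab, members in enumerate(ordered, start=1):
        labels[members] = lab
    ids = list(patient_ids) if patient_ids is not None else list(range(n))
    return ClusterAssignment(labels=labels, k=k, patient_ids=ids)
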