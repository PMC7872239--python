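"""Distance functions and Lance–Williams agglomerative clustering.

The clustering grid evaluates five distances (euclidean, maximum, manhattan,
canberra, minkowski) crossed with the classical hierarchical linkages, all
expressed through the Lance–Williams recurrence

    d(i∪j, k) = a_i d(i,k) + a_j d(j,k) + b d(i,j) + g |d(i,k) − d(j,k)|

applied to whatever distance matrix is supplied (the convention of R's
``hclust``, which the field's cluster-validity tooling builds on). ``ward_d``
applies the Ward coefficients to the raw distances; ``ward_d2`` applies them
to squared distances. ``median`` and ``centroid`` likewise operate on the
distances as given.

Only the partitions at each requested k are returned; merge heights are not
needed downstream.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

DISTANCES = ("euclidean", "maximum", "manhattan", "canberra", "minkowski")

#: hierarchical methods implemented via the Lance–Williams recurrence
LINKAGE_METHODS = ("ward_d", "ward_d2", "single", "complete", "average",
                   "mcquitty", "median", "centroid")

_SCIPY_METRIC = {
    "euclidean": "euclidean",
    "maximum": "chebyshev",
    "manhattan": "cityblock",
    "canberra": "canberra",
    "minkowski": "minkowski",
}


def distance_matrix(X: np.ndarray, distance: str, minkowski_p: float = 3.0) -> np.ndarray:
    """Full pairwise distance matrix for one of the supported distances.

    The Minkowski exponent defaults to 3 (p = 2 would duplicate euclidean).
    """
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    X = np.asarray(X, dtype=float)
    if distance == "minkowski":
        d = pdist(X, metric="minkowski", p=minkowski_p)
    else:
        d = pdist(X, metric=_SCIPY_METRIC[distance])
    return squareform(d)


def _lw_coefficients(method: str, ni: int, nj: int, nk: int):
    if method == "single":
        return 0.5, 0.5, 0.0, -0.5
    if method == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if method == "average":
        s = ni + nj
        return ni / s, nj / s, 0.0, 0.0
    if method == "mcquitty":
        return 0.5, 0.5, 0.0, 0.0
    if method == "median":
        return 0.5, 0.5, -0.25, 0.0
    if method == "centroid":
        s = ni + nj
        return ni / s, nj / s, -(ni * nj) / (s * s), 0.0
    if method in ("ward_d", "ward_d2"):
        t = ni + nj + nk
        return (ni + nk) / t, (nj + nk) / t, -nk / t, 0.0
    raise ValueError(f"unknown linkage method {method!r}")


def hierarchical_cut(D: np.ndarray, method: str,
                     k_values: Iterable[int]) -> Dict[int, np.ndarray]:
    """Agglomerate under ``method`` and return the partition at each k.

    Merges always join the currently closest active pair (ties: the
    lexicographically smallest index pair). Labels are canonical: cluster 0
    is the one containing the first point, and so on by first appearance.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}")
    n = D.shape[0]
    ks = sorted({int(k) for k in k_values if 1 <= int(k) <= n})
    out: Dict[int, np.ndarray] = {}
    if not ks:
        return out

    W = D.astype(float).copy()
    if method == "ward_d2":
        W = W ** 2
    np.fill_diagonal(W, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=int)
    labels = np.arange(n)

    def snapshot() -> np.ndarray:
        canon: Dict[int, int] = {}
        out_lab = np.empty(n, dtype=int)
        for idx, lab in enumerate(labels):
            if lab not in canon:
                canon[lab] = len(canon)
            out_lab[idx] = canon[lab]
        return out_lab

    n_active = n
    if n_active in ks:
        out[n_active] = snapshot()
    while n_active > max(1, ks[0]):
        # closest active pair; argmin scans row-major, so ties resolve to the
        # smallest (i, j)
        flat = np.argmin(W)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        ni, nj = int(sizes[i]), int(sizes[j])
        dij = W[i, j]
        mask = active.copy()
        mask[i] = mask[j] = False
        idx = np.where(mask)[0]
        if idx.size:
            dik = W[i, idx]
            djk = W[j, idx]
            if method in ("ward_d", "ward_d2"):
                nk = sizes[idx].astype(float)
                t = ni + nj + nk
                new = ((ni + nk) / t * dik + (nj + nk) / t * djk - nk / t * dij)
            else:
                ai, aj, b, g = _lw_coefficients(method, ni, nj, 0)
                new = ai * dik + aj * djk + b * dij + g * np.abs(dik - djk)
            W[i, idx] = new
            W[idx, i] = new
        active[j] = False
        sizes[i] = ni + nj
        W[j, :] = np.inf
        W[:, j] = np.inf
        labels[labels == j] = labels[i]
        n_active -= 1
        if n_active in ks:
            out[n_active] = snapshot()
    return out
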