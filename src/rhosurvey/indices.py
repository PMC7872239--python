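"""Cluster-validity indices with a uniform voting orientation.

Each index follows its standard published definition; ``ORIENTATION`` maps
index name to +1 (higher is better) or −1 (lower is better) so a majority
vote can treat them uniformly. An index that is undefined on a given
partition (e.g. no within-cluster pairs) returns NaN and abstains from the
vote.

Distance-based indices (silhouette, dunn, cindex, ptbiserial, mcclain) are
evaluated on the distance matrix of the combination under consideration;
Calinski–Harabasz and Davies–Bouldin are centroid-based and use the feature
matrix directly.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from sklearn.metrics import davies_bouldin_score, silhouette_score

INDEX_NAMES = ("silhouette", "ch", "db", "dunn", "cindex", "ptbiserial", "mcclain")

ORIENTATION: Dict[str, int] = {
    "silhouette": +1,
    "ch": +1,
    "db": -1,
    "dunn": +1,
    "cindex": -1,
    "ptbiserial": +1,
    "mcclain": -1,
}


def _calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Between/within dispersion ratio; +inf in the zero-within limit (a
    perfectly tight partition), which keeps the index's orientation coherent
    there."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = np.unique(labels)
    k = clusters.size
    overall = X.mean(axis=0)
    intra = 0.0
    extra = 0.0
    for c in clusters:
        Xc = X[labels == c]
        mu = Xc.mean(axis=0)
        intra += float(((Xc - mu) ** 2).sum())
        extra += Xc.shape[0] * float(((mu - overall) ** 2).sum())
    if intra == 0.0:
        return float("inf") if extra > 0.0 else float("nan")
    return extra * (n - k) / (intra * (k - 1))


def _pair_masks(labels: np.ndarray):
    n = labels.shape[0]
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    return iu, same


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    iu, same = _pair_masks(labels)
    d = D[iu]
    within = d[same]
    between = d[~same]
    if between.size == 0:
        return float("nan")
    diam = within.max() if within.size else 0.0
    if diam == 0.0:
        return float("inf")
    return float(between.min() / diam)


def _cindex(D: np.ndarray, labels: np.ndarray) -> float:
    iu, same = _pair_masks(labels)
    d = D[iu]
    nw = int(same.sum())
    if nw == 0:
        return float("nan")
    s = float(d[same].sum())
    d_sorted = np.sort(d)
    smin = float(d_sorted[:nw].sum())
    smax = float(d_sorted[-nw:].sum())
    if smax == smin:
        return float("nan")
    return (s - smin) / (smax - smin)


def _ptbiserial(D: np.ndarray, labels: np.ndarray) -> float:
    iu, same = _pair_masks(labels)
    d = D[iu]
    b = (~same).astype(float)  # 1 for between-cluster pairs
    if b.std() == 0.0 or d.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(d, b)[0, 1])


def _mcclain(D: np.ndarray, labels: np.ndarray) -> float:
    iu, same = _pair_masks(labels)
    d = D[iu]
    within = d[same]
    between = d[~same]
    if within.size == 0 or between.size == 0:
        return float("nan")
    mb = between.mean()
    if mb == 0.0:
        return float("nan")
    return float(within.mean() / mb)


def validity_index(name: str, X: np.ndarray, labels: np.ndarray,
                   D: np.ndarray) -> float:
    """Evaluate one validity index; NaN marks an undefined value.

    Parameters
    ----------
    name:
        One of :data:`INDEX_NAMES`.
    X:
        Feature matrix (metagenomes × retained RCs), used by the
        centroid-based indices.
    labels:
        Cluster labels covering all rows, at least two distinct.
    D:
        Pairwise distance matrix matching the combination being scored.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("validity indices require at least two clusters")
    if name == "silhouette":
        if np.unique(labels).size >= labels.size:
            return float("nan")  # singleton-only partition
        return float(silhouette_score(D, labels, metric="precomputed"))
    if name == "ch":
        return _calinski_harabasz(X, labels)
    if name == "db":
        return float(davies_bouldin_score(X, labels))
    if name == "dunn":
        return _dunn(D, labels)
    if name == "cindex":
        return _cindex(D, labels)
    if name == "ptbiserial":
        return _ptbiserial(D, labels)
    if name == "mcclain":
        return _mcclain(D, labels)
    raise ValueError(f"unknown validity index {name!r}")
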