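"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written from the definitions (plain loops,
dicts, no shared code with the package) so it can serve as an oracle for the
optimized implementations.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple


# ---------------------------------------------------------------------------
# Quantiles and the fragment classifier
# ---------------------------------------------------------------------------

def type7_quantile(values: Sequence[float], c: float) -> float:
    """Linear interpolation of order statistics at h = (n-1)c."""
    v = sorted(values)
    n = len(v)
    if n == 1:
        return v[0]
    h = (n - 1) * c
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_force_classify(hits, positives, c: float = 0.04,
                         min_score: float = 8.0,
                         length_tol: int = 0) -> List[bool]:
    """Re-derive every verdict from scratch: enumerate the conditioning set
    per hit and recompute both quantile thresholds."""
    out: List[bool] = []
    for x in hits:
        if x.score < min_score:
            out.append(False)
            continue
        q = []
        for p in positives:
            if abs(p.fragment_length - x.fragment_length) > length_tol:
                continue
            contains = p.ali_from <= x.ali_from and p.ali_to >= x.ali_to
            within = x.ali_from <= p.ali_from and x.ali_to >= p.ali_to
            if contains or within:
                q.append(p)
        if not q:
            out.append(False)
            continue
        xcov = (x.ali_to - x.ali_from + 1) / x.profile_length
        s_star = type7_quantile([p.score for p in q], c)
        v_star = type7_quantile(
            [(p.ali_to - p.ali_from + 1) / p.profile_length for p in q], c)
        out.append(x.score > s_star and xcov > v_star)
    return out


# ---------------------------------------------------------------------------
# Root-clade cut enumeration
# ---------------------------------------------------------------------------

def enumerate_covering_cuts(tree, n_rc: int) -> List[Tuple[int, ...]]:
    """All ways to cut the tree into exactly n_rc disjoint subtrees covering
    every leaf, as tuples of edge ids."""
    memo: Dict[Tuple[int, int], List[Tuple[int, ...]]] = {}

    def cuts(node, m: int) -> List[Tuple[int, ...]]:
        eid = tree.edge_id(node)
        key = (eid, m)
        if key in memo:
            return memo[key]
        res: List[Tuple[int, ...]] = []
        if m == 1:
            res.append((eid,))
        kids = node.child_nodes()
        if kids and m >= 2:
            def rec(i: int, remaining: int) -> List[Tuple[int, ...]]:
                if i == len(kids):
                    return [()] if remaining == 0 else []
                out: List[Tuple[int, ...]] = []
                tail = len(kids) - i - 1
                for mc in range(1, remaining - tail + 1):
                    for left in cuts(kids[i], mc):
                        for rest in rec(i + 1, remaining - mc):
                            out.append(left + rest)
                return out
            res.extend(rec(0, m))
        memo[key] = res
        return res

    return cuts(tree.tree.seed_node, n_rc)


def best_cut_by_enumeration(tree, n_rc: int) -> frozenset:
    """Minimal total root-distance covering cut, found by full enumeration."""
    rootdist = tree.root_distances()
    best = None
    best_cost = None
    for cut in enumerate_covering_cuts(tree, n_rc):
        cost = sum(rootdist[e] for e in cut)
        if best_cost is None or cost < best_cost:
            best, best_cost = cut, cost
    if best is None:
        raise ValueError(f"no covering cut of size {n_rc}")
    return frozenset(best)


# ---------------------------------------------------------------------------
# Agglomerative clustering by explicit merge search
# ---------------------------------------------------------------------------

def naive_linkage_labels(D, method: str, k: int) -> List[int]:
    """Brute-force agglomeration: at each step scan every active cluster
    pair, merge the closest, and recompute distances.

    single/complete/average distances are recomputed definitionally from the
    original pointwise matrix; the recurrence-defined methods (mcquitty,
    median, centroid, ward_d, ward_d2) update pairwise cluster distances via
    an independent transcription of their update formulas.
    """
    n = len(D)
    members: Dict[int, List[int]] = {i: [i] for i in range(n)}
    square = method == "ward_d2"
    work: Dict[Tuple[int, int], float] = {
        (i, j): (D[i][j] ** 2 if square else D[i][j])
        for i in range(n) for j in range(i + 1, n)
    }

    def defn_distance(a: int, b: int) -> float:
        vals = [D[p][q] for p in members[a] for q in members[b]]
        if method == "single":
            return min(vals)
        if method == "complete":
            return max(vals)
        if method == "average":
            return sum(vals) / len(vals)
        raise AssertionError

    while len(members) > k:
        pair = min(work, key=lambda ij: (work[ij], ij))
        i, j = pair
        dij = work.pop(pair)
        ni, nj = len(members[i]), len(members[j])
        others = [c for c in members if c not in (i, j)]
        old_i = {c: work[tuple(sorted((i, c)))] for c in others}
        old_j = {c: work[tuple(sorted((j, c)))] for c in others}
        members[i] = members[i] + members[j]
        del members[j]
        for c in others:
            del work[tuple(sorted((j, c)))]
        for c in others:
            key = tuple(sorted((i, c)))
            if method in ("single", "complete", "average"):
                work[key] = defn_distance(i, c)
                continue
            dik, djk = old_i[c], old_j[c]
            nk = len(members[c])
            if method == "mcquitty":
                work[key] = 0.5 * dik + 0.5 * djk
            elif method == "median":
                work[key] = 0.5 * dik + 0.5 * djk - 0.25 * dij
            elif method == "centroid":
                s = ni + nj
                work[key] = (ni * dik + nj * djk) / s - ni * nj * dij / (s * s)
            elif method in ("ward_d", "ward_d2"):
                t = ni + nj + nk
                work[key] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / t
            else:
                raise AssertionError(method)

    canon: Dict[int, int] = {}
    labels = [0] * n
    for cid in members:
        for p in members[cid]:
            labels[p] = cid
    out = []
    for lab in labels:
        if lab not in canon:
            canon[lab] = len(canon)
        out.append(canon[lab])
    return out
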