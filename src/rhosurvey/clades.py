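"""Root-clade selection and per-metagenome clade proportion profiles.

The reference rhodopsin tree is cut into ``n_rc`` disjoint subtrees — the
*root clades* (RCs, default 44) — chosen as the covering cut of the tree that
minimizes the total root-to-clade branch-length distance, i.e. the clades
closest to the root. Placed query fragments are then binned by RC and each
metagenome is summarized as a proportion vector

    p_i = sum_{fragments in RC i} (h/l)  /  sum_{all binned fragments} (h/l)

where h is the number of reads related to a fragment and l its length, so a
fragment contributes in proportion to its per-position read support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .errors import ValidationError
from .formats import PlacementTable, ReadSupportTable, ReferenceTree

logger = logging.getLogger(__name__)

_TIE_REL_TOL = 1e-12


@dataclass
class RootCladeSet:
    """A disjoint set of root-closest clades covering the reference leaves.

    ``clades`` maps rc_id → member reference leaves; edges whose leafset is
    not contained in a single clade (edges above the cut) are unassigned and
    fragments placed there are dropped by the profiler.
    """

    n_rc: int
    clades: Dict[str, FrozenSet[str]]
    cut_edges: Dict[str, int]
    root_distance: Dict[str, float]
    _leaf_to_rc: Dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._leaf_to_rc:
            for rc, leaves in self.clades.items():
                for leaf in leaves:
                    if leaf in self._leaf_to_rc:
                        raise ValidationError(f"leaf {leaf} in two root clades")
                    self._leaf_to_rc[leaf] = rc

    @property
    def rc_ids(self) -> List[str]:
        return list(self.clades.keys())

    def assign(self, leafset: FrozenSet[str]) -> Optional[str]:
        """RC containing every leaf below the placement edge, or None if the
        edge lies above the cut (or outside the tree's leaf set)."""
        rcs = {self._leaf_to_rc.get(leaf) for leaf in leafset}
        if len(rcs) == 1:
            return next(iter(rcs))
        return None


def _tie_key(cut: Tuple[int, ...], depths: Dict[int, int]) -> Tuple:
    return tuple(sorted((depths[e], e) for e in cut))


def select_root_clades(tree: ReferenceTree, n_rc: int = 44) -> RootCladeSet:
    """Cut the rooted tree into exactly ``n_rc`` disjoint subtrees covering
    all leaves, minimizing the summed root-to-clade-root branch-length
    distance ("the clades closest to the root").

    Exact dynamic program over the tree: for every node the minimal-cost way
    of splitting its subtree into m clades is either the node itself (m = 1)
    or a composition of its children's solutions. Cost ties are broken by
    topological depth of the cut nodes, then by node id.
    """
    if n_rc < 1:
        raise ValidationError("n_rc must be >= 1")
    if n_rc > tree.n_leaves:
        raise ValidationError(
            f"n_rc={n_rc} exceeds the attainable clade count "
            f"(max {tree.n_leaves} = number of leaves)"
        )
    rootdist = tree.root_distances()
    depths = tree.topological_depths()

    # tables[node] : m -> (cost, cut edge-id tuple)
    tables: Dict[int, Dict[int, Tuple[float, Tuple[int, ...]]]] = {}
    n_below: Dict[int, int] = {}
    for node in tree.tree.postorder_node_iter():
        eid = tree.edge_id(node)
        if node.is_leaf():
            n_below[eid] = 1
            tables[eid] = {1: (rootdist[eid], (eid,))}
            continue
        children = [tree.edge_id(ch) for ch in node.child_nodes()]
        n_below[eid] = sum(n_below[c] for c in children)
        cap = min(n_rc, n_below[eid])
        # combine children by sequential knapsack
        acc: Dict[int, Tuple[float, Tuple[int, ...]]] = dict(tables[children[0]])
        for c in children[1:]:
            nxt: Dict[int, Tuple[float, Tuple[int, ...]]] = {}
            for m1, (cost1, cut1) in acc.items():
                for m2, (cost2, cut2) in tables[c].items():
                    m = m1 + m2
                    if m > cap:
                        continue
                    cand = (cost1 + cost2, cut1 + cut2)
                    cur = nxt.get(m)
                    if cur is None or _better(cand, cur, depths):
                        nxt[m] = cand
            acc = nxt
        acc[1] = (rootdist[eid], (eid,))  # cut at this node itself
        tables[eid] = acc
        for c in children:  # free child tables
            del tables[c]

    root_eid = tree.edge_id(tree.tree.seed_node)
    if n_rc not in tables[root_eid]:
        raise ValidationError(
            f"tree cannot be cut into exactly {n_rc} covering clades"
        )
    _, cut = tables[root_eid][n_rc]
    ordered = sorted(cut, key=lambda e: (rootdist[e], depths[e], e))
    width = max(2, len(str(n_rc)))
    clades: Dict[str, FrozenSet[str]] = {}
    cut_edges: Dict[str, int] = {}
    rdist: Dict[str, float] = {}
    for i, eid in enumerate(ordered, start=1):
        rc = f"RC{i:0{width}d}"
        clades[rc] = tree.leafset(eid)
        cut_edges[rc] = eid
        rdist[rc] = rootdist[eid]
    return RootCladeSet(n_rc=n_rc, clades=clades, cut_edges=cut_edges,
                        root_distance=rdist)


def _better(cand, cur, depths) -> bool:
    ccost, ccut = cand
    kcost, kcut = cur
    tol = _TIE_REL_TOL * max(1.0, abs(ccost), abs(kcost))
    if abs(ccost - kcost) <= tol:
        return _tie_key(ccut, depths) < _tie_key(kcut, depths)
    return ccost < kcost


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class RCProfile:
    """Root-clade proportion vector for one metagenome.

    ``n_fragments`` counts fragments binned into some RC; proportions sum to
    one whenever the profile is non-empty (total h/l weight > 0).
    """

    metagenome_id: str
    p: Dict[str, float]
    n_fragments: int = 0
    n_unassigned: int = 0

    @property
    def is_empty(self) -> bool:
        return sum(self.p.values()) == 0.0


def profile_metagenome(placements: PlacementTable, reads: ReadSupportTable,
                       rcs: RootCladeSet) -> RCProfile:
    """Convert one metagenome's placements into an RC proportion profile.

    Fragments placed on edges above the clade cut cannot be attributed to a
    single RC and are dropped (their count is recorded and logged). A
    metagenome with zero total weight yields an all-zero profile flagged
    empty rather than NaNs.
    """
    weights: Dict[str, float] = {rc: 0.0 for rc in rcs.rc_ids}
    n_assigned = 0
    n_unassigned = 0
    for frag, (edge, _lwr) in placements.rows.items():
        leafset = placements.edge_leafsets[edge]
        rc = rcs.assign(leafset)
        if rc is None:
            n_unassigned += 1
            continue
        if frag not in reads.reads:
            raise ValidationError(f"fragment {frag} has no read-support entry")
        h = reads.reads[frag]
        l = placements.fragment_lengths.get(frag, reads.lengths.get(frag))
        if l is None:
            raise ValidationError(f"fragment {frag} has no recorded length")
        weights[rc] += h / l
        n_assigned += 1
    if n_unassigned:
        logger.info("%s: %d fragments above the clade cut were discarded",
                    placements.metagenome_id, n_unassigned)
    total = sum(weights.values())
    if total == 0.0:
        return RCProfile(placements.metagenome_id,
                         p={rc: 0.0 for rc in rcs.rc_ids},
                         n_fragments=n_assigned, n_unassigned=n_unassigned)
    return RCProfile(placements.metagenome_id,
                     p={rc: w / total for rc, w in weights.items()},
                     n_fragments=n_assigned, n_unassigned=n_unassigned)


def filter_metagenomes(profiles: Sequence[RCProfile],
                       min_fragments: int = 10) -> List[RCProfile]:
    """Exclude metagenomes with fewer than ``min_fragments`` fragments in the
    tree (default 10; a metagenome with exactly 10 is retained)."""
    return [pr for pr in profiles if pr.n_fragments >= min_fragments]


def family_proportions(profile: RCProfile, rcs: RootCladeSet,
                       tree: ReferenceTree) -> Dict[str, float]:
    """Rhodopsin-family proportions for one metagenome.

    Each family receives sum_i (fraction of RC i's reference leaves annotated
    with that family) × p_i; leaves without an annotation contribute to the
    "unknown" family, so the proportions always sum to the profile total.
    """
    out: Dict[str, float] = {}
    for rc, p_i in profile.p.items():
        leaves = rcs.clades[rc]
        if not leaves:
            raise ValidationError(f"{rc} has no reference leaves")
        frac = 1.0 / len(leaves)
        for leaf in leaves:
            fam = tree.families.get(leaf, "unknown")
            out[fam] = out.get(fam, 0.0) + frac * p_i
    return out
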