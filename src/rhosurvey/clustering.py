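"""Recursive consensus clustering of metagenomes by root-clade profiles.

Metagenomes are grouped by their RC proportion vectors through a recursive
procedure that builds a hierarchical grouping out of non-hierarchical
sub-groupings. At every level:

1. Uninformative RCs are eliminated by three criteria — (i) sparse columns
   (almost all metagenomes near zero and the rest still small), (ii) constant
   columns, and (iii) all but one of any set of fully correlated columns.
2. An exhaustive grid over distance functions × aggregation methods × k is
   evaluated; a panel of cluster-validity indices votes first for each
   combination's k and then for the winning combination.
3. The procedure recurses into every resulting group that is still large
   enough, re-running the elimination on the subgroup's submatrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DegenerateMatrixError, RhosurveyError, ValidationError
from .indices import INDEX_NAMES, ORIENTATION, validity_index
from .linkage import DISTANCES, LINKAGE_METHODS, distance_matrix, hierarchical_cut

logger = logging.getLogger(__name__)

AGGREGATION_METHODS = LINKAGE_METHODS + ("kmeans",)


class NoMajorityError(RhosurveyError):
    """No validity index produced a usable vote on this matrix."""


# ---------------------------------------------------------------------------
# RC elimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EliminationConfig:
    """Thresholds for the three RC-elimination criteria.

    Criterion (i): a column is sparse when more than ``sparse_major_frac`` of
    metagenomes sit below ``sparse_minor_prop`` and every remaining value is
    below ``sparse_major_prop``. Criterion (ii): a constant column.
    Criterion (iii): of any set of columns pairwise correlated at
    |r| ≥ ``corr_threshold`` (Pearson; the default 1.0 means "fully
    correlated", applied with a 1e-12 numerical allowance), only the first
    is kept.
    """

    sparse_major_frac: float = 0.95
    sparse_minor_prop: float = 0.001
    sparse_major_prop: float = 0.02
    corr_threshold: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sparse_major_frac", "sparse_minor_prop",
                     "sparse_major_prop", "corr_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0,1], got {v}")


@dataclass(frozen=True)
class RemovedRC:
    rc_id: str
    criterion: str  # "sparse", "constant", "correlated"
    detail: str = ""


def eliminate_rcs(matrix: pd.DataFrame,
                  config: EliminationConfig = EliminationConfig()
                  ) -> Tuple[pd.DataFrame, List[RemovedRC]]:
    """Drop uninformative RC columns; returns the reduced matrix and a report
    listing each removal with its triggering criterion.

    The three criteria are applied in order on the progressively reduced
    matrix, which makes the operation idempotent.
    """
    report: List[RemovedRC] = []
    df = matrix.copy()
    n = len(df)

    # (ii) constant columns first, so an all-zero column reports as
    # constant rather than as a trivially sparse one
    for col in list(df.columns):
        v = df[col].to_numpy(dtype=float)
        if v.size and v.max() == v.min():
            report.append(RemovedRC(str(col), "constant", f"value {v[0]!r}"))
            df = df.drop(columns=[col])

    # (i) sparse
    for col in list(df.columns):
        v = df[col].to_numpy(dtype=float)
        frac_minor = float((v < config.sparse_minor_prop).mean())
        rest = v[v >= config.sparse_minor_prop]
        if frac_minor > config.sparse_major_frac and bool(
                (rest < config.sparse_major_prop).all()):
            report.append(RemovedRC(str(col), "sparse",
                                    f"{frac_minor:.3f} of {n} below "
                                    f"{config.sparse_minor_prop}"))
            df = df.drop(columns=[col])

    # (iii) fully correlated — keep the lowest column index of each group
    cols = list(df.columns)
    if len(cols) > 1:
        corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
        thr = config.corr_threshold - 1e-12
        kept: List[int] = []
        for j in range(len(cols)):
            partner = next((i for i in kept
                            if abs(corr[i, j]) >= thr), None)
            if partner is None:
                kept.append(j)
            else:
                report.append(RemovedRC(str(cols[j]), "correlated",
                                        f"|r| with {cols[partner]} >= "
                                        f"{config.corr_threshold}"))
        df = df[[cols[j] for j in kept]]

    if df.shape[1] == 0:
        raise ValidationError(
            "all RC columns were eliminated; review elimination thresholds"
        )
    return df, report


# ---------------------------------------------------------------------------
# Grid search with index majority vote
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridConfig:
    """The exhaustive (distance × method × k) search space and the index
    panels that vote on it.

    ``k_indices`` choose each combination's number of groups; then
    ``combo_indices`` score the combinations at their voted k and elect the
    winner by plurality. K-means participates only with the euclidean
    distance (its objective) and uses ``kmeans_restarts`` restarts with a
    fixed seed.
    """

    distances: Tuple[str, ...] = DISTANCES
    methods: Tuple[str, ...] = AGGREGATION_METHODS
    k_min: int = 2
    k_max: int = 10
    k_indices: Tuple[str, ...] = INDEX_NAMES
    combo_indices: Tuple[str, ...] = INDEX_NAMES
    minkowski_p: float = 3.0
    kmeans_restarts: int = 25

    def __post_init__(self) -> None:
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValidationError("need 2 <= k_min <= k_max")
        if not self.k_indices or not self.combo_indices:
            raise ValidationError("index panels must be non-empty")
        for d in self.distances:
            if d not in DISTANCES:
                raise ValidationError(f"unknown distance {d!r}")
        for m in self.methods:
            if m not in AGGREGATION_METHODS:
                raise ValidationError(f"unknown aggregation method {m!r}")


@dataclass
class GridLevelResult:
    """Outcome of one grid search: the winning combination, its partition,
    and the full vote tallies."""

    distance: str
    method: str
    k: int
    labels: np.ndarray
    members: List[str]
    k_votes: Dict[Tuple[str, str], Dict[str, int]]
    voted_k: Dict[Tuple[str, str], int]
    combo_votes: Dict[str, Tuple[str, str]]

    def groups(self) -> List[List[str]]:
        return [[m for m, lab in zip(self.members, self.labels) if lab == c]
                for c in sorted(set(self.labels.tolist()))]


def _plurality(votes: Sequence, tie_key) -> Optional[object]:
    if not votes:
        return None
    tally: Dict[object, int] = {}
    for v in votes:
        tally[v] = tally.get(v, 0) + 1
    best = max(tally.values())
    winners = [v for v, c in tally.items() if c == best]
    return sorted(winners, key=tie_key)[0]


def cluster_grid(matrix: pd.DataFrame, grid: GridConfig = GridConfig(),
                 seed: int = 0) -> GridLevelResult:
    """Search (distance × method × k) and elect a grouping by index majority.

    For every combination, each k-index votes for the k it scores best
    (plurality, smaller k on ties); each combo-index then votes for the best
    combination evaluated at its voted k (ties: lexicographic
    (distance, method)).
    """
    if len(matrix) < 3:
        raise ValidationError("clustering needs at least 3 metagenomes")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("profile matrix contains non-finite values")
    if np.all(X == X[0]):
        raise DegenerateMatrixError("all metagenome profiles are identical")
    n = X.shape[0]
    ks = list(range(grid.k_min, min(grid.k_max, n - 1) + 1))
    if not ks:
        raise ValidationError(f"k range empty for n={n}")

    dist_mats = {d: distance_matrix(X, d, grid.minkowski_p) for d in grid.distances}

    partitions: Dict[Tuple[str, str], Dict[int, np.ndarray]] = {}
    for dname in grid.distances:
        D = dist_mats[dname]
        for mname in grid.methods:
            if mname == "kmeans":
                if dname != "euclidean":
                    continue  # k-means optimizes a euclidean objective
                parts = {}
                for k in ks:
                    km = KMeans(n_clusters=k, n_init=grid.kmeans_restarts,
                                random_state=seed)
                    with warnings.catch_warnings():
                        # duplicate points can collapse clusters; the vote
                        # simply sees the coarser partition
                        warnings.simplefilter("ignore")
                        parts[k] = km.fit_predict(X)
                partitions[(dname, mname)] = parts
            else:
                partitions[(dname, mname)] = hierarchical_cut(D, mname, ks)

    # cache index values: (combo, k, index) -> float
    values: Dict[Tuple[Tuple[str, str], int, str], float] = {}

    def value(combo, k, name) -> float:
        key = (combo, k, name)
        if key not in values:
            labels = partitions[combo][k]
            if np.unique(labels).size < 2:
                values[key] = float("nan")
            else:
                values[key] = validity_index(name, X, labels,
                                             dist_mats[combo[0]])
        return values[key]

    # per-combination k vote
    voted_k: Dict[Tuple[str, str], int] = {}
    k_votes: Dict[Tuple[str, str], Dict[str, int]] = {}
    for combo in partitions:
        votes: Dict[str, int] = {}
        for name in grid.k_indices:
            vals = [(k, value(combo, k, name)) for k in ks]
            finite = [(k, v) for k, v in vals if not np.isnan(v)]
            if not finite:
                continue
            sign = ORIENTATION[name]
            best = max(sign * v for _, v in finite)
            votes[name] = min(k for k, v in finite if sign * v == best)
        if votes:
            k_votes[combo] = votes
            voted_k[combo] = _plurality(list(votes.values()), tie_key=lambda k: k)

    if not voted_k:
        raise NoMajorityError("no validity index produced a vote for any "
                              "combination")

    # combination vote at each combination's voted k
    combo_votes: Dict[str, Tuple[str, str]] = {}
    for name in grid.combo_indices:
        scored = [(combo, value(combo, voted_k[combo], name))
                  for combo in voted_k]
        finite = [(c, v) for c, v in scored if not np.isnan(v)]
        if not finite:
            continue
        sign = ORIENTATION[name]
        best = max(sign * v for _, v in finite)
        combo_votes[name] = sorted(c for c, v in finite if sign * v == best)[0]
    if not combo_votes:
        raise NoMajorityError("no validity index could score the voted "
                              "combinations")

    winner = _plurality(list(combo_votes.values()), tie_key=lambda c: c)
    k_win = voted_k[winner]
    labels = partitions[winner][k_win]
    sizes = np.bincount(labels)
    if (sizes == 1).any():
        logger.info("winning partition contains %d singleton cluster(s)",
                    int((sizes == 1).sum()))
    return GridLevelResult(distance=winner[0], method=winner[1], k=k_win,
                           labels=labels, members=list(matrix.index),
                           k_votes=k_votes, voted_k=voted_k,
                           combo_votes=combo_votes)


# ---------------------------------------------------------------------------
# Recursive grouping
# ---------------------------------------------------------------------------

@dataclass
class GroupingNode:
    """One node of the nested grouping: a set of metagenomes, the grid result
    that split it (if any), and the sub-groups as children."""

    members: List[str]
    level: int
    note: str = ""
    elimination: List[RemovedRC] = field(default_factory=list)
    grid_result: Optional[GridLevelResult] = None
    children: List["GroupingNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["GroupingNode"]:
        if self.is_leaf:
            return [self]
        out: List[GroupingNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_partition(self) -> Dict[str, int]:
        """Finest partition: metagenome → index of its leaf group."""
        out: Dict[str, int] = {}
        for i, leaf in enumerate(self.leaves()):
            for m in leaf.members:
                out[m] = i
        return out

    def top_partition(self) -> Dict[str, int]:
        """Level-0 partition (the first split), or one group if none."""
        if self.is_leaf:
            return {m: 0 for m in self.members}
        return {m: i for i, ch in enumerate(self.children) for m in ch.members}


def recursive_grouping(matrix: pd.DataFrame,
                       grid: GridConfig = GridConfig(),
                       elim: EliminationConfig = EliminationConfig(),
                       min_group: int = 10,
                       seed: int = 0) -> GroupingNode:
    """Hierarchical grouping from recursively re-clustered sub-groups.

    Each node re-runs RC elimination on its submatrix (rows of the original
    matrix) and a fresh grid vote; groups smaller than ``min_group`` or whose
    submatrix is degenerate become leaves. A failing branch is reported on
    its node without aborting siblings.
    """

    def build(sub: pd.DataFrame, level: int, branch_seed: int) -> GroupingNode:
        node = GroupingNode(members=list(sub.index), level=level)
        if len(sub) < min_group:
            node.note = "below-min-size"
            return node
        try:
            reduced, node.elimination = eliminate_rcs(sub, elim)
        except ValidationError as exc:
            node.note = f"elimination failed: {exc}"
            return node
        try:
            node.grid_result = cluster_grid(reduced, grid, seed=branch_seed)
        except (DegenerateMatrixError, NoMajorityError, ValidationError) as exc:
            node.note = f"no further structure: {exc}"
            return node
        for i, group in enumerate(node.grid_result.groups()):
            child_seed = int((branch_seed * 1000003 + 7919 * (i + 1)) % (2**31 - 1))
            node.children.append(build(matrix.loc[group], level + 1, child_seed))
        return node

    return build(matrix, level=0, branch_seed=seed)
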