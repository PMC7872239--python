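"""Readers and writers for the external formats the pipeline touches.

All downstream modules operate on the in-memory types defined here:

* :class:`HitRecord` — one profile-search match (HMMER domain-table row or a
  plain TSV row) carrying the bit score and the profile alignment interval.
* :class:`ReadSupportTable` — per-fragment read counts (and optionally
  fragment lengths) used as weights throughout the pipeline.
* :class:`ReferenceTree` — the rooted reference rhodopsin tree with one
  family annotation per reference leaf.
* :class:`PlacementTable` — per-metagenome fragment-to-edge assignments
  reduced from a jplace file to the single most probable placement each.

Coordinates follow the HMMER convention: profile columns are 1-based and
alignment intervals are inclusive on both ends.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

UNKNOWN_FAMILY = "unknown"


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    """One profile-search match for a translated read fragment.

    ``ali_from``/``ali_to`` are the first and last profile columns covered by
    the alignment (1-based, inclusive). ``coverage`` is the fraction of the
    profile spanned by the alignment, which is the quantity the fragment
    classifier thresholds (together with the bit score).
    """

    fragment_id: str
    fragment_length: int
    score: float
    ali_from: int
    ali_to: int
    profile_length: int

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ValidationError(
                f"{self.fragment_id}: fragment_length must be >= 1, "
                f"got {self.fragment_length}"
            )
        if not (1 <= self.ali_from <= self.ali_to <= self.profile_length):
            raise ValidationError(
                f"{self.fragment_id}: require 1 <= ali_from <= ali_to <= "
                f"profile_length, got [{self.ali_from}, {self.ali_to}] on a "
                f"{self.profile_length}-column profile"
            )

    @property
    def coverage(self) -> float:
        """Fraction of profile columns covered by the alignment, in (0, 1]."""
        return (self.ali_to - self.ali_from + 1) / self.profile_length


#: domtblout column indices (whitespace-split): target name, tlen,
#: full-sequence bit score, qlen, hmm from, hmm to.
_DOMTBL_COLS = {"target": 0, "tlen": 2, "qlen": 5, "score": 7, "hmm_from": 15, "hmm_to": 16}


def _hit_from_fields(fields: Sequence[str], lineno: int) -> HitRecord:
    try:
        return HitRecord(
            fragment_id=fields[0],
            fragment_length=int(fields[1]),
            score=float(fields[2]),
            ali_from=int(fields[3]),
            ali_to=int(fields[4]),
            profile_length=int(fields[5]),
        )
    except (ValueError, IndexError) as exc:
        raise FormatError(f"line {lineno}: malformed hit row: {exc}") from exc


def _hit_from_domtbl(fields: Sequence[str], lineno: int) -> HitRecord:
    c = _DOMTBL_COLS
    try:
        return HitRecord(
            fragment_id=fields[c["target"]],
            fragment_length=int(fields[c["tlen"]]),
            score=float(fields[c["score"]]),
            ali_from=int(fields[c["hmm_from"]]),
            ali_to=int(fields[c["hmm_to"]]),
            profile_length=int(fields[c["qlen"]]),
        )
    except (ValueError, IndexError) as exc:
        raise FormatError(f"line {lineno}: malformed domtblout row: {exc}") from exc


def read_hit_table(path, dialect: str = "tsv", strict: bool = True) -> List[HitRecord]:
    """Read a profile-search hit table.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"domtbl"`` for HMMER ``--domtblout`` output (whitespace-delimited,
        ``#`` comment lines), or ``"tsv"`` for a six-column whitespace table
        ``fragment_id  fragment_length  score  ali_from  ali_to
        profile_length`` (an optional header line is detected and skipped).
    strict:
        If True (default), a malformed or invariant-violating row raises;
        if False, offending rows are dropped and their count logged.
    """
    if dialect not in ("domtbl", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parse = _hit_from_domtbl if dialect == "domtbl" else _hit_from_fields
    records: List[HitRecord] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if dialect == "tsv" and lineno == 1 and len(fields) >= 2:
                try:
                    float(fields[1])
                except ValueError:
                    continue  # header line
            try:
                records.append(parse(fields, lineno))
            except (FormatError, ValidationError):
                if strict:
                    raise
                n_rejected += 1
    if n_rejected:
        logger.warning("%s: rejected %d invalid hit rows", path, n_rejected)
    if not records:
        logger.warning("%s: hit table is empty", path)
    return records


def write_hit_table(records: Iterable[HitRecord], path) -> None:
    """Write hits in the plain six-column TSV dialect."""
    with open(path, "w") as fh:
        fh.write("fragment_id\tfragment_length\tscore\tali_from\tali_to\tprofile_length\n")
        for r in records:
            fh.write(
                f"{r.fragment_id}\t{r.fragment_length}\t{r.score!r}\t"
                f"{r.ali_from}\t{r.ali_to}\t{r.profile_length}\n"
            )


# ---------------------------------------------------------------------------
# Read-support tables
# ---------------------------------------------------------------------------

@dataclass
class ReadSupportTable:
    """Per-fragment read counts, optionally with fragment lengths.

    ``reads[f]`` is h, the number of reads related to fragment f. The
    optional ``lengths`` column lets one TSV carry both weights needed by the
    clade-profile statistic (h and l).
    """

    reads: Dict[str, int] = field(default_factory=dict)
    lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f, h in self.reads.items():
            if h < 0:
                raise ValidationError(f"{f}: read count must be >= 0, got {h}")
        for f, l in self.lengths.items():
            if l < 1:
                raise ValidationError(f"{f}: fragment length must be >= 1, got {l}")


def read_read_support(path) -> ReadSupportTable:
    """Read a 2- or 3-column TSV: fragment_id, reads[, length]."""
    reads: Dict[str, int] = {}
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1:
                try:
                    int(fields[1])
                except (ValueError, IndexError):
                    continue  # header
            try:
                reads[fields[0]] = int(fields[1])
                if len(fields) > 2:
                    lengths[fields[0]] = int(fields[2])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"line {lineno}: malformed read-support row") from exc
    return ReadSupportTable(reads=reads, lengths=lengths)


def write_read_support(table: ReadSupportTable, path) -> None:
    with_len = bool(table.lengths)
    with open(path, "w") as fh:
        fh.write("fragment_id\treads\tlength\n" if with_len else "fragment_id\treads\n")
        for f in sorted(table.reads):
            if with_len:
                fh.write(f"{f}\t{table.reads[f]}\t{table.lengths[f]}\n")
            else:
                fh.write(f"{f}\t{table.reads[f]}\n")


# ---------------------------------------------------------------------------
# Reference tree
# ---------------------------------------------------------------------------

class ReferenceTree:
    """A rooted reference rhodopsin tree with per-leaf family annotations.

    Every node (equivalently, the edge above it) carries a stable integer
    ``edge_id`` assigned in postorder; ``leafset(edge_id)`` is the set of leaf
    labels below that edge, which is how placements and root clades are
    matched without relying on node object identity.
    """

    def __init__(self, tree: dendropy.Tree, families: Optional[Mapping[str, str]] = None):
        tree.is_rooted = True
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValidationError("reference tree leaf labels are not unique")
        self.leaf_labels: List[str] = labels
        fam = dict(families or {})
        self.families: Dict[str, str] = {
            lab: fam.get(lab, UNKNOWN_FAMILY) for lab in labels
        }
        self._index_edges()

    def _index_edges(self) -> None:
        self._edge_of_node: Dict[int, int] = {}
        self._leafsets: Dict[int, FrozenSet[str]] = {}
        self._node_by_edge: Dict[int, dendropy.Node] = {}
        for i, node in enumerate(self.tree.postorder_node_iter()):
            self._edge_of_node[id(node)] = i
            self._node_by_edge[i] = node
            if node.is_leaf():
                self._leafsets[i] = frozenset({node.taxon.label})
            else:
                ls: set = set()
                for ch in node.child_nodes():
                    ls |= self._leafsets[self._edge_of_node[id(ch)]]
                self._leafsets[i] = frozenset(ls)

    # -- queries ------------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def edge_id(self, node: dendropy.Node) -> int:
        return self._edge_of_node[id(node)]

    def node_of_edge(self, edge_id: int) -> dendropy.Node:
        return self._node_by_edge[edge_id]

    def leafset(self, edge_id: int) -> FrozenSet[str]:
        return self._leafsets[edge_id]

    def edge_leafsets(self) -> Dict[int, FrozenSet[str]]:
        return dict(self._leafsets)

    def root_distances(self) -> Dict[int, float]:
        """Cumulative branch length from the root to each node, by edge id."""
        out: Dict[int, float] = {}
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is root:
                out[self.edge_id(node)] = 0.0
            else:
                bl = node.edge.length or 0.0
                out[self.edge_id(node)] = out[self.edge_id(node.parent_node)] + bl
        return out

    def topological_depths(self) -> Dict[int, int]:
        out: Dict[int, int] = {}
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is root:
                out[self.edge_id(node)] = 0
            else:
                out[self.edge_id(node)] = out[self.edge_id(node.parent_node)] + 1
        return out


def read_reference_tree(newick_path, annotations_path=None) -> ReferenceTree:
    """Read a plain-Newick reference tree plus an optional leaf→family TSV.

    Leaves absent from the annotation table are labelled ``"unknown"``.
    """
    tree = dendropy.Tree.get(
        path=str(newick_path), schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
    families: Dict[str, str] = {}
    if annotations_path is not None:
        with open(annotations_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"malformed annotation row: {line!r}")
                families[parts[0]] = parts[1]
    return ReferenceTree(tree, families)


def write_reference_tree(ref: ReferenceTree, newick_path, annotations_path=None) -> None:
    ref.tree.write(path=str(newick_path), schema="newick",
                   suppress_rooting=True, unquoted_underscores=True)
    if annotations_path is not None:
        with open(annotations_path, "w") as fh:
            for lab in ref.leaf_labels:
                fh.write(f"{lab}\t{ref.families[lab]}\n")


# ---------------------------------------------------------------------------
# jplace placements
# ---------------------------------------------------------------------------

@dataclass
class PlacementTable:
    """Best placement per fragment for one metagenome.

    ``rows[fragment_id] = (edge_id, like_weight_ratio)`` after reduction to
    the single most probable location; ``edge_leafsets`` describes the edge
    numbering of the tree the placements refer to, as the set of leaf labels
    below each numbered edge.
    """

    metagenome_id: str
    rows: Dict[str, Tuple[int, float]] = field(default_factory=dict)
    fragment_lengths: Dict[str, int] = field(default_factory=dict)
    edge_leafsets: Dict[int, FrozenSet[str]] = field(default_factory=dict)

    def with_lengths(self, lengths: Mapping[str, int]) -> "PlacementTable":
        merged = dict(self.fragment_lengths)
        merged.update(lengths)
        return PlacementTable(self.metagenome_id, dict(self.rows), merged,
                              dict(self.edge_leafsets))


_EDGE_NUM_RE = re.compile(r"\{(\d+)\}")


def _parse_edge_numbered_newick(newick: str) -> Dict[int, FrozenSet[str]]:
    """Map jplace edge numbers to the leaf-label set below each edge."""
    converted = _EDGE_NUM_RE.sub(lambda m: f"[&edge={m.group(1)}]", newick)
    tree = dendropy.Tree.get(
        data=converted, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
        extract_comment_metadata=True,
    )
    leafsets: Dict[int, FrozenSet[str]] = {}
    below: Dict[int, FrozenSet[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ls = frozenset({node.taxon.label})
        else:
            s: set = set()
            for ch in node.child_nodes():
                s |= below[id(ch)]
            ls = frozenset(s)
        below[id(node)] = ls
        edge = node.annotations.get_value("edge", None)
        if edge is not None:
            leafsets[int(edge)] = ls
    if not leafsets:
        raise FormatError("jplace tree carries no {n} edge numbers")
    return leafsets


def read_jplace(path, fragment_lengths: Optional[Mapping[str, int]] = None,
                metagenome_id: Optional[str] = None) -> PlacementTable:
    """Read a jplace (version 3) file, keeping only the most probable
    placement of each fragment (maximal like_weight_ratio; ties broken by the
    lowest edge number and logged).
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("tree", "placements", "fields"):
        if key not in doc:
            raise FormatError(f"jplace file missing mandatory key {key!r}")
    fields = doc["fields"]
    try:
        i_edge = fields.index("edge_num")
        i_lwr = fields.index("like_weight_ratio")
    except ValueError as exc:
        raise FormatError(f"jplace fields lack edge_num/like_weight_ratio: {fields}") from exc

    edge_leafsets = _parse_edge_numbered_newick(doc["tree"])
    rows: Dict[str, Tuple[int, float]] = {}
    for pquery in doc["placements"]:
        if "n" in pquery:
            names = list(pquery["n"])
        elif "nm" in pquery:
            names = [nm[0] for nm in pquery["nm"]]
        else:
            raise FormatError("placement entry lacks 'n'/'nm' name field")
        best: Optional[Tuple[int, float]] = None
        tie = False
        for p in pquery["p"]:
            edge, lwr = int(p[i_edge]), float(p[i_lwr])
            if edge not in edge_leafsets:
                raise ValidationError(f"placement on unknown edge {edge}")
            if best is None or lwr > best[1] + 0.0:
                best, tie = (edge, lwr), False
            elif lwr == best[1]:
                tie = True
                if edge < best[0]:
                    best = (edge, lwr)
        assert best is not None
        for name in names:
            if tie:
                logger.info("%s: like-weight-ratio tie, kept edge %d", name, best[0])
            rows[name] = best
    lengths = dict(fragment_lengths or {})
    mg = metagenome_id if metagenome_id is not None else str(path)
    return PlacementTable(metagenome_id=mg, rows=rows,
                          fragment_lengths=lengths, edge_leafsets=edge_leafsets)


def write_jplace(ref: ReferenceTree, placements: Mapping[str, Tuple[int, float]],
                 path, metadata: Optional[dict] = None) -> None:
    """Write placements against ``ref`` as a jplace v3 file.

    Edge numbers in the output are the reference tree's postorder edge ids,
    so a read/write round trip preserves edge identity.
    """

    def _newick(node: dendropy.Node) -> str:
        if node.is_leaf():
            base = node.taxon.label
        else:
            base = "(" + ",".join(_newick(ch) for ch in node.child_nodes()) + ")"
        bl = node.edge.length if node.edge.length is not None else 0.0
        return f"{base}:{bl!r}{{{ref.edge_id(node)}}}"

    doc = {
        "version": 3,
        "tree": _newick(ref.tree.seed_node) + ";",
        "fields": ["edge_num", "likelihood", "like_weight_ratio",
                   "distal_length", "pendant_length"],
        "placements": [
            {"p": [[edge, 0.0, lwr, 0.0, 0.0]], "n": [frag]}
            for frag, (edge, lwr) in sorted(placements.items())
        ],
        "metadata": metadata or {"invocation": "rhosurvey"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Profile matrices
# ---------------------------------------------------------------------------

def write_profile_matrix(profiles: Sequence, path) -> None:
    """Write root-clade profiles as a TSV matrix (metagenomes × RCs).

    All profiles must share one RC index set; values round-trip through
    :func:`read_profile_matrix` to full float precision.
    """
    if not profiles:
        raise ValidationError("no profiles to write")
    rc_ids = list(profiles[0].p.keys())
    for prof in profiles:
        if list(prof.p.keys()) != rc_ids:
            raise ValidationError(
                f"profile {prof.metagenome_id} has a mismatched RC set"
            )
    df = pd.DataFrame(
        [[prof.p[rc] for rc in rc_ids] for prof in profiles],
        index=[prof.metagenome_id for prof in profiles],
        columns=rc_ids,
    )
    df.to_csv(path, sep="\t", index_label="metagenome_id")


def read_profile_matrix(path) -> pd.DataFrame:
    """Read a profile matrix TSV into a DataFrame (rows = metagenomes)."""
    return pd.read_csv(path, sep="\t", index_col=0)
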