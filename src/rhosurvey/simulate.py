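"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study's inputs at desk scale: profile-search hit
tables with separated true/false score and coverage distributions, a random
reference tree with family annotations, jplace-style placements drawn
multinomially from planted root-clade profiles, read-support tables with
negative-binomial depth noise, and synthetic communities in which a chosen
fraction of genomes carries one rhodopsin gene while every genome carries
one recombinase.

All generators are deterministic under their seed and emit objects that the
:mod:`rhosurvey.formats` writers can serialize, so file round trips are
covered by the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .abundance import FragmentWeightSet
from .clades import RootCladeSet
from .classifier import PositiveSet
from .errors import ValidationError
from .formats import HitRecord, PlacementTable, ReadSupportTable, ReferenceTree

DEFAULT_FAMILIES = ("xanthorhodopsin", "proteorhodopsin", "halorhodopsin",
                    "NQ-rhodopsin", "sensory", "unknown")


def rc_names(n_rc: int) -> List[str]:
    width = max(2, len(str(n_rc)))
    return [f"RC{i:0{width}d}" for i in range(1, n_rc + 1)]


# ---------------------------------------------------------------------------
# Profile-search hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitSimSpec:
    """Generator settings for simulated profile-search hits.

    Scores follow a per-aligned-column model: a hit aligning ``s`` profile
    columns scores ``bits_per_column * s`` plus Gaussian noise, which couples
    score and coverage the way real profile searches do (longer alignments
    score higher). True hits align most of the profile (coverage
    Beta(8, 2)); false hits are short, weak matches (Beta(2, 5), lower
    per-column rate). Alignment intervals anchor on the profile's conserved
    core: the interval midpoint jitters around the profile center
    (``placement_beta`` controls the jitter; larger = tighter centering), so
    intervals of different widths tend to nest, giving candidates
    containment support among the positives. Fragment lengths come from a
    narrow band, so length-conditioned classification has support. A
    fraction of positives ("anchors") aligns nearly the whole profile.

    The positive reference set spans the family's full diversity and so has
    a heavier low-coverage tail (``positive_coverage_beta``) than the true
    candidates, which are typical family members; the c-quantile threshold
    is designed to cut exactly those reference stragglers.
    """

    n_true: int = 100
    n_false: int = 100
    n_positives: int = 200
    profile_length: int = 250
    length_min: int = 60
    length_max: int = 62
    true_bits_per_column: float = 0.55
    false_bits_per_column: float = 0.22
    score_sd: float = 2.5
    true_coverage_beta: Tuple[float, float] = (8.0, 2.0)
    false_coverage_beta: Tuple[float, float] = (2.0, 5.0)
    positive_coverage_beta: Tuple[float, float] = (4.0, 2.0)
    placement_beta: float = 50.0
    anchor_fraction: float = 0.1
    seed: int = 0


@dataclass
class SimulatedHits:
    hits: List[HitRecord]
    labels: np.ndarray  # True for genuine family members
    positives: PositiveSet


def _draw_hit(rng: np.random.Generator, spec: HitSimSpec, true_hit: bool,
              fragment_id: str, anchor: bool = False,
              positive: bool = False) -> HitRecord:
    L = spec.profile_length
    length = int(rng.integers(spec.length_min, spec.length_max + 1))
    if anchor:
        cov = float(rng.uniform(0.97, 1.0))
    else:
        if positive:
            a, b = spec.positive_coverage_beta
        else:
            a, b = spec.true_coverage_beta if true_hit else spec.false_coverage_beta
        cov = float(rng.beta(a, b))
    span = min(L, max(1, int(round(cov * L))))
    u = rng.beta(spec.placement_beta, spec.placement_beta)
    start = 1 + int(round(u * (L - span)))
    rate = spec.true_bits_per_column if true_hit else spec.false_bits_per_column
    score = rate * span + float(rng.normal(0.0, spec.score_sd))
    return HitRecord(fragment_id=fragment_id, fragment_length=length,
                     score=score, ali_from=start, ali_to=start + span - 1,
                     profile_length=L)


def simulate_hits(spec: HitSimSpec) -> SimulatedHits:
    """Simulate a positive reference set plus a labeled mix of candidates."""
    rng = np.random.default_rng(spec.seed)
    n_anchor = int(round(spec.anchor_fraction * spec.n_positives))
    positives = [
        _draw_hit(rng, spec, True, f"pos{i:04d}", anchor=(i < n_anchor),
                  positive=True)
        for i in range(spec.n_positives)
    ]
    hits: List[HitRecord] = []
    labels: List[bool] = []
    for i in range(spec.n_true):
        hits.append(_draw_hit(rng, spec, True, f"true{i:04d}"))
        labels.append(True)
    for i in range(spec.n_false):
        hits.append(_draw_hit(rng, spec, False, f"false{i:04d}"))
        labels.append(False)
    return SimulatedHits(hits=hits, labels=np.array(labels, dtype=bool),
                         positives=PositiveSet(records=positives,
                                               family="rhodopsin"))


# ---------------------------------------------------------------------------
# Communities (abundance ground truth)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySpec:
    """A synthetic prokaryotic community for the abundance estimator.

    Every genome carries exactly one recombinase gene; a fraction
    ``rho_carrier_fraction`` carries exactly one rhodopsin, so under uniform
    read sampling the true rhodopsins-per-genome is that fraction. Read
    counts per gene are negative-binomial around ``reads_mean`` (dispersion =
    NB size parameter; 0 disables depth noise), fragment lengths uniform in
    [length_min, length_max] (a single shared length when min == max).
    """

    n_genomes: int = 500
    rho_carrier_fraction: float = 0.3
    reads_mean: float = 50.0
    reads_dispersion: float = 5.0
    length_min: int = 80
    length_max: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_carrier_fraction <= 1.0):
            raise ValidationError("rho_carrier_fraction must lie in [0,1]")
        if self.length_min > self.length_max:
            raise ValidationError("length_min must be <= length_max")


def simulate_community(spec: CommunitySpec
                       ) -> Tuple[FragmentWeightSet, FragmentWeightSet, float]:
    """Returns (rhodopsin fragments, recombinase fragments, true fraction)."""
    rng = np.random.default_rng(spec.seed)

    def draw_reads() -> int:
        if spec.reads_dispersion and spec.reads_dispersion > 0:
            r = spec.reads_dispersion
            p = r / (r + spec.reads_mean)
            return int(rng.negative_binomial(r, p))
        return int(round(spec.reads_mean))

    def draw_length() -> int:
        return int(rng.integers(spec.length_min, spec.length_max + 1))

    n_carriers = int(round(spec.rho_carrier_fraction * spec.n_genomes))
    rec = [(f"rec{i:05d}", draw_reads(), draw_length())
           for i in range(spec.n_genomes)]
    rho = [(f"rho{i:05d}", draw_reads(), draw_length())
           for i in range(n_carriers)]
    return (FragmentWeightSet(family="RHO", fragments=rho),
            FragmentWeightSet(family="REC", fragments=rec),
            spec.rho_carrier_fraction)


# ---------------------------------------------------------------------------
# Reference trees
# ---------------------------------------------------------------------------

def simulate_tree(n_leaves: int, seed: int = 0,
                  families: Sequence[str] = DEFAULT_FAMILIES,
                  branch_scale: float = 0.1) -> ReferenceTree:
    """Random rooted binary tree with exponential branch lengths and a
    random family annotation per leaf."""
    if n_leaves < 2:
        raise ValidationError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    nodes: List[dendropy.Node] = []
    for i in range(n_leaves):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(f"ref{i + 1:04d}")
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for ch in (nodes[i], nodes[j]):
            parent.add_child(ch)
            ch.edge.length = float(rng.exponential(branch_scale)) + 1e-6
        nodes = [nd for t, nd in enumerate(nodes) if t not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    fam = {f"ref{i + 1:04d}": str(rng.choice(list(families)))
           for i in range(n_leaves)}
    return ReferenceTree(tree, fam)


# ---------------------------------------------------------------------------
# RC profiles with planted group structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSimSpec:
    """Planted-group RC profile matrices.

    Group centers are Dirichlet draws on the RC simplex (optionally redrawn
    until pairwise-separated by ``min_separation`` in euclidean distance);
    members are the center plus truncated Gaussian noise, renormalized.
    """

    n_groups: int = 3
    n_per_group: int = 15
    n_rc: int = 20
    dirichlet_concentration: float = 1.0
    noise_scale: float = 0.02
    min_separation: float = 0.0
    seed: int = 0


def _separated_centers(rng: np.random.Generator, n: int, n_rc: int,
                       conc: float, min_sep: float) -> np.ndarray:
    for _ in range(1000):
        centers = rng.dirichlet([conc] * n_rc, size=n)
        if n < 2 or min_sep <= 0:
            return centers
        dists = [np.linalg.norm(centers[i] - centers[j])
                 for i in range(n) for j in range(i + 1, n)]
        if min(dists) >= min_sep:
            return centers
    raise ValidationError(
        f"could not draw {n} centers separated by {min_sep} on a "
        f"{n_rc}-simplex; lower min_separation"
    )


def _noisy_member(rng: np.random.Generator, center: np.ndarray,
                  noise: float) -> np.ndarray:
    if noise <= 0:
        return center.copy()
    v = np.clip(center + rng.normal(0.0, noise, size=center.size), 0.0, None)
    s = v.sum()
    return v / s if s > 0 else center.copy()


def simulate_profiles(spec: ProfileSimSpec) -> Tuple[pd.DataFrame, np.ndarray]:
    """Returns (profile matrix, true group label per row)."""
    rng = np.random.default_rng(spec.seed)
    centers = _separated_centers(rng, spec.n_groups, spec.n_rc,
                                 spec.dirichlet_concentration,
                                 spec.min_separation)
    rows, ids, labels = [], [], []
    for g in range(spec.n_groups):
        for m in range(spec.n_per_group):
            rows.append(_noisy_member(rng, centers[g], spec.noise_scale))
            ids.append(f"g{g}_m{m:02d}")
            labels.append(g)
    df = pd.DataFrame(rows, index=ids, columns=rc_names(spec.n_rc))
    return df, np.array(labels)


def simulate_hierarchical_profiles(
        n_super: int = 2, n_sub_per_super: int = 2, n_per_sub: int = 10,
        n_rc: int = 20, dirichlet_concentration: float = 1.0,
        super_separation: float = 0.5, sub_scale: float = 0.08,
        noise_scale: float = 0.0, seed: int = 0
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Two-level planted structure: super-groups from separated Dirichlet
    centers, sub-groups as perturbations of their super-center.

    Returns (matrix, super labels, sub labels); sub labels are globally
    unique across super-groups.
    """
    rng = np.random.default_rng(seed)
    supers = _separated_centers(rng, n_super, n_rc, dirichlet_concentration,
                                super_separation)
    rows, ids, sup_lab, sub_lab = [], [], [], []
    sub_id = 0
    for s in range(n_super):
        for b in range(n_sub_per_super):
            center = _noisy_member(rng, supers[s], sub_scale)
            for m in range(n_per_sub):
                rows.append(_noisy_member(rng, center, noise_scale))
                ids.append(f"s{s}_b{b}_m{m:02d}")
                sup_lab.append(s)
                sub_lab.append(sub_id)
            sub_id += 1
    df = pd.DataFrame(rows, index=ids, columns=rc_names(n_rc))
    return df, np.array(sup_lab), np.array(sub_lab)


# ---------------------------------------------------------------------------
# Placements realizing a profile on a tree
# ---------------------------------------------------------------------------

def simulate_placements(tree: ReferenceTree, rcs: RootCladeSet,
                        profile: Mapping[str, float], n_reads: int = 100_000,
                        fragments_per_rc: int = 10, length_min: int = 80,
                        length_max: int = 120, seed: int = 0,
                        metagenome_id: str = "sim"
                        ) -> Tuple[PlacementTable, ReadSupportTable]:
    """Draw placements whose h/l-weighted RC profile recovers ``profile`` up
    to multinomial read noise.

    Each RC gets ``fragments_per_rc`` fragments placed on random leaf edges
    of that clade. One fragment-length vector is drawn and shared across
    RCs, and reads are allocated multinomially with per-fragment probability
    proportional to p_RC × fragment length; the shared lengths make the
    length terms cancel exactly in expectation, so recovery error is pure
    multinomial noise.
    """
    rng = np.random.default_rng(seed)
    p = np.array([profile.get(rc, 0.0) for rc in rcs.rc_ids], dtype=float)
    if p.sum() <= 0:
        raise ValidationError("profile has no mass on this RC set")
    p = p / p.sum()
    lengths = rng.integers(length_min, length_max + 1,
                           size=fragments_per_rc).astype(int)
    lsum = float(lengths.sum())

    leaf_edge = {next(iter(tree.leafset(e))): e
                 for e in tree.edge_leafsets() if len(tree.leafset(e)) == 1}

    frag_ids: List[str] = []
    frag_len: Dict[str, int] = {}
    frag_edge: Dict[str, int] = {}
    probs: List[float] = []
    for i, rc in enumerate(rcs.rc_ids):
        leaves = sorted(rcs.clades[rc])
        for j in range(fragments_per_rc):
            fid = f"{metagenome_id}_{rc}_f{j:03d}"
            leaf = leaves[int(rng.integers(len(leaves)))]
            frag_ids.append(fid)
            frag_len[fid] = int(lengths[j])
            frag_edge[fid] = leaf_edge[leaf]
            probs.append(p[i] * lengths[j] / lsum)
    counts = rng.multinomial(n_reads, np.array(probs))
    rows = {fid: (frag_edge[fid], float(rng.uniform(0.7, 1.0)))
            for fid in frag_ids}
    placements = PlacementTable(metagenome_id=metagenome_id, rows=rows,
                                fragment_lengths=dict(frag_len),
                                edge_leafsets=tree.edge_leafsets())
    reads = ReadSupportTable(
        reads={fid: int(c) for fid, c in zip(frag_ids, counts)},
        lengths=dict(frag_len),
    )
    return placements, reads
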