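"""Functional marker-group profiling, CPM normalization and alpha diversity.

Operates on per-metagenome annotation count tables (gene, marker id, taxon,
raw count, gene length). Raw counts are length-normalized with the TPM
scheme and reported as counts per million (CPM); biogeochemical processes
are profiled as the CPM mass of their marker-gene groups (KO/COG
identifiers), decomposed by taxon; and the alpha diversity of a sample is
the effective species number, the antilog of the Shannon entropy of species
annotation proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Tuple

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Marker-gene groups defining each biogeochemical process: KO identifiers
#: for the photosynthesis, sulfur and nitrogen cycling pathways, KO and COG
#: identifiers for the four carbon-fixation pathways.
DEFAULT_MARKER_GROUPS: Dict[str, FrozenSet[str]] = {
    "anoxygenic_photosynthesis": frozenset({
        "K08928", "K08929", "K08940", "K08941", "K08942", "K08943", "K08944"}),
    "photosynthesis": frozenset({
        "K02703", "K02704", "K02705", "K02706", "K02707", "K02708"}),
    "sulfate_reduction": frozenset({"K00394", "K00395", "K11180", "K11181"}),
    "sulfur_oxidation": frozenset({
        "K17222", "K17223", "K17224", "K17225", "K17226", "K17227"}),
    "nitrogen_fixation": frozenset({"K02588", "K02586", "K02591", "K00531"}),
    "denitrification": frozenset({
        "K00370", "K00371", "K00374", "K02567", "K02568", "K00368",
        "K15864", "K04561", "K02305", "K15877", "K00376"}),
    "ammonia_oxidation": frozenset({"K10944", "K10945", "K10946", "K10535"}),
    "carbon_fixation": frozenset({
        "K01601", "K01648", "K14534", "K14138", "K00193"}),
    "carbon_fixation_cog": frozenset({
        "COG1850", "COG2301", "COG2368", "COG1152"}),
}

REQUIRED_COLUMNS = ("gene_id", "marker_id", "taxon", "count", "length")


@dataclass(frozen=True)
class MarkerRegistry:
    """Mapping of process name → set of marker identifiers (KO or COG)."""

    groups: Mapping[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        for proc, ids in self.groups.items():
            if not ids:
                raise ValidationError(f"process {proc!r} has no marker ids")

    @classmethod
    def default(cls) -> "MarkerRegistry":
        return cls(dict(DEFAULT_MARKER_GROUPS))

    @classmethod
    def from_yaml(cls, path) -> "MarkerRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError("registry YAML must map process -> marker list")
        return cls({proc: frozenset(ids) for proc, ids in raw.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({p: sorted(ids) for p, ids in self.groups.items()}, fh)


def read_annotation_table(path) -> pd.DataFrame:
    """Read an annotation count TSV with columns gene_id, marker_id, taxon,
    count, length."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing columns {missing}")
    _validate_annotations(df)
    return df


def _validate_annotations(df: pd.DataFrame) -> None:
    if (df["count"] < 0).any():
        raise ValidationError("annotation counts must be non-negative")
    if (df["length"] < 1).any():
        raise ValidationError("gene lengths must be >= 1")


def cpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``cpm`` column: length-normalized counts rescaled to one
    million (the TPM scheme).

    cpm_g = 1e6 * (count_g/length_g) / sum_g'(count_g'/length_g'), so the
    column sums to 1e6 and is invariant to global depth changes.
    """
    _validate_annotations(table)
    rates = table["count"] / table["length"]
    total = float(rates.sum())
    if total == 0.0:
        raise ValidationError("all annotation counts are zero")
    out = table.copy()
    out["cpm"] = 1e6 * rates / total
    return out


def process_profile(table: pd.DataFrame, registry: MarkerRegistry
                    ) -> Tuple[pd.Series, pd.DataFrame]:
    """Per-process CPM mass and its per-taxon breakdown.

    Returns a Series (process → total cpm) and a DataFrame (process × taxon).
    Marker ids absent from the registry are ignored (their count is logged);
    processes without hits report 0.
    """
    if "cpm" not in table.columns:
        raise ValidationError("run cpm_normalize before process_profile")
    marker_to_proc: Dict[str, str] = {}
    for proc, ids in registry.groups.items():
        for mid in ids:
            marker_to_proc[mid] = proc
    known = table["marker_id"].map(marker_to_proc)
    n_unknown = int(known.isna().sum())
    if n_unknown:
        logger.info("%d annotation rows outside the marker registry", n_unknown)
    sub = table[known.notna()].copy()
    sub["process"] = known[known.notna()]
    by_taxon = (sub.pivot_table(index="process", columns="taxon", values="cpm",
                                aggfunc="sum", fill_value=0.0)
                if len(sub) else pd.DataFrame())
    by_taxon = by_taxon.reindex(sorted(registry.groups), fill_value=0.0)
    totals = by_taxon.sum(axis=1) if by_taxon.shape[1] else pd.Series(
        0.0, index=sorted(registry.groups))
    totals.name = "cpm"
    return totals, by_taxon


def alpha_diversity(counts: Mapping[str, float], base: float = 10.0) -> float:
    """Effective species number: antilog of the Shannon entropy of species
    annotation proportions.

    With proportions p_s = count_s / total, returns base**H where
    H = −sum_s p_s log_base(p_s). Equals S for S equally abundant species,
    regardless of the (configurable) logarithm base.
    """
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValidationError("total annotation count must be positive")
    h = 0.0
    for c in counts.values():
        if c < 0:
            raise ValidationError("species counts must be non-negative")
        if c > 0:
            p = c / total
            h -= p * math.log(p, base)
    return base ** h
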