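"""Recombinase-normalized rhodopsin abundance.

Rhodopsin (RHO) content of a metagenome is expressed per genome equivalent by
normalizing against recombinase (REC = RecA + Rad51) content, under the
single-copy assumption: recA/rad51 occur once per bacterial or archaeal
genome. Both families are quantified as sums of per-fragment read densities:

    RHO_abundance = sum_rho(h/l) / sum_rec(h/l)

with h the reads supporting a fragment and l its length, making the measure
invariant to sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FragmentWeightSet:
    """Classifier-accepted fragments of one family with their read weights.

    ``fragments`` holds (fragment_id, h reads, l length) triples.
    """

    family: str
    fragments: List[Tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for fid, h, l in self.fragments:
            if h < 0 or l < 1:
                raise ValidationError(f"{fid}: need h >= 0 and l >= 1, got h={h} l={l}")
            if fid in seen:
                raise ValidationError(f"duplicate fragment id {fid}")
            seen.add(fid)

    def sum_read_density(self) -> float:
        """Sum of h/l over the set's fragments."""
        return sum(h / l for _, h, l in self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class AbundanceResult:
    """Rhodopsins per recombinase (genome equivalent) for one metagenome.

    ``rho_abundance`` is None when the metagenome carried no recombinase
    weight — such metagenomes are flagged ``undefined`` and should be
    excluded from cross-metagenome comparisons rather than treated as
    infinitely rhodopsin-rich.
    """

    metagenome_id: str
    rho_abundance: Optional[float]
    n_rho_fragments: int
    n_rec_fragments: int

    @property
    def undefined(self) -> bool:
        return self.rho_abundance is None


def merge_recombinases(recA: FragmentWeightSet,
                       rad51: FragmentWeightSet) -> FragmentWeightSet:
    """Pool RecA and Rad51 fragments into one REC set.

    Fragment ids are kept unique by prefixing the subfamily label.
    """
    merged = [(f"{s.family}:{fid}", h, l)
              for s in (recA, rad51) for fid, h, l in s.fragments]
    return FragmentWeightSet(family="REC", fragments=merged)


def rho_abundance(rho: FragmentWeightSet, rec: FragmentWeightSet,
                  metagenome_id: str = "") -> AbundanceResult:
    """Compute sum_rho(h/l) / sum_rec(h/l) for one metagenome."""
    denom = rec.sum_read_density()
    if denom == 0.0:
        logger.warning("%s: no recombinase read weight; abundance undefined",
                       metagenome_id or "<metagenome>")
        return AbundanceResult(metagenome_id, None, len(rho), len(rec))
    value = rho.sum_read_density() / denom
    return AbundanceResult(metagenome_id, value, len(rho), len(rec))
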