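"""Trio phasing: parent-unique k-mer voting over bubble sides.

Parental short-read k-mer databases are reduced to *parent-unique
homozygous* k-mers: k-mers well supported in one parent and absent from the
other.  Each bubble side is scanned for matches against both unique sets and
the bubble is assigned a parent of origin by majority vote on the net lean

    lean = (pat0 - mat0) - (pat1 - mat1)

where ``patS``/``matS`` count distinct parent-unique k-mer hits on side S.
Positive lean calls side0 paternal; |lean| below ``min_votes`` (or a tie)
leaves the bubble unphased.  Unlike contact phasing, trio orientations are
globally anchored: orientation 0 always means side0 is paternal, so there is
no global-flip ambiguity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from ._kmers import canonical_kmer_set, canonical_kmers, decode_kmer
from .graph_io import AssemblyGraph
from .homology import Bubble, BubbleMap
from .phase_optimize import PhaseState

__all__ = [
    "TrioConfig",
    "ParentKmerSets",
    "build_parent_sets",
    "vote_bubble",
    "trio_phase_state",
    "read_kmer_dump",
    "write_kmer_dump",
    "PATERNAL_IS_SIDE0",
    "PATERNAL_IS_SIDE1",
    "UNPHASED",
]

logger = logging.getLogger(__name__)

PATERNAL_IS_SIDE0 = "paternal-is-side0"
PATERNAL_IS_SIDE1 = "paternal-is-side1"
UNPHASED = "unphased"


@dataclass
class TrioConfig:
    """kmer_size must be odd so no k-mer is its own reverse complement;
    min_votes is the minimum |net lean| to call a bubble; hom_threshold is
    the minimum count in the donor parent for a k-mer to count as
    homozygous-parental (the other parent must have count zero)."""

    kmer_size: int = 31
    min_votes: int = 3
    hom_threshold: int = 2

    def __post_init__(self):
        if self.kmer_size % 2 == 0:
            raise ValueError("kmer_size must be odd")
        if not 1 <= self.kmer_size <= 31:
            raise ValueError("kmer_size must be in [1, 31]")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")


@dataclass
class ParentKmerSets:
    """Disjoint sets of canonical k-mers unique to each parent."""

    paternal_unique: set[int]
    maternal_unique: set[int]
    kmer_size: int

    def __post_init__(self):
        overlap = self.paternal_unique & self.maternal_unique
        if overlap:
            raise ValueError(f"parent-unique sets overlap on {len(overlap)} k-mers")

    def swapped(self) -> "ParentKmerSets":
        return ParentKmerSets(
            paternal_unique=self.maternal_unique,
            maternal_unique=self.paternal_unique,
            kmer_size=self.kmer_size,
        )


# -- k-mer dump I/O ---------------------------------------------------------


def read_kmer_dump(path, k: int) -> dict[int, int]:
    """Read a text 'KMER<TAB>COUNT' dump into canonical-code -> count."""
    counts: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            kmer, count = line.split("\t")
            if len(kmer) != k:
                raise ValueError(
                    f"line {lineno}: k-mer length {len(kmer)} != expected {k}"
                )
            codes = canonical_kmers(kmer, k)
            if codes.size != 1:
                raise ValueError(f"line {lineno}: invalid k-mer {kmer!r}")
            code = int(codes[0])
            counts[code] = counts.get(code, 0) + int(count)
    return counts


def write_kmer_dump(path, counts: dict[int, int], k: int) -> None:
    with open(path, "w") as fh:
        for code in sorted(counts):
            fh.write(f"{decode_kmer(code, k)}\t{counts[code]}\n")


# -- voting -----------------------------------------------------------------


def build_parent_sets(
    paternal_counts: dict[int, int],
    maternal_counts: dict[int, int],
    config: TrioConfig | None = None,
) -> ParentKmerSets:
    """Select homozygous parent-unique k-mers by count subtraction.

    A k-mer is paternal-unique when its paternal count reaches
    ``hom_threshold`` and its maternal count is zero (and symmetrically);
    the two sets are disjoint by construction.
    """
    config = config or TrioConfig()
    thr = config.hom_threshold
    paternal = {
        k for k, c in paternal_counts.items() if c >= thr and k not in maternal_counts
    }
    maternal = {
        k for k, c in maternal_counts.items() if c >= thr and k not in paternal_counts
    }
    return ParentKmerSets(paternal, maternal, config.kmer_size)


def vote_bubble(
    bubble: Bubble,
    graph: AssemblyGraph,
    parent_sets: ParentKmerSets,
    config: TrioConfig | None = None,
) -> str:
    """Majority-vote parent-of-origin call for one bubble."""
    config = config or TrioConfig()
    k = config.kmer_size
    kmers0 = canonical_kmer_set(graph.segments[bubble.side0], k)
    kmers1 = canonical_kmer_set(graph.segments[bubble.side1], k)
    pat, mat = parent_sets.paternal_unique, parent_sets.maternal_unique
    lean = (len(kmers0 & pat) - len(kmers0 & mat)) - (
        len(kmers1 & pat) - len(kmers1 & mat)
    )
    if abs(lean) < config.min_votes:
        return UNPHASED
    return PATERNAL_IS_SIDE0 if lean > 0 else PATERNAL_IS_SIDE1


def trio_phase_state(
    bubbles: BubbleMap,
    graph: AssemblyGraph,
    parent_sets: ParentKmerSets,
    config: TrioConfig | None = None,
) -> PhaseState:
    """Phase every bubble by parental vote.

    Orientation 0 <=> side0 is paternal (haplotype 0 = paternal throughout).
    Uncalled bubbles are flagged unsupported.  Each bubble forms its own
    rigid set: trio evidence anchors bubbles independently.
    """
    config = config or TrioConfig()
    orientation: dict[int, int] = {}
    unsupported: set[int] = set()
    for bubble in bubbles:
        call = vote_bubble(bubble, graph, parent_sets, config)
        if call == UNPHASED:
            orientation[bubble.id] = 0
            unsupported.add(bubble.id)
        else:
            orientation[bubble.id] = 0 if call == PATERNAL_IS_SIDE0 else 1
    return PhaseState(
        orientation=orientation,
        merged_sets=[[b.id] for b in sorted(bubbles, key=lambda b: b.id)],
        unsupported=unsupported,
    )
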