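"""Identification of two-sided haplotypic bubbles.

A *bubble* is a pair of segments representing the two haplotypes of a
heterozygous locus.  Bubbles come from one of two sources:

1. assembler annotation — a sidecar table mapping segments to (bubble id,
   side), passed through verbatim after validation; or
2. sequence similarity search — a bottom-s MinHash sketch over canonical
   k-mers proposes candidate homologous pairs, which are then refined by
   orientation-aware global alignment and resolved into disjoint pairs by
   greedy matching on identity.

The estimated Jaccard similarity between two sketches uses the standard
bottom-s union estimator: among the s smallest hashes of the union of the
two sketches, the fraction present in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._kmers import canonical_kmers, hash_kmers
from .graph_io import AssemblyGraph, reverse_complement

__all__ = [
    "Bubble",
    "BubbleMap",
    "SketchParams",
    "bubbles_from_annotation",
    "sketch_candidates",
    "refine_candidates",
    "read_annotation_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Bubble:
    """Two alternative segments at one heterozygous locus."""

    id: int
    side0: str
    side1: str

    def __post_init__(self):
        if self.side0 == self.side1:
            raise ValueError(f"bubble {self.id} has identical sides")

    @property
    def sides(self) -> tuple[str, str]:
        return (self.side0, self.side1)


class BubbleMap:
    """Disjoint partition of a subset of segments into two-sided bubbles.

    Segments outside every bubble are homozygous/unphased by definition.
    """

    def __init__(self, bubbles: list[Bubble] = ()):
        self.bubbles: list[Bubble] = []
        self.segment_to_bubble: dict[str, tuple[int, int]] = {}
        self._by_id: dict[int, Bubble] = {}
        for b in bubbles:
            self.add(b)

    def add(self, bubble: Bubble) -> None:
        for side, seg in enumerate(bubble.sides):
            if seg in self.segment_to_bubble:
                raise ValueError(f"segment {seg!r} already belongs to a bubble")
        if bubble.id in self._by_id:
            raise ValueError(f"duplicate bubble id {bubble.id}")
        self.bubbles.append(bubble)
        self._by_id[bubble.id] = bubble
        for side, seg in enumerate(bubble.sides):
            self.segment_to_bubble[seg] = (bubble.id, side)

    def bubble(self, bubble_id: int) -> Bubble:
        return self._by_id[bubble_id]

    def side_of(self, segment: str) -> tuple[int, int] | None:
        """(bubble id, side) of a segment, or None if homozygous/unphased."""
        return self.segment_to_bubble.get(segment)

    def partner(self, segment: str) -> str | None:
        hit = self.segment_to_bubble.get(segment)
        if hit is None:
            return None
        bid, side = hit
        return self._by_id[bid].sides[1 - side]

    def __len__(self) -> int:
        return len(self.bubbles)

    def __iter__(self):
        return iter(self.bubbles)


@dataclass
class SketchParams:
    """MinHash sketch and refinement parameters.

    kmer_size:
        canonical k-mer length for sketching (>= 8).
    sketch_size:
        number of smallest hashes retained per segment (bottom-s sketch).
    similarity_threshold:
        minimum estimated Jaccard similarity for a candidate pair.
    identity_threshold:
        minimum alignment identity for a refined bubble edge.
    hash_seed:
        seed of the k-mer hash; fixed default for reproducibility.
    """

    kmer_size: int = 22
    sketch_size: int = 128
    similarity_threshold: float = 0.05
    identity_threshold: float = 0.9
    hash_seed: int = 42

    def __post_init__(self):
        if self.kmer_size < 8:
            raise ValueError("kmer_size must be >= 8")
        if self.sketch_size < 16:
            raise ValueError("sketch_size must be >= 16")
        for name in ("similarity_threshold", "identity_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


# -- annotation route -------------------------------------------------------


def read_annotation_tsv(path) -> dict[str, tuple[int, int]]:
    """Read a 3-column sidecar table: segment_name, bubble_id, side."""
    annotation: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("segment"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"annotation line {lineno}: need 3 columns")
            if fields[0] in annotation:
                raise ValueError(
                    f"annotation line {lineno}: segment {fields[0]!r} annotated twice"
                )
            annotation[fields[0]] = (int(fields[1]), int(fields[2]))
    return annotation


def bubbles_from_annotation(
    graph: AssemblyGraph, annotation
) -> BubbleMap:
    """Build a BubbleMap verbatim from an assembler annotation table.

    ``annotation`` is a mapping segment -> (bubble id, side), or an iterable
    of such pairs.  Bubble groups with a number of members other than two
    are dropped with a warning; a segment annotated into two bubbles raises.
    """
    items = annotation.items() if hasattr(annotation, "items") else annotation
    groups: dict[int, dict[int, str]] = {}
    seen: dict[str, int] = {}
    for seg, (bid, side) in items:
        if seg not in graph:
            raise ValueError(f"annotation references unknown segment {seg!r}")
        if seg in seen:
            raise ValueError(f"segment {seg!r} annotated into two bubbles")
        seen[seg] = bid
        group = groups.setdefault(bid, {})
        if side in group:
            # same side twice -> treat as a >2-member group, dropped below
            group[max(group) + 2] = seg
        else:
            group[side] = seg
    bubble_map = BubbleMap()
    n_dropped = 0
    for bid in sorted(groups):
        group = groups[bid]
        if set(group) != {0, 1}:
            n_dropped += 1
            logger.warning(
                "dropping bubble %d with %d members (exactly 2 required)",
                bid,
                len(group),
            )
            continue
        bubble_map.add(Bubble(bid, group[0], group[1]))
    if n_dropped:
        logger.warning("dropped %d malformed bubble groups", n_dropped)
    return bubble_map


# -- similarity-search route ------------------------------------------------


def _sketch(seq: str, params: SketchParams) -> np.ndarray:
    """Sorted bottom-s sketch of hashed canonical k-mers."""
    kmers = canonical_kmers(seq, params.kmer_size)
    if kmers.size == 0:
        return np.empty(0, dtype=np.uint64)
    hashes = np.unique(hash_kmers(kmers, seed=params.hash_seed))
    return hashes[: params.sketch_size]


def estimate_jaccard(sketch_a: np.ndarray, sketch_b: np.ndarray, s: int) -> float:
    """Bottom-s union estimator of Jaccard similarity from two sketches."""
    if sketch_a.size == 0 or sketch_b.size == 0:
        return 0.0
    union = np.union1d(sketch_a, sketch_b)[:s]
    shared = np.intersect1d(sketch_a, sketch_b, assume_unique=True)
    hits = np.isin(union, shared, assume_unique=True).sum()
    return float(hits) / float(union.size)


def sketch_candidates(
    graph: AssemblyGraph, params: SketchParams | None = None
) -> list[tuple[str, str, float]]:
    """Propose candidate homologous segment pairs by MinHash similarity.

    Returns unordered pairs ``(name_a, name_b, estimated_jaccard)`` with
    name_a < name_b, sorted, whose estimated Jaccard similarity of canonical
    k-mer sets reaches ``similarity_threshold``.  Segments shorter than the
    k-mer size are excluded.  Deterministic given the hash seed; symmetric in
    input order and invariant to reverse-complementing any segment (canonical
    k-mers).
    """
    params = params or SketchParams()
    sketches: dict[str, np.ndarray] = {}
    for name in sorted(graph.segments):
        sk = _sketch(graph.segments[name], params)
        if sk.size:
            sketches[name] = sk
    # inverted index: hash -> segments whose sketch holds it
    index: dict[int, list[str]] = {}
    for name, sk in sketches.items():
        for h in sk:
            index.setdefault(int(h), []).append(name)
    pair_hits: set[tuple[str, str]] = set()
    for members in index.values():
        if len(members) < 2:
            continue
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pair_hits.add((a, b) if a < b else (b, a))
    out = []
    for a, b in sorted(pair_hits):
        est = estimate_jaccard(sketches[a], sketches[b], params.sketch_size)
        if est >= params.similarity_threshold:
            out.append((a, b, est))
    return out


def _alignment_identity(seq_a: str, seq_b: str) -> tuple[float, str]:
    """Best global alignment identity of seq_a vs seq_b over both strands.

    Identity is 1 - edit_distance / max(len), a lower bound on per-column
    identity of the global alignment.  Returns (identity, strand) with
    strand in {'+', '-'}.
    """
    denom = max(len(seq_a), len(seq_b))
    best, strand = 0.0, "+"
    for orient, target in (("+", seq_b), ("-", reverse_complement(seq_b))):
        dist = edlib.align(seq_a, target, mode="NW", task="distance")["editDistance"]
        ident = 1.0 - dist / denom
        if ident > best:
            best, strand = ident, orient
    return best, strand


def refine_candidates(
    graph: AssemblyGraph,
    candidates: list[tuple[str, str, float]],
    params: SketchParams | None = None,
) -> BubbleMap:
    """Turn sketch candidates into disjoint bubbles by alignment + matching.

    Each candidate pair is aligned globally on both strands; pairs reaching
    ``identity_threshold`` become edges of a similarity graph, and a greedy
    descending-identity matching (ties by lexicographic names) selects
    disjoint two-sided bubbles.  Bubble ids are assigned in match order.
    """
    params = params or SketchParams()
    scored: list[tuple[float, str, str]] = []
    for a, b, _est in candidates:
        ident, _strand = _alignment_identity(graph.segments[a], graph.segments[b])
        if ident >= params.identity_threshold:
            scored.append((ident, a, b))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched: set[str] = set()
    bubble_map = BubbleMap()
    next_id = 0
    for ident, a, b in scored:
        if a in matched or b in matched:
            continue
        matched.update((a, b))
        bubble_map.add(Bubble(next_id, a, b))
        next_id += 1
    return bubble_map


def find_bubbles(graph: AssemblyGraph, params: SketchParams | None = None) -> BubbleMap:
    """Full similarity-search route: sketch then refine."""
    params = params or SketchParams()
    return refine_candidates(graph, sketch_candidates(graph, params), params)
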