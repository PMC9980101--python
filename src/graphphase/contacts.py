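"""Proximity-ligation alignments -> weighted contact graph over segments.

Hi-C read pairs and Pore-C concatemers are handled uniformly: all alignments
sharing a read name (mates, subreads) are grouped, and every unordered pair
of distinct segments hit by one read contributes +1 to the contact weight of
that segment pair.  A Pore-C read with m mapped segments therefore yields
C(m, 2) contacts; a read pair yields one.  Self-contacts (both alignments on
one segment) are excluded.
"""

from __future__ import annotations

import itertools
import logging
from collections import OrderedDict
from dataclasses import dataclass, field

import pysam

from .homology import BubbleMap

__all__ = [
    "ContactRecord",
    "ContactGraph",
    "ContactConfig",
    "parse_alignments",
    "build_contact_graph",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactRecord:
    """One usable alignment of a read (mate/subread) to a segment."""

    read_id: str
    segment: str
    mapq: int
    length: int = 0  # aligned query bases; informational


@dataclass
class ContactConfig:
    """Filtering policy for proximity-ligation alignments.

    min_mapq:
        records below this mapping quality are dropped.  The default of 1
        keeps mapQ > 0, the usable-contact criterion: mapQ 0 alignments are
        ambiguous and cannot cover a heterozygous site informatively.
    max_alignments_per_read:
        reads hitting more distinct segments than this are skipped entirely
        (guard against chimeric concatemers blowing up quadratically).
    include_supplementary:
        keep supplementary (0x800) records.  Off by default; Pore-C subreads
        are commonly emitted as supplementary alignments, so Pore-C
        workflows enable this.
    """

    min_mapq: int = 1
    max_alignments_per_read: int = 50
    include_supplementary: bool = False

    def __post_init__(self):
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.max_alignments_per_read < 2:
            raise ValueError("max_alignments_per_read must be >= 2")


class ContactGraph:
    """Undirected weighted graph over segments; weight = linking read count."""

    def __init__(self):
        self.edges: dict[tuple[str, str], int] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    def add(self, a: str, b: str, weight: int = 1) -> None:
        if a == b:
            raise ValueError("self-contacts are not representable")
        key = self._key(a, b)
        self.edges[key] = self.edges.get(key, 0) + weight

    def weight(self, a: str, b: str) -> int:
        if a == b:
            return 0
        return self.edges.get(self._key(a, b), 0)

    def merge(self, other: "ContactGraph") -> "ContactGraph":
        out = ContactGraph()
        for g in (self, other):
            for (a, b), w in g.edges.items():
                out.add(a, b, w)
        return out

    def __len__(self):
        return len(self.edges)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seg_a\tseg_b\tweight\n")
            for (a, b), w in sorted(self.edges.items()):
                fh.write(f"{a}\t{b}\t{w}\n")

    @classmethod
    def read_tsv(cls, path) -> "ContactGraph":
        graph = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("seg_a"):
                    continue
                a, b, w = line.split("\t")
                graph.add(a, b, int(w))
        return graph


def parse_alignments(
    alignment_file,
    config: ContactConfig | None = None,
    valid_segments: set[str] | None = None,
) -> "OrderedDict[str, list[ContactRecord]]":
    """Read SAM/BAM and return usable contact records grouped by read name.

    Unmapped and secondary records are always dropped; supplementary records
    are dropped unless ``config.include_supplementary``.  Records with
    mapq < min_mapq are dropped.  If ``valid_segments`` is given, records on
    other references are dropped with a counted warning.
    """
    config = config or ContactConfig()
    grouped: OrderedDict[str, list[ContactRecord]] = OrderedDict()
    n_unknown = 0
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(alignment_file), check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary:
                    continue
                if aln.is_supplementary and not config.include_supplementary:
                    continue
                if aln.mapping_quality < config.min_mapq:
                    continue
                segment = aln.reference_name
                if valid_segments is not None and segment not in valid_segments:
                    n_unknown += 1
                    continue
                record = ContactRecord(
                    read_id=aln.query_name,
                    segment=segment,
                    mapq=aln.mapping_quality,
                    length=aln.query_alignment_length,
                )
                grouped.setdefault(record.read_id, []).append(record)
    finally:
        pysam.set_verbosity(save)
    if n_unknown:
        logger.warning("dropped %d alignments on segments absent from graph", n_unknown)
    return grouped


def build_contact_graph(
    grouped: "OrderedDict[str, list[ContactRecord]]",
    bubble_map: BubbleMap | None = None,
    config: ContactConfig | None = None,
) -> ContactGraph:
    """Accumulate all-vs-all per-read contacts into a ContactGraph.

    For each read with m distinct mapped segments, every unordered segment
    pair receives +1 (each pair counted once per read, regardless of how
    many alignments hit each segment).  Reads exceeding the per-read segment
    cap are skipped.  All pairs are retained in the graph, including pairs
    where one or both segments lie outside every bubble; the phase optimizer
    is what restricts attention to inter-bubble evidence.
    """
    config = config or ContactConfig()
    graph = ContactGraph()
    for read_id, records in grouped.items():
        segments = sorted({r.segment for r in records})
        if len(segments) < 2:
            continue
        if len(segments) > config.max_alignments_per_read:
            logger.debug("skipping read %s with %d segments", read_id, len(segments))
            continue
        for a, b in itertools.combinations(segments, 2):
            graph.add(a, b)
    return graph
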