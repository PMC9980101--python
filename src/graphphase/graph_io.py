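"""Blunt GFA1 assembly graphs: parsing, writing, and haplotype FASTA output.

The central container is :class:`AssemblyGraph`, a bidirected sequence graph
with named segments, oriented links and (optionally) named paths.  Only
*blunt* graphs are accepted: every link must declare a zero-length overlap
(``0M`` or ``*``), so that concatenating sequences along a path is exact.
Overlapping links are rejected at parse time and no downstream module ever
sees one.

Orientation convention: ``+`` denotes the stored sequence, ``-`` its reverse
complement.  A link is an adjacency between the *end* of one oriented segment
and the *start* of the next; reading the same adjacency in the opposite
direction (both orientations flipped, endpoints swapped) denotes the same
link, and the graph stores each adjacency once but answers queries
symmetrically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Segment",
    "Link",
    "AssemblyGraph",
    "GFAParseError",
    "read_gfa",
    "write_gfa",
    "write_haplotype_fasta",
    "reverse_complement",
    "LEFT",
    "RIGHT",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_CHARS = frozenset("ACGTN")

#: Sides of a segment in the bidirected graph. ``LEFT`` is the start of the
#: stored (``+``) sequence, ``RIGHT`` its end.
LEFT, RIGHT = 0, 1


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class GFAParseError(ValueError):
    """Raised on malformed or non-blunt GFA input."""


@dataclass(frozen=True)
class Segment:
    """A named sequence node of the assembly graph."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Link:
    """Oriented adjacency between two segments with zero overlap."""

    from_segment: str
    from_orient: str
    to_segment: str
    to_orient: str

    def reversed(self) -> "Link":
        """The same adjacency read in the opposite direction."""
        flip = {"+": "-", "-": "+"}
        return Link(
            self.to_segment,
            flip[self.to_orient],
            self.from_segment,
            flip[self.from_orient],
        )

    def canonical(self) -> "Link":
        """Deterministic representative of {self, self.reversed()}."""
        rev = self.reversed()
        a = (self.from_segment, self.from_orient, self.to_segment, self.to_orient)
        b = (rev.from_segment, rev.from_orient, rev.to_segment, rev.to_orient)
        return self if a <= b else rev


def _side_of(orient: str, end: bool) -> int:
    # End of a "+" traversal is the RIGHT side of the stored sequence;
    # end of a "-" traversal is its LEFT side.
    if end:
        return RIGHT if orient == "+" else LEFT
    return LEFT if orient == "+" else RIGHT


class AssemblyGraph:
    """Bidirected blunt sequence graph.

    Parameters
    ----------
    segments:
        Mapping of segment name to uppercase nucleotide sequence.
    links:
        Iterable of :class:`Link`; each adjacency may be given in either
        reading, duplicates (including reverse-complement readings) collapse.
    paths:
        Optional named paths: ordered lists of ``(segment, orient)`` steps.
    """

    def __init__(
        self,
        segments: Mapping[str, str] | None = None,
        links: Iterable[Link] = (),
        paths: Mapping[str, list[tuple[str, str]]] | None = None,
    ) -> None:
        self.segments: dict[str, str] = {}
        self.links: set[Link] = set()
        self.paths: dict[str, list[tuple[str, str]]] = dict(paths or {})
        # adjacency: (segment, side) -> set of (segment, side)
        self._adj: dict[tuple[str, int], set[tuple[str, int]]] = {}
        for name, seq in (segments or {}).items():
            self.add_segment(name, seq)
        for link in links:
            self.add_link(link)

    # -- construction -------------------------------------------------------

    def add_segment(self, name: str, sequence: str) -> None:
        if name in self.segments:
            raise GFAParseError(f"duplicate segment name: {name!r}")
        seq = sequence.upper()
        if not seq:
            raise GFAParseError(f"segment {name!r} has empty sequence")
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise GFAParseError(
                f"segment {name!r} contains invalid characters: {sorted(bad)}"
            )
        self.segments[name] = seq

    def add_link(self, link: Link) -> None:
        for seg in (link.from_segment, link.to_segment):
            if seg not in self.segments:
                raise GFAParseError(f"link references unknown segment {seg!r}")
        canon = link.canonical()
        if canon in self.links:
            return
        self.links.add(canon)
        a = (canon.from_segment, _side_of(canon.from_orient, end=True))
        b = (canon.to_segment, _side_of(canon.to_orient, end=False))
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def add_path(self, name: str, steps: list[tuple[str, str]]) -> None:
        for seg, orient in steps:
            if seg not in self.segments:
                raise GFAParseError(f"path {name!r} references unknown segment {seg!r}")
            if orient not in "+-":
                raise GFAParseError(f"path {name!r} has invalid orientation {orient!r}")
        self.paths[name] = list(steps)

    # -- queries ------------------------------------------------------------

    def neighbors(self, segment: str, side: int) -> set[tuple[str, int]]:
        """Segment-ends adjacent to the given side of ``segment``."""
        return set(self._adj.get((segment, side), ()))

    def has_link(self, a: str, orient_a: str, b: str, orient_b: str) -> bool:
        return Link(a, orient_a, b, orient_b).canonical() in self.links

    def sequence_of(self, segment: str, orient: str) -> str:
        seq = self.segments[segment]
        return seq if orient == "+" else reverse_complement(seq)

    def total_bp(self) -> int:
        return sum(len(s) for s in self.segments.values())

    def __contains__(self, name: str) -> bool:
        return name in self.segments

    def __len__(self) -> int:
        return len(self.segments)

    def isomorphic_to(self, other: "AssemblyGraph") -> bool:
        """Name-preserving equality of segments, adjacencies and paths."""
        return (
            self.segments == other.segments
            and {l.canonical() for l in self.links}
            == {l.canonical() for l in other.links}
            and self.paths == other.paths
        )


# -- GFA1 I/O ---------------------------------------------------------------


def _parse_gfa_lines(lines: Iterator[str]) -> AssemblyGraph:
    graph = AssemblyGraph()
    deferred_links: list[tuple[int, Link]] = []
    deferred_paths: list[tuple[int, str, list[tuple[str, str]]]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        try:
            if tag == "H":
                continue
            elif tag == "S":
                if len(fields) < 3:
                    raise GFAParseError("S line needs name and sequence")
                name, seq = fields[1], fields[2]
                if seq == "*":
                    raise GFAParseError(
                        f"segment {name!r} has no sequence ('*'); sequences are required"
                    )
                graph.add_segment(name, seq)
            elif tag == "L":
                if len(fields) < 6:
                    raise GFAParseError("L line needs 5 fields")
                frm, fo, to, to_o, overlap = fields[1:6]
                if fo not in "+-" or to_o not in "+-":
                    raise GFAParseError(f"invalid orientation in L line")
                if overlap not in ("0M", "*"):
                    raise GFAParseError(
                        f"non-blunt link overlap {overlap!r}: only blunt "
                        "(zero-overlap) graphs are supported"
                    )
                deferred_links.append((lineno, Link(frm, fo, to, to_o)))
            elif tag == "P":
                if len(fields) < 3:
                    raise GFAParseError("P line needs name and steps")
                name, steps_field = fields[1], fields[2]
                steps = []
                for step in steps_field.split(","):
                    if len(step) < 2 or step[-1] not in "+-":
                        raise GFAParseError(f"malformed path step {step!r}")
                    steps.append((step[:-1], step[-1]))
                deferred_paths.append((lineno, name, steps))
            # other record types (C, W, ...) are ignored
        except GFAParseError as exc:
            raise GFAParseError(f"line {lineno}: {exc}") from None
    for lineno, link in deferred_links:
        try:
            graph.add_link(link)
        except GFAParseError as exc:
            raise GFAParseError(f"line {lineno}: {exc}") from None
    for lineno, name, steps in deferred_paths:
        try:
            graph.add_path(name, steps)
        except GFAParseError as exc:
            raise GFAParseError(f"line {lineno}: {exc}") from None
    return graph


def read_gfa(path) -> AssemblyGraph:
    """Parse a blunt GFA1 file into an :class:`AssemblyGraph`.

    Raises :class:`GFAParseError` (naming the offending line) on malformed
    input, duplicate segment names, dangling links, or any link whose overlap
    is not zero.
    """
    with open(path) as fh:
        return _parse_gfa_lines(fh)


def read_gfa_string(text: str) -> AssemblyGraph:
    """Parse GFA1 from a string (convenience for tests and fixtures)."""
    return _parse_gfa_lines(iter(io.StringIO(text)))


def write_gfa(graph: AssemblyGraph, path) -> None:
    """Write the graph as GFA1 with deterministic record order."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name in sorted(graph.segments):
            fh.write(f"S\t{name}\t{graph.segments[name]}\n")
        for link in sorted(
            (l.canonical() for l in graph.links),
            key=lambda l: (l.from_segment, l.from_orient, l.to_segment, l.to_orient),
        ):
            fh.write(
                f"L\t{link.from_segment}\t{link.from_orient}\t"
                f"{link.to_segment}\t{link.to_orient}\t0M\n"
            )
        for name in sorted(graph.paths):
            steps = ",".join(f"{seg}{o}" for seg, o in graph.paths[name])
            fh.write(f"P\t{name}\t{steps}\t*\n")


# -- FASTA output -----------------------------------------------------------


def _write_fasta_record(fh, name: str, seq: str, width: int = 80) -> None:
    fh.write(f">{name}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i : i + width] + "\n")


def write_haplotype_fasta(chains, phase, graph: AssemblyGraph, out_prefix: str) -> dict:
    """Materialize unzipped chains into two haplotype FASTA files.

    Each chain contributes one record per haplotype, named
    ``<chain_id>.<hap>`` with hap in {0, 1}; the record sequence is the
    orientation-aware concatenation of the haplotype path (blunt graph, so
    concatenation is exact).  Segments not covered by any chain are written
    to ``<out_prefix>.unphased.fasta`` so the three files partition the
    assembly.  Returns the mapping of output file role to path.

    Raises ``ValueError`` if a chain still contains an unphased het pair
    (these must be resolved or split upstream).
    """
    from .chaining import unzip  # local import to avoid a cycle

    used: set[str] = set()
    paths = {
        "hap0": f"{out_prefix}.hap0.fasta",
        "hap1": f"{out_prefix}.hap1.fasta",
        "unphased": f"{out_prefix}.unphased.fasta",
    }
    with open(paths["hap0"], "w") as f0, open(paths["hap1"], "w") as f1:
        for chain in chains:
            hap_paths = unzip(chain, phase)
            for hap, (steps, fh) in enumerate(zip(hap_paths, (f0, f1))):
                seq = "".join(graph.sequence_of(seg, orient) for seg, orient in steps)
                _write_fasta_record(fh, f"{chain.id}.{hap}", seq)
                used.update(seg for seg, _ in steps)
    with open(paths["unphased"], "w") as fu:
        for name in sorted(set(graph.segments) - used):
            _write_fasta_record(fu, name, graph.segments[name])
    return paths
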