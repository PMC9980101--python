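"""Diploid bubble-chain detection and haplotype unzipping.

A *bubble chain* is a collinear run of alternating homozygous segments and
phased heterozygous bubble pairs.  The topology accepted is deliberately
strict, to avoid misjoins: a bubble-side node is *diploid* only if on each
side it has at most two direct adjacencies and a single two-hop neighbor,
which must be its bubble partner (two-hop = step to a neighbor, then look
back at the neighbors attached at the entry side).  A homozygous node is
*in-chain* only if each of its sides is either a graph end or attaches to
exactly the two sides of one diploid bubble.  Everything else is a tangle
and terminates chains.

Chains are unzipped by assigning side ``h ^ orientation`` of every het pair
to haplotype h and duplicating homozygous nodes into both haplotypes, so
each haplotype path is a valid walk in the input graph and total unzipped
length equals twice the homozygous bases plus all het bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .graph_io import LEFT, RIGHT, AssemblyGraph
from .homology import BubbleMap
from .phase_optimize import PhaseState

__all__ = [
    "ChainElement",
    "BubbleChain",
    "UnphasedBubbleError",
    "classify_nodes",
    "find_chains",
    "unzip",
    "split_unphased",
    "chain_table",
    "haplotype_paths",
    "ngx",
    "DIPLOID",
    "HOM_CHAIN",
    "OTHER",
]

logger = logging.getLogger(__name__)

DIPLOID = "diploid"
HOM_CHAIN = "homozygous-in-chain"
OTHER = "other"


@dataclass(frozen=True)
class ChainElement:
    """One step of a chain: a homozygous node or a phased het pair.

    For kind 'homozygous', ``steps`` holds one oriented segment; for kind
    'het_pair' it holds the oriented side0 and side1 of ``bubble_id`` (in
    side order, not haplotype order).
    """

    kind: str  # 'homozygous' | 'het_pair'
    steps: tuple[tuple[str, str], ...]
    bubble_id: int | None = None

    def segments(self) -> tuple[str, ...]:
        return tuple(seg for seg, _ in self.steps)


@dataclass
class BubbleChain:
    id: str
    elements: list[ChainElement]
    circular: bool = False

    def n_bubbles(self) -> int:
        return sum(1 for e in self.elements if e.kind == "het_pair")

    def n_homs(self) -> int:
        return sum(1 for e in self.elements if e.kind == "homozygous")

    def segments(self) -> list[str]:
        return [seg for e in self.elements for seg in e.segments()]


class UnphasedBubbleError(ValueError):
    """An unresolved het pair was encountered while unzipping."""


# -- node classification ----------------------------------------------------


def _two_hop(graph: AssemblyGraph, segment: str, side: int) -> set[str]:
    """Segments seen by stepping out of ``side`` and looking back at the
    entry side of each neighbor; the node itself is excluded."""
    out: set[str] = set()
    for neigh, neigh_side in graph.neighbors(segment, side):
        for seg2, _ in graph.neighbors(neigh, neigh_side):
            out.add(seg2)
    out.discard(segment)
    return out


def _side_is_diploid(graph: AssemblyGraph, segment: str, side: int, partner: str) -> bool:
    direct = graph.neighbors(segment, side)
    if len(direct) > 2:
        return False
    two_hop = _two_hop(graph, segment, side)
    return two_hop <= {partner}


def classify_nodes(graph: AssemblyGraph, bubbles: BubbleMap) -> dict[str, str]:
    """Label every segment as diploid, homozygous-in-chain, or other."""
    labels: dict[str, str] = {}
    # pass 1: diploid bubble sides
    for bubble in bubbles:
        ok = True
        for seg, partner in (
            (bubble.side0, bubble.side1),
            (bubble.side1, bubble.side0),
        ):
            for side in (LEFT, RIGHT):
                if not _side_is_diploid(graph, seg, side, partner):
                    ok = False
        for seg in bubble.sides:
            labels[seg] = DIPLOID if ok else OTHER
    # pass 2: homozygous nodes flanked by diploid pairs (or graph ends)
    for name in graph.segments:
        if name in labels:
            continue
        flanked = True
        for side in (LEFT, RIGHT):
            neigh = {seg for seg, _ in graph.neighbors(name, side)}
            if not neigh:
                continue  # graph end
            hits = {bubbles.side_of(seg) for seg in neigh}
            bids = {h[0] for h in hits if h is not None}
            if (
                None in {h for h in hits}
                or len(bids) != 1
                or len(neigh) != 2
                or any(labels.get(seg) != DIPLOID for seg in neigh)
            ):
                flanked = False
                break
        labels[name] = HOM_CHAIN if flanked else OTHER
    return labels


# -- chain traversal --------------------------------------------------------


def _element_of(seg: str, labels: dict[str, str], bubbles: BubbleMap):
    if labels.get(seg) == DIPLOID:
        bid, _ = bubbles.side_of(seg)
        return ("B", bid)
    if labels.get(seg) == HOM_CHAIN:
        return ("H", seg)
    return None


def find_chains(
    graph: AssemblyGraph, labels: dict[str, str], bubbles: BubbleMap
) -> list[BubbleChain]:
    """Traverse labeled nodes into maximal chains.

    Chains terminate at tangles ('other' nodes) and graph ends; every
    labeled node lands in exactly one chain.  Chain ids derive from the
    lexicographically smallest member segment, so results do not depend on
    iteration order.
    """
    # element adjacency with, per neighbor, the side each member faces it with
    adjacency: dict[tuple, dict[tuple, dict[str, int]]] = {}
    members: dict[tuple, list[str]] = {}
    for seg in graph.segments:
        el = _element_of(seg, labels, bubbles)
        if el is not None:
            members.setdefault(el, []).append(seg)
            adjacency.setdefault(el, {})
    for link in graph.links:
        canon = link.canonical()
        ends = (
            (canon.from_segment, RIGHT if canon.from_orient == "+" else LEFT),
            (canon.to_segment, LEFT if canon.to_orient == "+" else RIGHT),
        )
        (sa, da), (sb, db) = ends
        ea, eb = (
            _element_of(sa, labels, bubbles),
            _element_of(sb, labels, bubbles),
        )
        if ea is None or eb is None or ea == eb:
            continue
        adjacency[ea].setdefault(eb, {})[sa] = da
        adjacency[eb].setdefault(ea, {})[sb] = db

    def min_name(el) -> str:
        return min(members[el])

    visited: set[tuple] = set()
    chains: list[BubbleChain] = []
    # deterministic scan order: by smallest member segment name
    for el in sorted(adjacency, key=min_name):
        if el in visited:
            continue
        # collect this component
        component = []
        stack = [el]
        seen = {el}
        while stack:
            cur = stack.pop()
            component.append(cur)
            for nb in adjacency[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        endpoints = [c for c in component if len(adjacency[c]) <= 1]
        if endpoints:
            start = min(endpoints, key=min_name)
            circular = False
        else:  # cycle
            start = min(component, key=min_name)
            circular = True
        # walk
        order: list[tuple] = [start]
        walk_seen = {start}
        prev = None
        cur = start
        while True:
            nxt_candidates = [
                nb for nb in adjacency[cur] if nb != prev and nb not in walk_seen
            ]
            if not nxt_candidates:
                break
            nxt = min(nxt_candidates, key=min_name)
            order.append(nxt)
            walk_seen.add(nxt)
            prev, cur = cur, nxt
        visited.update(walk_seen)
        elements = _orient_walk(order, adjacency, bubbles)
        chain_id = "chain_" + min(min_name(e) for e in order)
        chains.append(BubbleChain(id=chain_id, elements=elements, circular=circular))
    chains.sort(key=lambda c: c.id)
    return chains


def _orient_walk(order, adjacency, bubbles: BubbleMap) -> list[ChainElement]:
    elements = []
    for idx, el in enumerate(order):
        prev_el = order[idx - 1] if idx > 0 else None
        next_el = order[idx + 1] if idx + 1 < len(order) else None
        facing_prev = adjacency[el].get(prev_el, {}) if prev_el else {}
        facing_next = adjacency[el].get(next_el, {}) if next_el else {}

        def orient_of(seg: str) -> str:
            if seg in facing_prev:  # entered through this side
                return "+" if facing_prev[seg] == LEFT else "-"
            if seg in facing_next:  # exits through this side
                return "+" if facing_next[seg] == RIGHT else "-"
            return "+"

        kind, payload = el
        if kind == "H":
            elements.append(
                ChainElement(kind="homozygous", steps=((payload, orient_of(payload)),))
            )
        else:
            bubble = bubbles.bubble(payload)
            steps = tuple((seg, orient_of(seg)) for seg in bubble.sides)
            elements.append(
                ChainElement(kind="het_pair", steps=steps, bubble_id=payload)
            )
    return elements


# -- unzipping --------------------------------------------------------------


def unzip(
    chain: BubbleChain, phase: PhaseState
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Resolve a chain into its two haplotype paths.

    Haplotype h takes side ``h ^ orientation`` of every het pair and every
    homozygous node.  Raises :class:`UnphasedBubbleError` on a het pair
    whose bubble is unsupported; use :func:`split_unphased` first.
    """
    paths: tuple[list, list] = ([], [])
    for element in chain.elements:
        if element.kind == "homozygous":
            for path in paths:
                path.append(element.steps[0])
        else:
            bid = element.bubble_id
            if bid in phase.unsupported or bid not in phase.orientation:
                raise UnphasedBubbleError(
                    f"chain {chain.id}: bubble {bid} has no resolved phase"
                )
            orient = phase.orientation[bid]
            for hap in (0, 1):
                paths[hap].append(element.steps[hap ^ orient])
    return paths


def split_unphased(
    chains: list[BubbleChain], phase: PhaseState
) -> list[BubbleChain]:
    """Split chains at unphased het pairs, dropping the unphased bubbles.

    Fragments inherit ``<chain_id>.<k>`` ids; fully phased chains pass
    through unchanged.  Every split is logged.
    """
    out: list[BubbleChain] = []
    for chain in chains:
        fragments: list[list[ChainElement]] = [[]]
        n_split = 0
        for element in chain.elements:
            unresolved = element.kind == "het_pair" and (
                element.bubble_id in phase.unsupported
                or element.bubble_id not in phase.orientation
            )
            if unresolved:
                n_split += 1
                fragments.append([])
            else:
                fragments[-1].append(element)
        fragments = [f for f in fragments if f]
        if n_split == 0 and len(fragments) == 1:
            out.append(chain)
            continue
        logger.info("chain %s split at %d unphased bubbles", chain.id, n_split)
        for k, frag in enumerate(fragments):
            out.append(BubbleChain(id=f"{chain.id}.{k}", elements=frag))
    return out


def haplotype_paths(
    chains: list[BubbleChain], phase: PhaseState
) -> dict[str, list[tuple[str, str]]]:
    """Named haplotype paths ('<chain>.<hap>') for GFA P-line emission."""
    paths = {}
    for chain in chains:
        for hap, steps in enumerate(unzip(chain, phase)):
            paths[f"{chain.id}.{hap}"] = steps
    return paths


def chain_table(
    chains: list[BubbleChain], phase: PhaseState, graph: AssemblyGraph
) -> list[dict]:
    """Per-chain summary rows: bubbles, homs, and per-haplotype lengths."""
    rows = []
    for chain in chains:
        hap_bp = [0, 0]
        for hap, steps in enumerate(unzip(chain, phase)):
            hap_bp[hap] = sum(len(graph.segments[seg]) for seg, _ in steps)
        rows.append(
            {
                "chain_id": chain.id,
                "n_bubbles": chain.n_bubbles(),
                "n_homs": chain.n_homs(),
                "hap0_bp": hap_bp[0],
                "hap1_bp": hap_bp[1],
            }
        )
    return rows


def ngx(lengths: list[int], genome_size: int, x: float = 50.0) -> int:
    """NGx: the length L such that pieces >= L cover x% of ``genome_size``."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    target = genome_size * x / 100.0
    total = 0
    for length in sorted(lengths, reverse=True):
        total += length
        if total >= target:
            return length
    return 0
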