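"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from graphphase.contacts import ContactGraph
from graphphase.graph_io import LEFT, RIGHT, AssemblyGraph, Link
from graphphase.homology import Bubble, BubbleMap
from graphphase.phase_optimize import PhaseState, pair_score
from graphphase.synthetic import SimConfig, simulate_diploid_graph


# -- tiny deterministic graphs ----------------------------------------------


def make_graph(segments: dict[str, str], links: list[tuple[str, str, str, str]] = ()):
    g = AssemblyGraph(segments)
    for a, oa, b, ob in links:
        g.add_link(Link(a, oa, b, ob))
    return g


def random_blunt_graph(rng: np.random.Generator, n_segments: int = 10, seq_len: int = 40):
    """Random valid blunt graph with random links and a random path."""
    names = [f"s{i:03d}" for i in range(n_segments)]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    segments = {
        n: bases[rng.integers(0, 4, size=seq_len)].tobytes().decode() for n in names
    }
    g = AssemblyGraph(segments)
    n_links = int(rng.integers(0, 2 * n_segments))
    for _ in range(n_links):
        a, b = rng.choice(names, size=2, replace=False)
        oa, ob = rng.choice(["+", "-"], size=2)
        g.add_link(Link(a, oa, b, ob))
    if rng.random() < 0.7:
        steps = [
            (str(rng.choice(names)), str(rng.choice(["+", "-"])))
            for _ in range(int(rng.integers(1, 5)))
        ]
        g.add_path("p0", steps)
    return g


# -- phase instances and exhaustive oracle ----------------------------------


def random_phase_instance(rng: np.random.Generator, n_bubbles: int):
    """Random bubbles over dummy segments with random contact weights."""
    bubbles = BubbleMap()
    for i in range(n_bubbles):
        bubbles.add(Bubble(i, f"b{i}_0", f"b{i}_1"))
    contacts = ContactGraph()
    n_pairs = int(rng.integers(n_bubbles - 1, 3 * n_bubbles))
    for _ in range(n_pairs):
        i, j = rng.choice(n_bubbles, size=2, replace=False)
        si, sj = rng.integers(0, 2, size=2)
        contacts.add(f"b{i}_{si}", f"b{j}_{sj}", int(rng.integers(1, 10)))
    return bubbles, contacts


def exhaustive_optimum(bubbles: BubbleMap, contacts: ContactGraph) -> int:
    """Brute-force maximum of the phase objective over all 2^B states.

    Independent of the optimizer: enumerates orientation vectors directly
    and sums pair scores.
    """
    blist = sorted(bubbles, key=lambda b: b.id)
    pairs = []
    for a, b in itertools.combinations(blist, 2):
        if any(
            contacts.weight(sa, sb) for sa in a.sides for sb in b.sides
        ):
            base = pair_score(a, b, 0, 0, contacts)
            pairs.append((a.id, b.id, base))
    index = {b.id: i for i, b in enumerate(blist)}
    best = None
    for bits in itertools.product((0, 1), repeat=len(blist)):
        total = sum(
            base if bits[index[i]] == bits[index[j]] else -base
            for i, j, base in pairs
        )
        best = total if best is None else max(best, total)
    return best if best is not None else 0


def phase_error_vs_truth(state: PhaseState, truth) -> tuple[int, int]:
    """Per-bubble mismatches against planted truth, up to a flip per chain
    (chains are contact-disconnected components, so each flip is free)."""
    err = tot = 0
    for chain in truth.chains:
        mism = sum(
            state.orientation[b] != truth.phase.orientation[b]
            for b in chain.bubble_ids
        )
        err += min(mism, len(chain.bubble_ids) - mism)
        tot += len(chain.bubble_ids)
    return err, tot


# -- independent chain-topology checker -------------------------------------


def naive_node_labels(graph: AssemblyGraph, bubbles: BubbleMap) -> dict[str, str]:
    """Literal re-implementation of the diploid / in-chain node rules,
    written from the link list rather than the adjacency index."""

    def ends_of(link: Link):
        a = (link.from_segment, RIGHT if link.from_orient == "+" else LEFT)
        b = (link.to_segment, LEFT if link.to_orient == "+" else RIGHT)
        return a, b

    def direct(seg, side):
        out = set()
        for link in graph.links:
            a, b = ends_of(link)
            if a == (seg, side):
                out.add(b)
            if b == (seg, side):
                out.add(a)
        return out

    labels = {}
    for bubble in bubbles:
        ok = True
        for seg, partner in ((bubble.side0, bubble.side1), (bubble.side1, bubble.side0)):
            for side in (LEFT, RIGHT):
                neigh = direct(seg, side)
                if len(neigh) > 2:
                    ok = False
                two_hop = set()
                for t, dt in neigh:
                    two_hop |= {u for u, _ in direct(t, dt)}
                two_hop.discard(seg)
                if not two_hop <= {partner}:
                    ok = False
        for seg in bubble.sides:
            labels[seg] = "diploid" if ok else "other"
    for name in graph.segments:
        if name in labels:
            continue
        good = True
        for side in (LEFT, RIGHT):
            neigh_segs = {s for s, _ in direct(name, side)}
            if not neigh_segs:
                continue
            in_bubbles = {bubbles.side_of(s) for s in neigh_segs}
            if None in in_bubbles:
                good = False
                break
            bids = {bid for bid, _ in in_bubbles}
            if len(neigh_segs) != 2 or len(bids) != 1:
                good = False
                break
            if any(labels.get(s) != "diploid" for s in neigh_segs):
                good = False
                break
        labels[name] = "homozygous-in-chain" if good else "other"
    return labels


def random_bubble_graph(rng: np.random.Generator, n_segments: int = 30):
    """Random graph plus a random disjoint pairing of segments into bubbles
    (mostly non-chain topology; exercises the classifier's negative paths)."""
    g = random_blunt_graph(rng, n_segments=n_segments, seq_len=30)
    names = sorted(g.segments)
    rng.shuffle(names)
    bubbles = BubbleMap()
    n_bubbles = int(rng.integers(1, n_segments // 2))
    for i in range(n_bubbles):
        bubbles.add(Bubble(i, names[2 * i], names[2 * i + 1]))
    return g, bubbles


# -- common fixtures --------------------------------------------------------


@pytest.fixture(scope="session")
def small_truth():
    """A clean 2-chain, 10-bubble planted fixture."""
    return simulate_diploid_graph(
        SimConfig(n_chains=2, bubbles_per_chain=5, segment_bp=300, seed=7)
    )
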