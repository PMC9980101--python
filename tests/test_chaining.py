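"""Chain-topology labeling, traversal, and unzipping."""

import numpy as np
import pytest

from graphphase.chaining import (
    DIPLOID,
    HOM_CHAIN,
    OTHER,
    UnphasedBubbleError,
    chain_table,
    classify_nodes,
    find_chains,
    ngx,
    split_unphased,
    unzip,
)
from graphphase.graph_io import AssemblyGraph, Link
from graphphase.homology import Bubble, BubbleMap
from graphphase.phase_optimize import PhaseState
from graphphase.synthetic import SimConfig, simulate_diploid_graph

from conftest import make_graph, naive_node_labels, random_bubble_graph


def _chain_graph(n_bubbles: int, with_end_homs: bool = False):
    """hom-free alternating chain: b0 -- h0 -- b1 -- h1 -- ... """
    segments, links = {}, []
    bubbles = BubbleMap()
    for j in range(n_bubbles):
        segments[f"b{j}_0"] = "AC" * 5
        segments[f"b{j}_1"] = "GT" * 5
        bubbles.add(Bubble(j, f"b{j}_0", f"b{j}_1"))
        if j < n_bubbles - 1:
            segments[f"h{j}"] = "TT" * 5
            for s in (0, 1):
                links.append((f"b{j}_{s}", "+", f"h{j}", "+"))
                links.append((f"h{j}", "+", f"b{j+1}_{s}", "+"))
    if with_end_homs:
        segments["h_start"], segments["h_end"] = "AAAA", "CCCC"
        for s in (0, 1):
            links.append(("h_start", "+", f"b0_{s}", "+"))
            links.append((f"b{n_bubbles-1}_{s}", "+", "h_end", "+"))
    return make_graph(segments, links), bubbles


def test_clean_chain_labels():
    graph, bubbles = _chain_graph(2, with_end_homs=True)
    labels = classify_nodes(graph, bubbles)
    for j in range(2):
        assert labels[f"b{j}_0"] == DIPLOID
        assert labels[f"b{j}_1"] == DIPLOID
    assert labels["h0"] == HOM_CHAIN
    assert labels["h_start"] == HOM_CHAIN  # graph end on the other side


def test_three_neighbors_disqualify_diploid():
    graph, bubbles = _chain_graph(2)
    graph.add_segment("spur", "ACGT")
    graph.add_link(Link("b0_0", "+", "spur", "+"))  # third right-neighbor? no:
    graph.add_link(Link("b0_1", "+", "spur", "+"))
    graph.add_link(Link("h0", "+", "spur", "+"))  # now h0's right side has 3
    labels = classify_nodes(graph, bubbles)
    assert labels["h0"] == OTHER


def test_extra_direct_adjacency_makes_bubble_side_other():
    graph, bubbles = _chain_graph(3)
    # give b1_0 a third neighbor on its right side
    graph.add_segment("x1", "ACGT")
    graph.add_segment("x2", "ACGT")
    graph.add_segment("x3", "ACGT")
    for x in ("x1", "x2", "x3"):
        graph.add_link(Link("b1_0", "+", x, "+"))
    labels = classify_nodes(graph, bubbles)
    assert labels["b1_0"] == OTHER
    assert labels["b1_1"] == OTHER  # mirrored by partner


@pytest.mark.parametrize("seed", range(50))
def test_labels_match_naive_checker_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    graph, bubbles = random_bubble_graph(rng, n_segments=30)
    assert classify_nodes(graph, bubbles) == naive_node_labels(graph, bubbles)


def test_labels_match_naive_checker_on_planted_chains():
    truth = simulate_diploid_graph(
        SimConfig(n_chains=2, bubbles_per_chain=4, segment_bp=100, tangle_rate=0.3, seed=12)
    )
    assert classify_nodes(truth.graph, truth.bubbles) == naive_node_labels(
        truth.graph, truth.bubbles
    )


# -- chain traversal --------------------------------------------------------


def test_single_bubble_is_a_one_element_chain():
    graph = make_graph({"a": "ACGT", "b": "TTTT"})
    bubbles = BubbleMap([Bubble(0, "a", "b")])
    labels = classify_nodes(graph, bubbles)
    chains = find_chains(graph, labels, bubbles)
    assert len(chains) == 1
    assert [e.kind for e in chains[0].elements] == ["het_pair"]


def test_five_bubbles_four_homs_single_chain():
    graph, bubbles = _chain_graph(5)
    labels = classify_nodes(graph, bubbles)
    chains = find_chains(graph, labels, bubbles)
    assert len(chains) == 1
    kinds = [e.kind for e in chains[0].elements]
    assert len(kinds) == 9
    assert kinds == ["het_pair", "homozygous"] * 4 + ["het_pair"]


def test_tangle_splits_chain_as_hand_enumerated():
    graph, bubbles = _chain_graph(5)
    graph.add_segment("tangle", "ACGT")
    graph.add_link(Link("h2", "+", "tangle", "+"))  # break between b2 and b3
    labels = classify_nodes(graph, bubbles)
    assert labels["h2"] == OTHER
    # hand enumeration: the tangle makes h2 'other'; bubble b3 sees the
    # tangle as a second two-hop neighbor through h2, so b3 (and with it h3)
    # drops out too, leaving [b0 h0 b1 h1 b2] and the isolated [b4]
    assert labels["b3_0"] == OTHER and labels["h3"] == OTHER
    chains = find_chains(graph, labels, bubbles)
    assert sorted(len(c.elements) for c in chains) == [1, 5]
    covered = sorted(seg for c in chains for seg in c.segments())
    expected = sorted(s for s, l in labels.items() if l != OTHER)
    assert covered == expected


def test_every_labeled_node_in_exactly_one_chain():
    truth = simulate_diploid_graph(
        SimConfig(n_chains=3, bubbles_per_chain=5, segment_bp=100, tangle_rate=0.2, seed=31)
    )
    labels = classify_nodes(truth.graph, truth.bubbles)
    chains = find_chains(truth.graph, labels, truth.bubbles)
    covered = [seg for c in chains for seg in c.segments()]
    assert len(covered) == len(set(covered))
    assert sorted(covered) == sorted(s for s, l in labels.items() if l != OTHER)


# -- unzip ------------------------------------------------------------------


def test_unzip_takes_phase_sides_and_duplicates_homs():
    graph, bubbles = _chain_graph(2)
    labels = classify_nodes(graph, bubbles)
    [chain] = find_chains(graph, labels, bubbles)
    state = PhaseState(orientation={0: 0, 1: 1})
    hap0, hap1 = unzip(chain, state)
    segs0, segs1 = [s for s, _ in hap0], [s for s, _ in hap1]
    assert segs0 == ["b0_0", "h0", "b1_1"]
    assert segs1 == ["b0_1", "h0", "b1_0"]


def test_unzip_paths_follow_input_links():
    truth = simulate_diploid_graph(SimConfig(n_chains=2, bubbles_per_chain=6, segment_bp=100, seed=41))
    labels = classify_nodes(truth.graph, truth.bubbles)
    chains = find_chains(truth.graph, labels, truth.bubbles)
    for chain in chains:
        for steps in unzip(chain, truth.phase):
            for (a, oa), (b, ob) in zip(steps, steps[1:]):
                assert truth.graph.has_link(a, oa, b, ob)


def test_unzip_conservation_per_chain_and_globally():
    truth = simulate_diploid_graph(SimConfig(n_chains=3, bubbles_per_chain=5, segment_bp=200, seed=43))
    labels = classify_nodes(truth.graph, truth.bubbles)
    chains = find_chains(truth.graph, labels, truth.bubbles)
    seglen = truth.graph.segments
    total_unzipped = 0
    for chain in chains:
        hom_bp = sum(len(seglen[s]) for e in chain.elements if e.kind == "homozygous" for s in e.segments())
        het_bp = sum(len(seglen[s]) for e in chain.elements if e.kind == "het_pair" for s in e.segments())
        unzipped = sum(len(seglen[s]) for steps in unzip(chain, truth.phase) for s, _ in steps)
        assert unzipped == 2 * hom_bp + het_bp
        total_unzipped += unzipped
    rows = chain_table(chains, truth.phase, truth.graph)
    assert sum(r["hap0_bp"] + r["hap1_bp"] for r in rows) == total_unzipped


def test_unphased_bubble_raises_then_split_resolves():
    graph, bubbles = _chain_graph(3)
    labels = classify_nodes(graph, bubbles)
    [chain] = find_chains(graph, labels, bubbles)
    state = PhaseState(orientation={0: 0, 1: 0, 2: 0}, unsupported={1})
    with pytest.raises(UnphasedBubbleError):
        unzip(chain, state)
    fragments = split_unphased([chain], state)
    assert len(fragments) == 2
    for frag in fragments:
        unzip(frag, state)  # no error
    assert {b for f in fragments for e in f.elements if e.kind == "het_pair" for b in [e.bubble_id]} == {0, 2}


def test_chaining_never_shortens_ngx():
    truth = simulate_diploid_graph(SimConfig(n_chains=3, bubbles_per_chain=6, segment_bp=300, seed=47))
    labels = classify_nodes(truth.graph, truth.bubbles)
    chains = find_chains(truth.graph, labels, truth.bubbles)
    genome_size = truth.graph.total_bp() // 2
    raw = [len(truth.graph.segments[s]) for b in truth.bubbles for s in b.sides]
    unzipped = [
        sum(len(truth.graph.segments[s]) for s, _ in steps)
        for chain in chains
        for steps in unzip(chain, truth.phase)
    ]
    assert ngx(unzipped, genome_size) >= ngx(raw, genome_size)


def test_ngx_definition():
    assert ngx([50, 30, 20], 100, 50.0) == 50
    assert ngx([50, 30, 20], 100, 60.0) == 30
    assert ngx([50, 30, 20], 100, 90.0) == 20
    assert ngx([10], 1000, 50.0) == 0  # cannot reach half the genome
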