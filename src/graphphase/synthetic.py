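"""Seeded synthetic fixtures: diploid graphs, contacts, and trio k-mers.

The generator plants the exact structures the rest of the package infers:

* a diploid assembly graph made of bubble chains — alternating homozygous
  segments and heterozygous bubbles whose two sides are divergent copies of
  one locus — with optional tangle nodes that break the strict chain
  topology;
* proximity-ligation contact records over the planted chains.  Every read
  carries a true haplotype; its first endpoint always matches it and each
  further endpoint is *cis* (same haplotype) with probability
  ``signal_ratio``, mirroring the consistent/inconsistent dichotomy of real
  proximity data.  Hi-C mode emits read pairs across bubble pairs with
  geometrically decaying frequency in chain distance; Pore-C mode emits
  concatemers with a Poisson number of subreads spanning consecutive
  bubbles;
* parental k-mer databases derived from assigning each chain haplotype a
  parent of origin.

Everything is deterministic per seed, and truth (bubbles, phases, chains,
parent of origin) is always returned alongside the fixture, so downstream
tests are closed-loop through public interfaces only.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

from ._kmers import canonical_kmers
from .contacts import ContactRecord
from .evaluate import DiploidTruth
from .graph_io import AssemblyGraph, Link
from .homology import Bubble, BubbleMap
from .phase_optimize import PhaseState
from .trio_phase import ParentKmerSets, TrioConfig, build_parent_sets

__all__ = [
    "SimConfig",
    "ChainTruth",
    "SimTruth",
    "simulate_diploid_graph",
    "simulate_contacts",
    "simulate_trio_kmers",
    "write_sam",
    "diploid_truth_labels",
    "annotation_from_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions of the simulation.

    n_chains, bubbles_per_chain:
        planted chain structure (each chain also carries
        bubbles_per_chain + 1 homozygous segments).
    het_divergence:
        substitution fraction between the two sides of a bubble.
    segment_bp:
        length of every planted segment.
    contacts_per_pair:
        Hi-C reads per adjacent bubble pair (halved per extra step of chain
        distance); Pore-C read depth is scaled to match this adjacent-pair
        coverage.
    signal_ratio:
        probability that a contact endpoint matches its read's haplotype;
        must exceed 0.5 or the truth is unidentifiable.
    subreads_per_read:
        'fixed:2' for Hi-C pairs or 'poisson:M' for Pore-C concatemers.
    tangle_rate:
        probability that an interior homozygous node receives a spurious
        extra neighbor, breaking the strict chain topology there.
    mapq_high_prob:
        endpoints draw mapq 60 with this probability, else mapq 0, so
        mapping-quality filters are exercised.
    """

    n_chains: int = 10
    bubbles_per_chain: int = 20
    het_divergence: float = 0.01
    segment_bp: int = 1000
    contacts_per_pair: int = 20
    signal_ratio: float = 0.95
    subreads_per_read: str = "fixed:2"
    tangle_rate: float = 0.0
    mapq_high_prob: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0.5 < self.signal_ratio <= 1.0:
            raise ValueError("signal_ratio must be in (0.5, 1]")
        for name in ("n_chains", "bubbles_per_chain", "segment_bp", "contacts_per_pair"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        mode, _, value = self.subreads_per_read.partition(":")
        if mode not in ("fixed", "poisson"):
            raise ValueError("subreads_per_read must be 'fixed:N' or 'poisson:M'")
        self._subread_mode = mode
        self._subread_value = float(value)


@dataclass
class ChainTruth:
    """Planted layout of one chain."""

    index: int
    hom_names: list[str]
    bubble_ids: list[int]


@dataclass
class SimTruth:
    """A planted fixture: the graph plus everything the tools should infer."""

    graph: AssemblyGraph
    bubbles: BubbleMap
    phase: PhaseState  # orientation o: haplotype h of a bubble is side h ^ o
    chains: list[ChainTruth]
    tangle_segments: list[str] = field(default_factory=list)

    def haplotype_side(self, bubble_id: int, hap: int) -> str:
        bubble = self.bubbles.bubble(bubble_id)
        return bubble.sides[hap ^ self.phase.orientation[bubble_id]]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(codes.size) < divergence
    # substitute with a uniformly different base
    shift = rng.integers(1, 4, size=int(hit.sum()))
    idx = np.flatnonzero(hit)
    base_idx = np.searchsorted(_BASES, codes[idx])
    codes[idx] = _BASES[(base_idx + shift) % 4]
    return codes.tobytes().decode("ascii")


def simulate_diploid_graph(config: SimConfig) -> SimTruth:
    """Plant bubble chains (hom–het–hom alternation) with known phase."""
    rng = np.random.default_rng([config.seed % 2**31, 0])
    graph = AssemblyGraph()
    bubbles = BubbleMap()
    orientation: dict[int, int] = {}
    chains: list[ChainTruth] = []
    tangles: list[str] = []
    bid = 0
    for c in range(config.n_chains):
        hom_names, bubble_ids = [], []
        for i in range(config.bubbles_per_chain + 1):
            name = f"c{c:03d}h{i:03d}"
            graph.add_segment(name, _random_seq(rng, config.segment_bp))
            hom_names.append(name)
        for j in range(config.bubbles_per_chain):
            side0 = f"c{c:03d}b{j:03d}s0"
            side1 = f"c{c:03d}b{j:03d}s1"
            seq0 = _random_seq(rng, config.segment_bp)
            graph.add_segment(side0, seq0)
            graph.add_segment(side1, _mutate(rng, seq0, config.het_divergence))
            bubbles.add(Bubble(bid, side0, side1))
            orientation[bid] = int(rng.integers(0, 2))
            bubble_ids.append(bid)
            bid += 1
            for side in (side0, side1):
                graph.add_link(Link(hom_names[j], "+", side, "+"))
                graph.add_link(Link(side, "+", hom_names[j + 1], "+"))
        # tangles on interior homs
        for i in range(1, config.bubbles_per_chain):
            if rng.random() < config.tangle_rate:
                tname = f"c{c:03d}t{i:03d}"
                graph.add_segment(tname, _random_seq(rng, config.segment_bp))
                graph.add_link(Link(hom_names[i], "+", tname, "+"))
                tangles.append(tname)
        chains.append(ChainTruth(index=c, hom_names=hom_names, bubble_ids=bubble_ids))
    phase = PhaseState(orientation=orientation, merged_sets=[[b] for b in sorted(orientation)])
    return SimTruth(graph=graph, bubbles=bubbles, phase=phase, chains=chains, tangle_segments=tangles)


# -- contacts ---------------------------------------------------------------


def _endpoint(truth: SimTruth, bubble_id: int, hap: int) -> str:
    return truth.haplotype_side(bubble_id, hap)


def _mapq(rng: np.random.Generator, config: SimConfig) -> int:
    return 60 if rng.random() < config.mapq_high_prob else 0


def simulate_contacts(
    truth: SimTruth, config: SimConfig
) -> "OrderedDict[str, list[ContactRecord]]":
    """Draw proximity-ligation contact records over the planted chains.

    Returns records grouped by read id, exactly as
    :func:`graphphase.contacts.parse_alignments` would.  Use
    :func:`write_sam` to serialize them through the real alignment path.
    """
    rng = np.random.default_rng([config.seed % 2**31, 1])
    grouped: "OrderedDict[str, list[ContactRecord]]" = OrderedDict()
    counter = 0
    sr = config.signal_ratio
    read_len = min(150, config.segment_bp)

    def emit(read_segments_haps: list[tuple[int, int]], chain: ChainTruth):
        nonlocal counter
        read_id = f"r{counter:08d}"
        counter += 1
        records = []
        for bubble_pos, hap in read_segments_haps:
            seg = _endpoint(truth, chain.bubble_ids[bubble_pos], hap)
            records.append(
                ContactRecord(
                    read_id=read_id,
                    segment=seg,
                    mapq=_mapq(rng, config),
                    length=read_len,
                )
            )
        grouped[read_id] = records

    if config._subread_mode == "fixed":
        # read pairs across bubble pairs, geometric decay in chain distance
        for chain in truth.chains:
            n_bubbles = len(chain.bubble_ids)
            d = 1
            while True:
                n_reads = config.contacts_per_pair // (2 ** (d - 1))
                if n_reads < 1 or d >= n_bubbles:
                    break
                for j in range(n_bubbles - d):
                    for _ in range(n_reads):
                        h = int(rng.integers(0, 2))
                        h2 = h if rng.random() < sr else 1 - h
                        emit([(j, h), (j + d, h2)], chain)
                d += 1
    else:
        mean = config._subread_value
        for chain in truth.chains:
            n_bubbles = len(chain.bubble_ids)
            # scale read count so adjacent pairs see ~contacts_per_pair reads
            span = max(mean - 1.0, 1.0)
            n_reads = int(round(config.contacts_per_pair * n_bubbles / span))
            for _ in range(n_reads):
                m = int(rng.poisson(mean))
                if m < 1:
                    continue
                anchor = int(rng.integers(0, n_bubbles))
                h = int(rng.integers(0, 2))
                steps = [(anchor, h)]
                for offset in range(1, m):
                    hap = h if rng.random() < sr else 1 - h
                    steps.append(((anchor + offset) % n_bubbles, hap))
                emit(steps, chain)
    return grouped


def write_sam(
    grouped: "OrderedDict[str, list[ContactRecord]]",
    graph: AssemblyGraph,
    path,
) -> None:
    """Serialize contact records as SAM against the graph segments.

    Reads with exactly two records become a proper read pair (two
    primaries); additional subreads of longer reads are emitted as
    supplementary records, as Pore-C aligners do — parse with
    ``include_supplementary=True`` to recover them.
    """
    import pysam

    names = sorted(graph.segments)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(graph.segments[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read_id, records in grouped.items():
            paired = len(records) == 2
            for i, rec in enumerate(records):
                aln = pysam.AlignedSegment()
                aln.query_name = read_id
                aln.reference_id = tid[rec.segment]
                aln.reference_start = 0
                aln.mapping_quality = rec.mapq
                length = min(rec.length or 100, len(graph.segments[rec.segment]))
                aln.query_sequence = graph.segments[rec.segment][:length]
                aln.cigartuples = [(0, length)]
                if paired:
                    aln.flag = 0x1 | (0x40 if i == 0 else 0x80)
                elif i > 0:
                    aln.flag = 0x800
                out.write(aln)


def diploid_truth_labels(truth: SimTruth) -> DiploidTruth:
    """Truth haplotype label per bubble-side segment (for signal-ratio QC)."""
    labels = {}
    for bubble in truth.bubbles:
        for hap in (0, 1):
            labels[truth.haplotype_side(bubble.id, hap)] = f"hap{hap + 1}"
    return DiploidTruth(labels)


def annotation_from_truth(truth: SimTruth) -> dict[str, tuple[int, int]]:
    """Sidecar-style annotation table reproducing the planted bubbles."""
    out = {}
    for bubble in truth.bubbles:
        for side, seg in enumerate(bubble.sides):
            out[seg] = (bubble.id, side)
    return out


# -- trio -------------------------------------------------------------------


def simulate_trio_kmers(
    truth: SimTruth, config: SimConfig, trio_config: TrioConfig | None = None
) -> tuple[ParentKmerSets, dict[int, int]]:
    """Assign each chain's haplotypes to parents and derive unique k-mers.

    Returns the parent-unique k-mer sets plus per-bubble truth: the side
    index that is paternal.  K-mers shared between the parents' inherited
    haplotypes (all homozygous sequence, and conserved het stretches)
    subtract out; with zero divergence both sets are empty.
    """
    trio_config = trio_config or TrioConfig()
    k = trio_config.kmer_size
    rng = np.random.default_rng([config.seed % 2**31, 2])
    paternal_counts: dict[int, int] = {}
    maternal_counts: dict[int, int] = {}
    paternal_side: dict[int, int] = {}

    def add_kmers(counts: dict[int, int], seq: str):
        for code in canonical_kmers(seq, k):
            code = int(code)
            counts[code] = counts.get(code, 0) + trio_config.hom_threshold

    for chain in truth.chains:
        hap0_parent_is_pat = bool(rng.integers(0, 2))
        for name in chain.hom_names:
            add_kmers(paternal_counts, truth.graph.segments[name])
            add_kmers(maternal_counts, truth.graph.segments[name])
        for bid in chain.bubble_ids:
            pat_hap = 0 if hap0_parent_is_pat else 1
            pat_seg = truth.haplotype_side(bid, pat_hap)
            mat_seg = truth.haplotype_side(bid, 1 - pat_hap)
            add_kmers(paternal_counts, truth.graph.segments[pat_seg])
            add_kmers(maternal_counts, truth.graph.segments[mat_seg])
            bubble = truth.bubbles.bubble(bid)
            paternal_side[bid] = bubble.sides.index(pat_seg)
    parent_sets = build_parent_sets(paternal_counts, maternal_counts, trio_config)
    return parent_sets, paternal_side
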