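"""Stochastic phase optimization over the bubble contact graph.

Each two-sided bubble carries a binary *orientation*: orientation 0 means
side0 belongs to haplotype 0, orientation 1 swaps the sides.  A proximity
contact between segments of two bubbles is *consistent* with an orientation
assignment when it links sides placed in the same haplotype.  Between any
two bubbles there are four possible side-to-side contacts, and only the two
matching-phase ones score positively; the pair score is

    score(a, b) = [w(a_h0, b_h0) + w(a_h1, b_h1)] - [w(a_h0, b_h1) + w(a_h1, b_h0)]

where ``a_h`` is the side of bubble *a* assigned to haplotype *h*.  The
total objective is the sum over all bubble pairs that share at least one
contact edge, and maximizing it is an instance of weighted max-cut, which is
NP-hard; the optimizer is stochastic:

1. run many independent greedy hill-climbs from uniformly random states
   (restarts are embarrassingly parallel and reproducible: every sample's
   RNG is derived from (seed, round, sample index));
2. tally, across samples, the relative orientation of every contact-sharing
   bubble pair (the consistency matrix);
3. merge the most consistently co-oriented pairs into rigid sets whose
   relative orientation is frozen, and repeat on the coarsened instance.

Each set takes part in at most one merge per round, so after round r no
rigid set exceeds 2^r bubbles.  Contact phasing determines orientations
only up to a global flip within each contact-connected component.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactGraph
from .homology import Bubble, BubbleMap

__all__ = [
    "PhaseState",
    "SamplerConfig",
    "ConsistencyMatrix",
    "pair_score",
    "total_objective",
    "greedy_pass",
    "sample_orientations",
    "merge_and_iterate",
    "write_phase_tsv",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass
class SamplerConfig:
    """Sampling/merging schedule of the stochastic optimizer.

    n_samples:
        greedy restarts per merge round.
    n_rounds:
        merge rounds; after round r the largest rigid set is <= 2^r.
    merge_fraction:
        fraction of the most consistent distinct-set pairs merged per round.
    seed:
        master seed; all per-sample RNG streams derive from it.
    n_threads:
        worker threads for the independent samples.  Results are combined
        in sample order and are bitwise identical for any thread count.
    """

    n_samples: int = 30
    n_rounds: int = 10
    merge_fraction: float = 0.5
    seed: int = 0
    n_threads: int = 1

    def __post_init__(self):
        if self.n_samples < 1 or self.n_rounds < 1:
            raise ValueError("n_samples and n_rounds must be >= 1")
        if not 0 < self.merge_fraction <= 1:
            raise ValueError("merge_fraction must be in (0, 1]")


@dataclass
class PhaseState:
    """Orientation per bubble plus the rigid-set partition that produced it.

    orientation maps bubble id -> {0, 1}; merged_sets is a partition of the
    bubble ids into rigid groups (flipping a group flips all its members
    coherently); unsupported bubbles have no contact edge to any other
    bubble and their orientation is arbitrary.
    """

    orientation: dict[int, int]
    merged_sets: list[list[int]] = field(default_factory=list)
    unsupported: set[int] = field(default_factory=set)

    def haplotype_of(self, bubble_map: BubbleMap, segment: str) -> int | None:
        hit = bubble_map.side_of(segment)
        if hit is None:
            return None
        bid, side = hit
        return side ^ self.orientation[bid]


@dataclass
class ConsistencyMatrix:
    """Per bubble-pair tallies of relative orientation across samples."""

    counts: dict[tuple[int, int], tuple[int, int]]  # (id_a, id_b) -> (n_same, n_opposite)
    n_samples: int


# -- direct scoring (reference semantics, used by tests and construction) ---


def pair_score(
    bubble_a: Bubble,
    bubble_b: Bubble,
    orient_a: int,
    orient_b: int,
    contacts: ContactGraph,
) -> int:
    """Consistency score of one bubble pair under given orientations.

    Antisymmetric under flipping exactly one orientation; positive when
    contacts predominantly link sides assigned to the same haplotype.
    """
    a0, a1 = bubble_a.sides[orient_a], bubble_a.sides[1 - orient_a]
    b0, b1 = bubble_b.sides[orient_b], bubble_b.sides[1 - orient_b]
    w = contacts.weight
    return (w(a0, b0) + w(a1, b1)) - (w(a0, b1) + w(a1, b0))


def _contact_sharing_pairs(
    bubbles: BubbleMap, contacts: ContactGraph
) -> dict[tuple[int, int], int]:
    """Map of bubble-id pair -> base score (score at equal orientations).

    Only pairs of *distinct* bubbles sharing at least one contact edge
    appear.  Intra-bubble contact edges are ignored: a read linking the two
    sides of one bubble is self-inconsistent evidence and scores nothing.
    """
    pairs: dict[tuple[int, int], int] = {}
    for (seg_a, seg_b), weight in contacts.edges.items():
        hit_a = bubbles.side_of(seg_a)
        hit_b = bubbles.side_of(seg_b)
        if hit_a is None or hit_b is None:
            continue
        (bid_a, side_a), (bid_b, side_b) = hit_a, hit_b
        if bid_a == bid_b:
            continue
        key = (bid_a, bid_b) if bid_a < bid_b else (bid_b, bid_a)
        sign = 1 if side_a == side_b else -1
        pairs[key] = pairs.get(key, 0) + sign * weight
    return pairs


def total_objective(
    state: PhaseState, bubbles: BubbleMap, contacts: ContactGraph
) -> int:
    """Sum of pair scores over contact-sharing bubble pairs.

    Invariant under a global flip of every orientation.
    """
    total = 0
    for (ia, ib), base in _contact_sharing_pairs(bubbles, contacts).items():
        same = state.orientation[ia] == state.orientation[ib]
        total += base if same else -base
    return total


# -- coarsened instance -----------------------------------------------------


class _Instance:
    """Bubble pair graph in index space, coarsenable into rigid sets."""

    def __init__(self, bubbles: BubbleMap, contacts: ContactGraph):
        self.bubble_ids = sorted(b.id for b in bubbles)
        index = {bid: i for i, bid in enumerate(self.bubble_ids)}
        pair_base = _contact_sharing_pairs(bubbles, contacts)
        keys = sorted(pair_base)
        self.pair_i = np.array([index[a] for a, _ in keys], dtype=np.int64)
        self.pair_j = np.array([index[b] for _, b in keys], dtype=np.int64)
        self.base = np.array([pair_base[k] for k in keys], dtype=np.int64)
        self.n = len(self.bubble_ids)
        supported = np.zeros(self.n, dtype=bool)
        supported[self.pair_i] = True
        supported[self.pair_j] = True
        self.supported = supported
        # rigid-set state: every bubble starts as its own singleton set
        self.set_of = np.arange(self.n, dtype=np.int64)
        self.rel = np.zeros(self.n, dtype=np.int64)  # orientation within set
        self.n_sets = self.n

    def members_of_sets(self) -> list[list[int]]:
        members: dict[int, list[int]] = {}
        for i in range(self.n):
            members.setdefault(int(self.set_of[i]), []).append(i)
        return [members[s] for s in sorted(members)]

    def coarsen(self):
        """Super-graph over rigid sets: (edge arrays, constant term)."""
        su = self.set_of[self.pair_i]
        sv = self.set_of[self.pair_j]
        rel_sign = 1 - 2 * (self.rel[self.pair_i] ^ self.rel[self.pair_j])
        w = self.base * rel_sign
        intra = su == sv
        const = int(w[intra].sum())
        eu, ev, ew = su[~intra], sv[~intra], w[~intra]
        # collapse parallel edges
        lo = np.minimum(eu, ev)
        hi = np.maximum(eu, ev)
        order = np.lexsort((hi, lo))
        lo, hi, ew = lo[order], hi[order], ew[order]
        edges: dict[tuple[int, int], int] = {}
        for u, v, wt in zip(lo.tolist(), hi.tolist(), ew.tolist()):
            edges[(u, v)] = edges.get((u, v), 0) + wt
        adj: dict[int, list[tuple[int, int]]] = {}
        for (u, v), wt in edges.items():
            if wt == 0:
                continue
            adj.setdefault(u, []).append((v, wt))
            adj.setdefault(v, []).append((u, wt))
        return adj, edges, const


def _greedy_spins(
    spins: np.ndarray, adj: dict[int, list[tuple[int, int]]], rng: np.random.Generator
) -> np.ndarray:
    """In-place strictly-improving single-set flips until 1-flip-optimal.

    spins hold +-1 per rigid set; the contribution of super-edge (u, v, w)
    is w * s_u * s_v, so flipping u gains -2 * s_u * sum_v w_uv s_v, taken
    only when strictly positive.  Sets are visited in a fresh random order
    each sweep; the objective is monotone non-decreasing throughout.
    """
    n = spins.shape[0]
    improved = True
    while improved:
        improved = False
        for u in rng.permutation(n):
            neigh = adj.get(int(u))
            if not neigh:
                continue
            local = sum(w * spins[v] for v, w in neigh)
            if spins[u] * local < 0:
                spins[u] = -spins[u]
                improved = True
    return spins


def _spin_objective(
    spins: np.ndarray, edges: dict[tuple[int, int], int], const: int
) -> int:
    return const + sum(w * spins[u] * spins[v] for (u, v), w in edges.items())


def greedy_pass(
    state: PhaseState,
    bubbles: BubbleMap,
    contacts: ContactGraph,
    rng: np.random.Generator,
) -> PhaseState:
    """One greedy hill-climb from ``state`` to a 1-flip-optimal state.

    Visits rigid sets in random order, flipping any set whose flip strictly
    increases the total objective, until a full sweep makes no flip.
    """
    inst = _Instance(bubbles, contacts)
    members = state.merged_sets or [[bid] for bid in inst.bubble_ids]
    index = {bid: i for i, bid in enumerate(inst.bubble_ids)}
    spins = np.ones(len(members), dtype=np.int64)
    for s, group in enumerate(members):
        lead = state.orientation[group[0]]
        spins[s] = 1 - 2 * lead
        for bid in group:
            i = index[bid]
            inst.set_of[i] = s
            inst.rel[i] = state.orientation[bid] ^ lead
    inst.n_sets = len(members)
    adj, edges, const = inst.coarsen()
    _greedy_spins(spins, adj, rng)
    f = ((1 - spins) // 2).astype(np.int64)
    orientation = {}
    for s, group in enumerate(members):
        for bid in group:
            orientation[bid] = int(inst.rel[index[bid]] ^ f[s])
    return PhaseState(
        orientation=orientation,
        merged_sets=[list(g) for g in members],
        unsupported={
            bid for bid in inst.bubble_ids if not inst.supported[index[bid]]
        },
    )


# -- sampling and merging ---------------------------------------------------


def _run_sample(inst: _Instance, adj, edges, const, seed_key) -> tuple:
    rng = np.random.default_rng(seed_key)
    spins = rng.choice(np.array([-1, 1], dtype=np.int64), size=inst.n_sets)
    _greedy_spins(spins, adj, rng)
    objective = _spin_objective(spins, edges, const)
    f = ((1 - spins) // 2).astype(np.int64)
    orient = inst.rel ^ f[inst.set_of]
    same = (orient[inst.pair_i] == orient[inst.pair_j])
    return same, objective, orient


def _sample_round(
    inst: _Instance, config: SamplerConfig, round_idx: int
) -> tuple[np.ndarray, int, np.ndarray]:
    """Run one round of independent samples on the coarsened instance.

    Returns (n_same per pair, best objective, best orientation array).
    Samples are independent; with n_threads > 1 they run concurrently but
    are reduced in sample order, so results do not depend on thread count.
    """
    adj, edges, const = inst.coarsen()
    seed_keys = [
        [config.seed % _SEED_MOD, round_idx, s] for s in range(config.n_samples)
    ]
    if config.n_threads > 1:
        with ThreadPoolExecutor(max_workers=config.n_threads) as pool:
            results = list(
                pool.map(lambda key: _run_sample(inst, adj, edges, const, key), seed_keys)
            )
    else:
        results = [_run_sample(inst, adj, edges, const, key) for key in seed_keys]
    n_same = np.zeros(inst.pair_i.shape[0], dtype=np.int64)
    best_obj, best_orient = None, None
    for same, objective, orient in results:
        n_same += same
        if best_obj is None or objective > best_obj:
            best_obj, best_orient = objective, orient.copy()
    return n_same, int(best_obj), best_orient


def sample_orientations(
    bubbles: BubbleMap, contacts: ContactGraph, config: SamplerConfig
) -> ConsistencyMatrix:
    """Tally relative orientations of contact-sharing bubble pairs across
    independent greedy samples from random initial states."""
    inst = _Instance(bubbles, contacts)
    n_same, _obj, _orient = _sample_round(inst, config, round_idx=0)
    counts = {}
    for p in range(inst.pair_i.shape[0]):
        key = (
            inst.bubble_ids[int(inst.pair_i[p])],
            inst.bubble_ids[int(inst.pair_j[p])],
        )
        ns = int(n_same[p])
        counts[key] = (ns, config.n_samples - ns)
    return ConsistencyMatrix(counts=counts, n_samples=config.n_samples)


def _merge_round(inst: _Instance, n_same: np.ndarray, n_total: int, fraction: float):
    """Merge the most consistently co-oriented distinct-set pairs.

    Pairs are ranked by |n_same - n_opposite| (the imbalance fraction
    weighted by tally depth); ties by bubble index.  Each rigid set joins at
    most one merge per round, which bounds set sizes by 2^round.  The
    relative orientation of a merged pair is fixed to its majority tally.
    """
    n_opp = n_total - n_same
    score = np.abs(n_same - n_opp)
    distinct = inst.set_of[inst.pair_i] != inst.set_of[inst.pair_j]
    candidates = np.flatnonzero(distinct)
    if candidates.size == 0:
        return 0
    order = sorted(
        candidates.tolist(),
        key=lambda p: (-score[p], int(inst.pair_i[p]), int(inst.pair_j[p])),
    )
    n_target = math.ceil(fraction * len(order))
    merged_this_round: set[int] = set()
    n_merged = 0
    for p in order:
        if n_merged >= n_target:
            break
        i, j = int(inst.pair_i[p]), int(inst.pair_j[p])
        su, sv = int(inst.set_of[i]), int(inst.set_of[j])
        if su == sv or su in merged_this_round or sv in merged_this_round:
            continue
        want_same = n_same[p] >= n_opp[p]
        desired = 0 if want_same else 1
        g = int(inst.rel[i] ^ inst.rel[j]) ^ desired
        absorb = inst.set_of == sv
        if g:
            inst.rel[absorb] ^= 1
        inst.set_of[absorb] = su
        merged_this_round.update((su, sv))
        n_merged += 1
    # compact set ids
    _, inst.set_of = np.unique(inst.set_of, return_inverse=True)
    inst.n_sets = int(inst.set_of.max()) + 1 if inst.n else 0
    return n_merged


def merge_and_iterate(
    bubbles: BubbleMap, contacts: ContactGraph, config: SamplerConfig | None = None
) -> PhaseState:
    """Full optimizer: alternate sampling rounds with consistency merging.

    Each round draws ``n_samples`` greedy samples on the current coarsened
    instance, then merges the top ``merge_fraction`` of the most
    consistently co-oriented set pairs.  The returned state is the
    best-objective sample seen across all rounds (a merge that fixes a
    wrong relative orientation can only hurt later rounds, so earlier
    samples are kept competitive); bubbles without contact evidence keep
    their sampled orientation but are flagged unsupported.
    """
    config = config or SamplerConfig()
    inst = _Instance(bubbles, contacts)
    best_orient = np.zeros(inst.n, dtype=np.int64)
    best_overall = None
    for round_idx in range(1, config.n_rounds + 1):
        n_same, best_obj, orient = _sample_round(inst, config, round_idx)
        if orient is not None and (best_overall is None or best_obj > best_overall):
            best_overall, best_orient = best_obj, orient
        n_merged = _merge_round(inst, n_same, config.n_samples, config.merge_fraction)
        sizes = np.bincount(inst.set_of) if inst.n else np.array([0])
        largest = int(sizes.max()) if sizes.size else 0
        assert largest <= 2**round_idx, "rigid-set size exceeded 2^round bound"
        logger.info(
            "round %d: objective=%d merges=%d sets=%d largest_set=%d",
            round_idx,
            best_obj,
            n_merged,
            inst.n_sets,
            largest,
        )
    orientation = {
        bid: int(best_orient[i]) for i, bid in enumerate(inst.bubble_ids)
    }
    merged_sets = [
        [inst.bubble_ids[i] for i in group] for group in inst.members_of_sets()
    ]
    unsupported = {
        inst.bubble_ids[i] for i in range(inst.n) if not inst.supported[i]
    }
    return PhaseState(
        orientation=orientation, merged_sets=merged_sets, unsupported=unsupported
    )


def write_phase_tsv(
    path, state: PhaseState, bubbles: BubbleMap
) -> None:
    """Write per-segment phase assignments as TSV.

    Columns: segment_name, haplotype, bubble_id, merged_set_id, supported.
    """
    set_id_of = {}
    for s, group in enumerate(state.merged_sets):
        for bid in group:
            set_id_of[bid] = s
    with open(path, "w") as fh:
        fh.write("segment_name\thaplotype\tbubble_id\tmerged_set_id\tsupported\n")
        for bubble in sorted(bubbles, key=lambda b: b.id):
            orient = state.orientation[bubble.id]
            supported = int(bubble.id not in state.unsupported)
            for side, seg in enumerate(bubble.sides):
                hap = side ^ orient
                fh.write(
                    f"{seg}\t{hap}\t{bubble.id}\t"
                    f"{set_id_of.get(bubble.id, -1)}\t{supported}\n"
                )


def read_phase_tsv(path) -> tuple[BubbleMap, PhaseState]:
    """Inverse of :func:`write_phase_tsv` (for the standalone chain step)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("segment_name"):
                continue
            seg, hap, bid, set_id, supported = line.split("\t")
            rows.append((seg, int(hap), int(bid), int(set_id), int(supported)))
    by_bubble: dict[int, dict[int, str]] = {}
    orientation: dict[int, int] = {}
    unsupported: set[int] = set()
    sets: dict[int, set[int]] = {}
    for seg, hap, bid, set_id, supported in rows:
        by_bubble.setdefault(bid, {})[hap] = seg
        sets.setdefault(set_id, set()).add(bid)
        if not supported:
            unsupported.add(bid)
    bubble_map = BubbleMap()
    for bid in sorted(by_bubble):
        sides = by_bubble[bid]
        # haplotype 0 segment listed as side0 <=> orientation 0
        bubble_map.add(Bubble(bid, sides[0], sides[1]))
        orientation[bid] = 0
    state = PhaseState(
        orientation=orientation,
        merged_sets=[sorted(s) for _, s in sorted(sets.items())],
        unsupported=unsupported,
    )
    return bubble_map, state
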