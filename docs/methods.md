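# Methods

## Problem setting and model

A diploid assembly graph represents each heterozygous locus that the
assembler could separate as a *bubble*: two alternative segments (sides)
joined to the same flanking sequence. The graph is *blunt* — links carry
zero overlap — so concatenating segments along any walk reproduces sequence
exactly. Phasing means choosing, for every bubble *b*, an orientation
σ_b ∈ {0, 1} declaring which side belongs to haplotype 0. Homozygous
segments belong to both haplotypes.

### Contact objective

A proximity-ligation read links segments of one chromosome copy, so reads
whose alignments span two bubbles are evidence about the bubbles' relative
phase. With w(x, y) the number of reads linking segments x and y, the pair
score under orientations (σ_a, σ_b) is

    score(a, b) = [w(a_h0, b_h0) + w(a_h1, b_h1)] − [w(a_h0, b_h1) + w(a_h1, b_h0)],

where a_h is the side of *a* assigned to haplotype h. This is the simplest
function with the required sign structure — of the four possible contacts
between two bubbles only the two matching-phase ones are positive — and it
scales with evidence depth. It is antisymmetric under flipping exactly one
orientation, so the total objective (the sum over bubble pairs sharing at
least one contact edge) is invariant under a global flip; accuracy is
accordingly always scored up to a flip per contact-connected component.
Contacts between the two sides of one bubble are self-inconsistent evidence
and score nothing. Contacts touching non-bubble segments are retained in
the contact graph (they are useful QC) but invisible to the objective.

### Optimizer

Maximizing the objective is weighted max-cut, NP-hard in general. The
optimizer is a sampled greedy scheme designed for reproducibility on
fragmented graphs:

1. **Sampling.** n_samples independent hill-climbs start from uniformly
   random orientation states. A climb repeatedly sweeps the rigid sets in a
   fresh random order and takes any strictly improving single-set flip
   until a full sweep makes no flip (1-flip-optimal; zero-gain flips are
   refused for determinism). Each sample's RNG derives from
   (seed, round, sample index), so samples may run on any number of threads
   and are reduced in index order — results are bitwise independent of
   thread count.
2. **Consistency tally.** For every contact-sharing bubble pair and every
   sample, the relative orientation (same/opposite) is tallied.
3. **Merging.** Pairs are ranked by |n_same − n_opposite| (the imbalance
   fraction weighted by tally depth; ties by bubble index) and the top
   merge_fraction of distinct-set pairs are merged, freezing relative
   orientation at the majority tally. A set joins at most one merge per
   round, so after round r no set exceeds 2^r bubbles — the bound is
   asserted every round. Coarsening collapses the pair graph onto rigid
   sets exactly (intra-set pairs become a constant), so later rounds
   optimize the same objective over a shrinking state space.

The returned state is the best-objective sample seen in *any* round, not
only the last: a merge that freezes a wrong relative orientation would
otherwise make the optimum permanently unreachable, whereas keeping the
overall best is monotone in rounds. On random instances small enough to
enumerate (≤ 12 bubbles), this choice lifts exhaustive-optimum agreement
from 93/100 to 100/100.

Defaults: n_samples = 30, n_rounds = 10, merge_fraction = 0.5, seed = 0.
These are deliberately modest — the method's premise is many cheap
independent samples with few iterations each — and all are exposed in
`SamplerConfig` and on the command line. Bubbles with no contact edge keep
their sampled orientation but are flagged unsupported; chains split at such
bubbles rather than emitting arbitrary phase.

### Trio voting

Parental k-mer databases (k = 31 by default; odd so no k-mer equals its own
reverse complement) are reduced to parent-unique homozygous sets: count ≥
hom_threshold (default 2) in the donor and zero in the other parent. Each
bubble side is intersected with both sets and the bubble is called on the
net lean (pat₀ − mat₀) − (pat₁ − mat₁) over distinct canonical k-mer hits;
|lean| < min_votes (default 3) or a tie leaves the bubble uncalled. The
net-lean statistic is robust when both sides share residual parental
k-mers, compared with independent per-side majorities. Trio orientations
are globally anchored (haplotype 0 = paternal), so planted-truth recovery
is scored without flip normalization, and swapping the parent inputs
provably swaps every call.

### Bubble discovery

Where the assembler does not annotate bubbles, homologous segment pairs are
found by a bottom-s MinHash sketch (s = 128) over canonical 22-mers hashed
with a seeded splitmix64 finalizer; pairs whose union-estimator Jaccard
reaches 0.05 are aligned globally on both strands (edlib edit distance;
identity taken as 1 − d/max(len), a conservative per-column bound) and
pairs at identity ≥ 0.9 enter a greedy descending-identity matching with
lexicographic tie-breaks. Matching instead of optimal assignment is
justified because real haplotype bubbles are overwhelmingly isolated pairs.
All four thresholds are configuration values; none is sacred, and the
defaults were fixed once for determinism.

### Chain topology and unzipping

The chain definition is strict to avoid misjoins. A bubble side is
*diploid* iff on each side of the segment it has ≤ 2 direct neighbors and
its two-hop neighborhood — step out, then look back at the entry side of
each neighbor — contains at most its bubble partner; the partner must
satisfy the same. A homozygous node is *in-chain* iff each side is a graph
end or attaches to exactly the two sides of one diploid bubble. A node
satisfying the rule on only one side is excluded (strictness over recall).
Chains are maximal walks over the labeled nodes; element orientation is
inferred from which side each link enters, `-` meaning reverse complement.
Unzipping routes haplotype h through side h ⊕ σ of each bubble and copies
homozygous nodes into both haplotypes, so unzipped length is exactly
2·(hom bp) + (het bp) and every emitted step corresponds to an input link.
Isolated bubbles are emitted as one-element chains; they still carry phase.

## Synthetic study conditions

The fixture generator plants exactly the structures above: chains of
alternating homozygous segments and bubbles whose sides are copies
diverged by independent substitutions (default 1%, the realistic
human-like heterozygosity regime for assembler bubbles), with optional
tangle nodes that violate the adjacency rule. Defaults: 10 chains × 20
bubbles, 1 kbp segments, 20 contacts per adjacent bubble pair, endpoint
fidelity (signal ratio) 0.95, mapping quality 60 with probability 0.9 and
0 otherwise so that mapQ filtering is exercised.

The contact noise model: each read carries a true haplotype; its first
endpoint always matches it and every further endpoint is cis with
probability equal to the signal ratio. For Hi-C read pairs the probability
that a contact is consistent is therefore exactly the signal ratio (this is
the mode used to calibrate the signal-ratio estimator at 0.8). For Pore-C
concatemers (Poisson subread counts, consecutive bubbles with wrap-around),
subread pairs not involving the first subread are consistent with
probability sr² + (1−sr)², so the measured Pore-C signal ratio sits
slightly below the endpoint fidelity — e.g. ≈ 0.92 at 0.95 — which is why
the README's QC example prints 0.925.

What the generator does **not** emulate: read-level sequence errors and
mappability structure (alignments are taken as given, as the real tool also
does), restriction-site biases, PCR duplicates, distance-decay beyond a
geometric/span model, inter-chromosomal background contacts, and >2-sided
bubbles. Passing tests therefore demonstrate correctness of the inference
given contacts with the stated noise structure, not robustness to aligner
pathologies.

Because separate chains share no contacts, phase recovery is scored up to a
flip *per chain* — the per-chromosome convention — since nothing in the
data can identify the relative flip of disconnected components.

## Numerical and interface choices

* Orientation `+` is the stored sequence, `-` its reverse complement;
  links are stored once in canonical form and queried symmetrically.
  Non-blunt input (overlap other than `0M`/`*`) is rejected at parse time.
* Canonical k-mers are min(packed, revcomp-packed) of a 2-bit encoding
  (k ≤ 31); windows containing N are dropped. Hashing is a seeded
  splitmix64 finalizer; the seed is configuration, default fixed.
* All tie-breaks (merge ranking, matching, chain ids, output ordering) are
  lexicographic or index-based, making every output byte-reproducible for
  a given seed/config, independent of thread count and insertion order.
* Degenerate inputs: empty annotation or zero bubbles make phasing a no-op;
  segments shorter than the k-mer size are skipped by sketching; bubbles
  with identical sides (possible at low divergence × short segments) are
  legitimately uncallable by trio voting and are flagged rather than
  guessed.
* Per-read segment cap (default 50) guards the quadratic all-vs-all pair
  expansion against chimeric concatemers; secondary alignments are always
  dropped, supplementary alignments are opt-in (Pore-C subreads arrive as
  supplementary records).

## Problem sizes used in checks

The automated checks run at desk scale, sized to keep the full suite under
a few minutes while leaving each statistical check well-powered: optimizer
vs brute force on 100 instances of ≤ 12 bubbles (the enumeration limit);
phase recovery on 200 bubbles / 10 chains; trio recovery on 100 bubbles
with 2 kbp sides (≈ 20 planted variants per side at 1% divergence, i.e.
hundreds of k-mer votes — the same statistical regime as longer segments);
signal-ratio calibration on > 10 000 pair contacts; sketch fidelity at
0–10% divergence. These sizes are choices of the package's test design,
recorded here so they can be scaled up verbatim.

## Known limitations

* Only two-sided bubbles are modeled; multi-allelic sites and superbubble
  detection from topology alone are out of scope.
* Chains are not scaffolded across gaps; joining chains with long-range
  contacts is future work.
* Contact phasing cannot orient bubbles lacking contact evidence, and
  cannot relate disconnected components; trio phasing can, when parental
  data exist.
* The greedy matcher for homology can in principle mis-pair segments in
  highly repetitive graphs where one segment is similar to several; the
  identity threshold, not the matcher, is the main defense.
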