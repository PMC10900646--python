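# Methods

This note records the models, conventions and numerical choices behind
`dcjindel`, and what the validation suite does and does not establish.

## Genome model and homology

A genome is a graph whose vertices are marker extremities (tail `t`, head
`h`) and whose edges are markers and adjacencies, both forming matchings;
components are therefore simple paths (linear chromosomes) and cycles
(circular chromosomes).  Homology is an equivalence on markers keyed by
family label, extended head-to-head and tail-to-tail to extremities.  A
homology is *resolved* when no family occurs twice within a genome; a
*matching* is a resolved refinement, *maximal* when it pairs
min(|f_A|, |f_B|) members of every family.  Occurrence ids are assigned in
reading order, genome A before genome B, starting at 1, so every
downstream vertex ordering is reproducible from the input text alone.

The UniMoG dialect read and written here: whitespace-separated signed
family tokens; a chromosome is a maximal token run terminated by `|`
(linear) or `)` (circular); several chromosomes may share a line; empty
chromosomes are a parse error.  Chromosome equality is invariant under full
reversal (linear) and rotation plus reversal (circular); genome equality is
multiset equality of canonicalized chromosomes after relabeling through a
matching.

## Restricted distance and the component census

Indels are *restricted*: only segments consisting purely of unmatched
(singular) markers may be inserted or deleted, which rules out free-lunch
scenarios that delete and reinsert whole chromosomes.  Circular singletons
(circular chromosomes of only singular markers) cost exactly one indel each
and are stripped in pre-processing; their count `s` is added to the
formula.

The census is computed on the *augmented* multi-relational diagram: one
pseudo-cap vertex and pseudo-cap adjacency edge per telomere, one indel
edge per marker.  After augmentation every vertex lies in exactly one
adjacency edge, so the graph of adjacency plus selected extremity edges
decomposes into simple cycles and paths whose endpoints are pseudo-caps
(telomere ends, class `A`/`B`) or lava vertices (unmatched-marker ends,
class `a`/`b`).  Two conventions matter:

* **Parity** is measured in extremity edges.  Because extremity edges are
  the only edges crossing genomes, parity is implied by the endpoint
  classes (same genome ⇒ even, different ⇒ odd); the classifier asserts
  this redundancy on every component.  The opposite convention (length in
  adjacency edges) exists in the literature and is *not* used here.
* **A lava vertex that is also a telomere** becomes, after augmentation, a
  two-vertex path with zero extremity edges: an even pier (`P_A∘a` or
  `P_B∘b`).

The distance for a resolved matching is then

    d = n − c + ⌈(p_ab + max(p_A∘a, p_B|a) + max(p_A|b, p_B∘b) − p_A|B)/2⌉ + s

with the mathematical ceiling (exact for negative numerators, which occur
for equal genomes with linear chromosomes).

## Abstract operations, safety, bridges

DCJ operations are written on component types, e.g. `P_A∘a, P_B|a →
P_A|B, P_a∘a`.  The candidate space of such signatures is generated
mechanically: a DCJ acts in one genome on up to two cut sites (internal
adjacencies of generic components, or telomere ends of paths in that
genome), and resultant types follow from how the four loose ends are
rejoined.  A signature is *safe* when it lowers the formula term `F` by
exactly 1 in every surrounding component multiset.  Safety is decided by
evaluating ΔF over all context vectors with 0–4 copies of each of the six
census counters that enter `F` (the other component types do not appear in
`F` and cannot change ΔF; their presence is only needed when they are
sources).  The bound of 4 suffices because `F` is piecewise linear with
breakpoints only at equalities of the two max terms and at the ceiling
parity; spot checks at bound 6 agree.  The enumeration yields exactly
seven safe types once the cycle-extraction family `K → K' + C` is counted
once — the family includes the full circularization of a two-telomere
same-genome path (empty remainder `K'`) and the split of a cycle into two.

A *reduced bridge* is a bridge (a chain of components concatenated through
the indel edges of shared singular markers) abstracted to its unsaturated
components: two piers and at most one odd pontoon.  Consecutive lava ends
must share a genome, which yields six pier pairs with equal lava genome and
four pier–`P_a|b`–pier triples: ten types.  Two of them equal safe-operation
source pairs and are sortable internally; over the remaining eight, the
three recombination-enabling safe operations support 9, 9 and 10 bridge
pairings respectively (3×3 source placements for each pier recombination;
4 + C(4,2) selections of odd-pontoon carriers).  Two further recombinations
involving only even piers of one telomere genome are never needed (an
equally good internal operation always exists) and are excluded from the
counts.

## The integer program

The program optimizes the census formula over consistent decompositions.
Design choices:

* **Variables.** Per-edge binaries `x` with sibling-equality constraints
  (head and tail edges of a candidate pair agree); integer `y_v ∈ [0,
  ix(v)]` equal across every edge of a component (big-M = max ix for
  extremity edges, exact equality for always-selected adjacency edges);
  `z_v` marks the minimum-id vertex of lava-free components (`ix(v)·z_v ≤
  y_v`); endpoint-genome labels `l_v` pinned statically at pseudo-caps and
  dynamically at lava vertices.
* **Vertex ids.** Pseudo-caps of genome A get the lowest ids, then B's
  pseudo-caps, then all marker extremities.  Hence the minimum vertex of
  any path containing a telomere is a pseudo-cap, and of any path with an
  A-telomere an A pseudo-cap — cycle reports live on adjacency edges
  between non-cap vertices, `A|B` reports only on A-cap edges, pier
  reports only on cap edges of the matching genome, `a|b` reports on every
  adjacency edge (gated by a neighbouring selected indel edge).
* **Forcing.** Each report needing a `z` is licensed by the lower-id
  endpoint of its edge; since every vertex has exactly one adjacency edge,
  at most one licensed report per component follows for free.  Labels must
  agree along components except at edges reporting odd types, so every
  path with endpoint genomes differing must report; pseudo-caps whose
  component label `y` is 0 must report a pier.  Reports can over-state
  only cost-increasing types; the objective never benefits, and the
  distance and matching returned to callers are recomputed from the
  selected edges by the classifier, never read off report variables.
* **Ceiling.** An integer `q` bounded below by all four combinations
  `2q ≥ p_ab + α + β − p_A|B`, α ∈ {p_A∘a, p_B|a}, β ∈ {p_A|b, p_B∘b};
  minimization makes `q` the exact ceiling of the maximum.
* **Circular singletons.** One indicator per circular chromosome, forced
  to 1 when all its indel edges are selected; no pre-filtering by family —
  the constraint is simply inactive otherwise.
* **Matching models.** Per-family bounds (L, U): maximum = (min, min),
  intermediate = (1, min), exemplar = (1, 1); families present in one
  genome only get (0, 0).  The intermediate model's bounds follow the
  matching-model literature (a lower bound of one pair, up to the maximum).
* **Backend.** Models are solved with the HiGHS MIP solver bundled in
  scipy (`mip_rel_gap = 0`; objectives are integral).  LP and MPS text
  export allows any external exact solver to be substituted.

## Brute-force oracles

Two independent references validate the analytic paths:

* **Scenario BFS.**  Bidirectional breadth-first search over canonical
  genome states under all DCJ variants and all restricted indels
  (including sub-segments of singular runs and whole-chromosome indels,
  and insertion as a new linear chromosome).  Matched markers are labeled
  by pair, singular markers by genome and family — a leftover singular
  marker of one genome can never be equated with one of the other, while
  same-genome same-family singulars are interchangeable (inserted content
  is arbitrary, so any bijection is realizable at equal cost).  The search
  returns exact distances or raises an explicit *undecided* error at its
  state cap; it never returns a wrong number.
* **Matching enumeration.**  All maximal matchings (count per family
  C(max, min)·min!), each scored by the census formula; the minimum is the
  natural-genome reference for the ILP.

The exhaustive cross-validation covers every genome pair with up to three
markers per genome over a two-family alphabet (both orientations, linear
and circular, multiple chromosomes) under *every* resolved matching —
about 1.1 × 10⁵ pair/matching cases.  Cases are deduplicated through a
canonical signature (matched pairs renumbered, singular families
collapsed; the distance depends only on this structure), leaving about
1.2 × 10⁴ distinct instances whose BFS distances are all computed.  Problem
sizes in the ILP suite (hundreds of random genomes with ≤ 6 markers and
family multiplicity ≤ 3) keep exhaustive enumeration trustworthy while
exercising duplicated families, mixed topologies and singular content.

## Simulator

`make_root` lays out `n` distinct single-copy families, all forward,
spread evenly over `k` linear chromosomes.  `evolve_pair` applies a fixed
total operation budget split evenly between two lineages; each operation's
type is drawn with probability rate/(1 + Σ rates) with the DCJ rate fixed
at 1.  Defaults follow the reference parameterization: insertion 0.1,
deletion 0.2, duplication 0.4 (for a 10,000-operation budget this is 5882
DCJs in expectation), Zipf shape 4 for indel lengths and 6 for duplication
lengths.

Mechanics chosen where the model leaves freedom: a DCJ is drawn uniformly
from all distinct concrete operations (both rejoins of every adjacency
pair, both variants of every adjacency–telomere combination, every
telomere join, every adjacency fission); insertions place a fresh-family
segment at a site drawn uniformly from all adjacencies, telomeres and a
new-circular-chromosome option; deletions remove a Zipf-length segment
downstream of a uniform start marker, capped at the chromosome, and are
resampled if they would empty the genome; duplications copy such a segment
(families retained, unanchored) to a uniform insertion site, so tandem and
dispersed duplications both occur.  One PRNG stream consumed in fixed
order (lineage A, then B) makes runs bit-for-bit reproducible.

The ground-truth matching pairs the original (non-duplicate) descendants
of each root marker surviving in both lineages.  It is a valid resolved
matching but not necessarily a *maximal* one after duplications, and the
simulator emulates neither marker-order biases of real genomes nor
assembly fragmentation; passing tests therefore establish the arithmetic
of the model, not fidelity to any particular genome collection.

## Known limitations

* The BFS oracle is exponential; beyond roughly four markers per genome it
  exists only to validate, never to solve.
* The ILP is exact but the enumeration-based tests keep instances small;
  large fragmented genomes are the production use case of the program
  itself, exercised here only at simulation scale.
* `extract` requires an incumbent; on hard instances with a time limit the
  reported distance is an upper bound with the solver's dual bound
  attached, and the recomputed census always refers to the incumbent
  matching.
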