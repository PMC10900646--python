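"""Multi-relational diagram (MRD) construction and component classification.

The MRD of a genome pair has one vertex per marker extremity.  *Adjacency
edges* are the adjacencies of both genomes; *extremity edges* join
equivalent extremities (head-head, tail-tail) across genomes.  Under a
resolved matching, selecting the extremity edges of matched pairs leaves a
graph of simple cycles and paths, whose census drives the distance formula.

For the integer program (and to avoid a path degenerating to a single
vertex) the diagram is augmented:

* one *pseudo-cap* vertex and pseudo-cap adjacency edge per telomere, so
  every real vertex lies in exactly one adjacency edge;
* one *indel edge* per marker, joining its head and tail; a selected indel
  edge flags the marker's extremities as *lava vertices* (destined for an
  insertion or deletion);
* an injective vertex id ``ix`` with pseudo-caps of genome A lowest,
  then pseudo-caps of B, then all marker extremities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .genomes import (
    HEAD,
    TAIL,
    Extremity,
    FamilyAssignment,
    Genome,
    ResolvedMatching,
    genome_adjacencies,
    validate_matching,
)

#: Pseudo-cap vertices are ("cap", serial); marker extremities are (occ, "t"/"h").
Vertex = tuple

#: Component type labels, in the order used throughout the package.
COMPONENT_TYPES = (
    "C",  # cycle
    "AoA", "AB", "BoB",          # viaducts (two telomeres)
    "Aoa", "Ab", "Ba", "Bob",    # piers (telomere + lava vertex)
    "aoa", "ab", "bob",          # pontoons (two lava vertices)
)

PATH_TYPES = COMPONENT_TYPES[1:]


@dataclass(frozen=True)
class ExtremityEdge:
    """An extremity edge with its sibling bookkeeping.

    ``pair`` is the candidate marker pair (A occurrence, B occurrence) the
    edge belongs to; ``kind`` is ``"h"`` or ``"t"``.  The head and tail
    edges of the same pair are *siblings*: a consistent decomposition
    selects either both or neither.
    """

    u: Extremity
    v: Extremity
    pair: tuple[int, int]
    kind: str


@dataclass
class MRDGraph:
    genome_a: Genome
    genome_b: Genome
    families: FamilyAssignment
    adjacency_edges: list[frozenset]
    extremity_edges: list[ExtremityEdge]
    #: occurrence id -> ("A"|"B", family)
    occ_info: dict[int, tuple[str, str]]
    telomeres_a: list[Extremity]
    telomeres_b: list[Extremity]
    # --- augmentation state ---
    augmented: bool = False
    caps_a: list[Vertex] = field(default_factory=list)
    caps_b: list[Vertex] = field(default_factory=list)
    #: cap vertex -> the telomere it anchors
    cap_anchor: dict[Vertex, Extremity] = field(default_factory=dict)
    #: occurrence id -> (tail, head) indel edge endpoints
    indel_edges: dict[int, tuple[Extremity, Extremity]] = field(default_factory=dict)
    ix: dict[Vertex, int] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def vertices(self) -> list[Vertex]:
        verts: list[Vertex] = list(self.caps_a) + list(self.caps_b)
        for occ in (*self.genome_a.occurrences(), *self.genome_b.occurrences()):
            verts.append(occ.tail)
            verts.append(occ.head)
        return verts

    def genome_of(self, v: Vertex) -> str:
        if v[0] == "cap":
            return self.occ_info[self.cap_anchor[v][0]][0]
        return self.occ_info[v[0]][0]

    def is_cap(self, v: Vertex) -> bool:
        return v[0] == "cap"

    def candidate_pairs(self) -> list[tuple[int, int]]:
        """All cross-genome same-family occurrence pairs, deterministically."""
        pairs = []
        for f in sorted(self.families.families):
            in_a, in_b = self.families.families[f]
            for m in in_a:
                for n in in_b:
                    pairs.append((m, n))
        return pairs

    def dump_tsv(self) -> str:
        """Debug edge list: type, endpoints and their ix (if assigned)."""
        rows = ["type\tu\tv\tix_u\tix_v"]

        def fmt(v):
            return f"{v[0]}.{v[1]}"

        for e in self.adjacency_edges:
            u, v = sorted(e, key=lambda x: str(x))
            rows.append(
                f"adjacency\t{fmt(u)}\t{fmt(v)}\t{self.ix.get(u, '')}\t{self.ix.get(v, '')}"
            )
        for e in self.extremity_edges:
            rows.append(
                f"extremity\t{fmt(e.u)}\t{fmt(e.v)}\t"
                f"{self.ix.get(e.u, '')}\t{self.ix.get(e.v, '')}"
            )
        for occ, (u, v) in sorted(self.indel_edges.items()):
            rows.append(
                f"indel\t{fmt(u)}\t{fmt(v)}\t{self.ix.get(u, '')}\t{self.ix.get(v, '')}"
            )
        return "\n".join(rows) + "\n"


def build_mrd(a: Genome, b: Genome, fams: FamilyAssignment) -> MRDGraph:
    """Construct the un-augmented MRD of a pair under a homology.

    Extremity edges join exactly the equivalent head-head and tail-tail
    extremity pairs across genomes, so a family with ``|f_A|`` and ``|f_B|``
    occurrences contributes ``2 |f_A| |f_B|`` of them.
    """
    occ_info: dict[int, tuple[str, str]] = {}
    for occ in a.occurrences():
        occ_info[occ.occurrence_id] = ("A", occ.family)
    for occ in b.occurrences():
        if occ.occurrence_id in occ_info:
            raise ValueError(
                f"occurrence id {occ.occurrence_id} reused across the pair"
            )
        occ_info[occ.occurrence_id] = ("B", occ.family)

    adj_a, tel_a = genome_adjacencies(a)
    adj_b, tel_b = genome_adjacencies(b)

    ext_edges: list[ExtremityEdge] = []
    for f in sorted(fams.families):
        in_a, in_b = fams.families[f]
        for m in in_a:
            for n in in_b:
                ext_edges.append(ExtremityEdge((m, TAIL), (n, TAIL), (m, n), TAIL))
                ext_edges.append(ExtremityEdge((m, HEAD), (n, HEAD), (m, n), HEAD))

    def tel_order(t: Extremity):
        return (t[0], 0 if t[1] == TAIL else 1)

    return MRDGraph(
        genome_a=a,
        genome_b=b,
        families=fams,
        adjacency_edges=sorted(adj_a | adj_b, key=lambda e: sorted(map(str, e))),
        extremity_edges=ext_edges,
        occ_info=occ_info,
        telomeres_a=sorted(tel_a, key=tel_order),
        telomeres_b=sorted(tel_b, key=tel_order),
    )


def augment(m: MRDGraph) -> MRDGraph:
    """Add pseudo-caps, indel edges and the ``ix`` vertex ordering.

    Returns the same (mutated) graph for convenience.  The ordering places
    A pseudo-caps before B pseudo-caps before all marker extremities, each
    group in occurrence order, which downstream component reporting relies
    on (the minimum-id vertex of any path with a telomere is a pseudo-cap,
    and of a path with an A telomere an A pseudo-cap).
    """
    if m.augmented:
        raise ValueError("MRD is already augmented")
    serial = 0
    for tel_list, cap_list in ((m.telomeres_a, m.caps_a), (m.telomeres_b, m.caps_b)):
        for tel in tel_list:
            cap: Vertex = ("cap", serial)
            serial += 1
            cap_list.append(cap)
            m.cap_anchor[cap] = tel
            m.adjacency_edges.append(frozenset((cap, tel)))
    for occ in (*m.genome_a.occurrences(), *m.genome_b.occurrences()):
        m.indel_edges[occ.occurrence_id] = (occ.tail, occ.head)

    nxt = 1
    for v in m.vertices():
        m.ix[v] = nxt
        nxt += 1
    m.augmented = True
    return m


# ---------------------------------------------------------------------------
# Decompositions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Decomposition:
    """Selected extremity edges (as sibling pairs) and indel edges.

    ``pairs`` are the matched (A occurrence, B occurrence) pairs whose head
    and tail extremity edges are selected; ``indel_occurrences`` are the
    markers whose indel edge is selected (their extremities are lava).
    Adjacency edges are always implicitly selected.
    """

    pairs: frozenset[tuple[int, int]]
    indel_occurrences: frozenset[int]


def decomposition_from_matching(
    m: MRDGraph, match: ResolvedMatching
) -> Decomposition:
    """Select the extremity edges of matched pairs and the indel edges of
    every unmatched marker."""
    validate_matching(m.families, match)
    matched = match.matched_a() | match.matched_b()
    unmatched = frozenset(i for i in m.occ_info if i not in matched)
    return Decomposition(pairs=frozenset(match.pairs), indel_occurrences=unmatched)


# ---------------------------------------------------------------------------
# Component census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentReport:
    """Counts of cycles and the ten path types of a decomposition.

    ``n`` is the number of matched marker pairs, ``s`` the number of
    circular singletons handled in pre-processing.  Path subscripts use
    capital letters for telomere endpoints, lowercase for lava endpoints,
    and encode parity implicitly: endpoints in the same genome give an even
    number of extremity edges, endpoints in different genomes an odd one.
    """

    n: int = 0
    C: int = 0
    AoA: int = 0
    AB: int = 0
    BoB: int = 0
    Aoa: int = 0
    Ab: int = 0
    Ba: int = 0
    Bob: int = 0
    aoa: int = 0
    ab: int = 0
    bob: int = 0
    s: int = 0

    def counts(self) -> dict[str, int]:
        return {t: getattr(self, t) for t in COMPONENT_TYPES}

    def swap_genomes(self) -> "ComponentReport":
        """The census under the A <-> B relabeling of the pair."""
        return ComponentReport(
            n=self.n, C=self.C, s=self.s,
            AoA=self.BoB, BoB=self.AoA, AB=self.AB,
            Aoa=self.Bob, Bob=self.Aoa, Ab=self.Ba, Ba=self.Ab,
            aoa=self.bob, bob=self.aoa, ab=self.ab,
        )

    def to_tsv(self) -> str:
        keys = ["n", *COMPONENT_TYPES, "s"]
        vals = [str(self.n), *(str(getattr(self, t)) for t in COMPONENT_TYPES), str(self.s)]
        return "\t".join(keys) + "\n" + "\t".join(vals) + "\n"


def _endpoint_class(m: MRDGraph, v: Vertex) -> tuple[str, str]:
    """Classify a path endpoint: ("T", genome) for a pseudo-cap (telomere),
    ("L", genome) for a lava vertex."""
    if m.is_cap(v):
        anchor = m.cap_anchor[v]
        return ("T", m.occ_info[anchor[0]][0])
    return ("L", m.occ_info[v[0]][0])


_PATH_TYPE = {
    (("T", "A"), ("T", "A")): "AoA",
    (("T", "A"), ("T", "B")): "AB",
    (("T", "B"), ("T", "B")): "BoB",
    (("L", "A"), ("T", "A")): "Aoa",
    (("L", "B"), ("T", "A")): "Ab",
    (("L", "A"), ("T", "B")): "Ba",
    (("L", "B"), ("T", "B")): "Bob",
    (("L", "A"), ("L", "A")): "aoa",
    (("L", "A"), ("L", "B")): "ab",
    (("L", "B"), ("L", "B")): "bob",
}


def classify_components(
    m: MRDGraph, d: Decomposition, s: int = 0
) -> ComponentReport:
    """Census of the decomposition's components.

    Builds the graph of all adjacency edges plus the selected extremity
    edges; every connected component is a simple cycle or path.  Path
    endpoints are pseudo-caps (telomeres) or lava vertices.  Parity in
    extremity edges is implied by the endpoint genomes and asserted.
    """
    if not m.augmented:
        raise ValueError("classify_components requires an augmented MRD")
    g = nx.Graph()
    g.add_nodes_from(m.vertices())
    for e in m.adjacency_edges:
        u, v = tuple(e)
        g.add_edge(u, v, ext=False)
    selected_pairs = set(d.pairs)
    for e in m.extremity_edges:
        if e.pair in selected_pairs:
            g.add_edge(e.u, e.v, ext=True)

    counts = dict.fromkeys(COMPONENT_TYPES, 0)
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        degrees = dict(sub.degree())
        ends = [v for v, dgr in degrees.items() if dgr == 1]
        n_ext = sum(1 for _, _, is_ext in sub.edges(data="ext") if is_ext)
        if not ends:
            if any(dgr != 2 for dgr in degrees.values()):
                raise AssertionError("decomposition component is not simple")
            counts["C"] += 1
            continue
        if len(ends) != 2 or any(dgr > 2 for dgr in degrees.values()):
            raise AssertionError("decomposition component is not a simple path")
        key = tuple(sorted((_endpoint_class(m, ends[0]), _endpoint_class(m, ends[1]))))
        ptype = _PATH_TYPE[key]
        same_genome = key[0][1] == key[1][1]
        if (n_ext % 2 == 0) != same_genome:
            raise AssertionError(
                f"parity of {ptype} path inconsistent with endpoint genomes"
            )
        counts[ptype] += 1

    return ComponentReport(n=len(d.pairs), s=s, **{t: counts[t] for t in COMPONENT_TYPES})


def detect_circular_singletons(g: Genome, match: ResolvedMatching) -> int:
    """Number of circular chromosomes consisting only of unmatched markers.

    Each such chromosome costs exactly one indel and is dealt with in
    pre-processing, outside the component formula.
    """
    matched = match.matched_a() | match.matched_b()
    return sum(
        1
        for chrom in g.chromosomes
        if chrom.circular
        and all(m.occurrence_id not in matched for m in chrom.markers)
    )


def strip_circular_singletons(
    a: Genome, b: Genome, match: ResolvedMatching
) -> tuple[Genome, Genome, int]:
    """Remove circular-singleton chromosomes from both genomes; return the
    stripped pair and the combined count ``s``."""
    matched = match.matched_a() | match.matched_b()

    def strip(g: Genome) -> tuple[Genome, int]:
        keep, dropped = [], 0
        for chrom in g.chromosomes:
            if chrom.circular and all(
                m.occurrence_id not in matched for m in chrom.markers
            ):
                dropped += 1
            else:
                keep.append(chrom)
        return Genome(g.name, tuple(keep)), dropped

    a2, sa = strip(a)
    b2, sb = strip(b)
    return a2, b2, sa + sb
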