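"""Restricted DCJ-indel distance for resolved homologies.

The distance of a genome pair under a resolved matching is read off the
component census of the multi-relational diagram::

    d = n - c + ceil((p_ab + max(p_Aoa, p_Ba) + max(p_Ab, p_Bob) - p_AB) / 2) + s

with ``n`` matched marker pairs, ``c`` cycles, the ``p`` terms the path-type
counts and ``s`` circular singletons (each worth one indel, handled in
pre-processing).  The shorthand ``F = n - c + ceil(~p/2)`` denotes the
formula without the singleton term.

The module also provides the abstract-operation machinery around the
formula: DCJ operations written on component types (``P_Aoa, P_Ba ->
P_AB, P_aoa`` and the like), the enumeration that recovers the seven *safe*
operation types (those with ``delta F = -1`` in every surrounding component
multiset), the ten reduced-bridge types and the recombination counts they
support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

from .genomes import Genome, ResolvedMatching
from .mrd import (
    COMPONENT_TYPES,
    ComponentReport,
    augment,
    build_mrd,
    classify_components,
    decomposition_from_matching,
    strip_circular_singletons,
)
from .genomes import derive_families


def _ceil_div2(num: int) -> int:
    """Mathematical ceiling of num/2, correct for negative numerators."""
    return -((-num) // 2)


def formula_distance(r: ComponentReport) -> int:
    """Evaluate the distance formula on a component census."""
    num = r.ab + max(r.Aoa, r.Ba) + max(r.Ab, r.Bob) - r.AB
    return r.n - r.C + _ceil_div2(num) + r.s


def resolved_distance(
    a: Genome, b: Genome, match: ResolvedMatching
) -> tuple[int, ComponentReport]:
    """Restricted DCJ-indel distance of a pair under a resolved matching.

    Circular singletons are counted and stripped first, then the MRD of the
    remaining pair is decomposed along the matching and classified.
    """
    a2, b2, s = strip_circular_singletons(a, b, match)
    m = augment(build_mrd(a2, b2, derive_families(a2, b2)))
    d = decomposition_from_matching(m, match)
    report = classify_components(m, d, s=s)
    return formula_distance(report), report


# ---------------------------------------------------------------------------
# Abstract DCJ operations on component types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class OperationSignature:
    """A DCJ operation written on component types.

    ``sources`` and ``resultants`` are sorted tuples of component-type
    labels.  ``generic=True`` marks the cycle-extraction family
    ``K -> K' + C`` (any component sheds an even cycle; the remainder keeps
    the component's type and may be empty), which is counted once.
    """

    sources: tuple[str, ...]
    resultants: tuple[str, ...]
    generic: bool = False

    def swap_genomes(self) -> "OperationSignature":
        return OperationSignature(
            tuple(sorted(_SWAP[t] for t in self.sources)),
            tuple(sorted(_SWAP[t] for t in self.resultants)),
            self.generic,
        )

    def __str__(self) -> str:
        if self.generic:
            return "K -> K' + C"
        return ",".join(self.sources) + " -> " + ",".join(self.resultants)


_SWAP = {
    "C": "C", "K": "K", "AoA": "BoB", "BoB": "AoA", "AB": "AB",
    "Aoa": "Bob", "Bob": "Aoa", "Ab": "Ba", "Ba": "Ab",
    "aoa": "bob", "bob": "aoa", "ab": "ab",
}

#: Endpoint classes: ("T", genome) telomere, ("L", genome) lava vertex.
_ENDS = {
    "AoA": (("T", "A"), ("T", "A")),
    "AB": (("T", "A"), ("T", "B")),
    "BoB": (("T", "B"), ("T", "B")),
    "Aoa": (("T", "A"), ("L", "A")),
    "Ab": (("T", "A"), ("L", "B")),
    "Ba": (("T", "B"), ("L", "A")),
    "Bob": (("T", "B"), ("L", "B")),
    "aoa": (("L", "A"), ("L", "A")),
    "ab": (("L", "A"), ("L", "B")),
    "bob": (("L", "B"), ("L", "B")),
}

_TYPE_OF_ENDS = {tuple(sorted(v)): k for k, v in _ENDS.items()}


def _path_type(e1, e2) -> str:
    return _TYPE_OF_ENDS[tuple(sorted((e1, e2)))]


def _lava_counts(types: Iterable[str]) -> tuple[int, int, int, int]:
    """(A telomeres, B telomeres, A lava, B lava) over a type multiset."""
    ta = tb = la = lb = 0
    for t in types:
        if t == "C":
            continue
        for kind, g in _ENDS[t]:
            if kind == "T" and g == "A":
                ta += 1
            elif kind == "T":
                tb += 1
            elif g == "A":
                la += 1
            else:
                lb += 1
    return ta, tb, la, lb


def conserves_endpoints(op: OperationSignature) -> bool:
    """Lava endpoints are conserved per genome; telomere endpoints change by
    0 or +-2 in exactly one genome (a DCJ cut or join in that genome)."""
    if op.generic:
        return True
    sta, stb, sla, slb = _lava_counts(op.sources)
    rta, rtb, rla, rlb = _lava_counts(op.resultants)
    if (sla, slb) != (rla, rlb):
        return False
    da, db = rta - sta, rtb - stb
    return (da, db) in {(0, 0), (2, 0), (-2, 0), (0, 2), (0, -2)}


def _enumerate_dcj_signatures() -> set[OperationSignature]:
    """All abstract DCJ operation signatures on generic components.

    A DCJ acts in one genome on up to two cut sites, each an internal
    adjacency of a component or a telomere end of a path; the resultants'
    types follow from how the loose ends are rejoined.  Generic components
    of every type contain internal adjacencies of both genomes, so cut
    availability is not restricted by type; telomere ends require a
    telomere endpoint in the acting genome.
    """
    sigs: set[OperationSignature] = set()
    path_types = [t for t in COMPONENT_TYPES if t != "C"]

    def add(sources, resultants):
        sigs.add(
            OperationSignature(tuple(sorted(sources)), tuple(sorted(resultants)))
        )

    for g in ("A", "B"):
        tg = ("T", g)

        # one source, single cut (adjacency fission)
        add(["C"], [_path_type(tg, tg)])
        for s in path_types:
            e1, e2 = _ENDS[s]
            add([s], [_path_type(e1, tg), _path_type(tg, e2)])

        # one source, two adjacency cuts: inversion / cycle extraction
        add(["C"], ["C"])
        add(["C"], ["C", "C"])
        for s in path_types:
            add([s], [s])
            add([s], [s, "C"])

        # one source, adjacency cut + own telomere end
        for s in path_types:
            for e_tel, e_other in (_ENDS[s], _ENDS[s][::-1]):
                if e_tel != tg:
                    continue
                add([s], ["C", _path_type(tg, e_other)])
                add([s], [_path_type(tg, e_other)])

        # one source, both telomere ends joined (circularization)
        for s in path_types:
            if _ENDS[s] == (tg, tg):
                add([s], ["C"])

        # two sources, two adjacency cuts
        for s, t in itertools.combinations_with_replacement(COMPONENT_TYPES, 2):
            if s == "C" and t == "C":
                add([s, t], ["C"])
            elif s == "C" or t == "C":
                p = t if s == "C" else s
                add([s, t], [p])
            else:
                (e1, e2), (f1, f2) = _ENDS[s], _ENDS[t]
                add([s, t], [_path_type(e1, f1), _path_type(e2, f2)])
                add([s, t], [_path_type(e1, f2), _path_type(e2, f1)])

        # two sources, adjacency cut + telomere end
        for s in COMPONENT_TYPES:
            for t in path_types:
                for f_tel, f_other in (_ENDS[t], _ENDS[t][::-1]):
                    if f_tel != tg:
                        continue
                    if s == "C":
                        add([s, t], [_path_type(tg, f_other)])
                    else:
                        e1, e2 = _ENDS[s]
                        add([s, t], [_path_type(e1, f_other), _path_type(tg, e2)])
                        add([s, t], [_path_type(e2, f_other), _path_type(tg, e1)])

        # two sources, telomere join
        for s in path_types:
            for t in path_types:
                for e_tel, e_other in (_ENDS[s], _ENDS[s][::-1]):
                    for f_tel, f_other in (_ENDS[t], _ENDS[t][::-1]):
                        if e_tel == tg and f_tel == tg:
                            add([s, t], [_path_type(e_other, f_other)])
    return sigs


# ---------------------------------------------------------------------------
# delta F and the safe catalogue
# ---------------------------------------------------------------------------

def _F(counts: dict[str, int]) -> int:
    """F on a component-count vector, with n treated as 0 (DCJ-invariant)."""
    num = (
        counts["ab"]
        + max(counts["Aoa"], counts["Ba"])
        + max(counts["Ab"], counts["Bob"])
        - counts["AB"]
    )
    return -counts["C"] + _ceil_div2(num)


def _apply(counts: dict[str, int], op: OperationSignature) -> dict[str, int]:
    after = dict(counts)
    for t in op.sources:
        after[t] -= 1
        if after[t] < 0:
            raise ValueError(f"context lacks a source component of type {t}")
    for t in op.resultants:
        after[t] += 1
    return after


def delta_F(op: OperationSignature, context: ComponentReport) -> int:
    """Change of F when applying an abstract operation in a given context.

    For the generic cycle-extraction signature the operation is
    instantiated against every component type present in the context; all
    instantiations agree (the census change is ``+1`` cycle).
    """
    counts = context.counts()
    if op.generic:
        present = [t for t in COMPONENT_TYPES if counts[t] > 0]
        if not present:
            raise ValueError("context has no component to extract a cycle from")
        deltas = {
            _F(_apply(counts, OperationSignature((t,), tuple(sorted((t, "C"))))))
            - _F(counts)
            for t in present
        }
        assert len(deltas) == 1
        return deltas.pop()
    before = _F(counts)
    return _F(_apply(counts, op)) - before


#: Component types that enter F; contexts only need to range over these.
_F_TYPES = ("AB", "Aoa", "Ab", "Ba", "Bob", "ab")


def _is_safe(op: OperationSignature, max_copies: int = 4) -> bool:
    """True iff delta F = -1 for every context with 0..max_copies copies per
    component type (types outside the formula are held at max_copies; they
    do not enter F)."""
    base = dict.fromkeys(COMPONENT_TYPES, max_copies)
    for combo in itertools.product(range(max_copies + 1), repeat=len(_F_TYPES)):
        counts = dict(base)
        counts.update(zip(_F_TYPES, combo))
        if any(counts[t] < op.sources.count(t) for t in set(op.sources)):
            continue
        if _F(_apply(counts, op)) - _F(counts) != -1:
            return False
    return True


def _is_extraction(op: OperationSignature) -> bool:
    """Membership in the generic cycle-extraction family K -> K' + C, where
    the remainder K' keeps K's type and may be empty (full circularization
    of a two-telomere same-genome path, or a cycle splitting in two)."""
    if len(op.sources) != 1:
        return False
    (k,) = op.sources
    if op.resultants == tuple(sorted((k, "C"))):
        return True
    return op.resultants == ("C",) and k in ("AoA", "BoB", "C")


GENERIC_EXTRACTION = OperationSignature(("K",), ("C", "K"), generic=True)


def safe_catalogue(max_copies: int = 4) -> set[OperationSignature]:
    """The distinct types of safe DCJ operations, found by enumeration.

    Candidate signatures come from the abstract DCJ move generator; a
    signature is safe when it decreases F by exactly 1 in every surrounding
    component multiset.  All members of the cycle-extraction family are
    collapsed into the single generic signature.
    """
    safe: set[OperationSignature] = set()
    for op in _enumerate_dcj_signatures():
        if not conserves_endpoints(op):  # sanity filter; generator conserves
            continue
        if not _is_safe(op, max_copies=max_copies):
            continue
        safe.add(GENERIC_EXTRACTION if _is_extraction(op) else op)
    return safe


# ---------------------------------------------------------------------------
# Reduced bridges and recombinations
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ReducedBridge:
    """A bridge abstracted to its unsaturated components: two piers and at
    most one odd pontoon between them."""

    piers: tuple[str, str]
    pontoon: str | None = None

    def components(self) -> tuple[str, ...]:
        if self.pontoon is None:
            return self.piers
        return (self.piers[0], self.pontoon, self.piers[1])


_PIER_LAVA = {"Aoa": "A", "Ba": "A", "Ab": "B", "Bob": "B"}


def reduced_bridge_types() -> set[ReducedBridge]:
    """Enumerate the reduced-bridge types.

    Consecutive components of a bridge are linked through singular markers,
    whose two extremities lie in one genome: neighbouring lava ends must
    share a genome.  Without an odd pontoon the two piers' lava genomes
    agree; with the odd pontoon ``P_ab`` in between, one pier attaches on
    its A-lava side and the other on its B-lava side.
    """
    bridges: set[ReducedBridge] = set()
    piers = sorted(_PIER_LAVA)
    for p1, p2 in itertools.combinations_with_replacement(piers, 2):
        if _PIER_LAVA[p1] == _PIER_LAVA[p2]:
            bridges.add(ReducedBridge(tuple(sorted((p1, p2)))))
        else:
            bridges.add(ReducedBridge(tuple(sorted((p1, p2))), "ab"))
    return bridges


#: The three safe operations that can recombine two bridges.
RECOMBINING_OPS = {
    OperationSignature(("Aoa", "Ba"), ("AB", "aoa")): "i",
    OperationSignature(("Ab", "Bob"), ("AB", "bob")): "ii",
    OperationSignature(("ab", "ab"), ("aoa", "bob")): "iii",
}

def _internally_sortable() -> set[ReducedBridge]:
    """Bridge types sortable entirely by internal safe operations: their
    pier pair is itself a safe operation's source pair (and no odd pontoon
    is left over)."""
    sortable = set()
    source_pairs = {op.sources for op in RECOMBINING_OPS if op.sources[0] != op.sources[1]}
    for br in reduced_bridge_types():
        if tuple(sorted(br.piers)) in source_pairs and br.pontoon is None:
            sortable.add(br)
    return sortable


def count_recombinations(op: OperationSignature) -> int:
    """Number of reduced-bridge pairings supplying an operation's sources.

    Bridges sortable by internal safe operations never take part.  For an
    operation with two distinct sources, any bridge containing the first
    may pair with any containing the second; for the odd-pontoon operation,
    two bridges of the same type or any unordered distinct pair qualify.
    """
    if op not in RECOMBINING_OPS:
        raise ValueError(f"{op} is not one of the recombination-enabling safe operations")
    usable = reduced_bridge_types() - _internally_sortable()
    s1, s2 = op.sources
    if s1 != s2:
        with_s1 = [br for br in usable if s1 in br.components()]
        with_s2 = [br for br in usable if s2 in br.components()]
        return len(with_s1) * len(with_s2)
    with_s = [br for br in usable if s1 in br.components()]
    k = len(with_s)
    return k + k * (k - 1) // 2
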