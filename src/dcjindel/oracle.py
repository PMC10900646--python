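"""Independent brute-force references for the restricted DCJ-indel distance.

Two oracles, both deliberately naive and only meant for toy instances:

* :func:`bfs_restricted_distance` — bidirectional breadth-first search over
  whole-genome states under DCJ operations and restricted indels (segments
  of unmatched markers only), with genomes canonicalized up to chromosome
  order, linear reversal and circular rotation/reversal.
* :func:`enumerate_maximal_matchings` / :func:`min_distance_by_enumeration`
  — exhaustive search over maximal matchings, scoring each with the
  component-census distance.

States label matched markers by their pair, and unmatched (singular)
markers by genome and family: a leftover marker of genome A can never be
equated with a singular marker of B, so sorting must delete all A-singular
content and insert all B-singular content.  Singular markers of the same
genome and family are interchangeable.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Iterable, Iterator

from .genomes import (
    FORWARD,
    FamilyAssignment,
    Genome,
    ResolvedMatching,
    canonical_circular,
    canonical_genome,
    canonical_linear,
    chromosomes_from_graph,
    chromosomes_to_graph,
)

#: A state is a sorted tuple of (circular, signed-label sequence) chromosomes.
State = tuple


class OracleUndecided(RuntimeError):
    """The BFS hit its state cap before deciding; the result is unknown."""


class MatchingExplosion(RuntimeError):
    """Too many maximal matchings to enumerate; carries the computed count."""

    def __init__(self, count: int, limit: int):
        super().__init__(f"{count} maximal matchings exceed the limit of {limit}")
        self.count = count


# ---------------------------------------------------------------------------
# State construction and canonicalization
# ---------------------------------------------------------------------------

def genome_state(g: Genome, match: ResolvedMatching, side: str) -> State:
    """Canonical labeled state of a genome under a matching.

    Matched occurrences are labeled by their pair; unmatched ones by
    ``("sa", family)`` or ``("sb", family)`` depending on the genome.
    """
    a_to_b = match.a_to_b()
    b_to_a = match.b_to_a()
    chroms = []
    for chrom in g.chromosomes:
        seq = []
        for m in chrom.markers:
            oid = m.occurrence_id
            if side == "A" and oid in a_to_b:
                lab = ("m", (oid, a_to_b[oid]))
            elif side == "B" and oid in b_to_a:
                lab = ("m", (b_to_a[oid], oid))
            else:
                lab = ("sa" if side == "A" else "sb", m.family)
            seq.append((lab, m.orientation))
        chroms.append((tuple(seq), chrom.circular))
    return canonical_genome(chroms)


def _canonicalize(chroms: Iterable[tuple[tuple, bool]]) -> State:
    return canonical_genome(chroms)


def _is_singular(label) -> bool:
    return label[0] in ("sa", "sb")


def _singular_counter(state: State) -> Counter:
    c: Counter = Counter()
    for seq, _ in state:
        for lab, _ in seq:
            if _is_singular(lab):
                c[lab] += 1
    return c


# ---------------------------------------------------------------------------
# Successor generation
# ---------------------------------------------------------------------------

def _materialize(state: State):
    return chromosomes_to_graph(state)


def _rebuild(labels, adjacencies) -> State:
    return _canonicalize(chromosomes_from_graph(labels, adjacencies))


def _dcj_successors(state: State) -> Iterator[State]:
    """All states one DCJ away: two-adjacency rejoins, adjacency+telomere
    moves, telomere joins, and single-adjacency fissions."""
    labels, adjacencies, telomeres = _materialize(state)
    adj_set = set(adjacencies)

    def emit(remove, add):
        new_adj = (adj_set - set(remove)) | set(add)
        yield _rebuild(labels, new_adj)

    for e1, e2 in itertools.combinations(adjacencies, 2):
        a, b = tuple(e1)
        c, d = tuple(e2)
        yield from emit([e1, e2], [frozenset((a, c)), frozenset((b, d))])
        yield from emit([e1, e2], [frozenset((a, d)), frozenset((b, c))])
    for e1 in adjacencies:
        a, b = tuple(e1)
        for s in telomeres:
            yield from emit([e1], [frozenset((a, s))])
            yield from emit([e1], [frozenset((b, s))])
        yield from emit([e1], [])  # fission ab -> a, b
    for s, t in itertools.combinations(telomeres, 2):
        yield from emit([], [frozenset((s, t))])


def _deletion_successors(state: State) -> Iterator[State]:
    """All states one restricted deletion away: remove any contiguous
    segment of singular markers (including a whole singular chromosome)."""
    for ci, (seq, circular) in enumerate(state):
        others = list(state[:ci] + state[ci + 1:])
        k = len(seq)
        sing = [_is_singular(lab) for lab, _ in seq]
        if all(sing):
            yield _canonicalize(others)  # whole chromosome in one indel
        if circular:
            if all(sing):
                windows = [
                    (i, ln) for i in range(k) for ln in range(1, k)
                ]
            else:
                windows = [
                    (i, ln)
                    for i in range(k)
                    for ln in range(1, k)
                    if all(sing[(i + j) % k] for j in range(ln))
                ]
            for i, ln in windows:
                keep = [seq[(i + ln + j) % k] for j in range(k - ln)]
                yield _canonicalize(others + [(tuple(keep), True)])
        else:
            for i in range(k):
                if not sing[i]:
                    continue
                for j in range(i, k):
                    if not sing[j]:
                        break
                    keep = seq[:i] + seq[j + 1:]
                    if keep:
                        yield _canonicalize(others + [(keep, False)])
                    # empty keep == whole-chromosome deletion, emitted above


def _segments_over(avail: Counter) -> Iterator[tuple]:
    """All signed sequences over a multiset of insertable labels."""
    items = list(avail.elements())
    seen = set()
    for ln in range(1, len(items) + 1):
        for perm in itertools.permutations(items, ln):
            for signs in itertools.product((1, -1), repeat=ln):
                seg = tuple(zip(perm, signs))
                if seg not in seen:
                    seen.add(seg)
                    yield seg


def _insertion_successors(state: State, budget: Counter) -> Iterator[State]:
    """All states one restricted insertion away.

    ``budget`` bounds how many markers of each singular label may still be
    inserted (the target's count minus the current state's).  A segment may
    arrive as a new linear or circular chromosome, be spliced into an
    adjacency, or extend a telomere — all covered by enumerating every gap
    position of every chromosome plus the two standalone placements.
    """
    avail = budget - _singular_counter(state)
    avail = +avail
    if not avail:
        return
    chroms = list(state)
    for seg in _segments_over(avail):
        yield _canonicalize(chroms + [(seg, False)])
        yield _canonicalize(chroms + [(seg, True)])
        for ci, (seq, circular) in enumerate(chroms):
            others = chroms[:ci] + chroms[ci + 1:]
            positions = range(len(seq)) if circular else range(len(seq) + 1)
            for p in positions:
                new_seq = seq[:p] + seg + seq[p:]
                yield _canonicalize(others + [(new_seq, circular)])


def _successors(state: State, budget: Counter) -> Iterator[State]:
    yield from _dcj_successors(state)
    yield from _deletion_successors(state)
    yield from _insertion_successors(state, budget)


# ---------------------------------------------------------------------------
# Bidirectional BFS
# ---------------------------------------------------------------------------

def bfs_restricted_distance(
    a: Genome,
    b: Genome,
    match: ResolvedMatching,
    max_states: int = 400_000,
) -> int:
    """Shortest restricted DCJ-indel scenario length between two genomes
    under a resolved matching, by bidirectional breadth-first search.

    Raises :class:`OracleUndecided` when the cap on explored states is hit,
    never returning a wrong number.  Both directions use the same move set
    (every DCJ and indel is invertible), with insertion budgets taken from
    the opposite endpoint's singular content.
    """
    start = genome_state(a, match, "A")
    goal = genome_state(b, match, "B")
    if start == goal:
        return 0

    budgets = {0: _singular_counter(goal), 1: _singular_counter(start)}
    dist = ({start: 0}, {goal: 0})
    frontier = ([start], [goal])
    depth = [0, 0]
    best = None

    while frontier[0] and frontier[1]:
        if best is not None and depth[0] + depth[1] + 1 >= best:
            return best
        side = 0 if len(frontier[0]) <= len(frontier[1]) else 1
        other = 1 - side
        new_frontier = []
        for state in frontier[side]:
            for succ in _successors(state, budgets[side]):
                if succ in dist[side]:
                    continue
                dist[side][succ] = depth[side] + 1
                new_frontier.append(succ)
                if succ in dist[other]:
                    cand = depth[side] + 1 + dist[other][succ]
                    if best is None or cand < best:
                        best = cand
            if len(dist[0]) + len(dist[1]) > max_states:
                raise OracleUndecided(
                    f"state cap {max_states} exceeded at depth "
                    f"{depth[0]}+{depth[1]}"
                )
        frontier[side][:] = new_frontier
        depth[side] += 1

    if best is not None:
        return best
    raise OracleUndecided("search space exhausted without meeting")


def canonical_case(a: Genome, b: Genome, match: ResolvedMatching) -> tuple:
    """Canonical signature of a (pair, matching) instance.

    Two instances with the same signature have the same restricted
    distance: the distance only depends on the arrangement of matched pairs
    and on which positions hold singular markers of which genome, not on
    singular family identities or occurrence ids.  Matched pairs are
    renumbered by first appearance and singular labels collapsed per
    genome.  Used to deduplicate exhaustive sweeps.
    """
    sa = genome_state(a, match, "A")
    sb = genome_state(b, match, "B")
    order: dict = {}
    for seq, _ in sa:
        for lab, _ in seq:
            if lab[0] == "m" and lab[1] not in order:
                order[lab[1]] = len(order)

    def relabel(state: State) -> State:
        out = []
        for seq, circ in state:
            out.append(
                (
                    tuple(
                        (("m", order[lab[1]]) if lab[0] == "m" else (lab[0],), sgn)
                        for lab, sgn in seq
                    ),
                    circ,
                )
            )
        return canonical_genome(out)

    return (relabel(sa), relabel(sb))


# ---------------------------------------------------------------------------
# Matching enumeration
# ---------------------------------------------------------------------------

def _family_matchings(
    in_a: tuple[int, ...], in_b: tuple[int, ...], maximal_only: bool
) -> list[tuple[tuple[int, int], ...]]:
    lo = min(len(in_a), len(in_b))
    sizes = [lo] if maximal_only else range(lo + 1)
    out = []
    for k in sizes:
        for sub_a in itertools.combinations(in_a, k):
            for sub_b in itertools.permutations(in_b, k):
                out.append(tuple(zip(sub_a, sub_b)))
    return out


def count_maximal_matchings(fams: FamilyAssignment) -> int:
    total = 1
    for in_a, in_b in fams.families.values():
        lo, hi = sorted((len(in_a), len(in_b)))
        ways = 1
        for i in range(lo):
            ways *= hi - i
        total *= ways
    return total


def enumerate_maximal_matchings(
    fams: FamilyAssignment, limit: int = 100_000
) -> Iterator[ResolvedMatching]:
    """All maximal matchings: min(|f_A|, |f_B|) pairs per family.

    Their number is the product over families of C(max, min) * min!; a
    :class:`MatchingExplosion` is raised when it exceeds ``limit``.
    """
    count = count_maximal_matchings(fams)
    if count > limit:
        raise MatchingExplosion(count, limit)
    per_family = [
        _family_matchings(in_a, in_b, maximal_only=True)
        for _, (in_a, in_b) in sorted(fams.families.items())
    ]
    for combo in itertools.product(*per_family):
        yield ResolvedMatching(frozenset(p for fam in combo for p in fam))


def enumerate_resolved_matchings(
    fams: FamilyAssignment, limit: int = 1_000_000
) -> Iterator[ResolvedMatching]:
    """All resolved matchings, maximal or not (every injective refinement)."""
    per_family = [
        _family_matchings(in_a, in_b, maximal_only=False)
        for _, (in_a, in_b) in sorted(fams.families.items())
    ]
    total = 1
    for opts in per_family:
        total *= len(opts)
    if total > limit:
        raise MatchingExplosion(total, limit)
    for combo in itertools.product(*per_family):
        yield ResolvedMatching(frozenset(p for fam in combo for p in fam))


def min_distance_by_enumeration(
    a: Genome, b: Genome, fams: FamilyAssignment, limit: int = 100_000
) -> int:
    """Minimum restricted DCJ-indel distance over all maximal matchings."""
    from .distance import resolved_distance

    best = None
    for match in enumerate_maximal_matchings(fams, limit=limit):
        d, _ = resolved_distance(a, b, match)
        if best is None or d < best:
            best = d
    if best is None:
        raise ValueError("no maximal matching enumerated")
    return best


# ---------------------------------------------------------------------------
# Exhaustive tiny-genome generation (test support)
# ---------------------------------------------------------------------------

def enumerate_small_genomes(
    max_markers: int,
    families: tuple[str, ...] = ("1", "2"),
    include_circular: bool = True,
) -> list[tuple[tuple[tuple[tuple[str, int], ...], bool], ...]]:
    """All genomes with up to ``max_markers`` markers over the given
    families, as chromosome-spec tuples, deduplicated up to chromosome
    order, linear reversal and circular rotation/reversal."""
    single: dict[int, list[tuple[tuple, bool]]] = {}
    for k in range(1, max_markers + 1):
        chroms = set()
        for fams_seq in itertools.product(families, repeat=k):
            for signs in itertools.product((1, -1), repeat=k):
                seq = tuple(zip(fams_seq, signs))
                chroms.add((canonical_linear(seq), False))
                if include_circular:
                    chroms.add((canonical_circular(seq), True))
        single[k] = sorted(chroms)

    genomes: set[tuple] = set()

    def partitions(total: int) -> Iterator[tuple[int, ...]]:
        if total == 0:
            yield ()
            return
        for first in range(1, total + 1):
            for rest in partitions(total - first):
                if not rest or first <= rest[0]:
                    yield (first, *rest)

    for total in range(1, max_markers + 1):
        for part in partitions(total):
            pools = [single[k] for k in part]
            for combo in itertools.product(*pools):
                genomes.add(tuple(sorted(combo)))
    return sorted(genomes)
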