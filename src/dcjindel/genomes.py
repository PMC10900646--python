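"""Genome data model and UniMoG text I/O.

A genome is a set of linear and circular chromosomes over oriented
*markers* (genes).  Each marker occurrence carries a *family* label; shared
family labels across a genome pair define the homology.  Marker ends are
called *extremities*: every occurrence has a tail ``t`` (its beginning) and
a head ``h`` (its end).  Neighbouring extremities on a chromosome form
*adjacencies*; the free ends of linear chromosomes are *telomeres*.

The text format is the UniMoG dialect: ``>name`` headers introduce genomes,
chromosomes are whitespace-separated runs of signed family tokens terminated
by ``|`` (linear) or ``)`` (circular).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

FORWARD = 1
REVERSE = -1

#: Extremity kinds.
TAIL = "t"
HEAD = "h"

#: An extremity is a pair (occurrence_id, "t" | "h").
Extremity = tuple[int, str]


class UnimogParseError(ValueError):
    """Raised on malformed UniMoG input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class MarkerOccurrence:
    """One occurrence of a marker family in a genome.

    ``occurrence_id`` is unique across the genome *pair* so that extremities
    of both genomes live in one id space.
    """

    occurrence_id: int
    family: str
    genome: str  # "A" or "B"
    orientation: int  # FORWARD or REVERSE

    @property
    def tail(self) -> Extremity:
        return (self.occurrence_id, TAIL)

    @property
    def head(self) -> Extremity:
        return (self.occurrence_id, HEAD)

    @property
    def left(self) -> Extremity:
        """Extremity facing the previous marker on the chromosome."""
        return self.tail if self.orientation == FORWARD else self.head

    @property
    def right(self) -> Extremity:
        """Extremity facing the next marker on the chromosome."""
        return self.head if self.orientation == FORWARD else self.tail


@dataclass(frozen=True)
class Chromosome:
    markers: tuple[MarkerOccurrence, ...]
    circular: bool = False

    def __post_init__(self):
        if not self.markers:
            raise ValueError("empty chromosomes are not allowed")

    def signed_families(self) -> tuple[tuple[str, int], ...]:
        return tuple((m.family, m.orientation) for m in self.markers)


@dataclass(frozen=True)
class Genome:
    name: str
    chromosomes: tuple[Chromosome, ...] = ()

    def occurrences(self) -> Iterator[MarkerOccurrence]:
        for chrom in self.chromosomes:
            yield from chrom.markers

    @property
    def n_markers(self) -> int:
        return sum(len(c.markers) for c in self.chromosomes)


# ---------------------------------------------------------------------------
# UniMoG parsing and writing
# ---------------------------------------------------------------------------

def parse_unimog(text: str) -> list[Genome]:
    """Parse UniMoG text into a list of genomes.

    Occurrence ids are assigned deterministically in reading order, starting
    at 1, across *all* genomes in the file.  The first genome is tagged
    ``A``, the second ``B``; further genomes are tagged by their index.
    A leading ``-`` on a token denotes reverse orientation.
    """
    raw: list[tuple[str, list[tuple[list[tuple[str, int]], bool]]]] = []
    current: list[tuple[list[tuple[str, int]], bool]] | None = None
    pending: list[tuple[str, int]] = []
    pending_line = 0
    saw_header = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if pending:
                raise UnimogParseError(
                    "chromosome not terminated by '|' or ')'", pending_line
                )
            name = stripped[1:].strip()
            if not name:
                raise UnimogParseError("header with empty genome name", lineno)
            current = []
            raw.append((name, current))
            saw_header = True
            continue
        if current is None:
            raise UnimogParseError("chromosome data before first '>' header", lineno)
        for tok in stripped.split():
            if tok in ("|", ")"):
                if not pending:
                    raise UnimogParseError("empty chromosome", lineno)
                current.append((pending, tok == ")"))
                pending = []
            else:
                fam, orient = tok, FORWARD
                if tok.startswith("-"):
                    fam, orient = tok[1:], REVERSE
                if not fam:
                    raise UnimogParseError(f"malformed token {tok!r}", lineno)
                if not pending:
                    pending_line = lineno
                pending.append((fam, orient))
    if pending:
        raise UnimogParseError(
            "chromosome not terminated by '|' or ')'", pending_line
        )
    if not saw_header:
        raise UnimogParseError("no '>' header found", 1)

    genomes: list[Genome] = []
    next_id = 1
    for idx, (name, chrom_specs) in enumerate(raw):
        tag = "A" if idx == 0 else "B" if idx == 1 else str(idx)
        chroms = []
        for tokens, circular in chrom_specs:
            markers = []
            for fam, orient in tokens:
                markers.append(MarkerOccurrence(next_id, fam, tag, orient))
                next_id += 1
            chroms.append(Chromosome(tuple(markers), circular))
        genomes.append(Genome(name, tuple(chroms)))
    return genomes


def write_unimog(genomes: Iterable[Genome]) -> str:
    """Serialize genomes to canonical UniMoG text (one chromosome per line)."""
    lines = []
    for g in genomes:
        lines.append(f">{g.name}")
        for chrom in g.chromosomes:
            toks = [
                (f"-{m.family}" if m.orientation == REVERSE else m.family)
                for m in chrom.markers
            ]
            toks.append(")" if chrom.circular else "|")
            lines.append(" ".join(toks))
    return "\n".join(lines) + "\n"


def genome_from_spec(
    name: str,
    chromosomes: Iterable[tuple[Iterable[tuple[str, int]], bool]],
    tag: str = "A",
    start_id: int = 1,
) -> Genome:
    """Build a genome from ``[(signed-family list, circular), ...]`` specs.

    Convenience constructor for tests, the simulator and the oracle; ids are
    assigned consecutively from ``start_id``.
    """
    next_id = start_id
    chroms = []
    for tokens, circular in chromosomes:
        markers = []
        for fam, orient in tokens:
            markers.append(MarkerOccurrence(next_id, str(fam), tag, orient))
            next_id += 1
        chroms.append(Chromosome(tuple(markers), circular))
    return Genome(name, tuple(chroms))


def reindex_pair(a: Genome, b: Genome) -> tuple[Genome, Genome]:
    """Reassign occurrence ids over a pair: genome A first, then B, from 1.

    Guarantees the pair-wide uniqueness invariant for programmatically
    constructed genomes and makes downstream vertex orderings deterministic.
    """
    next_id = 1
    out = []
    for g, tag in ((a, "A"), (b, "B")):
        chroms = []
        for chrom in g.chromosomes:
            markers = []
            for m in chrom.markers:
                markers.append(replace(m, occurrence_id=next_id, genome=tag))
                next_id += 1
            chroms.append(Chromosome(tuple(markers), chrom.circular))
        out.append(Genome(g.name, tuple(chroms)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Adjacencies and telomeres
# ---------------------------------------------------------------------------

def genome_adjacencies(
    g: Genome,
) -> tuple[set[frozenset[Extremity]], set[Extremity]]:
    """Derive the adjacency set and telomere set of a genome.

    Consecutive markers contribute the adjacency between the right extremity
    of the left marker and the left extremity of the right marker.  Circular
    chromosomes wrap around; the two outer extremities of a linear
    chromosome are telomeres.  A single-marker circular chromosome yields
    the self-adjacency between its own head and tail.
    """
    adjacencies: set[frozenset[Extremity]] = set()
    telomeres: set[Extremity] = set()
    for chrom in g.chromosomes:
        ms = chrom.markers
        for left, right in zip(ms, ms[1:]):
            adjacencies.add(frozenset((left.right, right.left)))
        if chrom.circular:
            adjacencies.add(frozenset((ms[-1].right, ms[0].left)))
        else:
            telomeres.add(ms[0].left)
            telomeres.add(ms[-1].right)
    return adjacencies, telomeres


# ---------------------------------------------------------------------------
# Homology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyAssignment:
    """Partition of occurrences into families, keyed by family label.

    ``families`` maps each label to the occurrence-id tuples in genome A and
    genome B (reading order).  Head extremities are equivalent to heads and
    tails to tails within a family; no head is ever equivalent to a tail.
    """

    families: Mapping[str, tuple[tuple[int, ...], tuple[int, ...]]]

    def singular_families(self) -> set[str]:
        """Families with occurrences in only one genome."""
        return {
            f for f, (in_a, in_b) in self.families.items() if not in_a or not in_b
        }

    def ambiguous_families(self) -> set[str]:
        """Families with more than one occurrence in some genome."""
        return {
            f
            for f, (in_a, in_b) in self.families.items()
            if len(in_a) > 1 or len(in_b) > 1
        }

    def is_resolved(self) -> bool:
        return not self.ambiguous_families()


def derive_families(a: Genome, b: Genome) -> FamilyAssignment:
    fams: dict[str, tuple[list[int], list[int]]] = {}
    for side, g in ((0, a), (1, b)):
        for occ in g.occurrences():
            fams.setdefault(occ.family, ([], []))[side].append(occ.occurrence_id)
    return FamilyAssignment(
        {f: (tuple(xs), tuple(ys)) for f, (xs, ys) in fams.items()}
    )


@dataclass(frozen=True)
class ResolvedMatching:
    """Injective pairing of occurrences (A id, B id) refining a homology."""

    pairs: frozenset[tuple[int, int]]

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[int, int]:
        return {x: y for x, y in self.pairs}

    def b_to_a(self) -> dict[int, int]:
        return {y: x for x, y in self.pairs}

    def matched_a(self) -> set[int]:
        return {x for x, _ in self.pairs}

    def matched_b(self) -> set[int]:
        return {y for _, y in self.pairs}

    def reversed(self) -> "ResolvedMatching":
        """The same matching with the roles of the genomes swapped."""
        return ResolvedMatching(frozenset((y, x) for x, y in self.pairs))


def validate_matching(
    fams: FamilyAssignment, match: ResolvedMatching
) -> None:
    """Check injectivity and family-refinement; raise ``ValueError`` if broken."""
    fam_of: dict[int, str] = {}
    side_a: set[int] = set()
    side_b: set[int] = set()
    for f, (in_a, in_b) in fams.families.items():
        for i in in_a:
            fam_of[i] = f
            side_a.add(i)
        for i in in_b:
            fam_of[i] = f
            side_b.add(i)
    seen_a: set[int] = set()
    seen_b: set[int] = set()
    for x, y in match.pairs:
        if x not in side_a or y not in side_b:
            raise ValueError(f"pair ({x},{y}) does not map genome A to genome B")
        if fam_of[x] != fam_of[y]:
            raise ValueError(
                f"pair ({x},{y}) crosses families {fam_of[x]!r} and {fam_of[y]!r}"
            )
        if x in seen_a or y in seen_b:
            raise ValueError(f"occurrence matched twice in pair ({x},{y})")
        seen_a.add(x)
        seen_b.add(y)


def is_maximal(fams: FamilyAssignment, match: ResolvedMatching) -> bool:
    """True iff every family has min(|f_A|, |f_B|) matched pairs."""
    per_family: dict[str, int] = {}
    fam_of = {
        i: f
        for f, (in_a, in_b) in fams.families.items()
        for i in (*in_a, *in_b)
    }
    for x, _ in match.pairs:
        per_family[fam_of[x]] = per_family.get(fam_of[x], 0) + 1
    for f, (in_a, in_b) in fams.families.items():
        if per_family.get(f, 0) != min(len(in_a), len(in_b)):
            return False
    return True


def identity_matching(a: Genome, b: Genome) -> ResolvedMatching:
    """The unique maximal matching of a pair with a resolved homology.

    Raises ``ValueError`` on ambiguous families (more than one occurrence of
    a family in a genome), for which no canonical matching exists.
    """
    fams = derive_families(a, b)
    if not fams.is_resolved():
        raise ValueError(
            f"homology is not resolved; ambiguous families: "
            f"{sorted(fams.ambiguous_families())}"
        )
    pairs = {
        (in_a[0], in_b[0])
        for in_a, in_b in fams.families.values()
        if in_a and in_b
    }
    return ResolvedMatching(frozenset(pairs))


# ---------------------------------------------------------------------------
# Generic chromosome <-> adjacency-graph conversion
# ---------------------------------------------------------------------------
#
# These helpers work on bare chromosome specs ``(sequence, circular)`` where
# the sequence holds ``(label, sign)`` pairs with arbitrary hashable labels.
# They back both the brute-force oracle (canonical sorting states) and the
# evolution simulator (DCJ surgery), which rearrange genomes far more often
# than they need the full data model.

def chromosomes_to_graph(
    chroms: Iterable[tuple[tuple, bool]]
):
    """Explode chromosome specs into marker instances, adjacencies and
    telomeres.  Instances are indexed 0..k-1 in input order; extremities
    are ``(index, "t"|"h")``."""
    labels = []
    adjacencies = []
    telomeres = []
    idx = 0
    for seq, circular in chroms:
        chrom_start = None
        prev_right = None
        for lab, sgn in seq:
            labels.append((lab, sgn))
            left = (idx, TAIL) if sgn == FORWARD else (idx, HEAD)
            right = (idx, HEAD) if sgn == FORWARD else (idx, TAIL)
            if prev_right is not None:
                adjacencies.append(frozenset((prev_right, left)))
            else:
                chrom_start = left
            prev_right = right
            idx += 1
        if circular:
            adjacencies.append(frozenset((prev_right, chrom_start)))
        else:
            telomeres.append(chrom_start)
            telomeres.append(prev_right)
    return labels, adjacencies, telomeres


def chromosomes_from_graph(labels, adjacencies) -> list[tuple[tuple, bool]]:
    """Reassemble chromosome specs from instances and an adjacency matching.

    Linear chromosomes are walked from a free extremity, remaining
    instances belong to circular chromosomes.
    """
    nbr = {}
    for e in adjacencies:
        u, v = tuple(e)
        nbr[u] = v
        nbr[v] = u

    def other(ext):
        i, k = ext
        return (i, HEAD if k == TAIL else TAIL)

    seen = set()
    chroms = []
    for i in range(len(labels)):
        for kind in (TAIL, HEAD):
            start = (i, kind)
            if start in nbr or i in seen:
                continue
            seq = []
            ext = start
            while True:
                inst = ext[0]
                seen.add(inst)
                sgn = FORWARD if ext[1] == TAIL else REVERSE
                seq.append((labels[inst][0], sgn))
                out = other(ext)
                if out not in nbr:
                    break
                ext = nbr[out]
            chroms.append((tuple(seq), False))
            break
    for i in range(len(labels)):
        if i in seen:
            continue
        seq = []
        ext = (i, TAIL)
        while ext[0] not in seen:
            inst = ext[0]
            seen.add(inst)
            sgn = FORWARD if ext[1] == TAIL else REVERSE
            seq.append((labels[inst][0], sgn))
            ext = nbr[other(ext)]
        chroms.append((tuple(seq), True))
    return chroms


# ---------------------------------------------------------------------------
# Chromosome / genome canonicalization (used for equality and by the oracle)
# ---------------------------------------------------------------------------

def canonical_linear(seq: tuple) -> tuple:
    """Canonical form of a linear chromosome: minimum of the sequence and its
    reverse complement (reversal flips order and signs)."""
    rev = tuple((lab, -sign) for lab, sign in reversed(seq))
    return min(seq, rev)


def canonical_circular(seq: tuple) -> tuple:
    """Canonical form of a circular chromosome: minimum over all rotations of
    the sequence and of its reverse complement."""
    rev = tuple((lab, -sign) for lab, sign in reversed(seq))
    best = None
    for s in (seq, rev):
        for i in range(len(s)):
            rot = s[i:] + s[:i]
            if best is None or rot < best:
                best = rot
    return best


def canonical_genome(
    chromosomes: Iterable[tuple[tuple, bool]]
) -> tuple:
    """Canonical form of a genome given ``(signed-label sequence, circular)``
    chromosomes: the sorted tuple of canonicalized chromosomes."""
    canon = []
    for seq, circular in chromosomes:
        if circular:
            canon.append((canonical_circular(seq), True))
        else:
            canon.append((canonical_linear(seq), False))
    return tuple(sorted(canon))
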