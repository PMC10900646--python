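"""Genome-pair evolution simulator.

Two genomes are evolved independently from a common root under
rate-weighted DCJ, insertion, deletion and (segmental) duplication
operations.  The DCJ rate is fixed at 1 and the other rates are relative
to it, so with a total operation budget ``N`` each type is applied
``N * rate / (1 + sum(rates))`` times in expectation.  Indel and
duplication segment lengths follow Zipf (power-law) distributions, a
standard model for the heavy-tailed length spectra of real indels and
segmental duplications.

Markers carry their ancestry: the original descendant of each root marker
is tracked through both lineages, yielding a ground-truth matching on the
emitted pair.  Duplicated copies keep their family (creating ambiguous
families) but are not anchored; inserted markers found fresh families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomes import (
    FORWARD,
    Chromosome,
    Genome,
    MarkerOccurrence,
    ResolvedMatching,
    chromosomes_from_graph,
    chromosomes_to_graph,
)

OP_TYPES = ("dcj", "insertion", "deletion", "duplication")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulation run.

    ``rates`` are relative to a DCJ rate of 1; ``zipf_indel`` and
    ``zipf_dup`` are the Zipf shape parameters for indel and duplication
    segment lengths (defaults 4 and 6: indels are mostly short,
    duplications even shorter).
    """

    n_markers: int = 100
    n_chromosomes: int = 1
    n_ops: int = 50
    insertion_rate: float = 0.1
    deletion_rate: float = 0.2
    duplication_rate: float = 0.4
    zipf_indel: float = 4.0
    zipf_dup: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if min(self.insertion_rate, self.deletion_rate, self.duplication_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.zipf_indel <= 1 or self.zipf_dup <= 1:
            raise ValueError("Zipf shapes must exceed 1")
        if not 1 <= self.n_chromosomes <= self.n_markers:
            raise ValueError("need n_markers >= n_chromosomes >= 1")

    @property
    def rates(self) -> dict[str, float]:
        return {
            "dcj": 1.0,
            "insertion": self.insertion_rate,
            "deletion": self.deletion_rate,
            "duplication": self.duplication_rate,
        }


@dataclass
class EvolvedPair:
    """A simulated genome pair with its ground truth.

    ``matching`` pairs the occurrence ids of original descendants of the
    same root marker that survive in both lineages — a valid resolved
    matching of the pair.
    """

    genome_a: Genome
    genome_b: Genome
    matching: ResolvedMatching
    op_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def expected_op_counts(n_ops: int, rates: dict[str, float]) -> dict[str, float]:
    """Expected number of operations per type: ``n_ops * rate / (1 + sum)``
    with the DCJ rate fixed at 1.  ``rates`` maps any of "insertion",
    "deletion", "duplication" to a non-negative relative rate."""
    extra = {t: float(rates.get(t, 0.0)) for t in OP_TYPES[1:]}
    if min(extra.values(), default=0.0) < 0:
        raise ValueError("rates must be non-negative")
    total = 1.0 + sum(extra.values())
    out = {"dcj": n_ops / total}
    out.update({t: n_ops * r / total for t, r in extra.items()})
    return out


def sample_zipf(
    shape: float,
    seed: int | None = None,
    size: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Draw from the Zipf distribution P(k) proportional to k^(-shape), k >= 1."""
    if shape <= 1:
        raise ValueError("Zipf shape must exceed 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    draw = rng.zipf(shape, size=size)
    return draw if size is not None else int(draw)


def make_root(n_markers: int, n_chromosomes: int, seed: int = 0) -> Genome:
    """Root genome: distinct families 1..n_markers, all forward, spread as
    evenly as possible over linear chromosomes.  Deterministic (the seed is
    accepted for interface symmetry; the layout does not use it)."""
    if n_chromosomes > n_markers:
        raise ValueError("more chromosomes than markers")
    base, extra = divmod(n_markers, n_chromosomes)
    chroms = []
    nxt = 1
    for i in range(n_chromosomes):
        size = base + (1 if i < extra else 0)
        markers = tuple(
            MarkerOccurrence(nxt + j, str(nxt + j), "A", FORWARD)
            for j in range(size)
        )
        nxt += size
        chroms.append(Chromosome(markers, circular=False))
    return Genome("root", tuple(chroms))


# ---------------------------------------------------------------------------
# Lineage evolution
# ---------------------------------------------------------------------------
#
# Internally a lineage is a list of chromosome specs (sequence, circular)
# whose labels are (uid, family, anchor): uid is unique within the lineage,
# anchor is the root marker id for original descendants and None for
# duplicated or inserted markers.


class _Lineage:
    def __init__(self, root: Genome, rng: np.random.Generator, fresh_family_start: int):
        self.rng = rng
        self.chroms: list[tuple[tuple, bool]] = [
            (
                tuple(
                    ((m.occurrence_id, m.family, m.occurrence_id), m.orientation)
                    for m in chrom.markers
                ),
                chrom.circular,
            )
            for chrom in root.chromosomes
        ]
        self.next_uid = root.n_markers + 1
        self.next_family = fresh_family_start

    # -- site bookkeeping ----------------------------------------------

    def _graph(self):
        return chromosomes_to_graph(self.chroms)

    @property
    def n_markers(self) -> int:
        return sum(len(seq) for seq, _ in self.chroms)

    # -- operations ------------------------------------------------------

    def dcj(self) -> None:
        """One DCJ, uniform over all distinct concrete operations: the two
        rejoins of every adjacency pair, the two variants of every
        adjacency/telomere combination, every telomere join and every
        adjacency fission."""
        labels, adjacencies, telomeres = self._graph()
        na, nt = len(adjacencies), len(telomeres)
        w_pair = na * (na - 1)  # C(na,2) * 2 variants
        w_adj_tel = na * nt * 2
        w_tel = nt * (nt - 1) // 2
        w_fission = na
        total = w_pair + w_adj_tel + w_tel + w_fission
        if total == 0:
            return  # single circular one-marker genome has one adjacency; total>0
        pick = int(self.rng.integers(total))
        adj_set = set(adjacencies)
        if pick < w_pair:
            i, j = self.rng.choice(na, size=2, replace=False)
            e1, e2 = adjacencies[int(i)], adjacencies[int(j)]
            a, b = tuple(e1)
            c, d = tuple(e2)
            if self.rng.integers(2):
                new = [frozenset((a, c)), frozenset((b, d))]
            else:
                new = [frozenset((a, d)), frozenset((b, c))]
            adj_set -= {e1, e2}
            adj_set |= set(new)
        elif pick < w_pair + w_adj_tel:
            e1 = adjacencies[int(self.rng.integers(na))]
            s = telomeres[int(self.rng.integers(nt))]
            a, b = tuple(e1)
            keep = a if self.rng.integers(2) else b
            adj_set.discard(e1)
            adj_set.add(frozenset((keep, s)))
        elif pick < w_pair + w_adj_tel + w_tel:
            i, j = self.rng.choice(nt, size=2, replace=False)
            adj_set.add(frozenset((telomeres[int(i)], telomeres[int(j)])))
        else:
            adj_set.discard(adjacencies[int(self.rng.integers(na))])
        self.chroms = chromosomes_from_graph(labels, adj_set)

    def _random_segment(self, shape: float) -> tuple[int, int, int] | None:
        """Pick a uniform start marker and a Zipf length, capped at the
        markers available downstream (whole chromosome for circular)."""
        total = self.n_markers
        if total == 0:
            return None
        flat = int(self.rng.integers(total))
        for ci, (seq, circular) in enumerate(self.chroms):
            if flat < len(seq):
                k = int(self.rng.zipf(shape))
                cap = len(seq) if circular else len(seq) - flat
                return ci, flat, min(k, cap)
            flat -= len(seq)
        raise AssertionError("unreachable")

    def deletion(self, shape: float) -> bool:
        """Delete a random segment; refuse (return False) if the genome
        would be emptied, so the caller can resample."""
        seg = self._random_segment(shape)
        if seg is None:
            return False
        ci, start, k = seg
        seq, circular = self.chroms[ci]
        if k >= len(seq):
            if len(self.chroms) == 1:
                return False
            del self.chroms[ci]
            return True
        if circular:
            keep = tuple(seq[(start + k + j) % len(seq)] for j in range(len(seq) - k))
            self.chroms[ci] = (keep, True)
        else:
            self.chroms[ci] = (seq[:start] + seq[start + k:], False)
        return True

    def _insertion_sites(self):
        """(kind, position) insertion sites: one per adjacency (splice), one
        per telomere (extend), plus a fresh circular chromosome."""
        sites = [("circular", None)]
        for ci, (seq, circular) in enumerate(self.chroms):
            if circular:
                for p in range(len(seq)):
                    sites.append(("gap", (ci, p)))
            else:
                for p in range(len(seq) + 1):
                    sites.append(("gap", (ci, p)))
        return sites

    def _place(self, segment: tuple) -> None:
        sites = self._insertion_sites()
        kind, pos = sites[int(self.rng.integers(len(sites)))]
        if kind == "circular":
            self.chroms.append((segment, True))
        else:
            ci, p = pos
            seq, circular = self.chroms[ci]
            self.chroms[ci] = (seq[:p] + segment + seq[p:], circular)

    def insertion(self, shape: float) -> None:
        k = int(self.rng.zipf(shape))
        segment = []
        for _ in range(k):
            lab = (self.next_uid, str(self.next_family), None)
            self.next_uid += 1
            self.next_family += 1
            segment.append((lab, 1 if self.rng.integers(2) else -1))
        self._place(tuple(segment))

    def duplication(self, shape: float) -> None:
        seg = self._random_segment(shape)
        if seg is None:
            return
        ci, start, k = seg
        seq, circular = self.chroms[ci]
        copied = []
        for j in range(k):
            (uid, fam, _anchor), sgn = seq[(start + j) % len(seq)]
            copied.append(((self.next_uid, fam, None), sgn))
            self.next_uid += 1
        self._place(tuple(copied))


def _to_genome(
    lineage: _Lineage, name: str, tag: str, start_id: int
) -> tuple[Genome, dict[int, int]]:
    """Convert a lineage to a Genome; returns the anchor -> occurrence map."""
    anchor_to_occ: dict[int, int] = {}
    nxt = start_id
    chroms = []
    for seq, circular in lineage.chroms:
        markers = []
        for (uid, fam, anchor), sgn in seq:
            markers.append(MarkerOccurrence(nxt, fam, tag, sgn))
            if anchor is not None:
                anchor_to_occ[anchor] = nxt
            nxt += 1
        chroms.append(Chromosome(tuple(markers), circular))
    return Genome(name, tuple(chroms)), anchor_to_occ


def evolve_pair(root: Genome, cfg: SimulationConfig) -> EvolvedPair:
    """Evolve two lineages from a common root and emit the pair.

    The operation budget is split evenly between the lineages; each
    operation's type is drawn from the rate-induced multinomial.  A single
    PRNG stream, consumed in a fixed order (lineage A fully, then B), makes
    a run bit-for-bit reproducible from the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    rates = cfg.rates
    total_rate = sum(rates.values())
    probs = np.array([rates[t] / total_rate for t in OP_TYPES])

    budgets = (cfg.n_ops // 2, cfg.n_ops - cfg.n_ops // 2)
    lineages = []
    op_counts: dict[str, dict[str, int]] = {}
    fresh_start = root.n_markers + 1
    for side, budget in zip(("A", "B"), budgets):
        lin = _Lineage(root, rng, fresh_family_start=fresh_start)
        counts = dict.fromkeys(OP_TYPES, 0)
        done = 0
        while done < budget:
            op = OP_TYPES[int(rng.choice(len(OP_TYPES), p=probs))]
            if op == "dcj":
                lin.dcj()
            elif op == "insertion":
                lin.insertion(cfg.zipf_indel)
            elif op == "deletion":
                if not lin.deletion(cfg.zipf_indel):
                    continue  # would empty the genome; resample
            else:
                lin.duplication(cfg.zipf_dup)
            counts[op] += 1
            done += 1
        fresh_start = lin.next_family  # keep inserted families disjoint
        lineages.append(lin)
        op_counts[side] = counts

    genome_a, anchors_a = _to_genome(lineages[0], "A", "A", 1)
    genome_b, anchors_b = _to_genome(
        lineages[1], "B", "B", genome_a.n_markers + 1
    )
    pairs = frozenset(
        (anchors_a[r], anchors_b[r]) for r in anchors_a.keys() & anchors_b.keys()
    )
    return EvolvedPair(
        genome_a=genome_a,
        genome_b=genome_b,
        matching=ResolvedMatching(pairs),
        op_counts=op_counts,
    )
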