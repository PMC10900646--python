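"""Shared fixtures: seeded random genome generators."""

from __future__ import annotations

import random

import pytest

from dcjindel.genomes import genome_from_spec, reindex_pair


def random_genome_spec(rng: random.Random, max_markers=6, n_families=4, max_mult=3):
    """Chromosome specs for a random genome with bounded family multiplicity."""
    n = rng.randint(1, max_markers)
    counts: dict[str, int] = {}
    toks = []
    for _ in range(n):
        f = str(rng.randint(1, n_families))
        if counts.get(f, 0) >= max_mult:
            continue
        counts[f] = counts.get(f, 0) + 1
        toks.append((f, rng.choice((1, -1))))
    if not toks:
        toks = [("1", 1)]
    k = rng.randint(1, min(3, len(toks)))
    cuts = sorted(rng.sample(range(1, len(toks)), k - 1)) if k > 1 else []
    chroms, prev = [], 0
    for c in cuts + [len(toks)]:
        chroms.append((tuple(toks[prev:c]), rng.random() < 0.3))
        prev = c
    return chroms


def random_natural_pair(rng: random.Random, **kw):
    a = genome_from_spec("A", random_genome_spec(rng, **kw))
    b = genome_from_spec("B", random_genome_spec(rng, **kw))
    return reindex_pair(a, b)


def random_resolved_pair(rng: random.Random, max_markers=6):
    """A pair whose homology is resolved: a permuted, re-oriented subset of
    shared families plus private singular families on each side."""
    n = rng.randint(1, max_markers)
    fa = [(str(i + 1), rng.choice((1, -1))) for i in range(n)]
    fb = [(str(i + 1), rng.choice((1, -1))) for i in range(n)]
    rng.shuffle(fb)
    # private singular markers, one fresh family each
    for side, toks in (("a", fa), ("b", fb)):
        for j in range(rng.randint(0, 2)):
            toks.insert(
                rng.randint(0, len(toks)), (f"{side}{j}", rng.choice((1, -1)))
            )

    def split(toks):
        k = rng.randint(1, min(2, len(toks)))
        cuts = sorted(rng.sample(range(1, len(toks)), k - 1)) if k > 1 else []
        chroms, prev = [], 0
        for c in cuts + [len(toks)]:
            chroms.append((tuple(toks[prev:c]), rng.random() < 0.3))
            prev = c
        return chroms

    a = genome_from_spec("A", split(fa))
    b = genome_from_spec("B", split(fb))
    return reindex_pair(a, b)


@pytest.fixture
def rng():
    return random.Random(20260101)
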