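"""MRD construction, augmentation, decompositions and the component census."""

import pytest

from dcjindel.genomes import (
    ResolvedMatching,
    derive_families,
    identity_matching,
    parse_unimog,
)
from dcjindel.mrd import (
    augment,
    build_mrd,
    classify_components,
    decomposition_from_matching,
    detect_circular_singletons,
)
from conftest import random_natural_pair
from dcjindel.oracle import enumerate_maximal_matchings


def make(text):
    a, b = parse_unimog(text)
    return a, b, derive_families(a, b)


class TestBuild:
    def test_single_shared_marker(self):
        a, b, fams = make(">A\n1 |\n>B\n1 |")
        m = build_mrd(a, b, fams)
        assert len(m.occ_info) * 2 == 4
        assert m.adjacency_edges == []
        assert len(m.extremity_edges) == 2

    def test_duplicate_family_cross_product(self):
        a, b, fams = make(">A\n1 1 |\n>B\n1 |")
        m = build_mrd(a, b, fams)
        assert len(m.extremity_edges) == 4  # 2 * |f_A| * |f_B|
        kinds = sorted(e.kind for e in m.extremity_edges)
        assert kinds == ["h", "h", "t", "t"]

    def test_singular_family_contributes_no_edges(self):
        a, b, fams = make(">A\n1 2 |\n>B\n1 |")
        m = build_mrd(a, b, fams)
        assert len(m.extremity_edges) == 2

    def test_edge_count_formula(self, rng):
        for _ in range(20):
            a, b = random_natural_pair(rng)
            fams = derive_families(a, b)
            m = build_mrd(a, b, fams)
            expected = sum(
                2 * len(in_a) * len(in_b) for in_a, in_b in fams.families.values()
            )
            assert len(m.extremity_edges) == expected


class TestAugment:
    def test_linear_pair_gets_caps_and_indel_edges(self):
        a, b, fams = make(">A\n1 |\n>B\n1 |")
        m = augment(build_mrd(a, b, fams))
        assert len(m.caps_a) == 2 and len(m.caps_b) == 2
        assert sum(1 for e in m.adjacency_edges if any(v[0] == "cap" for v in e)) == 4
        assert len(m.indel_edges) == 2  # one per marker, both genomes

    def test_fully_circular_pair_has_no_caps(self):
        a, b, fams = make(">A\n1 )\n>B\n1 )")
        m = augment(build_mrd(a, b, fams))
        assert m.caps_a == [] and m.caps_b == []

    def test_ix_orders_caps_before_extremities(self, rng):
        for _ in range(10):
            a, b = random_natural_pair(rng)
            m = augment(build_mrd(a, b, derive_families(a, b)))
            ix = m.ix
            caps_a = [ix[v] for v in m.caps_a]
            caps_b = [ix[v] for v in m.caps_b]
            others = [ix[v] for v in m.vertices() if not m.is_cap(v)]
            assert sorted(ix.values()) == list(range(1, len(ix) + 1))
            if caps_a and caps_b:
                assert max(caps_a) < min(caps_b)
            if caps_b and others:
                assert max(caps_b) < min(others)

    def test_double_augmentation_rejected(self):
        a, b, fams = make(">A\n1 |\n>B\n1 |")
        m = augment(build_mrd(a, b, fams))
        with pytest.raises(ValueError):
            augment(m)


class TestDecomposition:
    def test_identity_selects_all_extremity_edges(self):
        a, b, fams = make(">A\n1 |\n>B\n1 |")
        m = augment(build_mrd(a, b, fams))
        d = decomposition_from_matching(m, identity_matching(a, b))
        assert d.pairs == frozenset({(1, 2)})
        assert d.indel_occurrences == frozenset()

    def test_empty_matching_selects_all_indel_edges(self):
        a, b, fams = make(">A\n1 |\n>B\n1 |")
        m = augment(build_mrd(a, b, fams))
        d = decomposition_from_matching(m, ResolvedMatching(frozenset()))
        assert d.pairs == frozenset()
        assert d.indel_occurrences == frozenset({1, 2})

    def test_partial_matching_on_duplicates(self):
        a, b, fams = make(">A\n1 1 |\n>B\n1 |")
        m = augment(build_mrd(a, b, fams))
        d = decomposition_from_matching(m, ResolvedMatching(frozenset({(1, 3)})))
        assert d.indel_occurrences == frozenset({2})

    def test_cross_family_pair_rejected(self):
        a, b, fams = make(">A\n1 2 |\n>B\n1 2 |")
        m = augment(build_mrd(a, b, fams))
        with pytest.raises(ValueError):
            decomposition_from_matching(m, ResolvedMatching(frozenset({(1, 4)})))


class TestClassify:
    def classify(self, text, pairs=None):
        a, b = parse_unimog(text)
        match = (
            identity_matching(a, b)
            if pairs is None
            else ResolvedMatching(frozenset(pairs))
        )
        m = augment(build_mrd(a, b, derive_families(a, b)))
        return classify_components(m, decomposition_from_matching(m, match))

    def test_equal_one_marker_linear(self):
        r = self.classify(">A\n1 |\n>B\n1 |")
        assert (r.n, r.AB) == (1, 2)
        assert sum(r.counts().values()) == 2

    def test_pier_example(self):
        r = self.classify(">A\n1 2 |\n>B\n1 |", pairs={(1, 3)})
        assert (r.n, r.AB, r.Ba, r.Aoa) == (1, 1, 1, 1)

    def test_equal_circular_gives_one_cycle(self):
        r = self.classify(">A\n1 )\n>B\n1 )")
        assert (r.n, r.C) == (1, 1)
        assert sum(r.counts().values()) == 1

    def test_single_extremity_lava_telomere_is_even_pier(self):
        # B's singular marker 2 sits alone on a linear chromosome: each of
        # its extremities is a lava vertex that is also a telomere.
        r = self.classify(">A\n1 |\n>B\n1 | 2 |", pairs={(1, 2)})
        assert r.Bob == 2

    def test_fission_example(self):
        r = self.classify(">A\n1 2 |\n>B\n1 | 2 |")
        assert (r.n, r.AB, r.BoB) == (2, 2, 1)


class TestCensusInvariants:
    def test_telomere_and_lava_identities(self, rng):
        for _ in range(40):
            a, b = random_natural_pair(rng)
            fams = derive_families(a, b)
            m = augment(build_mrd(a, b, fams))
            for match in list(enumerate_maximal_matchings(fams, limit=2000))[:5]:
                d = decomposition_from_matching(m, match)
                r = classify_components(m, d)
                assert 2 * r.AoA + r.AB + r.Aoa + r.Ab == len(m.telomeres_a)
                assert 2 * r.BoB + r.AB + r.Ba + r.Bob == len(m.telomeres_b)
                unmatched_a = sum(
                    1 for i in d.indel_occurrences if m.occ_info[i][0] == "A"
                )
                unmatched_b = len(d.indel_occurrences) - unmatched_a
                assert 2 * r.aoa + r.ab + r.Aoa + r.Ba == 2 * unmatched_a
                assert 2 * r.bob + r.ab + r.Ab + r.Bob == 2 * unmatched_b

    def test_swap_symmetry(self, rng):
        for _ in range(20):
            a, b = random_natural_pair(rng)
            fams = derive_families(a, b)
            match = next(iter(enumerate_maximal_matchings(fams, limit=2000)))
            m = augment(build_mrd(a, b, fams))
            r = classify_components(m, decomposition_from_matching(m, match))
            # swap roles: relabel b as genome A and a as genome B
            from dcjindel.genomes import reindex_pair

            b2, a2 = reindex_pair(b, a)
            remap = dict(
                zip(
                    [m_.occurrence_id for m_ in (*a.occurrences(), *b.occurrences())],
                    [m_.occurrence_id for m_ in (*a2.occurrences(), *b2.occurrences())],
                )
            )
            swapped = ResolvedMatching(
                frozenset((remap[y], remap[x]) for x, y in match.pairs)
            )
            m2 = augment(build_mrd(b2, a2, derive_families(b2, a2)))
            r2 = classify_components(m2, decomposition_from_matching(m2, swapped))
            assert r2 == r.swap_genomes()


class TestCircularSingletons:
    def test_singular_circular_chromosome_detected(self):
        a, b = parse_unimog(">A\n1 | 2 )\n>B\n1 |")
        match = ResolvedMatching(frozenset({(1, 3)}))
        assert detect_circular_singletons(a, match) == 1
        assert detect_circular_singletons(b, match) == 0

    def test_no_circular_chromosomes(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n1 |")
        assert detect_circular_singletons(a, ResolvedMatching(frozenset())) == 0

    def test_matched_marker_disqualifies(self):
        a, b = parse_unimog(">A\n1 2 )\n>B\n1 |")
        match = ResolvedMatching(frozenset({(1, 3)}))
        assert detect_circular_singletons(a, match) == 0
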