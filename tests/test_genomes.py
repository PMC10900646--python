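"""Genome model, UniMoG parsing/writing, homology derivation."""

import pytest
from hypothesis import given, settings, strategies as st

from dcjindel.genomes import (
    FORWARD,
    REVERSE,
    ResolvedMatching,
    UnimogParseError,
    canonical_circular,
    canonical_genome,
    canonical_linear,
    derive_families,
    genome_adjacencies,
    genome_from_spec,
    identity_matching,
    is_maximal,
    parse_unimog,
    reindex_pair,
    validate_matching,
    write_unimog,
)


class TestParsing:
    def test_minimal_linear(self):
        (g,) = parse_unimog(">A\n1 -2 |")
        assert len(g.chromosomes) == 1
        chrom = g.chromosomes[0]
        assert not chrom.circular
        assert chrom.signed_families() == (("1", FORWARD), ("2", REVERSE))

    def test_two_circular_genomes(self):
        a, b = parse_unimog(">A\n1 )\n>B\n1 )")
        assert a.chromosomes[0].circular and b.chromosomes[0].circular
        assert [m.genome for m in (*a.occurrences(), *b.occurrences())] == ["A", "B"]

    def test_duplicate_family_gets_distinct_ids(self):
        (g,) = parse_unimog(">A\n2 1 2 |")
        ids = [m.occurrence_id for m in g.occurrences()]
        assert ids == [1, 2, 3]
        assert [m.family for m in g.occurrences()] == ["2", "1", "2"]

    def test_ids_run_across_genomes_in_reading_order(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n1 |")
        assert [m.occurrence_id for m in a.occurrences()] == [1, 2]
        assert [m.occurrence_id for m in b.occurrences()] == [3]

    def test_multiple_chromosomes_on_one_line(self):
        (g,) = parse_unimog(">A\n1 | 2 3 ) 4 |")
        assert [c.circular for c in g.chromosomes] == [False, True, False]

    @pytest.mark.parametrize(
        "text,lineno",
        [
            (">A\n1 2", 2),          # missing terminator
            (">A\n|", 2),            # empty chromosome
            (">A\n1 |\n>\n2 |", 3),  # empty genome name
            ("1 |", 1),              # data before header
        ],
    )
    def test_errors_carry_line_numbers(self, text, lineno):
        with pytest.raises(UnimogParseError) as err:
            parse_unimog(text)
        assert err.value.line == lineno

    def test_round_trip_is_identity_on_canonical_text(self):
        text = ">A\n1 -2 |\n>B\n3 )\n-1 2 |\n"
        assert write_unimog(parse_unimog(text)) == text


@st.composite
def genome_specs(draw):
    n_chrom = draw(st.integers(1, 3))
    chroms = []
    for _ in range(n_chrom):
        k = draw(st.integers(1, 4))
        seq = tuple(
            (str(draw(st.integers(1, 5))), draw(st.sampled_from((1, -1))))
            for _ in range(k)
        )
        chroms.append((seq, draw(st.booleans())))
    return chroms


@settings(derandomize=True, max_examples=60, deadline=None)
@given(genome_specs(), genome_specs())
def test_write_parse_round_trip(spec_a, spec_b):
    a = genome_from_spec("A", spec_a)
    b = genome_from_spec("B", spec_b, tag="B", start_id=a.n_markers + 1)
    text = write_unimog([a, b])
    again = write_unimog(parse_unimog(text))
    assert again == text


@settings(derandomize=True, max_examples=60, deadline=None)
@given(genome_specs())
def test_every_extremity_is_adjacency_xor_telomere(spec):
    g = genome_from_spec("A", spec)
    adjacencies, telomeres = genome_adjacencies(g)
    in_adj = {e for adj in adjacencies for e in adj}
    assert not (in_adj & telomeres)
    all_ext = {e for m in g.occurrences() for e in (m.tail, m.head)}
    assert in_adj | telomeres == all_ext


class TestAdjacencies:
    def test_linear_two_markers(self):
        (g,) = parse_unimog(">A\n1 2 |")
        adj, tel = genome_adjacencies(g)
        assert adj == {frozenset({(1, "h"), (2, "t")})}
        assert tel == {(1, "t"), (2, "h")}

    def test_single_circular(self):
        (g,) = parse_unimog(">A\n1 )")
        adj, tel = genome_adjacencies(g)
        assert adj == {frozenset({(1, "h"), (1, "t")})}
        assert tel == set()

    def test_single_linear(self):
        (g,) = parse_unimog(">A\n1 |")
        adj, tel = genome_adjacencies(g)
        assert adj == set()
        assert tel == {(1, "t"), (1, "h")}

    def test_reverse_marker_flips_extremity_roles(self):
        (g,) = parse_unimog(">A\n-1 2 |")
        adj, tel = genome_adjacencies(g)
        assert adj == {frozenset({(1, "t"), (2, "t")})}
        assert tel == {(1, "h"), (2, "h")}


class TestFamilies:
    def test_singular_family(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n1 |")
        fams = derive_families(a, b)
        assert fams.singular_families() == {"2"}
        assert fams.is_resolved()

    def test_ambiguous_family(self):
        a, b = parse_unimog(">A\n1 1 |\n>B\n1 |")
        fams = derive_families(a, b)
        assert fams.ambiguous_families() == {"1"}
        assert not fams.is_resolved()

    def test_disjoint_families_both_singular(self):
        a, b = parse_unimog(">A\n1 |\n>B\n2 |")
        fams = derive_families(a, b)
        assert fams.singular_families() == {"1", "2"}

    def test_identity_matching_rejects_ambiguous(self):
        a, b = parse_unimog(">A\n1 1 |\n>B\n1 |")
        with pytest.raises(ValueError, match="not resolved"):
            identity_matching(a, b)

    def test_matching_validation(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n1 2 |")
        fams = derive_families(a, b)
        validate_matching(fams, identity_matching(a, b))
        with pytest.raises(ValueError, match="crosses families"):
            validate_matching(fams, ResolvedMatching(frozenset({(1, 4)})))
        dup_fams = derive_families(*parse_unimog(">A\n1 1 |\n>B\n1 1 |"))
        with pytest.raises(ValueError, match="twice"):
            validate_matching(dup_fams, ResolvedMatching(frozenset({(1, 3), (1, 4)})))

    def test_maximality_flag(self):
        a, b = parse_unimog(">A\n1 1 |\n>B\n1 |")
        fams = derive_families(a, b)
        assert is_maximal(fams, ResolvedMatching(frozenset({(1, 3)})))
        assert not is_maximal(fams, ResolvedMatching(frozenset()))


class TestCanonicalization:
    def test_linear_reversal_invariance(self):
        seq = (("1", 1), ("2", -1))
        rev = (("2", 1), ("1", -1))
        assert canonical_linear(seq) == canonical_linear(rev)

    def test_circular_rotation_reversal_invariance(self):
        seq = (("1", 1), ("2", 1), ("3", -1))
        rot = (("2", 1), ("3", -1), ("1", 1))
        rev = (("3", 1), ("2", -1), ("1", -1))
        assert (
            canonical_circular(seq)
            == canonical_circular(rot)
            == canonical_circular(rev)
        )

    def test_genome_canonical_sorts_chromosomes(self):
        c1 = ((("1", 1),), False)
        c2 = ((("2", 1),), True)
        assert canonical_genome([c1, c2]) == canonical_genome([c2, c1])


def test_reindex_pair_assigns_contiguous_ids():
    a = genome_from_spec("A", [((("1", 1), ("2", 1)), False)], start_id=10)
    b = genome_from_spec("B", [((("1", 1),), True)], start_id=99)
    a2, b2 = reindex_pair(a, b)
    assert [m.occurrence_id for m in a2.occurrences()] == [1, 2]
    assert [m.occurrence_id for m in b2.occurrences()] == [3]
    assert all(m.genome == "B" for m in b2.occurrences())
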