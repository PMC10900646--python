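"""Evolution simulator: root construction, operation mix, ground truth."""

import numpy as np
import pytest
from scipy.special import zeta

from dcjindel.distance import resolved_distance
from dcjindel.genomes import (
    derive_families,
    genome_adjacencies,
    validate_matching,
    write_unimog,
)
from dcjindel.ilp import ilp_distance
from dcjindel.simulator import (
    SimulationConfig,
    evolve_pair,
    expected_op_counts,
    make_root,
    sample_zipf,
)


class TestRoot:
    def test_large_single_chromosome(self):
        g = make_root(20_000, 1)
        assert len(g.chromosomes) == 1
        assert g.n_markers == 20_000
        assert len({m.family for m in g.occurrences()}) == 20_000

    def test_one_marker_per_chromosome(self):
        g = make_root(5, 5)
        assert [len(c.markers) for c in g.chromosomes] == [1] * 5
        assert all(not c.circular for c in g.chromosomes)

    def test_even_spread(self):
        g = make_root(10, 3)
        assert sorted(len(c.markers) for c in g.chromosomes) == [3, 3, 4]

    def test_deterministic(self):
        assert write_unimog([make_root(30, 4, seed=1)]) == write_unimog(
            [make_root(30, 4, seed=2)]
        )

    def test_too_many_chromosomes(self):
        with pytest.raises(ValueError):
            make_root(3, 5)


class TestExpectedCounts:
    def test_reference_parameterization(self):
        exp = expected_op_counts(
            10_000, {"insertion": 0.1, "deletion": 0.2, "duplication": 0.4}
        )
        assert int(exp["dcj"]) == 5882

    def test_dcj_only(self):
        assert expected_op_counts(10_000, {})["dcj"] == 10_000

    def test_scales_linearly(self):
        exp = expected_op_counts(
            1_700, {"insertion": 0.1, "deletion": 0.2, "duplication": 0.4}
        )
        assert exp["dcj"] == pytest.approx(1_000)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            expected_op_counts(100, {"insertion": -0.1})


class TestZipf:
    def test_shape_four_mean_matches_zeta_ratio(self):
        draws = sample_zipf(4.0, seed=11, size=1_000_000)
        mean = draws.mean()
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        expected = zeta(3) / zeta(4)
        assert abs(mean - expected) < 3 * se

    def test_large_shape_concentrates_at_one(self):
        draws = sample_zipf(50.0, seed=12, size=100_000)
        assert (draws == 1).mean() > 0.999

    def test_seed_reproducibility(self):
        assert np.array_equal(
            sample_zipf(4.0, seed=3, size=100), sample_zipf(4.0, seed=3, size=100)
        )

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            sample_zipf(1.0)


class TestEvolution:
    def test_dcj_only_preserves_marker_content(self):
        cfg = SimulationConfig(
            n_markers=25, n_ops=30, insertion_rate=0, deletion_rate=0,
            duplication_rate=0, seed=4,
        )
        pair = evolve_pair(make_root(25, 2), cfg)
        fa = sorted(m.family for m in pair.genome_a.occurrences())
        fb = sorted(m.family for m in pair.genome_b.occurrences())
        assert fa == fb
        assert len(pair.matching) == 25

    def test_reproducible_from_seed(self):
        cfg = SimulationConfig(n_markers=40, n_ops=30, seed=9)
        root = make_root(40, 2)
        p1 = evolve_pair(root, cfg)
        p2 = evolve_pair(root, cfg)
        assert write_unimog([p1.genome_a, p1.genome_b]) == write_unimog(
            [p2.genome_a, p2.genome_b]
        )
        assert p1.matching == p2.matching

    def test_ground_truth_is_valid_matching(self):
        for seed in range(6):
            cfg = SimulationConfig(n_markers=20, n_chromosomes=2, n_ops=25, seed=seed)
            pair = evolve_pair(make_root(20, 2), cfg)
            fams = derive_families(pair.genome_a, pair.genome_b)
            validate_matching(fams, pair.matching)

    def test_genome_invariants_hold_after_evolution(self):
        for seed in range(6):
            cfg = SimulationConfig(n_markers=15, n_chromosomes=3, n_ops=40, seed=seed)
            pair = evolve_pair(make_root(15, 3), cfg)
            for g in (pair.genome_a, pair.genome_b):
                adjacencies, telomeres = genome_adjacencies(g)
                covered = [e for adj in adjacencies for e in adj]
                assert len(covered) == len(set(covered))  # adjacency matching
                assert not (set(covered) & telomeres)
                assert all(c.markers for c in g.chromosomes)

    def test_distance_bounded_by_operation_count(self):
        # each evolutionary operation changes the distance by at most 1
        for seed in range(8):
            cfg = SimulationConfig(n_markers=8, n_ops=6, seed=seed)
            pair = evolve_pair(make_root(8, 1), cfg)
            d, _ = resolved_distance(pair.genome_a, pair.genome_b, pair.matching)
            assert d <= cfg.n_ops

    def test_op_counts_sum_to_budget(self):
        cfg = SimulationConfig(n_markers=30, n_ops=41, seed=2)
        pair = evolve_pair(make_root(30, 1), cfg)
        assert sum(pair.op_counts["A"].values()) == 20
        assert sum(pair.op_counts["B"].values()) == 21

    def test_type_frequencies_match_multinomial(self):
        # pooled type draws over a modest budget; the full-scale calibration
        # lives in the acceptance suite
        rates = {"insertion": 0.1, "deletion": 0.2, "duplication": 0.4}
        totals = dict.fromkeys(("dcj", *rates), 0)
        n_ops_per_run = 1_000
        runs = 10
        for seed in range(runs):
            cfg = SimulationConfig(
                n_markers=100, n_chromosomes=2, n_ops=n_ops_per_run, seed=seed,
                insertion_rate=0.1, deletion_rate=0.2, duplication_rate=0.4,
            )
            pair = evolve_pair(make_root(100, 2), cfg)
            for side in ("A", "B"):
                for t, c in pair.op_counts[side].items():
                    totals[t] += c
        n = runs * n_ops_per_run
        expected = expected_op_counts(n, rates)
        for t, count in totals.items():
            p = expected[t] / n
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(count - expected[t]) < 4 * sigma, (t, count, expected[t])

    def test_ilp_recovers_low_divergence(self):
        cfg = SimulationConfig(
            n_markers=8, n_ops=3, duplication_rate=0.5, insertion_rate=0.1,
            deletion_rate=0.2, seed=13,
        )
        pair = evolve_pair(make_root(8, 1), cfg)
        d_ilp, _, _, sol = ilp_distance(pair.genome_a, pair.genome_b)
        d_truth, _ = resolved_distance(pair.genome_a, pair.genome_b, pair.matching)
        assert sol.status == "optimal"
        assert d_ilp <= d_truth <= cfg.n_ops
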