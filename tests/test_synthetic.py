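"""Synthetic community generator: GC targets, marker planting, MDA bias,
fragmentation, and truth-table bookkeeping."""

import numpy as np
import pytest

from colonybin.markers import MarkerCatalog
from colonybin.synthetic import (
    AbundanceDesign,
    MdaBiasModel,
    SimulationError,
    fragment_to_scaffolds,
    generate_genome,
    simulate_bulk_reads,
    simulate_colony_reads,
)


def _read_gc(reads) -> float:
    gc = total = 0
    for _, seq, _ in reads:
        gc += seq.count("G") + seq.count("C")
        total += len(seq)
    return gc / total


class TestGenerateGenome:
    def test_zero_gc_limit_yields_only_at(self):
        g = generate_genome("at_only", 10_000, 0.0, 0, None, seed=3)
        assert set(g.sequence) <= {"A", "T"}

    def test_high_gc_genome_hits_target_and_markers_are_findable(self):
        catalog = MarkerCatalog.synthetic(107, 60, seed=5)
        g = generate_genome("hi", 200_000, 0.68, 105, catalog, seed=4)
        realized = (g.sequence.count("G") + g.sequence.count("C")) / len(g.sequence)
        assert 0.67 <= realized <= 0.69
        assert len(g.marker_positions) == 105
        planted_ids = {m for m, _, _ in g.marker_positions}
        assert len(planted_ids) == 105  # each marker exactly once
        for mid, start, end in g.marker_positions:
            assert g.sequence[start:end] == catalog.sequences[mid]
            assert g.sequence.find(catalog.sequences[mid]) >= 0

    def test_marker_intervals_disjoint_and_in_bounds(self, catalog):
        g = generate_genome("m", 30_000, 0.5, 30, catalog, seed=8)
        intervals = sorted((s, e) for _, s, e in g.marker_positions)
        assert all(0 <= s < e <= g.length for s, e in intervals)
        assert all(b[0] >= a[1] for a, b in zip(intervals, intervals[1:]))

    def test_same_seed_reproduces_sequence(self, catalog):
        a = generate_genome("r", 12_000, 0.45, 5, catalog, seed=42)
        b = generate_genome("r", 12_000, 0.45, 5, catalog, seed=42)
        assert a.sequence == b.sequence
        assert a.marker_positions == b.marker_positions

    def test_placement_failure_names_genome(self):
        bulky = MarkerCatalog.synthetic(4, tag_length=3000, seed=1)
        with pytest.raises(SimulationError, match="crowded"):
            generate_genome("crowded", 10_000, 0.5, 4, bulky, seed=1,
                            max_placement_tries=5)

    def test_too_many_markers_rejected(self, catalog):
        with pytest.raises(SimulationError):
            generate_genome("x", 20_000, 0.5, catalog.size + 1, catalog, seed=0)


@pytest.fixture(scope="module")
def two_genomes():
    return [
        generate_genome("lo", 20_000, 0.30, 0, None, seed=21),
        generate_genome("hi", 20_000, 0.70, 0, None, seed=22),
    ]


class TestReadSimulation:
    def test_unbiased_equal_weights_split_reads_binomially(self, two_genomes):
        design = AbundanceDesign(np.array([[0.5], [0.5]]), ("lo", "hi"), ("s1",))
        samples, truth = simulate_colony_reads(
            two_genomes, design, 10_000, bias=MdaBiasModel(beta=0), seed=1
        )
        counts = samples["s1"].fragments["genome_id"].value_counts()
        sd3 = 3 * np.sqrt(10_000 * 0.25)
        assert abs(counts["lo"] - 5000) <= sd3
        assert abs(counts["hi"] - 5000) <= sd3
        assert len(truth.reads) == 10_000

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_bias_favors_low_gc_genome(self, two_genomes, seed):
        design = AbundanceDesign(np.array([[0.5], [0.5]]), ("lo", "hi"), ("s1",))
        samples, _ = simulate_colony_reads(
            two_genomes, design, 10_000, bias=MdaBiasModel(beta=3), seed=seed
        )
        counts = samples["s1"].fragments["genome_id"].value_counts()
        assert counts["lo"] > counts["hi"]

    def test_error_free_reads_are_exact_genome_substrings(self, two_genomes):
        from colonybin._seq import revcomp

        design = AbundanceDesign(np.array([[1.0], [0.0]]), ("lo", "hi"), ("s1",))
        samples, _ = simulate_colony_reads(
            two_genomes, design, 200, error_rate=0.0, seed=9
        )
        genome = two_genomes[0].sequence
        for (_, s1, _), (_, s2, _) in zip(samples["s1"].r1, samples["s1"].r2):
            assert s1 in genome
            assert revcomp(s2) in genome

    def test_degenerate_design_rejected(self):
        with pytest.raises(SimulationError, match="all-zero"):
            AbundanceDesign(np.array([[0.0], [0.0]]), ("a", "b"), ("s1",))

    def test_truth_table_counts_conserved(self, two_genomes):
        design = AbundanceDesign(
            np.array([[0.8, 0.1], [0.2, 0.9]]), ("lo", "hi"), ("s1", "s2")
        )
        samples, truth = simulate_colony_reads(two_genomes, design, 500, seed=3)
        assert len(truth.reads) == 1000  # every pair exactly once, both samples
        for sid in ("s1", "s2"):
            assert len(samples[sid].fragments) == 500

    def test_weak_design_warns(self):
        with pytest.warns(UserWarning, match="ratio"):
            AbundanceDesign(
                np.array([[0.5, 0.45], [0.5, 0.55]]), ("a", "b"), ("s1", "s2")
            )


class TestBulkSample:
    def test_bulk_equals_unbiased_colony_with_same_seed(self, two_genomes):
        bulk, _ = simulate_bulk_reads(
            two_genomes, [0.5, 0.5], 300, sample_id="s1", seed=5
        )
        design = AbundanceDesign(np.array([[0.5], [0.5]]), ("lo", "hi"), ("s1",))
        samples, _ = simulate_colony_reads(
            two_genomes, design, 300, bias=MdaBiasModel(beta=0), seed=5
        )
        assert bulk.r1 == samples["s1"].r1
        assert bulk.r2 == samples["s1"].r2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_bulk_mean_read_gc_exceeds_biased_colony(self, two_genomes, seed):
        bulk, _ = simulate_bulk_reads(two_genomes, [0.5, 0.5], 5000, seed=seed)
        design = AbundanceDesign(np.array([[0.5], [0.5]]), ("lo", "hi"), ("s1",))
        biased, _ = simulate_colony_reads(
            two_genomes, design, 5000, bias=MdaBiasModel(beta=3), seed=seed
        )
        assert _read_gc(bulk.r1) > _read_gc(biased["s1"].r1)

    @pytest.mark.parametrize("betas", [(0.0, 1.0), (1.0, 3.0)])
    def test_mean_read_gc_non_increasing_in_beta(self, two_genomes, betas):
        design = AbundanceDesign(np.array([[0.5], [0.5]]), ("lo", "hi"), ("s1",))
        lo_beta, hi_beta = betas
        gcs = []
        for beta in betas:
            means = []
            for seed in range(5):
                s, _ = simulate_colony_reads(
                    two_genomes, design, 10_000, bias=MdaBiasModel(beta=beta), seed=seed
                )
                means.append(_read_gc(s["s1"].r1))
            gcs.append(np.mean(means))
        assert gcs[1] <= gcs[0]


class TestFragmentation:
    def test_pieces_respect_min_length_and_conservation(self, small_genomes):
        scaffolds, truth, discarded = fragment_to_scaffolds(
            small_genomes, min_len=1000, mean_len=3000, seed=2
        )
        assert all(s.length >= 1000 for s in scaffolds)
        total = sum(g.length for g in small_genomes)
        kept = sum(s.length for s in scaffolds)
        assert kept + round(discarded * total) == total
        assert set(truth.scaffolds) == {s.scaffold_id for s in scaffolds}

    def test_same_seed_reproduces_scaffolds(self, small_genomes):
        a = fragment_to_scaffolds(small_genomes, 1000, 3000, seed=7)[0]
        b = fragment_to_scaffolds(small_genomes, 1000, 3000, seed=7)[0]
        assert [(s.scaffold_id, s.sequence) for s in a] == [
            (s.scaffold_id, s.sequence) for s in b
        ]

    def test_markers_never_split_across_breakpoints(self, small_genomes):
        scaffolds, _, _ = fragment_to_scaffolds(small_genomes, 1000, 2000, seed=3)
        planted = sum(len(g.marker_positions) for g in small_genomes)
        found = 0
        by_genome = {g.genome_id: g for g in small_genomes}
        for s in scaffolds:
            for _, m_start, m_end in by_genome[s.genome_id].marker_positions:
                if s.start <= m_start and m_end <= s.end:
                    found += 1
        # every marker that fell on a *kept* piece is intact; none straddles
        for s in scaffolds:
            for _, m_start, m_end in by_genome[s.genome_id].marker_positions:
                straddles = m_start < s.end < m_end or m_start < s.start < m_end
                assert not straddles
        assert found <= planted

    def test_mean_below_min_rejected(self, small_genomes):
        with pytest.raises(SimulationError):
            fragment_to_scaffolds(small_genomes, min_len=2000, mean_len=1500, seed=0)
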