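"""Coverage-space clustering, composition refinement, bin assembly, read extraction."""

import numpy as np
import pandas as pd
import pytest

from colonybin.binning import (
    NOISE,
    BinningError,
    CoverageMatrix,
    assemble_bins,
    cluster_scaffolds,
    coverage_space,
    extract_bin_reads,
    refine_bin,
)
from colonybin.markers import MarkerCatalog, detect_markers, duplicated_marker_count
from colonybin.profiles import compute_gc, compute_tnf
from colonybin.synthetic import fragment_to_scaffolds, generate_genome


def _matrix(depths, samples=("a", "b", "c")):
    depths = np.asarray(depths, dtype=float)
    ids = tuple(f"s{i}" for i in range(len(depths)))
    return CoverageMatrix(ids, depths, tuple(samples))


class TestCoverageSpace:
    def test_zero_depth_maps_to_minus_two(self):
        pts = coverage_space(_matrix([[0, 0, 0]]))
        assert np.allclose(pts, -2.0)

    def test_pseudocount_completes_to_round_log(self):
        pts = coverage_space(_matrix([[0.99, 0.99, 0.99]]))
        assert np.allclose(pts, 0.0)

    def test_transform_is_monotone_per_coordinate(self, rng):
        d = np.sort(rng.random(20))
        pts = coverage_space(_matrix(np.column_stack([d, d, d])))
        assert (np.diff(pts[:, 0]) >= 0).all()

    def test_requires_exactly_three_samples(self):
        with pytest.raises(BinningError, match="3 samples"):
            coverage_space(_matrix([[1, 2]], samples=("a", "b")))
        # explicit opt-in generalizes
        pts = coverage_space(_matrix([[1, 2]], samples=("a", "b")),
                             allow_any_samples=True)
        assert pts.shape == (1, 2)


class TestClusterScaffolds:
    def test_two_separated_clouds_recovered_exactly(self, rng):
        a = rng.normal([0, 0, 0], 0.05, size=(200, 3))
        b = rng.normal([2, 0, 0], 0.05, size=(200, 3))
        labels = cluster_scaffolds(np.vstack([a, b]), 10, 0.3)
        assert set(labels) == {0, 1}
        assert len(set(labels[:200])) == 1
        assert len(set(labels[200:])) == 1
        assert labels[0] != labels[200]

    def test_single_point_is_noise(self):
        labels = cluster_scaffolds(np.zeros((1, 3)), min_cluster_size=5)
        assert labels.tolist() == [NOISE]

    def test_identical_points_form_one_cluster(self):
        labels = cluster_scaffolds(np.ones((30, 3)), 10, 0.3)
        assert set(labels) == {0}

    def test_invalid_radius_rejected(self):
        with pytest.raises(BinningError):
            cluster_scaffolds(np.zeros((5, 3)), 2, 0.0)

    def test_labels_deterministic(self, rng):
        pts = rng.normal(size=(100, 3))
        a = cluster_scaffolds(pts, 5, 0.8)
        b = cluster_scaffolds(pts, 5, 0.8)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def highgc_mixture():
    """Two near-identical-GC genomes with distinct composition, fragmented."""
    catalog = MarkerCatalog.synthetic(50, 60, seed=71)
    g4 = generate_genome("g4", 100_000, 0.676, 40, catalog, seed=72)
    g6 = generate_genome("g6", 100_000, 0.685, 40, catalog, seed=73)
    scaffolds, truth, _ = fragment_to_scaffolds([g4, g6], 1000, 5000, seed=74)
    hits = detect_markers([(s.scaffold_id, s.sequence) for s in scaffolds], catalog)
    gc = np.array([compute_gc(s.sequence) for s in scaffolds])
    tnf = np.vstack([compute_tnf(s.sequence) for s in scaffolds])
    lengths = np.array([s.length for s in scaffolds], dtype=float)
    ids = [s.scaffold_id for s in scaffolds]
    return ids, gc, tnf, lengths, hits, truth


class TestRefineBin:
    def test_clean_bin_is_returned_unchanged(self, highgc_mixture):
        ids, gc, tnf, lengths, hits, truth = highgc_mixture
        mask = [truth.scaffolds[i] == "g4" for i in ids]
        sub = [i for i, m in zip(ids, mask) if m]
        pieces = refine_bin(sub, gc[mask], tnf[mask], hits, max_duplicated=5,
                            lengths=lengths[mask])
        assert pieces == [sub]

    def test_two_genome_mixture_splits_along_composition(self, highgc_mixture):
        ids, gc, tnf, lengths, hits, truth = highgc_mixture
        assert duplicated_marker_count(hits, ids) > 5  # the refinement trigger
        pieces = refine_bin(ids, gc, tnf, hits, max_duplicated=5, lengths=lengths)
        assert len(pieces) >= 2
        # each sub-bin is nearly clean of duplicates...
        for piece in pieces:
            assert duplicated_marker_count(hits, piece) <= 1
        # ...and each genome's length is dominated by a single sub-bin
        length_of = dict(zip(ids, lengths))
        for genome in ("g4", "g6"):
            total = sum(length_of[i] for i in ids if truth.scaffolds[i] == genome)
            best = max(
                sum(length_of[i] for i in piece if truth.scaffolds[i] == genome)
                for piece in pieces
            )
            assert best / total > 0.9

    def test_split_not_reducing_duplicates_is_rejected(self):
        # every scaffold carries the same duplicated marker: no split can help
        ids = ["s1", "s2", "s3", "s4"]
        hits = pd.DataFrame(
            {"scaffold_id": ids, "marker_id": "m1", "count": 2}
        )
        gc = np.array([0.3, 0.4, 0.6, 0.7])
        rng = np.random.default_rng(0)
        tnf = rng.random((4, 136))
        pieces = refine_bin(ids, gc, tnf, hits, max_duplicated=0)
        assert pieces == [ids]

    def test_refinement_never_raises_total_duplicates(self, highgc_mixture):
        ids, gc, tnf, lengths, hits, _ = highgc_mixture
        before = duplicated_marker_count(hits, ids)
        pieces = refine_bin(ids, gc, tnf, hits, max_duplicated=5, lengths=lengths)
        after = sum(duplicated_marker_count(hits, p) for p in pieces)
        assert after <= before


class TestAssembleBins:
    @pytest.fixture()
    def toy(self):
        profile = pd.DataFrame(
            {
                "scaffold_id": ["s1", "s2", "s3", "s4"],
                "length": [1000, 3000, 2000, 1500],
                "gc": [0.40, 0.50, 0.60, 0.55],
            }
        )
        catalog = MarkerCatalog(("m1", "m2"))
        hits = pd.DataFrame(
            {"scaffold_id": ["s1", "s2"], "marker_id": ["m1", "m2"], "count": [1, 1]}
        )
        return profile, catalog, hits

    def test_total_length_is_conserved(self, toy):
        profile, catalog, hits = toy
        bins, noise = assemble_bins(np.array([0, 0, 0, NOISE]), profile, hits, catalog)
        assert bins[0].total_length == 6000
        assert noise == ["s4"]

    def test_gc_is_length_weighted(self, toy):
        profile, catalog, hits = toy
        bins, _ = assemble_bins(np.array([0, 0, 1, 1]), profile, hits, catalog)
        expected = (1000 * 0.40 + 3000 * 0.50) / 4000
        assert bins[0].gc == pytest.approx(expected)

    def test_bins_plus_noise_partition_scaffolds(self, toy):
        profile, catalog, hits = toy
        bins, noise = assemble_bins(np.array([0, 1, 1, NOISE]), profile, hits, catalog)
        seen = set(noise)
        for b in bins:
            assert not (seen & set(b.scaffold_ids))
            seen |= set(b.scaffold_ids)
        assert seen == set(profile["scaffold_id"])

    def test_label_cover_mismatch_raises(self, toy):
        profile, catalog, hits = toy
        with pytest.raises(BinningError):
            assemble_bins(np.array([0, 0]), profile, hits, catalog)


class TestExtractBinReads:
    def _aln(self, rows):
        return pd.DataFrame(
            rows, columns=["read_id", "scaffold_id", "aligned_bases", "mate"]
        )

    def test_pair_rules(self):
        aln = self._aln(
            [
                ("both", "in1", 100, 1), ("both", "in2", 100, 2),
                ("one", "in1", 100, 1), ("one", "out", 100, 2),
                ("none", "out", 100, 1), ("none", "out", 100, 2),
                ("orphan", "in2", 80, 2),
            ]
        )
        selected = extract_bin_reads(aln, ["in1", "in2"])
        assert selected == {"both", "one", "orphan"}

    def test_matches_brute_force_enumeration(self, rng):
        scaffolds = [f"s{i}" for i in range(20)]
        members = set(rng.choice(scaffolds, size=6, replace=False))
        rows = []
        for i in range(300):
            for mate in (1, 2):
                if rng.random() < 0.9:  # some mates unmapped
                    rows.append(
                        (f"p{i}", scaffolds[int(rng.integers(20))],
                         int(rng.integers(50, 150)), mate)
                    )
        aln = self._aln(rows)
        brute = set()
        for rid, sid, _, _ in rows:
            if sid in members:
                brute.add(rid)
        assert extract_bin_reads(aln, members) == brute

    def test_missing_mate_flags_raise(self):
        bad = pd.DataFrame({"read_id": ["r"], "scaffold_id": ["s"], "aligned_bases": [5]})
        with pytest.raises(BinningError):
            extract_bin_reads(bad, ["s"])
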