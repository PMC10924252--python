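"""Genome rearrangement simulator, coordinate liftover and read generation."""

import numpy as np
import pytest

from linksv import (
    CoordinateMap,
    MoleculeModel,
    SimulatedSV,
    SimulationConfig,
    apply_svs,
    induce_svs,
    make_null_dataset,
    random_genome,
    read_truth_bed,
    simulate_tagged_reads,
    stream_tagged_alignments,
    write_truth_bed,
)
from linksv.simulate import read_fasta, revcomp, write_fasta


class TestInduceSVs:
    def test_events_are_sorted_nonoverlapping_and_poisson_like(self):
        genome = random_genome(10_000_000, seed=1)
        cfg = SimulationConfig(seed=2)
        _, truth, _ = induce_svs(genome, cfg)
        # expected count ~ length / (spacing + mean footprint) ~ 27; allow 3 sigma
        assert 12 <= len(truth) <= 45
        prev_end = -1
        for sv in truth:
            assert sv.ref_start >= prev_end
            prev_end = max(sv.ref_end, sv.ref_start)
        assert {sv.type for sv in truth} <= {"insertion", "deletion", "inversion"}
        assert {sv.size for sv in truth} <= set(cfg.sv_sizes)

    def test_single_inversion_reverse_complements_footprint(self):
        genome = random_genome(30_000, seed=3)
        ref = genome["chr1"]
        truth = [SimulatedSV("chr1", 10_000, 15_000, "inversion", 5_000)]
        derived = apply_svs(genome, truth)["chr1"]
        assert derived[:10_000] == ref[:10_000]
        assert derived[15_000:] == ref[15_000:]
        assert derived[10_000:15_000] == revcomp(ref[10_000:15_000])

    def test_deletion_shifts_downstream_liftover_by_size(self):
        cmap = CoordinateMap.from_truth(
            [SimulatedSV("chr1", 5_000, 7_000, "deletion", 2_000)], ref_length=20_000
        )
        assert cmap.derived_length == 18_000
        assert cmap.lift_point(4_999) == 4_999
        assert cmap.lift_point(5_000) == 7_000  # first base after the junction
        assert cmap.lift_point(10_000) == 12_000

    def test_induced_genome_matches_independent_truth_replay(self):
        genome = random_genome(2_000_000, seed=5, n_chromosomes=2)
        cfg = SimulationConfig(spacing_mean=120_000, sv_sizes=(5_000, 20_000), seed=6)
        derived, truth, _ = induce_svs(genome, cfg)
        assert truth  # the test is vacuous without events
        replayed = apply_svs(genome, truth)
        assert replayed == derived  # byte-for-byte

    def test_seeded_reproducibility(self):
        genome = random_genome(1_000_000, seed=7)
        a = induce_svs(genome, SimulationConfig(seed=8))
        b = induce_svs(genome, SimulationConfig(seed=8))
        assert a[0] == b[0] and a[1] == b[1]


class TestCoordinateMap:
    def _map(self):
        truth = [
            SimulatedSV("chr1", 10_000, 14_000, "deletion", 4_000),
            SimulatedSV("chr1", 20_000, 20_000, "insertion", 3_000, "A" * 3_000),
            SimulatedSV("chr1", 30_000, 36_000, "inversion", 6_000),
        ]
        return CoordinateMap.from_truth(truth, ref_length=50_000)

    def test_segments_partition_derived_genome(self):
        cmap = self._map()
        assert cmap.derived_length == 50_000 - 4_000 + 3_000
        assert cmap.segments[0].derived_start == 0

    def test_liftover_roundtrip_on_mappable_positions(self):
        cmap = self._map()
        rng = np.random.default_rng(0)
        for d in rng.integers(0, cmap.derived_length, 500):
            r = cmap.lift_point(int(d))
            if r is not None:
                assert cmap.project_point(r) == int(d)
        for r in rng.integers(0, cmap.ref_length, 500):
            d = cmap.project_point(int(r))
            if d is not None:
                assert cmap.lift_point(d) == int(r)

    def test_deleted_reference_positions_do_not_project(self):
        cmap = self._map()
        assert cmap.project_point(12_000) is None

    def test_novel_positions_do_not_lift(self):
        cmap = self._map()
        # insertion occupies derived [16_000, 19_000) after the 4-kb deletion
        assert cmap.lift_point(17_000) is None

    def test_inverted_positions_lift_mirrored(self):
        cmap = self._map()
        # derived inversion interval maps reversed onto reference [30_000, 36_000)
        d0 = cmap.project_point(30_000)
        d1 = cmap.project_point(35_999)
        assert d1 is not None and d0 is not None and d1 == d0 - 5_999

    def test_tsv_roundtrip(self, tmp_path):
        cmap = self._map()
        path = tmp_path / "map.tsv"
        cmap.to_tsv(path)
        back = CoordinateMap.from_tsv(path)
        assert back.ref_length == cmap.ref_length
        assert back.segments == cmap.segments


class TestSimulateReads:
    def test_identity_map_preserves_positions_and_orientation(self):
        reads = make_null_dataset(500_000, seed=1)
        assert not reads.reverse.any()
        assert (reads.starts[1:] >= reads.starts[:-1]).all()
        assert reads.starts.min() >= 0
        assert reads.starts.max() < 500_000

    def test_fixed_seed_is_reproducible(self):
        a = make_null_dataset(300_000, seed=4)
        b = make_null_dataset(300_000, seed=4)
        assert np.array_equal(a.starts, b.starts)
        assert np.array_equal(a.barcode_ids, b.barcode_ids)

    def test_read_coverage_matches_target_within_five_percent(self):
        model = MoleculeModel(target_read_coverage=8.0)
        reads = make_null_dataset(5_000_000, model, seed=2)
        assert abs(reads.read_coverage() - 8.0) / 8.0 < 0.05

    def test_window_barcode_count_matches_uniform_placement_expectation(self):
        # a window of size m collects every molecule overlapping it:
        # E[count] = molecule_coverage * (1 + m / L) for fixed length L
        model = MoleculeModel(molecule_length_range=(50_000, 50_000), molecule_coverage=20.0)
        reads = make_null_dataset(5_000_000, model, seed=6)
        from linksv import WindowGrid, collect_window_barcodes

        grid = WindowGrid("chr1", 5_000_000, 10_000)
        sets = collect_window_barcodes(reads, grid)
        counts = [len(s) for s in sets.sets[5:-5]]  # interior windows only
        expected = 20.0 * (1 + 10_000 / 50_000)
        assert abs(np.mean(counts) - expected) / expected < 0.1

    def test_molecule_spanning_deletion_leaves_flanking_clusters(self):
        truth = [SimulatedSV("chr1", 200_000, 250_000, "deletion", 50_000)]
        cmap = CoordinateMap.from_truth(truth, ref_length=500_000)
        reads = simulate_tagged_reads(cmap, seed=3)
        rl = reads.read_length
        # no read may start strictly inside the deleted reference footprint
        inside = (reads.starts > 200_000) & (reads.starts < 250_000 - rl)
        assert not inside.any()
        # barcodes present on both flanks exist (molecules crossing the junction)
        left = set(reads.barcode_ids[(reads.starts > 150_000) & (reads.starts < 200_000)])
        right = set(reads.barcode_ids[(reads.starts >= 250_000) & (reads.starts < 300_000)])
        assert left & right

    def test_inversion_breakpoint_molecules_share_distal_windows(self):
        truth = [SimulatedSV("chr1", 200_000, 300_000, "inversion", 100_000)]
        cmap = CoordinateMap.from_truth(truth, ref_length=600_000)
        reads = simulate_tagged_reads(cmap, seed=5)
        # molecules crossing the left breakpoint put reads just left of the
        # inversion AND near its right edge (mirrored liftover)
        left = set(reads.barcode_ids[(reads.starts > 160_000) & (reads.starts < 200_000)])
        distal = set(reads.barcode_ids[(reads.starts > 260_000) & (reads.starts < 300_000)])
        proximal = set(reads.barcode_ids[(reads.starts > 200_000) & (reads.starts < 240_000)])
        assert len(left & distal) > len(left & proximal)

    def test_sam_roundtrip_through_alignment_streaming(self, tmp_path):
        genome = random_genome(200_000, seed=9)
        model = MoleculeModel(target_read_coverage=2.0, molecule_length_range=(20_000, 30_000))
        reads = make_null_dataset(200_000, model, seed=9)
        path = tmp_path / "reads.sam"
        reads.to_sam(path, reference=genome["chr1"])
        back = list(stream_tagged_alignments(path))
        assert len(back) == len(reads)
        assert [a.start for a in back] == list(reads.starts)
        assert back[0].bx == reads.barcode(0)
        assert all(a.mapq == 60 for a in back[:10])


def test_truth_bed_roundtrip(tmp_path):
    truth = [
        SimulatedSV("chr1", 1_000, 6_000, "deletion", 5_000),
        SimulatedSV("chr1", 9_000, 9_000, "insertion", 2_000, "C" * 2_000),
        SimulatedSV("chr1", 20_000, 25_000, "inversion", 5_000),
    ]
    path = tmp_path / "truth.bed"
    write_truth_bed(truth, path, insertions_fasta=tmp_path / "ins.fasta")
    back = read_truth_bed(path)
    assert [(s.chrom, s.ref_start, s.ref_end, s.type, s.size) for s in back] == [
        (s.chrom, s.ref_start, s.ref_end, s.type, s.size) for s in truth
    ]
    assert ">insertion_2" in (tmp_path / "ins.fasta").read_text()


def test_fasta_roundtrip(tmp_path):
    genome = random_genome(1_000, seed=11, n_chromosomes=2)
    path = tmp_path / "ref.fasta"
    write_fasta(genome, path)
    assert read_fasta(path) == genome
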