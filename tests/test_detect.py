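"""Decay-model fitting, outlier cells, clustering and call intersection."""

import subprocess

import numpy as np
import pytest
from scipy import optimize
from scipy.stats import norm

from linksv import (
    CandidateSV,
    DecayModel,
    DetectionConfig,
    MoleculeModel,
    SharingMatrix,
    WindowGrid,
    cluster_candidates,
    collect_window_barcodes,
    build_matrix,
    compute_distance_stats,
    detect_outlier_cells,
    fit_decay_model,
    intersect_reciprocal,
    make_null_dataset,
    read_calls_bed,
    write_calls_bed,
)
from linksv.detect import OutlierCell


def decay_matrix(a, b, c, n=200, noise=0.0, seed=5, m=10_000):
    rng = np.random.default_rng(seed)
    x = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    v = np.exp(a + b * np.exp(-c * x))
    if noise:
        v = v * (1 + rng.normal(0, noise, v.shape))
    v = np.triu(v) + np.triu(v, 1).T
    np.fill_diagonal(v, 1.0)
    return SharingMatrix(WindowGrid("chr1", n * m, m), v)


class TestDecayFit:
    @pytest.mark.parametrize("a,b,c", [(-6.0, 4.0, 0.2), (-4.0, 2.5, 0.5), (-8.0, 6.0, 0.05)])
    def test_noise_free_recovery_to_machine_precision(self, a, b, c):
        model = fit_decay_model(decay_matrix(a, b, c))
        assert model.converged
        for got, true in ((model.a, a), (model.b, b), (model.c, c)):
            assert abs(got - true) / abs(true) <= 1e-6

    def test_one_percent_noise_recovery_within_five_percent(self):
        model = fit_decay_model(decay_matrix(-6.0, 4.0, 0.2, noise=0.01))
        for got, true in ((model.a, -6.0), (model.b, 4.0), (model.c, 0.2)):
            assert abs(got - true) / abs(true) <= 0.05

    def test_constant_matrix_degenerates_to_flat_curve(self):
        n = 100
        v = np.full((n, n), 0.05)
        np.fill_diagonal(v, 1.0)
        model = fit_decay_model(SharingMatrix(WindowGrid("c", n * 10_000, 10_000), v))
        assert abs(model.b) < 1e-6
        np.testing.assert_allclose(model.predict([1, 10, 50]), 0.05, rtol=1e-6)

    def test_decay_rate_tracks_molecule_length(self):
        # molecules of L = 50 kb over m = 10 kb windows, with realistic barcode
        # reuse providing a background sharing floor: 1/c ~ L/m within a factor 2
        mm = MoleculeModel(
            molecule_length_range=(50_000, 50_000), molecules_per_barcode=4, barcode_space=1000
        )
        reads = make_null_dataset(5_000_000, mm, seed=3)
        grid = WindowGrid("chr1", 5_000_000, 10_000)
        model = fit_decay_model(build_matrix(collect_window_barcodes(reads, grid)))
        assert 5 / 2 <= 1.0 / model.c <= 5 * 2

    def test_sufficient_statistics_fit_equals_cell_level_fit(self):
        """The per-distance weighted fit must match a direct fit on all cells."""
        mat = decay_matrix(-5.0, 3.0, 0.3, n=40, noise=0.05, seed=8)
        model = fit_decay_model(mat)
        n = mat.values.shape[0]
        xs, ys = [], []
        for x in range(1, n):
            d = np.diagonal(mat.values, offset=x)
            xs.append(np.full(d.size, float(x)))
            ys.append(d)
        x_all, y_all = np.concatenate(xs), np.concatenate(ys)
        res = optimize.least_squares(
            lambda p: y_all - np.exp(p[0] + p[1] * np.exp(-p[2] * x_all)),
            x0=np.array([model.a, model.b, model.c]) + 0.05,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        np.testing.assert_allclose(res.x, [model.a, model.b, model.c], rtol=1e-5)
        sd_cells = np.sqrt(np.sum((y_all - np.exp(
            model.a + model.b * np.exp(-model.c * x_all))) ** 2) / (y_all.size - 3))
        np.testing.assert_allclose(model.residual_sd, sd_cells, rtol=1e-6)

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_decay_model(decay_matrix(-6, 4, 0.2, n=3))


class TestDistanceStats:
    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(4)
        n = 30
        v = rng.random((n, n))
        v = (v + v.T) / 2
        mat = SharingMatrix(WindowGrid("c", n * 100, 100), v)
        stats = compute_distance_stats(mat)
        for x in range(n):
            vals = [v[i, i + x] for i in range(n - x)]
            assert stats.count[x] == n - x
            np.testing.assert_allclose(stats.mean[x], np.mean(vals))
            np.testing.assert_allclose(stats.sd[x], np.std(vals) if len(vals) > 1 else 0.0)

    def test_single_entry_offset_has_sd_zero(self):
        mat = decay_matrix(-6, 4, 0.2, n=5)
        stats = compute_distance_stats(mat)
        assert stats.count[4] == 1 and stats.sd[4] == 0.0


class TestOutlierCells:
    def _setup(self, n=60):
        mat = decay_matrix(-4.0, 2.0, 0.3, n=n)
        model = fit_decay_model(mat)
        # inflate residual_sd so bands have width to play with
        model.residual_sd = 0.01
        return mat, model

    def test_cell_exactly_on_band_boundary_is_not_an_outlier(self):
        mat, model = self._setup()
        q = norm.ppf(1 - 0.05 / 2)
        x = 10
        boundary = model.predict(float(x))[()] + q * model.residual_sd
        mat.values[5, 5 + x] = mat.values[5 + x, 5] = boundary
        mat.values[20, 20 + x] = mat.values[20 + x, 20] = boundary + 1e-6
        stats = compute_distance_stats(mat)
        cells = detect_outlier_cells(mat, model, stats, DetectionConfig())
        flagged = {(c.i, c.j) for c in cells}
        assert (5, 15) not in flagged
        assert (20, 30) in flagged

    def test_z_filter_is_conjunctive(self):
        mat, model = self._setup()
        x = 10
        stats0 = compute_distance_stats(mat)
        # a bump above the band but < z_threshold sd of its distance class
        mat.values[5, 5 + x] = mat.values[5 + x, 5] = model.predict(float(x))[()] + 0.05
        mat.values[20, 20 + x] = mat.values[20 + x, 20] = model.predict(float(x))[()] + 0.051
        stats = compute_distance_stats(mat)
        assert stats.sd[x] > 0
        band_only = detect_outlier_cells(mat, model, stats, apply_z_filter=False)
        both = detect_outlier_cells(mat, model, stats, apply_z_filter=True)
        assert len(both) <= len(band_only)
        assert {(c.i, c.j) for c in both} <= {(c.i, c.j) for c in band_only}

    def test_depletion_direction_mirrors_excess(self):
        mat, model = self._setup()
        x = 5
        mat.values[8, 8 + x] = mat.values[8 + x, 8] = max(
            model.predict(float(x))[()] - 0.2, 0.0
        )
        stats = compute_distance_stats(mat)
        excess_only = detect_outlier_cells(mat, model, stats, DetectionConfig(direction="excess"))
        both = detect_outlier_cells(mat, model, stats, DetectionConfig(direction="both"))
        assert (8, 13) not in {(c.i, c.j) for c in excess_only}
        assert (8, 13) in {(c.i, c.j) for c in both}
        cell = next(c for c in both if (c.i, c.j) == (8, 13))
        assert cell.z < 0 and cell.excess < 0

    @pytest.mark.parametrize("alpha2,z2", [(0.01, 2.0), (0.05, 3.0), (0.01, 3.0)])
    def test_stricter_settings_never_add_outliers(self, alpha2, z2):
        mat = decay_matrix(-4.0, 2.0, 0.3, n=80, noise=0.2, seed=10)
        model = fit_decay_model(mat)
        stats = compute_distance_stats(mat)
        base = {(c.i, c.j) for c in detect_outlier_cells(
            mat, model, stats, DetectionConfig(alpha=0.05, z_threshold=2.0, direction="both"))}
        strict = {(c.i, c.j) for c in detect_outlier_cells(
            mat, model, stats, DetectionConfig(alpha=alpha2, z_threshold=z2, direction="both"))}
        assert strict <= base


class TestClustering:
    GRID = WindowGrid("chr1", 1_000_000, 10_000)

    def test_single_cell_call_interval(self):
        calls = cluster_candidates([OutlierCell(10, 50, 5.0, 0.1)], self.GRID)
        (call,) = calls
        assert (call.start, call.end) == (100_000, 510_000)
        assert call.breakpoint_a == (10, 11) and call.breakpoint_b == (50, 51)
        assert call.n_cells == 1 and call.peak_z == 5.0

    def test_diagonally_adjacent_cells_merge(self):
        cells = [OutlierCell(10, 50, 3.0, 0.1), OutlierCell(11, 51, 4.0, 0.2)]
        calls = cluster_candidates(cells, self.GRID)
        assert len(calls) == 1
        assert calls[0].n_cells == 2 and calls[0].peak_z == 4.0
        assert calls[0].breakpoint_a == (10, 12)

    def test_separated_cells_stay_separate(self):
        cells = [OutlierCell(10, 50, 3.0, 0.1), OutlierCell(10, 54, 3.0, 0.1)]
        assert len(cluster_candidates(cells, self.GRID)) == 2

    def test_cluster_gap_bridges_larger_separations(self):
        cells = [OutlierCell(10, 50, 3.0, 0.1), OutlierCell(10, 53, 3.0, 0.1)]
        cfg = DetectionConfig(cluster_gap=3)
        assert len(cluster_candidates(cells, self.GRID, cfg)) == 1

    def test_no_cells_no_calls(self):
        assert cluster_candidates([], self.GRID) == []


def _call(chrom, start, end):
    return CandidateSV(chrom, start, end, (0, 1), (0, 1), 1, 1.0, 0.1)


class TestReciprocalIntersection:
    def test_identical_intervals_are_shared(self):
        parts = intersect_reciprocal([_call("c", 0, 100)], [_call("c", 0, 100)])
        assert len(parts["shared"]) == 1 and not parts["specific"]

    def test_half_overlap_is_specific(self):
        parts = intersect_reciprocal([_call("c", 0, 100)], [_call("c", 50, 150)])
        assert not parts["shared"] and len(parts["specific"]) == 1

    def test_nested_interval_meets_both_fractions(self):
        parts = intersect_reciprocal([_call("c", 0, 100)], [_call("c", 10, 90)])
        assert len(parts["shared"]) == 1  # 80 >= 0.8*100 and >= 0.8*80

    def test_chromosomes_do_not_mix(self):
        parts = intersect_reciprocal([_call("c1", 0, 100)], [_call("c2", 0, 100)])
        assert not parts["shared"]

    def test_agrees_with_bedtools_reciprocal_semantics(self, tmp_path):
        rng = np.random.default_rng(12)
        a = [_call("chr1", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 10_000, 20), rng.integers(50, 2_000, 20))]
        b = [_call("chr1", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 10_000, 20), rng.integers(50, 2_000, 20))]
        fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
        fa.write_text("".join(f"chr1\t{c.start}\t{c.end}\n" for c in sorted(a, key=lambda c: c.start)))
        fb.write_text("".join(f"chr1\t{c.start}\t{c.end}\n" for c in sorted(b, key=lambda c: c.start)))
        try:
            out = subprocess.run(
                ["bedtools", "intersect", "-a", fa, "-b", fb, "-f", "0.8", "-F", "0.8", "-u"],
                capture_output=True, text=True, check=True,
            ).stdout
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("bedtools unavailable")
        expected = {tuple(map(int, line.split("\t")[1:3])) for line in out.splitlines()}
        parts = intersect_reciprocal(a, b, min_fraction=0.8)
        got = {(c.start, c.end) for c in parts["shared"]}
        assert got == expected


def test_bed_writer_reader_roundtrip(tmp_path):
    calls = [_call("chr1", 1000, 5000), _call("chr1", 9000, 12_000)]
    path = tmp_path / "calls.bed"
    write_calls_bed(calls, path)
    back = read_calls_bed(path)
    assert [(c.chrom, c.start, c.end) for c in back] == [
        ("chr1", 1000, 5000), ("chr1", 9000, 12_000)
    ]
    assert (tmp_path / "calls.bed.tsv").exists()
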