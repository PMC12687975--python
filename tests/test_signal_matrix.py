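import math

import numpy as np
import pytest

from panmod.classifier import gene_zones
from panmod.genome_io import GeneModel, GenomicInterval, SignalTrack
from panmod.signal_matrix import (
    SignalMatrix,
    body_signal_summary,
    compute_matrix,
    estimate_elongation_rate,
    log2_compare,
    read_matrix,
    sort_by_region_length,
    wavefront_estimate,
    write_matrix,
)
from panmod.synthetic_data import SimulationConfig, gen_annotation, gen_runoff_tracks

from oracles import brute_force_bin_mean, reflect_gene


def constant_track(value, start=0, end=100_000, chrom="chr1"):
    return SignalTrack.from_runs([(chrom, start, end, value)])


class TestLog2Compare:
    def test_identical_tracks_give_zero_everywhere(self):
        t = SignalTrack.from_runs([("chr1", 0, 100, 4.0), ("chr1", 200, 300, 1.5)])
        result = log2_compare(t, t)
        assert result.mean_over("chr1", 0, 300) == 0.0

    def test_hand_arithmetic(self):
        t = constant_track(4.0, 0, 100)
        c = constant_track(1.0, 0, 100)
        result = log2_compare(t, c, pseudocount=1.0)
        assert result.mean_over("chr1", 0, 100) == pytest.approx(
            math.log2(5 / 2)
        )

    def test_uncovered_positions_stay_zero(self):
        t = constant_track(2.0, 50, 100)
        c = constant_track(2.0, 50, 100)
        result = log2_compare(t, c)
        assert result.mean_over("chr1", 0, 50) == 0.0

    def test_negative_values_rejected(self):
        t = SignalTrack.from_runs([("chr1", 0, 10, -1.0)])
        with pytest.raises(ValueError, match="negative"):
            log2_compare(t, constant_track(1.0, 0, 10))

    def test_antisymmetric_under_swap(self, rng):
        runs_t = [("chr1", int(s), int(s) + 50, float(v)) for s, v in
                  zip(range(0, 500, 100), rng.uniform(0, 8, 5))]
        runs_c = [("chr1", int(s) + 25, int(s) + 60, float(v)) for s, v in
                  zip(range(0, 500, 100), rng.uniform(0, 8, 5))]
        a = log2_compare(SignalTrack.from_runs(runs_t), SignalTrack.from_runs(runs_c))
        b = log2_compare(SignalTrack.from_runs(runs_c), SignalTrack.from_runs(runs_t))
        for lo in range(0, 560, 7):
            assert a.mean_over("chr1", lo, lo + 7) == pytest.approx(
                -b.mean_over("chr1", lo, lo + 7)
            )


def _gene(gid, start, end, strand):
    return GeneModel(gid, GenomicInterval("chr1", start, end, strand))


class TestComputeMatrix:
    def test_constant_track_gives_constant_bins(self):
        genes = [_gene("a", 30_000, 50_000, "+"), _gene("b", 30_000, 50_000, "-")]
        mat = compute_matrix(
            constant_track(2.0, 0, 200_000),
            genes,
            upstream=2_000,
            downstream=10_000,
            bin_size=100,
        )
        assert np.allclose(mat.values[np.isfinite(mat.values)], 2.0)
        assert not np.isnan(mat.values).any()

    def test_minus_strand_orientation(self):
        # signal only 3' of the minus-strand TSS in transcription direction
        # (genomically left of the TSS): downstream bins 1, upstream bins 0
        gene = _gene("g", 10_000, 50_000, "-")
        track = constant_track(1.0, 0, 50_000)  # covers the gene, not beyond
        mat = compute_matrix(track, [gene], upstream=2_000, downstream=10_000,
                             bin_size=100)
        n_up = 2_000 // 100
        assert np.allclose(mat.values[0, n_up:], 1.0)
        # upstream of the TSS (genomically right of 50_000) is uncovered
        assert np.allclose(mat.values[0, : n_up - 1], 0.0)

    def test_bin_straddling_two_runs_is_weighted_mean(self):
        track = SignalTrack.from_runs(
            [("chr1", 10_000, 10_050, 0.0), ("chr1", 10_050, 10_100, 2.0)]
        )
        gene = _gene("g", 10_000, 20_000, "+")
        mat = compute_matrix(track, [gene], upstream=0, downstream=200, bin_size=100)
        assert mat.values[0, 0] == pytest.approx(1.0)

    def test_out_of_chromosome_bins_are_missing(self):
        gene = _gene("g", 1_000, 9_000, "+")
        mat = compute_matrix(
            constant_track(1.0, 0, 10_000),
            [gene],
            upstream=2_000,
            downstream=10_000,
            bin_size=100,
            chrom_lengths={"chr1": 10_000},
        )
        # window spans genomic [-1000, 11000): bins below 0 and past the
        # 10 kb chromosome end are missing
        assert np.isnan(mat.values[0, :10]).all()
        assert np.isfinite(mat.values[0, 10:110]).all()
        assert np.isnan(mat.values[0, 110:]).all()

    def test_matches_per_base_oracle(self, rng):
        runs = []
        pos = 0
        while pos < 9_000:
            width = int(rng.integers(20, 400))
            if rng.random() < 0.6:
                runs.append(("chr1", pos, min(pos + width, 10_000),
                             float(rng.uniform(0, 5))))
            pos += width
        track = SignalTrack.from_runs(runs)
        genes = [_gene("p", 3_000, 6_000, "+"), _gene("m", 3_000, 6_000, "-")]
        mat = compute_matrix(track, genes, upstream=500, downstream=2_000,
                             bin_size=50)
        for row, gene in zip(mat.values, genes):
            for j, value in enumerate(row):
                offset = -500 + j * 50
                if gene.strand == "+":
                    lo = gene.tss + offset
                    hi = lo + 50
                else:
                    hi = gene.tss - offset + 1
                    lo = hi - 50
                expected = brute_force_bin_mean(runs, "chr1", lo, hi, 12_000)
                assert value == pytest.approx(expected), (gene.strand, j)

    def test_mirror_invariance(self, rng):
        runs = [("chr1", int(s), int(s + 80), float(v))
                for s, v in zip(range(2_000, 8_000, 200), rng.uniform(0, 4, 30))]
        track = SignalTrack.from_runs(runs)
        genes = [_gene("p", 3_000, 6_000, "+"), _gene("m", 2_500, 7_000, "-")]
        mat = compute_matrix(track, genes, upstream=500, downstream=2_500,
                             bin_size=50)
        pivot = 20_000
        mirrored_track = SignalTrack.from_runs(
            [("chr1", pivot - e, pivot - s, v) for _, s, e, v in runs]
        )
        mirrored = compute_matrix(
            mirrored_track,
            [reflect_gene(g, pivot) for g in genes],
            upstream=500,
            downstream=2_500,
            bin_size=50,
        )
        np.testing.assert_allclose(mirrored.values, mat.values)


class TestSortByRegionLength:
    def _matrix(self, lengths, ids=None):
        n = len(lengths)
        ids = ids or [f"g{i}" for i in range(n)]
        return SignalMatrix(
            gene_ids=tuple(ids),
            gene_lengths=np.array(lengths),
            bin_size=100,
            upstream=0,
            downstream=300,
            values=np.arange(n * 3, dtype=float).reshape(n, 3),
        )

    def test_ascending(self):
        mat = sort_by_region_length(self._matrix([30_000, 10_000, 20_000]))
        assert list(mat.gene_lengths) == [10_000, 20_000, 30_000]
        assert mat.gene_ids == ("g1", "g2", "g0")

    def test_stable_for_ties(self):
        mat = sort_by_region_length(self._matrix([5_000, 5_000, 1_000]))
        assert mat.gene_ids == ("g2", "g0", "g1")

    def test_descending_reverses_distinct_lengths(self):
        base = self._matrix([3, 1, 2])
        up = sort_by_region_length(base, ascending=True)
        down = sort_by_region_length(base, ascending=False)
        assert down.gene_ids == tuple(reversed(up.gene_ids))


class TestBodySignalSummary:
    def test_constant_track(self, plus_gene):
        zones = gene_zones(plus_gene)
        assert body_signal_summary(constant_track(3.0), zones) == pytest.approx(3.0)

    def test_half_and_half(self, plus_gene):
        zones = gene_zones(plus_gene)
        body = zones.body[0]
        mid = (body.start + body.end) // 2
        track = SignalTrack.from_runs(
            [("chr1", body.start, mid, 0.0), ("chr1", mid, body.end, 4.0)]
        )
        expected = 4.0 * (body.end - mid) / len(body)
        assert body_signal_summary(track, zones) == pytest.approx(expected)

    def test_empty_body_is_missing(self):
        gene = GeneModel("g", GenomicInterval("chr1", 1_000, 1_100, "+"))
        zones = gene_zones(gene)
        assert math.isnan(body_signal_summary(constant_track(1.0), zones))


class TestWavefront:
    def test_step_profile(self):
        profile = np.concatenate([np.zeros(100), np.ones(100)])
        assert wavefront_estimate(profile, bin_size=100) == pytest.approx(10_000)

    def test_flat_profile_has_no_front(self):
        assert math.isnan(wavefront_estimate(np.ones(100)))

    def test_fully_cleared_profile_has_no_front(self):
        assert math.isnan(wavefront_estimate(np.zeros(100)))

    def test_simulated_runoff_front_within_one_bin(self):
        config = SimulationConfig(
            seed=11,
            n_genes=30,
            gene_length_bounds=(30_000, 80_000),
            track_noise_sd=0.0,
            inhibition_times=(5.0,),
        )
        annotation = gen_annotation(config)
        tracks = gen_runoff_tracks(annotation.genes, config)
        control = compute_matrix(tracks.control, annotation.genes)
        treated = compute_matrix(tracks.inhibition[5.0], annotation.genes)
        ctrl = control.downstream_slice()
        rel = treated.downstream_slice() / np.where(ctrl > 1.0, ctrl, np.nan)
        fronts = [wavefront_estimate(row, bin_size=100) for row in rel]
        fronts = [f for f in fronts if np.isfinite(f)]
        assert fronts, "expected at least one gene with a resolvable front"
        expected = config.elongation_rate * 5.0
        assert all(abs(f - expected) <= 100 for f in fronts)


def test_rate_regression_recovers_slope():
    fronts = {5.0: [10_050, 9_950], 15.0: [30_100, 29_900], 30.0: [60_000]}
    rate, intercept = estimate_elongation_rate(fronts)
    assert rate == pytest.approx(2_000, rel=0.01)
    assert intercept == pytest.approx(0, abs=200)


def test_rate_regression_needs_two_time_points():
    with pytest.raises(ValueError):
        estimate_elongation_rate({5.0: [10_000]})


def test_matrix_file_round_trip(tmp_path, rng):
    values = rng.uniform(-2, 2, size=(4, 30))
    values[0, :3] = np.nan
    mat = SignalMatrix(
        gene_ids=("a", "b", "c", "d"),
        gene_lengths=np.array([100, 400, 200, 300]),
        bin_size=100,
        upstream=1_000,
        downstream=2_000,
        values=values,
    )
    path = tmp_path / "matrix.tsv.gz"
    write_matrix(mat, path)
    back = read_matrix(path)
    assert back.gene_ids == mat.gene_ids
    assert list(back.gene_lengths) == list(mat.gene_lengths)
    np.testing.assert_allclose(back.values, mat.values)
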