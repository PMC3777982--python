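"""Comparison statistics: sparse-track correlation and binned correlation."""

import numpy as np
import pandas as pd
import pytest

from epichain import (GenomicMapping, NucleationLayout, OccupancyProfile,
                      RateParams, ScoreTrack, SimulationConfig,
                      UndefinedCorrelationError, bin_track,
                      binned_correlation, correlation_eq1, correlation_matrix,
                      fit_grid, project_to_units, random_layout,
                      read_score_track, run_simulation, write_score_track)


def make_profile(x, n_marks=2):
    """Occupancy profile with mark-1 values x (and zeros for mark 2)."""
    x = np.asarray(x, dtype=float)
    occ = np.zeros((n_marks, x.size))
    occ[0] = x
    return OccupancyProfile(occupancy=occ, global_series=np.zeros((1, n_marks), dtype=np.int64),
                            n_units=x.size, n_marks=n_marks, measure_steps=1,
                            record_stride=1, final_state=np.zeros(x.size, dtype=np.int8))


def track_at_units(units, scores, mapping, mark="t"):
    rows = [(*mapping.unit_span(j), s) for j, s in zip(units, scores)]
    return ScoreTrack(mark=mark, chromosome=mapping.chromosome,
                      records=pd.DataFrame(rows, columns=["start", "end", "score"]))


MAP4 = GenomicMapping("chr1", 400, 100)


class TestSparseTrackCorrelation:
    def test_hand_computed_four_point_pearson(self):
        profile = make_profile([0.1, 0.2, 0.3, 0.4])
        up = track_at_units([0, 1, 2, 3], [1, 2, 3, 4], MAP4)
        down = track_at_units([0, 1, 2, 3], [4, 3, 2, 1], MAP4)
        assert correlation_eq1(profile, 1, up, MAP4) == pytest.approx(1.0)
        assert correlation_eq1(profile, 1, down, MAP4) == pytest.approx(-1.0)

    def test_restricted_to_detected_units(self):
        # undetected units carry no information: only units 0 and 2 count
        profile = make_profile([0.1, 0.9, 0.2, 0.9])
        track = track_at_units([0, 2], [1.0, 2.0], MAP4)
        r = correlation_eq1(profile, 1, track, MAP4)
        assert r == pytest.approx(1.0)  # (0.1, 0.2) vs (1, 2)

    def test_constant_profile_is_undefined_not_zero(self):
        profile = make_profile([0.5, 0.5, 0.5, 0.5])
        track = track_at_units([0, 1, 2], [1.0, 2.0, 3.0], MAP4)
        with pytest.raises(UndefinedCorrelationError):
            correlation_eq1(profile, 1, track, MAP4)

    def test_single_detected_unit_is_undefined(self):
        profile = make_profile([0.1, 0.2, 0.3, 0.4])
        track = track_at_units([2], [1.0], MAP4)
        with pytest.raises(UndefinedCorrelationError):
            correlation_eq1(profile, 1, track, MAP4)

    def test_invariant_under_positive_affine_rescaling(self, rng):
        n = 50
        mapping = GenomicMapping("chr1", n * 100, 100)
        profile = make_profile(rng.random(n))
        units = np.arange(0, n, 2)
        scores = rng.random(units.size) * 5
        base = correlation_eq1(profile, 1, track_at_units(units, scores, mapping), mapping)
        scaled = correlation_eq1(profile, 1,
                                 track_at_units(units, 3.0 * scores + 2.0, mapping), mapping)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_shuffled_signals_nearly_uncorrelated(self, rng):
        n = 2000
        mapping = GenomicMapping("chr1", n * 100, 100)
        profile = make_profile(rng.random(n))
        scores = rng.permutation(rng.random(n))
        track = track_at_units(np.arange(n), scores, mapping)
        r = correlation_eq1(profile, 1, track, mapping)
        assert abs(r) < 0.08  # ~3.5/sqrt(n)

    def test_interval_record_spreads_to_every_overlapped_unit(self):
        mapping = GenomicMapping("chr1", 500, 100)
        track = ScoreTrack(mark="t", chromosome="chr1",
                           records=pd.DataFrame([(150, 420, 2.0)],
                                                columns=["start", "end", "score"]))
        scores, covered = project_to_units(track, mapping)
        assert covered.tolist() == [False, True, True, True, True]
        assert scores.tolist() == [0.0, 2.0, 2.0, 2.0, 2.0]


class TestBinnedTrack:
    def test_toy_bin_sums_by_floor_rule(self):
        mapping = GenomicMapping("chr1", 30, 1)
        track = ScoreTrack(mark="t", chromosome="chr1",
                           records=pd.DataFrame([(5, 6, 2.0), (15, 16, 3.0)],
                                                columns=["start", "end", "score"]))
        binned = bin_track(track, chrom_length=30, bin_width=10)
        assert binned.sums.tolist() == [2.0, 3.0, 0.0]

    def test_total_score_conserved_exactly(self, rng):
        n_rec = 300
        starts = rng.integers(0, 999_000, size=n_rec)
        records = pd.DataFrame({"start": starts, "end": starts + 500,
                                "score": rng.random(n_rec) * 7})
        track = ScoreTrack(mark="t", chromosome="chr1", records=records)
        binned = bin_track(track, chrom_length=1_000_000)
        assert binned.sums.sum() == pytest.approx(track.total_score, rel=1e-12)

    def test_empty_track_gives_zero_bins(self):
        track = ScoreTrack(mark="t", chromosome="chr1",
                           records=pd.DataFrame(columns=["start", "end", "score"]))
        binned = bin_track(track, chrom_length=250_000)
        assert binned.sums.tolist() == [0.0, 0.0, 0.0]

    def test_zero_bin_exclusion_matches_enumeration(self):
        a = type("B", (), {})
        from epichain.compare import BinnedTrack
        a = BinnedTrack("a", "chr1", 10, np.array([1.0, 0.0, 2.0, 4.0]))
        b = BinnedTrack("b", "chr1", 10, np.array([2.0, 5.0, 4.0, 8.0]))
        r, n_used = binned_correlation(a, b)
        assert n_used == 3  # bins 0, 2, 3 retained by hand enumeration
        expected = np.corrcoef([1, 2, 4], [2, 4, 8])[0, 1]
        assert r == pytest.approx(expected)

    def test_self_correlation_is_one(self):
        from epichain.compare import BinnedTrack
        a = BinnedTrack("a", "chr1", 10, np.array([1.0, 2.0, 3.0]))
        r, n_used = binned_correlation(a, a)
        assert r == pytest.approx(1.0) and n_used == 3

    def test_too_few_retained_bins_undefined(self):
        from epichain.compare import BinnedTrack
        a = BinnedTrack("a", "chr1", 10, np.array([1.0, 0.0, 0.0]))
        b = BinnedTrack("b", "chr1", 10, np.array([1.0, 1.0, 0.0]))
        with pytest.raises(UndefinedCorrelationError):
            binned_correlation(a, b)

    def test_mismatched_tilings_rejected(self):
        from epichain.compare import BinnedTrack
        a = BinnedTrack("a", "chr1", 10, np.array([1.0, 2.0]))
        b = BinnedTrack("b", "chr1", 20, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            binned_correlation(a, b)


class TestAntagonisticDomains:
    def test_competing_marks_anticorrelate_in_coarse_bins(self):
        """Heterochromatin and euchromatin tracks from one simulation oppose
        each other when summed into coarse bins."""
        from epichain import TrackNoiseModel, make_synthetic_track

        n = 4000
        mapping = GenomicMapping("chrS", n * 100, 100)
        layout = NucleationLayout(
            n, {1: np.arange(100, 1900, 60), 2: np.arange(2100, 3900, 60)})
        rates = RateParams(p_a=0.1, p_d=0.01, p_s=0.1)
        config = SimulationConfig(seed=3, total_steps=4000, measure_steps=2000,
                                  record_stride=20)
        profile = run_simulation(config, n, layout, rates)
        tracks = [make_synthetic_track(profile, mark, mapping,
                                       TrackNoiseModel(q=0.4, seed=mark))
                  for mark in (1, 2)]
        binned = [bin_track(t, mapping.chrom_length, bin_width=10_000)
                  for t in tracks]
        r, n_used = binned_correlation(*binned)
        assert r < -0.3
        assert n_used >= 2

        same = [make_synthetic_track(profile, 1, mapping,
                                     TrackNoiseModel(q=0.4, seed=s))
                for s in (10, 11)]
        r_same, _ = binned_correlation(
            *[bin_track(t, mapping.chrom_length, bin_width=10_000) for t in same])
        assert r_same > 0.3

    def test_correlation_matrix_layout(self):
        from epichain.compare import BinnedTrack
        a = BinnedTrack("h1", "c", 10, np.array([1.0, 2.0, 3.0]))
        b = BinnedTrack("h2", "c", 10, np.array([2.0, 4.0, 6.0]))
        mat = correlation_matrix([a, b])
        assert mat.loc["h1", "h2"] == pytest.approx(1.0)
        assert mat.loc["h1", "h1"] == 1.0


class TestFitGrid:
    def test_degenerate_single_cell_grid(self):
        n = 500
        mapping = GenomicMapping("chrS", n * 100, 100)
        layout = random_layout(n, 12, rng=np.random.default_rng(0))
        config = SimulationConfig(seed=5, total_steps=1500, measure_steps=500,
                                  record_stride=10)
        profile = run_simulation(config, n, layout,
                                 RateParams(p_a=0.05, p_d=0.01, p_s=0.1))
        from epichain import TrackNoiseModel, make_synthetic_track
        track = make_synthetic_track(profile, 1, mapping,
                                     TrackNoiseModel(q=0.5, seed=1), label="h")
        grid = fit_grid(config, layout, mapping, {1: [track]},
                        p_a_values=[0.05], p_d_values=[0.01],
                        p_s1_values=[0.1], p_s2=0.1)
        assert len(grid) == 1
        assert {"r_h", "good_match", "mean_r"} <= set(grid.columns)

    def test_out_of_range_grid_rejected(self):
        mapping = GenomicMapping("chrS", 1000, 100)
        layout = random_layout(10, 2, rng=np.random.default_rng(0))
        config = SimulationConfig(seed=0, total_steps=10, measure_steps=5)
        with pytest.raises(ValueError):
            fit_grid(config, layout, mapping, {}, [1.5], [0.01], [0.1])


class TestTrackIO:
    def test_bedgraph_round_trip(self, tmp_path):
        track = ScoreTrack(mark="h", chromosome="chr2",
                           records=pd.DataFrame([(0, 100, 1.5), (300, 400, 2.0)],
                                                columns=["start", "end", "score"]))
        path = tmp_path / "t.bedgraph"
        write_score_track(track, path)
        again = read_score_track(path, mark="h", chromosome="chr2")
        assert np.allclose(again.records["score"], track.records["score"])

    def test_bed_with_score_uses_fifth_column(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("track type=bed\nchr1\t0\t100\tpeak1\t7.5\t+\n")
        track = read_score_track(path, mark="x")
        assert track.records.iloc[0]["score"] == 7.5

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            ScoreTrack(mark="x", chromosome="c",
                       records=pd.DataFrame([(0, 10, -1.0)],
                                            columns=["start", "end", "score"]))
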