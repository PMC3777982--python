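"""Time-evolution driver: profiles, global statistics, scans."""

import numpy as np
import pandas as pd
import pytest

from epichain import (GenomicMapping, NucleationLayout, RateParams,
                      SimulationConfig, global_stats, random_layout,
                      run_simulation, scan_parameter, write_profile_bedgraph,
                      write_profile_tsv)
from epichain.simulate import OccupancyProfile


class TestConfigValidation:
    def test_measure_must_not_exceed_total(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, total_steps=10, measure_steps=11)

    def test_positive_stride_required(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, total_steps=10, measure_steps=5, record_stride=0)


class TestRunSimulation:
    def test_no_nucleation_means_zero_occupancy(self, small_layout):
        rates = RateParams(p_a=0.0, p_d=0.3, p_s=0.9)
        profile = run_simulation(SimulationConfig(seed=1, total_steps=200, measure_steps=100),
                                 6, small_layout, rates)
        assert np.all(profile.occupancy == 0.0)
        assert np.all(profile.global_series == 0)

    def test_two_state_closed_form_isolated_site(self):
        # single unit nucleating mark 1 with p_s=0: occupancy p_a/(p_a+p_d)
        layout = NucleationLayout(1, {1: [0]})
        rates = RateParams(p_a=0.05, p_d=0.05, p_s=0.0)
        config = SimulationConfig(seed=2, total_steps=220_000, measure_steps=200_000)
        profile = run_simulation(config, 1, layout, rates)
        assert profile.occupancy[0, 0] == pytest.approx(0.5, abs=0.02)
        assert profile.occupancy[1, 0] == 0.0

    def test_occupancy_bounds_and_exclusivity(self, small_layout, default_rates):
        profile = run_simulation(SimulationConfig(seed=3, total_steps=500, measure_steps=400),
                                 6, small_layout, default_rates)
        assert np.all(profile.occupancy >= 0) and np.all(profile.occupancy <= 1)
        # a site is one mark at a time, so summed occupancies cannot exceed 1
        assert np.all(profile.occupancy.sum(axis=0) <= 1 + 1e-12)

    def test_deterministic_given_seed(self, small_layout, default_rates):
        config = SimulationConfig(seed=7, total_steps=300, measure_steps=100)
        a = run_simulation(config, 6, small_layout, default_rates)
        b = run_simulation(config, 6, small_layout, default_rates)
        assert np.array_equal(a.occupancy, b.occupancy)
        assert np.array_equal(a.global_series, b.global_series)

    def test_burn_in_doubling_leaves_estimate_within_noise(self):
        layout = NucleationLayout(4, {1: [0], 2: [3]})
        rates = RateParams(p_a=0.3, p_d=0.3, p_s=0.4)
        short = run_simulation(SimulationConfig(seed=5, total_steps=60_000,
                                                measure_steps=50_000),
                               4, layout, rates)
        long = run_simulation(SimulationConfig(seed=6, total_steps=70_000,
                                               measure_steps=50_000),
                              4, layout, rates)
        assert np.abs(short.occupancy - long.occupancy).max() < 0.02

    def test_mirror_symmetry_of_occupancy(self):
        # mirrored layouts and symmetric rates: x̄_2 reversed matches x̄_1
        n = 9
        layout = NucleationLayout(n, {1: [1, 4], 2: [4, 7]})
        rates = RateParams(p_a=0.3, p_d=0.2, p_s=0.3)
        profile = run_simulation(SimulationConfig(seed=8, total_steps=120_000,
                                                  measure_steps=100_000),
                                 n, layout, rates)
        assert np.allclose(profile.occupancy[0],
                           profile.occupancy[1][::-1], atol=0.02)


class TestGlobalStats:
    def make_profile(self, series, n_units):
        series = np.asarray(series, dtype=np.int64)
        return OccupancyProfile(occupancy=np.zeros((2, n_units)),
                                global_series=series, n_units=n_units,
                                n_marks=2, measure_steps=series.shape[0],
                                record_stride=1,
                                final_state=np.zeros(n_units, dtype=np.int8))

    def test_constant_series_has_zero_fluctuation(self):
        stats = global_stats(self.make_profile([[3, 1]] * 10, 10))
        assert stats.loc[stats["mark"] == 1, "fluctuation"].item() == pytest.approx(0.0, abs=1e-12)
        assert stats.loc[stats["mark"] == 1, "mean_frequency"].item() == pytest.approx(0.3)

    def test_two_sample_mean(self):
        stats = global_stats(self.make_profile([[0, 0], [1, 0]], 1))
        assert stats.loc[stats["mark"] == 1, "mean_frequency"].item() == pytest.approx(0.5)

    def test_alternating_saturated_series_maximizes_fluctuation(self):
        stats = global_stats(self.make_profile([[0, 0], [4, 0]] * 5, 4))
        row = stats[stats["mark"] == 1].iloc[0]
        # sd of a {0,1} series with mean 1/2 is exactly 1/2, the variance bound
        assert row["fluctuation"] == pytest.approx(0.5)

    def test_empty_series_rejected(self):
        profile = self.make_profile(np.zeros((0, 2)), 4)
        with pytest.raises(ValueError):
            global_stats(profile)


class TestScanParameter:
    def test_single_value_single_replicate(self, small_layout, default_rates):
        config = SimulationConfig(seed=1, total_steps=200, measure_steps=100)
        table = scan_parameter(config, 6, small_layout, default_rates,
                               "p_d", [0.2], replicates=1)
        assert len(table) == 2  # one row per mark
        assert set(table.columns) >= {"param", "value", "replicate", "mark",
                                      "mean_frequency", "fluctuation"}

    def test_unknown_parameter_rejected(self, small_layout, default_rates):
        config = SimulationConfig(seed=1, total_steps=10, measure_steps=5)
        with pytest.raises(ValueError):
            scan_parameter(config, 6, small_layout, default_rates, "p_x", [0.1])

    def test_scan_reproducible_as_a_whole(self, small_layout, default_rates):
        config = SimulationConfig(seed=42, total_steps=100, measure_steps=50)
        a = scan_parameter(config, 6, small_layout, default_rates,
                           "p_s,1", [0.1, 0.5], replicates=2)
        b = scan_parameter(config, 6, small_layout, default_rates,
                           "p_s,1", [0.1, 0.5], replicates=2)
        pd.testing.assert_frame_equal(a, b)

    def test_mark1_frequency_monotone_in_its_propagation_rate(self):
        # coarse monotonicity at desk scale, tolerant to sampling noise
        layout = random_layout(300, 12, rng=np.random.default_rng(9))
        rates = RateParams(p_a=0.1, p_d=0.05, p_s=[0.1, 0.1])
        config = SimulationConfig(seed=17, total_steps=6000, measure_steps=3000,
                                  record_stride=10)
        table = scan_parameter(config, 300, layout, rates, "p_s,1",
                               [0.02, 0.1, 0.3], replicates=2)
        means = (table[table["mark"] == 1]
                 .groupby("value")["mean_frequency"].mean().sort_index())
        assert means.is_monotonic_increasing


class TestWriters:
    def test_profile_tsv_and_bedgraph_parse_back(self, tmp_path, small_layout,
                                                 default_rates):
        profile = run_simulation(SimulationConfig(seed=4, total_steps=300,
                                                  measure_steps=200),
                                 6, small_layout, default_rates)
        tsv = tmp_path / "profile.tsv"
        write_profile_tsv(profile, tsv)
        df = pd.read_csv(tsv, sep="\t")
        assert list(df.columns) == ["unit", "x_mark1", "x_mark2"]
        assert np.allclose(df["x_mark1"], profile.occupancy[0], atol=1e-6)

        mapping = GenomicMapping("chrZ", 600, 100)
        bg = tmp_path / "m1.bedgraph"
        write_profile_bedgraph(profile, mapping, bg, mark=1)
        back = pd.read_csv(bg, sep="\t", header=None,
                           names=["chrom", "start", "end", "value"])
        assert (back["end"] - back["start"]).eq(100).all()
        assert np.allclose(back["value"], profile.occupancy[0], atol=1e-6)
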