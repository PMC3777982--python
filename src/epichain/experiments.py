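"""Packaged validation experiments shared by the test suite and scripts.

Each function runs one of the package's headline computations end to end at
a stated desk-scale geometry and returns plain numbers. Problem sizes are
chosen so the full battery completes on a single CPU in minutes; the
methods note discusses what the scaled-down geometries do and do not probe.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .chain import RateParams
from .compare import correlation_eq1
from .nucleation import GenomicMapping, random_layout, shift_sites
from .simulate import SimulationConfig, run_simulation, scan_parameter
from .synthetic import TrackNoiseModel, make_synthetic_track
from .validation import simulator_vs_oracle

# the fitted-regime rates used throughout the chromosome-style experiments
REGIME_RATES = dict(p_a=0.05, p_d=0.01)

# switch-scan geometry: 10,000 units, 100 random nucleation sites per mark
SWITCH_N = 10_000
SWITCH_SITES = 100
SWITCH_VALUES = (0.05, 0.08, 0.1, 0.12, 0.16)


def oracle_battery(seed: int, n_configs: int = 20,
                   measure_steps: int = 200_000) -> pd.DataFrame:
    """Simulator-vs-oracle comparisons over random tiny-chain configurations.

    Chain lengths cycle through 2..8; layouts and rates are drawn per
    configuration (deletion and association rates kept away from 0 so the
    chain is irreducible and mixes within the measurement window).

    With roughly two hundred site-level comparisons, a correct simulator is
    expected to produce the occasional marginal exceedance of a 3-standard-
    error band purely by multiplicity. A configuration whose worst deviation
    exceeds 3 SE is therefore re-measured with four times the data and an
    independent trajectory seed; the re-measured deviation (recorded in
    ``max_dev_se_final``) is the one that must fall within the band. For a
    correct kernel the probability that a flagged site fails again is the
    nominal 0.3%.
    """
    rows = []
    children = np.random.SeedSequence(seed).spawn(n_configs)
    for i, child in enumerate(children):
        n_units = 2 + i % 7
        cfg_seed = int(child.generate_state(1)[0] % (2**31))
        sites = 1 + (i % n_units)
        report = simulator_vs_oracle(n_units=n_units, sites_per_mark=sites,
                                     seed=cfg_seed,
                                     measure_steps=measure_steps)
        report["escalated"] = False
        report["max_dev_se_final"] = report["max_dev_se"]
        if report["max_dev_se"] > 3.0:
            rerun = simulator_vs_oracle(n_units=n_units, sites_per_mark=sites,
                                        seed=cfg_seed,
                                        measure_steps=4 * measure_steps,
                                        sim_seed=cfg_seed + 1)
            report["escalated"] = True
            report["max_dev_se_final"] = rerun["max_dev_se"]
            report["max_abs_dev"] = rerun["max_abs_dev"]
        rows.append(report)
    return pd.DataFrame(rows)


def closed_form_occupancy(seed: int, p_a: float = 0.05, p_d: float = 0.05,
                          measure_steps: int = 200_000) -> Dict[str, float]:
    """Isolated nucleation site with no propagation: occupancy p_a/(p_a+p_d)."""
    from .nucleation import NucleationLayout

    layout = NucleationLayout(1, {1: [0]})
    rates = RateParams(p_a=p_a, p_d=p_d, p_s=0.0)
    config = SimulationConfig(seed=seed, total_steps=measure_steps + 20_000,
                              measure_steps=measure_steps)
    profile = run_simulation(config, 1, layout, rates)
    return {
        "measured": float(profile.occupancy[0, 0]),
        "expected": p_a / (p_a + p_d),
    }


def switch_scan(seed: int, param: str = "p_s,1",
                values: Sequence[float] = SWITCH_VALUES,
                p_s1_fixed: float = 0.1,
                total_steps: int = 400_000,
                measure_steps: int = 100_000) -> pd.DataFrame:
    """Propagation-rate (or association-rate) scan at the switch geometry.

    Burn-in is long (300,000 sweeps by default) because domain walls move
    only through rare deletion events near the transition; the mark-1 table
    returned has one row per scanned value.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    layout = random_layout(SWITCH_N, SWITCH_SITES, rng=rng)
    rates = RateParams(p_a=REGIME_RATES["p_a"], p_d=REGIME_RATES["p_d"],
                       p_s=[p_s1_fixed, 0.1])
    config = SimulationConfig(seed=seed, total_steps=total_steps,
                              measure_steps=measure_steps, record_stride=10)
    table = scan_parameter(config, SWITCH_N, layout, rates, param,
                           list(values), replicates=1)
    return (table[table["mark"] == 1]
            .sort_values("value").reset_index(drop=True))


def layout_sensitivity(seed: int, n_seeds: int = 5, shift: int = 500,
                       total_steps: int = 15_000,
                       measure_steps: int = 5_000) -> pd.DataFrame:
    """Sparse-track correlation with the true layout vs a shifted copy.

    For each replicate: simulate on a random layout, emit a sparse noisy
    track from the mark-1 profile, re-simulate on the layout shifted by
    ``shift`` units (many domain widths), and correlate both profiles
    against the track.
    """
    rows = []
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    mapping = GenomicMapping("chrS", SWITCH_N * 100, 100)
    rates = RateParams(p_a=REGIME_RATES["p_a"], p_d=REGIME_RATES["p_d"],
                       p_s=[0.1, 0.1])
    for child in children:
        s = int(child.generate_state(1)[0] % (2**31))
        layout = random_layout(SWITCH_N, SWITCH_SITES,
                               rng=np.random.default_rng(child))
        config = SimulationConfig(seed=s, total_steps=total_steps,
                                  measure_steps=measure_steps, record_stride=10)
        profile = run_simulation(config, SWITCH_N, layout, rates)
        track = make_synthetic_track(
            profile, 1, mapping,
            TrackNoiseModel(q=0.3, scale=10.0, noise_sd=1.0, seed=s + 1))
        shifted = shift_sites(shift_sites(layout, 1, shift), 2, shift)
        profile_shifted = run_simulation(config, SWITCH_N, shifted, rates)
        rows.append({
            "seed": s,
            "r_true": correlation_eq1(profile, 1, track, mapping),
            "r_shifted": correlation_eq1(profile_shifted, 1, track, mapping),
        })
    return pd.DataFrame(rows)


def bin_capacity(bp_per_unit: int = 100, bin_width: int = 100_000) -> int:
    """Nucleosomal units per coarse bin under the genomic mapping."""
    mapping = GenomicMapping("chr1", bin_width, bp_per_unit)
    return mapping.n_units
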