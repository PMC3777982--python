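"""Synthetic score tracks and packaged end-to-end fixtures.

Real comparison inputs are CCAT-style significance tracks: nonnegative
scores at a sparse subset of positions, with everything below the caller's
evidence threshold simply absent. The generator emulates that structure
from a known simulated occupancy profile: each chain unit is independently
retained with detection probability ``q`` (default 0.3, matching the
"rather sparse" character of heterochromatin tracks), and a retained unit
emits ``max(0, scale * x̄ + noise)`` over its genomic span, with truncated
normal noise on the score scale. What the generator does NOT emulate:
read-level sampling, fragment-size smoothing, or the spatial correlation of
a real peak caller's window statistics — so tests built on these tracks
probe the comparison machinery and layout sensitivity, not caller behavior.

Fixtures are self-contained directories (chrom.sizes, per-mark nucleation
BEDs, bedGraph tracks, plus a plain key-value manifest recording every
generator parameter and seed) that the CLI can re-run end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .chain import RateParams
from .compare import ScoreTrack, write_score_track
from .nucleation import (GenomicMapping, NucleationLayout, random_layout,
                         write_layout_bed)
from .simulate import (OccupancyProfile, SimulationConfig, global_stats,
                       run_simulation)


@dataclass(frozen=True)
class TrackNoiseModel:
    """Sparsification + noise applied to an occupancy profile.

    q : probability that a unit is detected at all (emits a record).
    scale : multiplicative score scale applied to x̄ (score units).
    noise_sd : standard deviation of additive normal noise on the score
        scale, truncated at zero so emitted scores stay nonnegative.
    seed : generator seed; the same model instance always emits the same track.
    """

    q: float = 0.3
    scale: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("detection probability q must be in [0, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def make_synthetic_track(
    profile: OccupancyProfile,
    mark: int,
    mapping: GenomicMapping,
    noise: TrackNoiseModel,
    label: str | None = None,
) -> ScoreTrack:
    """Emit a sparse pseudo-ChIP score track from a simulated profile.

    Each unit is independently retained with probability ``q``; retained
    units emit ``max(0, scale * x̄ + N(0, noise_sd))`` over the unit's
    genomic span.
    """
    if mapping.n_units != profile.n_units:
        raise ValueError("mapping and profile disagree on chain length")
    rng = np.random.default_rng(noise.seed)
    x = profile.mark_profile(mark)
    detected = rng.random(profile.n_units) < noise.q
    eps = rng.normal(0.0, noise.noise_sd, size=profile.n_units) if noise.noise_sd else 0.0
    scores = np.maximum(0.0, noise.scale * x + eps)
    rows = []
    for j in np.flatnonzero(detected):
        start, end = mapping.unit_span(int(j))
        rows.append((start, end, scores[j]))
    records = pd.DataFrame(rows, columns=["start", "end", "score"])
    return ScoreTrack(mark=label or f"sim_mark{mark}", chromosome=mapping.chromosome,
                      records=records)


# ---------------------------------------------------------------------------
# packaged scenarios
# ---------------------------------------------------------------------------

_N_UNITS = 2000
_STEPS = SimulationConfig(seed=0, total_steps=3000, measure_steps=1000, record_stride=10)


def _scenario_two_domain(rng: np.random.Generator) -> tuple[NucleationLayout, RateParams]:
    """Two well-separated nucleation clusters, one per mark -> two stable domains."""
    left = rng.choice(np.arange(200, 600), size=30, replace=False)
    right = rng.choice(np.arange(1400, 1800), size=30, replace=False)
    layout = NucleationLayout(_N_UNITS, {1: left, 2: right})
    return layout, RateParams(p_a=0.05, p_d=0.01, p_s=[0.1, 0.1])


def _scenario_boundary_standoff(rng: np.random.Generator) -> tuple[NucleationLayout, RateParams]:
    """Dense opposing clusters flanking unit 1000 -> stable narrow border."""
    left = rng.choice(np.arange(850, 1000), size=60, replace=False)
    right = rng.choice(np.arange(1000, 1150), size=60, replace=False)
    layout = NucleationLayout(_N_UNITS, {1: left, 2: right})
    return layout, RateParams(p_a=0.08, p_d=0.01, p_s=[0.12, 0.1])


def _scenario_insertion_response(rng: np.random.Generator) -> tuple[NucleationLayout, RateParams]:
    """Sparse competing sites; the manifest marks a mark-1 site to insert."""
    m1 = rng.choice(_N_UNITS, size=18, replace=False)
    m2 = rng.choice(_N_UNITS, size=20, replace=False)
    layout = NucleationLayout(_N_UNITS, {1: m1, 2: m2})
    return layout, RateParams(p_a=0.05, p_d=0.01, p_s=[0.1, 0.1])


def _scenario_switch_scan(rng: np.random.Generator) -> tuple[NucleationLayout, RateParams]:
    """Random symmetric layout for a propagation-rate switch scan."""
    layout = random_layout(_N_UNITS, 40, rng=rng)
    return layout, RateParams(p_a=0.05, p_d=0.01, p_s=[0.1, 0.1])


_SCENARIOS = {
    "two_domain": _scenario_two_domain,
    "boundary_standoff": _scenario_boundary_standoff,
    "insertion_response": _scenario_insertion_response,
    "switch_scan": _scenario_switch_scan,
}


def make_fixture(scenario: str, seed: int, out_dir) -> Dict[str, object]:
    """Write a self-contained scenario directory and return its manifest.

    The directory holds chrom.sizes, per-mark nucleation BEDs, one bedGraph
    score track per mark generated from the scenario's own simulation, and
    ``manifest.txt`` (key<TAB>value) recording every parameter, seed and the
    summary statistics of the generating run — enough to re-run and verify.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"expected one of {sorted(_SCENARIOS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    layout, rates = _SCENARIOS[scenario](rng)
    mapping = GenomicMapping("chrS", _N_UNITS * 100, 100)

    config = SimulationConfig(seed=seed, total_steps=_STEPS.total_steps,
                              measure_steps=_STEPS.measure_steps,
                              record_stride=_STEPS.record_stride)
    profile = run_simulation(config, _N_UNITS, layout, rates)
    stats = global_stats(profile)

    (out / "chrom.sizes").write_text(f"{mapping.chromosome}\t{mapping.chrom_length}\n")
    for mark in (1, 2):
        write_layout_bed(layout, mapping, out / f"nucleation_mark{mark}.bed", mark)
        noise = TrackNoiseModel(seed=seed + mark)
        track = make_synthetic_track(profile, mark, mapping, noise)
        write_score_track(track, out / f"track_mark{mark}.bedgraph")

    manifest: Dict[str, object] = {
        "scenario": scenario,
        "seed": seed,
        "n_units": _N_UNITS,
        "bp_per_unit": mapping.bp_per_unit,
        "chromosome": mapping.chromosome,
        "total_steps": config.total_steps,
        "measure_steps": config.measure_steps,
        "record_stride": config.record_stride,
        "p_a": f"{rates.p_a[0]:g},{rates.p_a[1]:g}",
        "p_d": f"{rates.p_d[0]:g},{rates.p_d[1]:g}",
        "p_s": f"{rates.p_s[0]:g},{rates.p_s[1]:g}",
        "noise_q": TrackNoiseModel().q,
        "noise_scale": TrackNoiseModel().scale,
        "noise_sd": TrackNoiseModel().noise_sd,
    }
    for _, row in stats.iterrows():
        manifest[f"mean_frequency_mark{int(row['mark'])}"] = f"{row['mean_frequency']:.6f}"
        manifest[f"fluctuation_mark{int(row['mark'])}"] = f"{row['fluctuation']:.6f}"
    if scenario == "insertion_response":
        # a fresh mark-1 site roughly midway between existing ones
        free = np.setdiff1d(np.arange(_N_UNITS), layout.sites(1))
        manifest["insert_mark1_site"] = int(rng.choice(free))

    with open(out / "manifest.txt", "w") as fh:
        for key, value in manifest.items():
            fh.write(f"{key}\t{value}\n")
    return manifest


def read_manifest(path) -> Dict[str, str]:
    """Read a fixture manifest back as a string-valued dict."""
    manifest: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, value = line.split("\t", 1)
            manifest[key] = value
    return manifest


def rerun_manifest(fixture_dir) -> pd.DataFrame:
    """Re-run the simulation a fixture manifest describes; return global stats."""
    fixture_dir = Path(fixture_dir)
    manifest = read_manifest(fixture_dir / "manifest.txt")
    rng = np.random.default_rng(int(manifest["seed"]))
    layout, rates = _SCENARIOS[manifest["scenario"]](rng)
    config = SimulationConfig(
        seed=int(manifest["seed"]),
        total_steps=int(manifest["total_steps"]),
        measure_steps=int(manifest["measure_steps"]),
        record_stride=int(manifest["record_stride"]),
    )
    profile = run_simulation(config, int(manifest["n_units"]), layout, rates)
    return global_stats(profile)
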