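"""Comparison statistics between simulated occupancy and score tracks.

Two statistics connect the simulator to peak-caller output:

1. The sparse-track correlation: the per-unit time-averaged occupancy
   x̄_i(j) is compared to a significance-score track s(j) by Pearson
   correlation restricted to the units where the track detected anything at
   all. Missing positions carry no information (peak callers emit nothing
   where the evidence is weak), so they are excluded rather than treated as
   zeros. r = 1 is a perfect linear match, r = 0 no similarity, r < 0
   opposition.

2. The coarse binned correlation: each chromosome is tiled into fixed-width
   bins (100 kbp by default — about a thousand nucleosomal units), per-bin
   score sums are taken for two tracks, bins where either sum is zero are
   discarded, and Pearson correlation is computed over the remainder. This
   is how heterochromatic and euchromatic mark families are shown to occupy
   opposing domains on a coarse scale.

Undefined correlations (fewer than two usable points, or zero variance on
either side) raise :class:`UndefinedCorrelationError` — they are never
silently coerced to 0, because 0 is itself a meaningful "no similarity"
value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .chain import RateParams
from .nucleation import GenomicMapping, NucleationLayout
from .simulate import OccupancyProfile, SimulationConfig, run_simulation

DEFAULT_BIN_WIDTH = 100_000


class UndefinedCorrelationError(ValueError):
    """Raised when a Pearson correlation has no defined value."""


@dataclass
class ScoreTrack:
    """Sparse genomic score signal (peak-caller-like output).

    ``records`` holds (start, end, score) rows in BED/bedGraph convention
    (0-based half-open); positions without records mean "no detection", not
    score zero. Scores are nonnegative significance values.
    """

    mark: str
    chromosome: str
    records: pd.DataFrame  # columns: start, end, score
    assembly: str | None = None

    def __post_init__(self):
        rec = self.records.reset_index(drop=True)
        if not {"start", "end", "score"}.issubset(rec.columns):
            raise ValueError("records need columns start, end, score")
        if len(rec) and (rec["start"] < 0).any():
            raise ValueError("negative start coordinate")
        if len(rec) and (rec["start"] >= rec["end"]).any():
            raise ValueError("empty or inverted interval in track")
        if len(rec) and (rec["score"] < 0).any():
            raise ValueError("scores must be nonnegative")
        self.records = rec

    @property
    def total_score(self) -> float:
        return float(self.records["score"].sum())


@dataclass(frozen=True)
class BinnedTrack:
    """Per-bin score sums tiling [0, chrom_length) at a fixed bin width."""

    mark: str
    chromosome: str
    bin_width: int
    sums: np.ndarray


def project_to_units(track: ScoreTrack, mapping: GenomicMapping) -> Tuple[np.ndarray, np.ndarray]:
    """Project a track onto chain units.

    Returns ``(scores, covered)``: an interval record contributes its score
    to every unit it overlaps; multiple records per unit sum. ``covered``
    flags units touched by at least one record — only those count as
    "detected" for the sparse-track correlation.
    """
    n = mapping.n_units
    scores = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    for start, end, score in track.records[["start", "end", "score"]].itertuples(index=False):
        units = mapping.units_overlapping(int(start), int(end))
        scores[units] += score
        covered[units] = True
    return scores, covered


def correlation_eq1(
    profile: OccupancyProfile,
    mark: int,
    track: ScoreTrack,
    mapping: GenomicMapping,
) -> float:
    """Pearson correlation of x̄_mark against the track, at detected units only."""
    if mapping.n_units != profile.n_units:
        raise ValueError("mapping and profile disagree on chain length")
    scores, covered = project_to_units(track, mapping)
    x = profile.mark_profile(mark)[covered]
    s = scores[covered]
    if x.size < 2:
        raise UndefinedCorrelationError(
            f"only {x.size} unit(s) carry experimental values; need >= 2"
        )
    if np.ptp(x) == 0.0 or np.ptp(s) == 0.0:
        raise UndefinedCorrelationError("zero variance on one side of the correlation")
    return float(scipy.stats.pearsonr(x, s).statistic)


def bin_track(
    track: ScoreTrack,
    chrom_length: int,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> BinnedTrack:
    """Sum scores into tiling bins of ``bin_width`` bp; empty bins sum to 0.

    A record is assigned to the bin containing its start coordinate, so the
    binned total equals the track total exactly.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n_bins = -(-chrom_length // bin_width)
    sums = np.zeros(n_bins)
    if len(track.records):
        if (track.records["start"] >= chrom_length).any():
            raise ValueError("record starts beyond chromosome end")
        idx = (track.records["start"] // bin_width).to_numpy()
        np.add.at(sums, idx, track.records["score"].to_numpy())
    return BinnedTrack(track.mark, track.chromosome, bin_width, sums)


def binned_correlation(a: BinnedTrack, b: BinnedTrack) -> Tuple[float, int]:
    """Pearson correlation over bins where BOTH sums are nonzero.

    Zero bins are excluded to avoid artifacts from low antibody specificity
    and missing signal. Returns (r, number of retained bins).
    """
    if a.bin_width != b.bin_width or a.sums.shape != b.sums.shape:
        raise ValueError("binned tracks must share bin width and tiling")
    keep = (a.sums > 0) & (b.sums > 0)
    n_kept = int(keep.sum())
    if n_kept < 2:
        raise UndefinedCorrelationError(f"only {n_kept} bin(s) retained; need >= 2")
    x, y = a.sums[keep], b.sums[keep]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero variance among retained bins")
    return float(scipy.stats.pearsonr(x, y).statistic), n_kept


def correlation_matrix(tracks: Sequence[BinnedTrack]) -> pd.DataFrame:
    """All-pairs binned correlations; diagonal is 1 by construction."""
    names = [t.mark for t in tracks]
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(tracks):
        out.iloc[i, i] = 1.0
        for k in range(i + 1, len(tracks)):
            r, _ = binned_correlation(a, tracks[k])
            out.iloc[i, k] = out.iloc[k, i] = r
    return out


def fit_grid(
    config: SimulationConfig,
    layout: NucleationLayout,
    mapping: GenomicMapping,
    tracks: Mapping[int, Sequence[ScoreTrack]],
    p_a_values: Sequence[float],
    p_d_values: Sequence[float],
    p_s1_values: Sequence[float],
    p_s2: float = 0.1,
) -> pd.DataFrame:
    """Parameter-grid fit: one simulation per (p_a, p_d, p_s1) cell.

    ``tracks`` maps each simulated mark (1 = heterochromatin, 2 =
    euchromatin) to the experimental score tracks it should be compared to.
    Each cell reports the sparse-track correlation per experimental track
    and a ``good_match`` flag set when every correlation is positive. Grid
    seeds are spawned deterministically from the base seed.
    """
    for name, vals in (("p_a", p_a_values), ("p_d", p_d_values),
                       ("p_s,1", p_s1_values), ("p_s,2", [p_s2])):
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} value {v} outside [0, 1]")
    cells = [(pa, pd_, ps1) for pa in p_a_values for pd_ in p_d_values
             for ps1 in p_s1_values]
    children = np.random.SeedSequence(config.seed).spawn(len(cells))
    rows = []
    for (pa, pd_, ps1), child in zip(cells, children):
        rates = RateParams(p_a=pa, p_d=pd_, p_s=[ps1, p_s2])
        seed = int(child.generate_state(1)[0] % (2**31))
        prof = run_simulation(dc_replace(config, seed=seed),
                              mapping.n_units, layout, rates)
        row: Dict[str, object] = {"p_a": pa, "p_d": pd_, "p_s1": ps1, "p_s2": p_s2}
        corrs = []
        for mark, mark_tracks in tracks.items():
            for track in mark_tracks:
                r = correlation_eq1(prof, mark, track, mapping)
                row[f"r_{track.mark}"] = r
                corrs.append(r)
        row["mean_r"] = float(np.mean(corrs))
        row["good_match"] = bool(all(r > 0 for r in corrs))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text genomics IO
# ---------------------------------------------------------------------------

def read_score_track(path, mark: str, chromosome: str | None = None,
                     assembly: str | None = None) -> ScoreTrack:
    """Read a bedGraph (4 columns) or BED-with-score (5+ columns) track.

    Tolerates ``track``/``browser`` lines and ``#`` comments. For 4-column
    input the score is column 4; for 5+ columns the BED score column 5.
    """
    rows = []
    chrom_seen = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"score track line has fewer than 4 columns: {line!r}")
            chrom = parts[0]
            if chromosome is not None and chrom != chromosome:
                continue
            chrom_seen = chrom_seen or chrom
            score = float(parts[3]) if len(parts) == 4 else float(parts[4])
            rows.append((int(parts[1]), int(parts[2]), score))
    records = pd.DataFrame(rows, columns=["start", "end", "score"])
    return ScoreTrack(mark=mark, chromosome=chromosome or chrom_seen or "unknown",
                      records=records, assembly=assembly)


def write_score_track(track: ScoreTrack, path) -> None:
    """Write a track as bedGraph (chrom, start, end, score)."""
    with open(path, "w") as fh:
        for start, end, score in track.records[["start", "end", "score"]].itertuples(index=False):
            fh.write(f"{track.chromosome}\t{int(start)}\t{int(end)}\t{score:.6g}\n")


def plot_fit_grid(grid: pd.DataFrame, path, value: str = "mean_r") -> None:
    """Optional heatmap of a fit grid (p_s1 x p_d panels over p_a); needs matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p_a_vals = sorted(grid["p_a"].unique())
    fig, axes = plt.subplots(1, len(p_a_vals), figsize=(4 * len(p_a_vals), 3.2),
                             squeeze=False)
    for ax, pa in zip(axes[0], p_a_vals):
        sub = grid[grid["p_a"] == pa].pivot(index="p_d", columns="p_s1", values=value)
        im = ax.imshow(sub.to_numpy(), origin="lower", cmap="RdYlGn",
                       vmin=-1, vmax=1, aspect="auto")
        ax.set_xticks(range(len(sub.columns)), [f"{v:g}" for v in sub.columns])
        ax.set_yticks(range(len(sub.index)), [f"{v:g}" for v in sub.index])
        ax.set_xlabel("p_s,1")
        ax.set_ylabel("p_d")
        ax.set_title(f"p_a = {pa:g}")
    fig.colorbar(im, ax=axes[0], label=value)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
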