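"""Nucleation-site layouts: random, genomic (BED-derived), and perturbed.

Nucleation sites are the units where a mark can be deposited directly —
standing in for SINE-Alu elements (heterochromatin, mark 1) and CpG islands
(euchromatin, mark 2). Layouts come in two flavors: random placements for
the general model study, and genomic placements obtained by projecting BED
intervals onto the chain under a fixed bp-per-unit mapping (one histone H3
per 100 bp by default).

All genomic coordinates follow the BED convention: 0-based, half-open.
Unit ``j`` covers the genomic span ``[bp_per_unit * j, bp_per_unit * (j+1))``;
any overlap of at least 1 bp makes a unit a nucleation site. Strand is
ignored — the model has no strandedness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicMapping:
    """Chain-to-genome coordinate mapping for one chromosome."""

    chromosome: str
    chrom_length: int
    bp_per_unit: int = 100

    def __post_init__(self):
        if self.bp_per_unit < 1:
            raise ValueError("bp_per_unit must be >= 1")
        if self.chrom_length < self.bp_per_unit:
            raise ValueError("chrom_length must be >= bp_per_unit")

    @property
    def n_units(self) -> int:
        return math.ceil(self.chrom_length / self.bp_per_unit)

    def unit_span(self, j: int) -> Tuple[int, int]:
        """Genomic [start, end) of unit j, clipped to the chromosome."""
        start = j * self.bp_per_unit
        return start, min(start + self.bp_per_unit, self.chrom_length)

    def units_overlapping(self, start: int, end: int) -> np.ndarray:
        """All units whose span overlaps the half-open interval [start, end)."""
        if start < 0 or end > self.chrom_length:
            raise ValueError(
                f"interval [{start}, {end}) outside chromosome of length {self.chrom_length}"
            )
        if start >= end:
            raise ValueError(f"interval start {start} must be < end {end}")
        return np.arange(start // self.bp_per_unit, (end - 1) // self.bp_per_unit + 1)


class NucleationLayout:
    """Per-mark sets of chain units where direct mark deposition may occur.

    Marks are 1-based; within one mark, indices are distinct and sorted.
    Different marks may share a unit (e.g. overlapping Alu and CpG
    annotations); the update rule then picks one of the nucleating marks
    uniformly before attempting deposition.
    """

    def __init__(self, n_units: int, sites: Mapping[int, Iterable[int]], n_marks: int = 2):
        if n_units < 1:
            raise ValueError("n_units must be >= 1")
        self.n_units = int(n_units)
        self.n_marks = int(n_marks)
        self._sites: Dict[int, np.ndarray] = {}
        for mark in range(1, self.n_marks + 1):
            idx = np.unique(np.asarray(list(sites.get(mark, ())), dtype=np.int64))
            if idx.size and (idx[0] < 0 or idx[-1] >= self.n_units):
                raise ValueError(f"mark-{mark} site index outside [0, {self.n_units})")
            self._sites[mark] = idx
        self._mask_cache: np.ndarray | None = None

    def sites(self, mark: int) -> np.ndarray:
        return self._sites[mark]

    def n_sites(self, mark: int) -> int:
        return int(self._sites[mark].size)

    def mask(self, n_units: int | None = None) -> np.ndarray:
        """(M, N) uint8 indicator array consumed by the update kernel."""
        if n_units is not None and n_units != self.n_units:
            raise ValueError("layout built for a different chain length")
        if self._mask_cache is None:
            m = np.zeros((self.n_marks, self.n_units), dtype=np.uint8)
            for mark, idx in self._sites.items():
                m[mark - 1, idx] = 1
            self._mask_cache = m
        return self._mask_cache

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NucleationLayout)
            and self.n_units == other.n_units
            and self.n_marks == other.n_marks
            and all(np.array_equal(self._sites[m], other._sites[m])
                    for m in self._sites)
        )

    def __repr__(self) -> str:
        counts = ", ".join(f"mark{m}={v.size}" for m, v in self._sites.items())
        return f"NucleationLayout(n_units={self.n_units}, {counts})"


def random_layout(
    n_units: int,
    sites_per_mark: int,
    n_marks: int = 2,
    rng: np.random.Generator | int | None = None,
) -> NucleationLayout:
    """Place ``sites_per_mark`` distinct nucleation sites per mark uniformly.

    Every mark family is fed by the same number of sites, sampled without
    replacement within a mark and independently across marks (cross-mark
    overlap is allowed).
    """
    if not 0 <= sites_per_mark <= n_units:
        raise ValueError(f"sites_per_mark must be in [0, {n_units}], got {sites_per_mark}")
    rng = np.random.default_rng(rng)
    sites = {
        mark: rng.choice(n_units, size=sites_per_mark, replace=False)
        for mark in range(1, n_marks + 1)
    }
    return NucleationLayout(n_units, sites, n_marks)


def layout_from_intervals(
    intervals: Mapping[int, Sequence[Tuple[int, int]]],
    mapping: GenomicMapping,
    n_marks: int = 2,
) -> NucleationLayout:
    """Project per-mark genomic intervals onto chain units.

    Every unit whose 100-bp (by default) span overlaps an interval of mark
    ``i`` by at least one bp becomes a nucleation site for mark ``i``;
    duplicates collapse. Intervals must lie within the chromosome and be
    non-empty under the half-open convention.
    """
    sites: Dict[int, np.ndarray] = {}
    for mark in range(1, n_marks + 1):
        chunks = [mapping.units_overlapping(int(s), int(e))
                  for s, e in intervals.get(mark, ())]
        sites[mark] = np.unique(np.concatenate(chunks)) if chunks else np.array([], dtype=np.int64)
    return NucleationLayout(mapping.n_units, sites, n_marks)


def insert_sites(layout: NucleationLayout, mark: int, indices: Iterable[int]) -> NucleationLayout:
    """Copy the layout with new nucleation sites for ``mark`` added.

    Indices already present for that mark are skipped with a warning.
    """
    idx = np.asarray(list(indices), dtype=np.int64)
    existing = layout.sites(mark)
    dup = np.isin(idx, existing)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} index(es) already nucleate mark {mark}; skipped",
            stacklevel=2,
        )
        idx = idx[~dup]
    new = {m: layout.sites(m) for m in range(1, layout.n_marks + 1)}
    new[mark] = np.concatenate([existing, idx])
    return NucleationLayout(layout.n_units, new, layout.n_marks)


def delete_sites(layout: NucleationLayout, mark: int, indices: Iterable[int]) -> NucleationLayout:
    """Copy the layout with the given mark-``mark`` sites removed.

    Deleting an index that is not a nucleation site of that mark is an error.
    """
    idx = np.asarray(list(indices), dtype=np.int64)
    existing = layout.sites(mark)
    missing = idx[~np.isin(idx, existing)]
    if missing.size:
        raise ValueError(f"cannot delete absent mark-{mark} site(s) {missing.tolist()}")
    new = {m: layout.sites(m) for m in range(1, layout.n_marks + 1)}
    new[mark] = existing[~np.isin(existing, idx)]
    return NucleationLayout(layout.n_units, new, layout.n_marks)


def shift_sites(layout: NucleationLayout, mark: int, offset: int) -> NucleationLayout:
    """Copy the layout with every mark-``mark`` site translated by ``offset``.

    Sites shifted past either chain end are dropped (clipped), so a large
    shift thins the layout rather than piling sites onto the boundary unit.
    """
    shifted = layout.sites(mark) + int(offset)
    shifted = shifted[(shifted >= 0) & (shifted < layout.n_units)]
    new = {m: layout.sites(m) for m in range(1, layout.n_marks + 1)}
    new[mark] = shifted
    return NucleationLayout(layout.n_units, new, layout.n_marks)


def perturb_layout(layout: NucleationLayout, edit: str, mark: int, *,
                   indices: Iterable[int] | None = None,
                   offset: int | None = None) -> NucleationLayout:
    """Dispatch wrapper: ``edit`` is one of 'insert', 'delete', 'shift'."""
    if edit == "insert":
        return insert_sites(layout, mark, indices or ())
    if edit == "delete":
        return delete_sites(layout, mark, indices or ())
    if edit == "shift":
        if offset is None:
            raise ValueError("shift requires an offset")
        return shift_sites(layout, mark, offset)
    raise ValueError(f"unknown edit {edit!r}; expected insert/delete/shift")


# ---------------------------------------------------------------------------
# plain-text genomics IO
# ---------------------------------------------------------------------------

def read_bed(path, chromosome: str | None = None) -> pd.DataFrame:
    """Read a BED file (3+ tab-separated columns) into (chrom, start, end).

    Tolerates ``track``/``browser`` header lines and ``#`` comments; extra
    columns are ignored. Optionally restricts to one chromosome.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if chromosome is not None:
        df = df[df["chrom"] == chromosome].reset_index(drop=True)
    return df


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a chrom.sizes table (name<TAB>length) into a dict."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
    return sizes


def layout_from_bed(
    bed_paths: Mapping[int, str],
    mapping: GenomicMapping,
    n_marks: int = 2,
) -> NucleationLayout:
    """Build a layout from one BED file per mark, restricted to the mapped chromosome."""
    intervals = {}
    for mark, path in bed_paths.items():
        df = read_bed(path, chromosome=mapping.chromosome)
        intervals[mark] = list(zip(df["start"], df["end"]))
    return layout_from_intervals(intervals, mapping, n_marks)


def write_layout_bed(layout: NucleationLayout, mapping: GenomicMapping, path, mark: int) -> None:
    """Write one mark's nucleation units as BED intervals (one per unit)."""
    with open(path, "w") as fh:
        for j in layout.sites(mark):
            start, end = mapping.unit_span(int(j))
            fh.write(f"{mapping.chromosome}\t{start}\t{end}\tmark{mark}\n")
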