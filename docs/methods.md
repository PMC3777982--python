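# Methods

## Model

A chromosome is a linear chain of `N` nucleosomal units with only
nearest-neighbor coupling. Each unit is in one of `M + 1` states:
unmodified, or carrying exactly one of `M` antagonistic mark families
(default `M = 2`: mark 1 heterochromatin-like, e.g. H3K9me2/3; mark 2
euchromatin-like, e.g. H3K4me2/3 and H3 acetylations). Three stochastic
processes act, all expressed as probabilities per histone per time step:

* **nucleation** — at a dedicated nucleation site (SINE-Alu-like for mark
  1, CpG-island-like for mark 2), an unmodified unit gains the site's mark
  with rate `p_a`;
* **propagation** — a modified unit copies its mark to one uniformly
  chosen nearest neighbor with rate `p_s,i` (per mark family `i`), but only
  if that neighbor is unmodified;
* **deletion** — a modified unit loses its mark with rate `p_d`.

Mutual exclusion (a new mark is never written over an existing one) is the
only interaction between the families; it is what turns independent
spreading processes into competing, non-overlapping domains. The model has
no explicit boundary elements: stable borders emerge where accumulations of
opposing nucleation sites face each other.

Deliberately absent: 3-D/long-range contacts between non-neighboring
nucleosomes, replication-coupled histone turnover, multiply-modified
histones, and any sequence information beyond the nucleation-site
positions.

## Update scheme and draw discipline

One time step ("sweep") applies `N` micro-events at units drawn uniformly
with replacement, so each histone is updated once per step in expectation.
Within one micro-event at a modified unit, the propagation attempt is
evaluated first and the deletion attempt second, as two *independent*
Bernoulli draws — both rates then keep their marginal meaning, and because
propagation targets a neighbor while deletion targets the unit itself, the
resulting state does not depend on the evaluation order. An unmodified
unit that nucleates several families picks one uniformly before the
deposition attempt. A nucleation site already carrying its own mark is not
"refreshed"; the state is equivalent either way.

Every event consumes a fixed block of five uniforms — neighbor choice,
propagation, deletion, nucleation mark-choice, nucleation accept — in that
order, drawn (together with the per-sweep site indices) from a single
seeded SFC64 stream in documented chunks (SFC64 rather than the numpy
default PCG64 because bulk generation dominates the event loop). Unused draws in a block are
still consumed, so a trajectory is a pure function of the seed. Boundary
units choose uniformly among their existing neighbors; no propagation
attempt is wasted off-chain. The pre-drawn blocks use single-precision
uniforms (24-bit resolution, ample for Bernoulli thresholds on rates of
order 0.01–1) because draw generation, not the update arithmetic,
dominates the runtime.

The production kernel is a numba-compiled loop; a pure-Python function
with identical semantics consumes the same pre-drawn arrays and is
cross-checked against it event by event in the test suite, alongside the
single-event reference `update_site`.

## Exact oracle

For `N ≤ 8` the full state space (`3^N ≤ 6561` assignments for two marks)
is enumerated and the single micro-update transition matrix built by
summing, for each state and each unit (weight `1/N`), the exact
probabilities of the four propagation-by-deletion outcomes per neighbor
choice and of each nucleation deposition. The stationary distribution is
obtained by a sparse linear solve of `πP = π` with the normalization
constraint replacing one equation, verified to a fixed-point residual
below 1e-10, and marginalized to per-site occupancies. The matrix is kept
at micro-update resolution — the stationary law is the same as the full
sweep's, and the matrix stays sparse.

The simulator-versus-oracle battery draws random tiny-chain
configurations (N 2–8, random layouts; `p_a`, `p_d` in [0.1, 0.5] and
`p_s` in [0, 0.5] so the chain is irreducible and mixes quickly) and
compares the Monte-Carlo occupancy over ≥ 200,000 measured sweeps against
the exact marginals. The Monte-Carlo standard error is estimated by batch
means (50 batches, batch length far above the relaxation time ~1/p_d).
Because the battery makes on the order of two hundred site-level
comparisons, a correct kernel is expected to brush a 3-standard-error band
occasionally by multiplicity alone; a flagged configuration is therefore
re-measured with four times the data on an independent trajectory and
must pass then. This sequential design keeps the 3-SE band meaningful
per comparison without widening it.

## Time averaging and global statistics

A run starts from the completely unmodified chain, discards a burn-in of
`total_steps − measure_steps` sweeps, and accumulates over the final
`measure_steps` sweeps: the per-unit occupancy `x̄_i(j)` (fraction of
measured sweeps unit `j` carried mark `i`) and the global per-mark count
series sampled every `record_stride` sweeps. The mean global frequency is
the time average of count/N; the temporal fluctuation is the standard
deviation of the same series (several fluctuation estimators are
defensible here; the plain standard deviation is the one this package
uses and states).

Stationarity has no automatic criterion; burn-in is configurable, and the
test suite verifies that doubling it moves small-chain occupancies by less
than the Monte-Carlo noise. Near the propagation-rate transition this
matters a great deal — domain walls between opposing domains are frozen
except when a deletion at the wall opens a gap, so wall mobility scales
with `p_d` and equilibration at `p_d = 0.01` takes on the order of 10^5
sweeps (see "Parameter scans" below).

## Genomic mapping and layouts

One histone H3 unit per 100 bp of DNA; unit `j` covers the 0-based
half-open span `[100·j, 100·(j+1))`. BED intervals (0-based half-open)
mark every unit they overlap by at least 1 bp as a nucleation site —
multi-unit Alu/CpG intervals therefore yield one site per overlapped unit,
the more conservative of the two collapse conventions (the alternative,
one site per interval, would thin dense repeat clusters). Strand is
ignored. Chromosome lengths come from a user-supplied chrom.sizes table;
nothing is downloaded.

Layout edits for perturbation experiments: `insert` (duplicates skipped
with a warning), `delete` (deleting an absent site is an error), and
`shift` by a fixed offset, where sites shifted past either chain end are
dropped rather than clamped — clamping would pile sites onto the boundary
unit and manufacture a spurious nucleation cluster.

## Comparison statistics

**Sparse-track correlation.** Peak-caller output (CCAT-like significance
scores) is sparse; absent positions mean "no detection", not zero signal.
The simulated `x̄_i(j)` is therefore correlated (Pearson) with the score
`s(j)` only over units touched by at least one track record. An interval
record contributes its score to every unit it overlaps and multiple
records per unit sum (per-unit summation rather than per-base
aggregation; this is the documented projection choice). Correlations with fewer than two usable units or zero variance on
either side raise an error — they are never coerced to 0, because 0 is the
meaningful "no similarity" value.

**Binned correlation.** Each chromosome is tiled into 100-kbp bins (1,000
units at 100 bp/unit); per-bin score sums are correlated between two
tracks over the bins where *both* sums are nonzero. A record is assigned
to the bin containing its start coordinate, which keeps the binned total
exactly equal to the track total. This statistic is what shows
heterochromatic and euchromatic families occupying opposing coarse
domains (negative cross-family correlation).

**Grid fit.** `fit_grid` runs one simulation per (`p_a`, `p_d`, `p_s,1`)
cell at fixed `p_s,2`, computes the sparse-track correlation per
experimental track, and flags a cell as a good match when every
correlation is positive. The regime `p_a` 0.01–0.1, `p_d` 0.01–0.02,
`p_s,1` 0.1–0.16 at `p_s,2 = 0.1` — where simulated profiles correlate
positively with human chromosome ChIP-seq tracks for both mark families —
is the package's default neighborhood for genomic runs.

## Synthetic tracks and fixtures

The track generator emulates the *statistical shape* of peak-caller
output from a known simulated profile: each unit is retained independently
with detection probability `q` (default 0.3, chosen to mimic the sparsity
of typical heterochromatin tracks; a modeling choice, not a measured
constant), and retained units emit
`max(0, scale·x̄ + ε)` with `ε ~ N(0, noise_sd)` — a zero-truncated
normal on the score scale (default scale 10, noise_sd 1). It does not
emulate read sampling, fragment smoothing, or spatially correlated caller
statistics, so tests built on it certify the comparison machinery and
layout sensitivity, not peak-caller behavior. All generator parameters and
seeds are recorded in each fixture's manifest, and re-running a manifest
reproduces the recorded summary statistics exactly (same seed, same
trajectory).

## Parameter scans and the switch

Sweeping `p_s,1` across `p_s,2` with symmetric random layouts produces the
model's chromosome-scale switch: mark 1 is confined to nucleation-site
pockets when it spreads slower than its competitor and floods the chain
when it spreads faster, with coexistence near `p_s,1 = p_s,2`. Scans
derive per-cell seeds from the base seed via `SeedSequence` spawning, so a
whole scan is reproducible.

The scan geometry used by the validation experiments is N = 10,000 with
100 random nucleation sites per mark at `p_a = 0.05`, `p_d = 0.01`,
`p_s,2 = 0.1`, scanning `p_s,1` over {0.05, 0.08, 0.1, 0.12, 0.16} —
small enough to run in minutes, large enough that domains are well
separated from the site spacing. Burn-in is set to several hundred
thousand sweeps because wall motion is deletion-limited (see above);
values adjacent to the transition relax slowest. At this pinning strength
(`p_a/p_d = 5` with 100 sites per mark) the fluctuation maximum among
the tested values sits adjacent to the symmetric point within practical
windows: finite-window fluctuation measurements near a slow transition
are dominated by which slow modes the window can resolve. The scan over
`p_a` (at fixed `p_s,1 = 0.12`, inside the fitted regime but off the
critical point so the scan is not confounded by critical slowing) shows
the contrasting behavior: means vary smoothly, no saturated-to-saturated
transition, and no interior fluctuation peak.

## Numerical choices

* Rates are validated into [0, 1] at construction; nothing is clamped
  later.
* The stationary solve uses `scipy.sparse.linalg.spsolve`; tiny negative
  round-off in π is clipped and renormalized after the residual check.
* Pearson correlations come from `scipy.stats.pearsonr`.
* Replicate/grid seeds: `SeedSequence(base).spawn(...)`, truncated below
  2^31.
* Degenerate inputs (empty layouts, all-zero rates, single-unit chains)
  are exercised in the test suite; the kernel handles N = 1 (no neighbor,
  no propagation) explicitly.

## Known limitations

* Real ChIP-seq comparisons (human chromosomes, hg18 Alu/CpG layouts)
  require user-supplied BED/bedGraph inputs; the package never downloads
  data, and its correctness on real tracks is certified only indirectly
  through the synthetic-track experiments.
* The fluctuation statistic near the propagation-rate transition depends
  on window length relative to deletion-limited wall dynamics; finite
  windows underestimate the slow ergodic wandering at the symmetric point
  (discussed above).
* The oracle is limited to `(M+1)^N ≤ 3^10` states; correctness at
  chromosome scale rests on the kernel being identical code at all scales.
* Scans are run serially; they are embarrassingly parallel but correctness
  is defined by the serial seed-derivation order.
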