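# epichain

Stochastic simulation of antagonistic histone-mark domains on a 1-D
nucleosome chain, with genomic mapping, ChIP-seq-track comparison
statistics, parameter-scan machinery, and an exact small-chain oracle.

## The problem

Heterochromatin (H3K9me2/3-marked, silent) and euchromatin
(H3K4me2/3- and acetylation-marked, active) partition chromosomes into
large, mutually exclusive domains. A minimal mechanistic explanation needs
only four processes: histone marks are **nucleated** at dedicated genomic
elements (SINE-Alu repeats for heterochromatin, CpG islands for
euchromatin), **propagate** to neighboring nucleosomes, are stochastically
**deleted**, and **compete** — a nucleosome carries at most one mark
family. `epichain` implements this lattice model for people who want to
simulate chromatin-domain formation on real or synthetic nucleation-site
layouts, study its switch-like response to rate changes, and compare
simulated occupancy against sparse peak-caller score tracks.

## The model

A chromosome is a chain of `N` nucleosomal units (one histone H3 unit per
100 bp). Unit `j` is unmodified or carries mark `i ∈ {1..M}` (`M = 2` by
default). Per time step, each unit is updated once in expectation (random
sequential updating); a micro-event at unit `j` applies, with everything a
probability per histone per step:

* `j` unmodified and a nucleation site of mark `i`: gain mark `i` with
  rate `p_a`;
* `j` carrying mark `i`: copy the mark to one uniformly chosen nearest
  neighbor with rate `p_s,i` if and only if that neighbor is unmodified,
  and independently lose the mark with rate `p_d`.

The simulator's observable is the occupancy profile `x̄_i(j)` — the
fraction of measured sweeps unit `j` carried mark `i` — the in-silico
analogue of a ChIP-seq signal. Two statistics connect it to experiment:
Pearson correlation against a sparse score track restricted to detected
units, and Pearson correlation of per-100-kbp score sums between two
tracks, excluding bins where either sum is zero. On tiny chains (`N ≤ 8`)
an exact enumeration of the `3^N`-state Markov chain provides stationary
marginals that the Monte-Carlo kernel is validated against.

## Worked example

```python
import numpy as np
from epichain import (RateParams, SimulationConfig, global_stats,
                      random_layout, run_simulation)

layout = random_layout(2000, 40, rng=np.random.default_rng(42))
rates = RateParams(p_a=0.05, p_d=0.01, p_s=[0.1, 0.1])
config = SimulationConfig(seed=7, total_steps=6000, measure_steps=3000,
                          record_stride=10)
profile = run_simulation(config, 2000, layout, rates)
print(global_stats(profile).to_string(index=False))
```

prints

```
 mark  mean_frequency  fluctuation
    1        0.426667     0.009061
    2        0.463717     0.009171
```

With equal propagation rates the two marks split the chain into
complementary domains anchored at their nucleation sites: each mark covers
~45% of the chain on time average (the remainder is transiently
unmodified), and the small standard deviation of the frequency series
shows the domain pattern is stable rather than flickering. Raising
`p_s,1` above `p_s,2` tips this balance sharply — see
`examples/02_switch_scan.py`.

The `examples/` directory walks through each capability: basic
simulation, the propagation-rate switch, genomic BED/bedGraph workflows
with synthetic tracks, and oracle validation.

## Command line

The same machinery is available as a thin CLI for shell pipelines:

```sh
epichain simulate --n-units 10000 --sites-per-mark 100 --seed 1 \
    --p-s1 0.12 --total-steps 20000 --measure-steps 5000 --out-dir run/
epichain scan --n-units 2000 --sites-per-mark 20 --param p_s,1 \
    --values 0.05,0.1,0.16 --seed 2 --total-steps 20000 --measure-steps 8000
epichain bincorr --track a.bedgraph --track b.bedgraph --chrom-length 20000000
epichain fixtures --scenario boundary_standoff --seed 3 --out-dir fx/
epichain oracle-check --n-units 6 --sites-per-mark 2 --seed 4
```

Genomic runs take nucleation intervals as BED (`--het-bed`, `--eu-bed`)
plus a chrom.sizes table; every command writes a `resolved_config.yaml`
sufficient to reproduce it.

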