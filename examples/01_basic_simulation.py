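"""Simulate competing histone-mark domains on a random chain.

Builds a 2,000-unit chain with 40 random nucleation sites per mark, runs the
stochastic dynamics to a stationary-like state, and prints the global mark
frequencies. With equal propagation rates the two marks partition the chain
into complementary domains anchored at their nucleation sites.
"""

import numpy as np

from epichain import (RateParams, SimulationConfig, global_stats,
                      random_layout, run_simulation)

n_units = 2000
layout = random_layout(n_units, 40, rng=np.random.default_rng(42))
rates = RateParams(p_a=0.05, p_d=0.01, p_s=[0.1, 0.1])
config = SimulationConfig(seed=7, total_steps=6000, measure_steps=3000,
                          record_stride=10)

profile = run_simulation(config, n_units, layout, rates)
stats = global_stats(profile)
print(stats.to_string(index=False))
print()
for mark in (1, 2):
    x = profile.mark_profile(mark)
    print(f"mark {mark}: occupied fraction of units with x̄ > 0.5: "
          f"{(x > 0.5).mean():.3f}")

# mean_frequency is the time-averaged fraction of the chain carrying each
# mark; fluctuation is the standard deviation of that series. Roughly equal
# frequencies near 0.4-0.5 with small fluctuations indicate stable coexisting
# domains rather than one mark taking over.
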