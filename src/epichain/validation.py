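"""Simulator-versus-oracle comparison on tiny chains.

The Monte-Carlo occupancy x̄_i(j) estimated over the measurement window is
compared to the exact stationary marginal from the enumerated Markov chain.
Because successive sweeps are autocorrelated, the Monte-Carlo standard
error of x̄ is estimated by batch means: the measurement window is split
into contiguous batches much longer than the relaxation time, and the
standard error is the standard deviation of batch means divided by
sqrt(number of batches).
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .chain import RateParams
from .nucleation import NucleationLayout, random_layout
from .oracle import exact_marginals
from .simulate import SimulationConfig


def batch_occupancy(
    config: SimulationConfig,
    n_units: int,
    layout: NucleationLayout,
    rates: RateParams,
    n_batches: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy estimate and its batch-means standard error, shape (M, N) each.

    Runs ``n_batches`` consecutive measurement segments of one simulation
    (burn-in applied once, then each batch continues from the previous
    state via a longer single run split into windows).
    """
    if config.measure_steps % n_batches != 0:
        raise ValueError("measure_steps must divide into n_batches")
    batch_len = config.measure_steps // n_batches
    # per-site batch means need the evolving chain, so the batches run as one
    # chained trajectory: burn-in once, then measure window after window
    means = np.empty((n_batches, rates.n_marks, n_units))
    rng = np.random.Generator(np.random.SFC64(config.seed))
    mask = layout.mask(n_units)
    from ._kernel import _sweep_loop
    from .chain import init_chain

    chain = init_chain(n_units, rates.n_marks)
    burn_in = config.total_steps - config.measure_steps

    def run_block(n_sweeps: int, accumulate: bool) -> np.ndarray | None:
        occ = np.zeros((rates.n_marks, n_units), dtype=np.int64)
        counts = np.zeros((n_sweeps, rates.n_marks), dtype=np.int64)
        sites = rng.integers(0, n_units, size=n_sweeps * n_units, dtype=np.uint32)
        u = rng.random((n_sweeps * n_units, 5), dtype=np.float32)
        _sweep_loop(chain.states, mask, rates.p_a, rates.p_d, rates.p_s,
                    sites, u, 0 if accumulate else n_sweeps, occ, counts)
        return occ if accumulate else None

    if burn_in:
        run_block(burn_in, accumulate=False)
    for b in range(n_batches):
        occ = run_block(batch_len, accumulate=True)
        means[b] = occ / batch_len
    x_bar = means.mean(axis=0)
    se = means.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return x_bar, se


def simulator_vs_oracle(
    n_units: int,
    sites_per_mark: int,
    seed: int,
    rates: RateParams | None = None,
    measure_steps: int = 200_000,
    burn_in: int = 20_000,
    n_batches: int = 50,
    sim_seed: int | None = None,
) -> Dict[str, float]:
    """Run one simulator/oracle comparison; report the worst deviation.

    Returns max_dev_se (max |x̄ - exact| in batch-means standard-error
    units over all sites and marks), max_abs_dev, and the geometry used.
    A deviation floor of half a standard error's worth of estimation noise
    is folded into the denominator to keep ratios finite when a site's
    occupancy is pinned near 0 or 1.
    """
    rng = np.random.default_rng(seed)
    if rates is None:
        rates = RateParams(
            p_a=rng.uniform(0.1, 0.5, size=2),
            p_d=rng.uniform(0.1, 0.5, size=2),
            p_s=rng.uniform(0.0, 0.5, size=2),
        )
    layout = random_layout(n_units, sites_per_mark, rng=rng)
    exact = exact_marginals(layout, rates)
    config = SimulationConfig(seed=seed if sim_seed is None else sim_seed,
                              total_steps=burn_in + measure_steps,
                              measure_steps=measure_steps)
    x_bar, se = batch_occupancy(config, n_units, layout, rates, n_batches)
    dev = np.abs(x_bar - exact)
    se_floor = np.maximum(se, 1e-6)
    return {
        "n_units": n_units,
        "sites_per_mark": sites_per_mark,
        "seed": seed,
        "max_abs_dev": float(dev.max()),
        "max_dev_se": float((dev / se_floor).max()),
    }
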