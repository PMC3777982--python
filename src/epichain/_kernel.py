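"""Low-level micro-update kernels.

One micro-event touches a single chain unit ``j``:

* if ``j`` carries mark ``m`` (state value ``m + 1``): a propagation attempt
  is evaluated first — one neighbor is chosen uniformly among the existing
  neighbors and receives mark ``m`` with probability ``p_s[m]`` if and only
  if it is unmodified — then an independent deletion attempt clears ``j``
  with probability ``p_d[m]``;
* if ``j`` is unmodified and nucleates at least one mark, one nucleating
  mark is chosen uniformly and deposited with probability ``p_a[mark]``;
* otherwise nothing happens.

Every event consumes a fixed block of five uniforms
``[neighbor, propagation, deletion, mark-choice, nucleation-accept]`` in
that order, whether or not each draw is used, so trajectories are fully
reproducible from the seed and the documented draw order.

The production path is a numba ``njit`` compilation of ``_sweep_loop_py``;
the pure-Python function itself is the reference implementation used by the
single-event API and by equivalence tests.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every simulation
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


def apply_event(states, j, nuc_mask, p_a, p_d, p_s, u):
    """Apply one micro-event at unit ``j`` in place.

    Parameters
    ----------
    states : (N,) int8 array; 0 = unmodified, m+1 = mark m (0-based m).
    nuc_mask : (M, N) uint8 array; nuc_mask[m, j] == 1 if unit j nucleates mark m.
    p_a, p_d, p_s : (M,) float64 per-mark rates.
    u : length-5 sequence of uniforms in the documented draw order.
    """
    n = states.shape[0]
    n_marks = p_a.shape[0]
    st = states[j]
    if st > 0:
        m = st - 1
        if n > 1:
            if j == 0:
                nb = 1
            elif j == n - 1:
                nb = n - 2
            else:
                nb = j - 1 if u[0] < 0.5 else j + 1
            if u[1] < p_s[m] and states[nb] == 0:
                states[nb] = st
        if u[2] < p_d[m]:
            states[j] = 0
    else:
        k = 0
        for m in range(n_marks):
            if nuc_mask[m, j]:
                k += 1
        if k > 0:
            pick = int(u[3] * k)
            if pick >= k:  # guard u == 1.0
                pick = k - 1
            seen = -1
            sel = -1
            for m in range(n_marks):
                if nuc_mask[m, j]:
                    seen += 1
                    if seen == pick:
                        sel = m
                        break
            if u[4] < p_a[sel]:
                states[j] = sel + 1


def _sweep_loop_py(states, nuc_mask, p_a, p_d, p_s, sites, u, measure_from, occ, counts):
    """Run a chunk of sweeps; semantics identical to repeated apply_event.

    sites : (S*N,) int64 target unit per micro-event (uniform with replacement).
    u : (S*N, 5) float64 uniforms per event.
    measure_from : sweep index within this chunk from which occupancy accrues.
    occ : (M, N) int64, occupancy sweep-counts, accumulated in place.
    counts : (S, M) int64 out, per-mark totals after each sweep.
    """
    n = states.shape[0]
    n_marks = p_a.shape[0]
    n_sweeps = sites.shape[0] // n
    cur = np.zeros(n_marks, np.int64)
    for j in range(n):
        if states[j] > 0:
            cur[states[j] - 1] += 1
    e = 0
    for s in range(n_sweeps):
        for _ in range(n):
            j = sites[e]
            st = states[j]
            if st > 0:
                m = st - 1
                if n > 1:
                    if j == 0:
                        nb = 1
                    elif j == n - 1:
                        nb = n - 2
                    else:
                        nb = j - 1 if u[e, 0] < 0.5 else j + 1
                    if u[e, 1] < p_s[m] and states[nb] == 0:
                        states[nb] = st
                        cur[m] += 1
                if u[e, 2] < p_d[m]:
                    states[j] = 0
                    cur[m] -= 1
            else:
                k = 0
                for m in range(n_marks):
                    if nuc_mask[m, j]:
                        k += 1
                if k > 0:
                    pick = int(u[e, 3] * k)
                    if pick >= k:
                        pick = k - 1
                    seen = -1
                    sel = -1
                    for m in range(n_marks):
                        if nuc_mask[m, j]:
                            seen += 1
                            if seen == pick:
                                sel = m
                                break
                    if u[e, 4] < p_a[sel]:
                        states[j] = sel + 1
                        cur[sel] += 1
            e += 1
        for m in range(n_marks):
            counts[s, m] = cur[m]
        if s >= measure_from:
            for j in range(n):
                if states[j] > 0:
                    occ[states[j] - 1, j] += 1


if _HAVE_NUMBA:
    _sweep_loop = njit(cache=True, nogil=True)(_sweep_loop_py)
else:  # pragma: no cover
    _sweep_loop = _sweep_loop_py
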