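"""Exact stationary state of tiny chains by brute-force enumeration.

For chains small enough that all (M+1)^N mark assignments can be
enumerated, the single micro-update rule (uniform unit choice marginalized
in) defines a sparse stochastic matrix whose stationary distribution can be
solved exactly. The resulting per-site, per-mark stationary occupancies are
the reference values the Monte-Carlo simulator is validated against: the
simulator's time-averaged x̄ must agree with them to within Monte-Carlo
error on every site.

The transition probabilities below mirror the kernel's event semantics
exactly — propagation (uniform neighbor choice among existing neighbors,
success only onto an unmodified unit) and deletion are independent Bernoulli
attempts within one event, and an unmodified nucleation unit picks one of
its nucleating marks uniformly before the deposition attempt. Any change to
the kernel's conventions must be reflected here; the equivalence tests make
a divergence loud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .chain import RateParams
from .nucleation import NucleationLayout

DEFAULT_STATE_CAP = 3**10


@dataclass(frozen=True)
class StateSpace:
    """All (M+1)^N assignments, indexed by base-(M+1) encoding.

    State index u decodes to site states ``digit(u, j) = (u // (M+1)^j) % (M+1)``
    with 0 = unmodified; the encoding is bijective and stable across runs.
    """

    n_units: int
    n_marks: int

    @property
    def size(self) -> int:
        return (self.n_marks + 1) ** self.n_units

    def decode(self, index: int) -> np.ndarray:
        base = self.n_marks + 1
        out = np.empty(self.n_units, dtype=np.int8)
        for j in range(self.n_units):
            out[j] = index % base
            index //= base
        return out

    def encode(self, states: np.ndarray) -> int:
        base = self.n_marks + 1
        idx = 0
        for j in range(self.n_units - 1, -1, -1):
            idx = idx * base + int(states[j])
        return idx


def enumerate_states(n_units: int, n_marks: int = 2,
                     cap: int = DEFAULT_STATE_CAP) -> StateSpace:
    """State space of the N-unit, M-mark chain; refuses sizes beyond ``cap``."""
    space = StateSpace(n_units, n_marks)
    if space.size > cap:
        raise ValueError(
            f"state space of size {space.size} exceeds cap {cap}; reduce N or M"
        )
    return space


def transition_matrix(space: StateSpace, layout: NucleationLayout,
                      rates: RateParams) -> scipy.sparse.csr_matrix:
    """Exact one-micro-update transition matrix over the state space.

    Entry (u, v) is the probability that a single micro-event — at a unit
    chosen uniformly — maps assignment u to assignment v.
    """
    if layout.n_units != space.n_units:
        raise ValueError("layout and state space disagree on chain length")
    if rates.n_marks != space.n_marks:
        raise ValueError("rates and state space disagree on mark count")
    n, n_marks = space.n_units, space.n_marks
    mask = layout.mask(n)
    site_w = 1.0 / n

    rows, cols, vals = [], [], []

    def add(u, v, p):
        if p > 0.0:
            rows.append(u)
            cols.append(v)
            vals.append(p)

    for u in range(space.size):
        st = space.decode(u)
        for j in range(n):
            if st[j] > 0:
                m = st[j] - 1
                neighbors = [k for k in (j - 1, j + 1) if 0 <= k < n]
                nb_w = 1.0 / len(neighbors) if neighbors else 0.0
                p_del = rates.p_d[m]
                if not neighbors:
                    st2 = st.copy(); st2[j] = 0
                    add(u, space.encode(st2), site_w * p_del)
                    add(u, u, site_w * (1.0 - p_del))
                else:
                    for nb in neighbors:
                        p_prop = rates.p_s[m] if st[nb] == 0 else 0.0
                        # four prop x del outcomes for this neighbor choice
                        both = st.copy(); both[nb] = st[j]; both[j] = 0
                        prop_only = st.copy(); prop_only[nb] = st[j]
                        del_only = st.copy(); del_only[j] = 0
                        w = site_w * nb_w
                        add(u, space.encode(both), w * p_prop * p_del)
                        add(u, space.encode(prop_only), w * p_prop * (1.0 - p_del))
                        add(u, space.encode(del_only), w * (1.0 - p_prop) * p_del)
                        add(u, u, w * (1.0 - p_prop) * (1.0 - p_del))
            else:
                nuc_marks = [m for m in range(n_marks) if mask[m, j]]
                if nuc_marks:
                    stay = 1.0
                    for m in nuc_marks:
                        p = rates.p_a[m] / len(nuc_marks)
                        st2 = st.copy(); st2[j] = m + 1
                        add(u, space.encode(st2), site_w * p)
                        stay -= p
                    add(u, u, site_w * stay)
                else:
                    add(u, u, site_w)

    mat = scipy.sparse.coo_matrix(
        (vals, (rows, cols)), shape=(space.size, space.size)
    ).tocsr()
    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    if not np.allclose(row_sums, 1.0, atol=1e-12):
        raise AssertionError("transition matrix rows do not sum to 1")
    return mat


def stationary_distribution(matrix: scipy.sparse.csr_matrix,
                            tol: float = 1e-10) -> np.ndarray:
    """Solve pi @ P = pi, sum(pi) = 1 exactly via a sparse linear solve."""
    size = matrix.shape[0]
    a = (matrix.T - scipy.sparse.identity(size, format="csr")).tolil()
    a[0, :] = 1.0  # replace one equation by the normalization constraint
    b = np.zeros(size)
    b[0] = 1.0
    pi = scipy.sparse.linalg.spsolve(a.tocsr(), b)
    residual = np.abs(pi @ matrix - pi).max()
    if residual > tol:
        raise ArithmeticError(
            f"stationary solve residual {residual:.2e} exceeds tolerance {tol:.0e}"
        )
    # guard tiny negative round-off
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def stationary_marginals(space: StateSpace, pi: np.ndarray) -> np.ndarray:
    """Per-site, per-mark stationary occupancy, shape (M, N).

    Entry (i-1, j) is the stationary probability that unit j carries mark i;
    together with the unmodified probability these sum to 1 at every site.
    """
    out = np.zeros((space.n_marks, space.n_units))
    for u in range(space.size):
        if pi[u] == 0.0:
            continue
        st = space.decode(u)
        for j in range(space.n_units):
            if st[j] > 0:
                out[st[j] - 1, j] += pi[u]
    return out


def exact_marginals(layout: NucleationLayout, rates: RateParams,
                    cap: int = DEFAULT_STATE_CAP) -> np.ndarray:
    """Convenience: enumerate, build the matrix, solve, and marginalize."""
    space = enumerate_states(layout.n_units, rates.n_marks, cap)
    mat = transition_matrix(space, layout, rates)
    pi = stationary_distribution(mat)
    return stationary_marginals(space, pi)
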