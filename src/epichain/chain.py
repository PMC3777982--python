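"""Core chain state, stochastic rates, and the single-event/sweep update API.

A chromosome is a linear chain of ``N`` nucleosomal units with only
nearest-neighbor interactions. Each unit is either unmodified or carries
exactly one of ``M`` antagonistic mark families (mark 1 is
heterochromatin-like, mark 2 euchromatin-like in the default two-mark
setting). Marks nucleate at dedicated units with rate ``p_a``, spread to an
unmodified nearest neighbor with rate ``p_s,i``, and are erased with rate
``p_d`` — all probabilities per histone per time step. A new mark is never
written over an existing one (mutual exclusion), which is the only coupling
between the mark families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from ._kernel import apply_event

if TYPE_CHECKING:
    from .nucleation import NucleationLayout

UNMODIFIED = 0


def _as_rate_array(value, n_marks: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=np.float64))
    if arr.size == 1:
        arr = np.full(n_marks, float(arr[0]))
    if arr.shape != (n_marks,):
        raise ValueError(f"{name} must be a scalar or length-{n_marks} sequence")
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {arr}")
    return arr


@dataclass(frozen=True)
class RateParams:
    """Per-mark stochastic rates (probability per histone per time step).

    ``p_a`` is the association rate at nucleation sites, ``p_d`` the deletion
    rate, ``p_s`` the propagation rate to an unmodified nearest neighbor.
    Scalars broadcast to every mark; by default association and deletion are
    shared across marks while propagation may differ (``p_s[0]`` is the
    heterochromatin rate ``p_s,1``).
    """

    p_a: np.ndarray
    p_d: np.ndarray
    p_s: np.ndarray
    n_marks: int = 2

    def __init__(self, p_a=0.05, p_d=0.01, p_s=0.1, n_marks: int = 2):
        if n_marks < 1:
            raise ValueError("n_marks must be >= 1")
        object.__setattr__(self, "n_marks", int(n_marks))
        object.__setattr__(self, "p_a", _as_rate_array(p_a, n_marks, "p_a"))
        object.__setattr__(self, "p_d", _as_rate_array(p_d, n_marks, "p_d"))
        object.__setattr__(self, "p_s", _as_rate_array(p_s, n_marks, "p_s"))

    def replace(self, **kwargs) -> "RateParams":
        """Return a copy with the named rate(s) replaced."""
        current = {"p_a": self.p_a, "p_d": self.p_d, "p_s": self.p_s,
                   "n_marks": self.n_marks}
        current.update(kwargs)
        return RateParams(**current)


@dataclass
class ChainState:
    """Mark assignment of every nucleosomal unit.

    ``states[j] == 0`` means unmodified; ``states[j] == i`` means unit ``j``
    carries mark ``i`` (1-based mark index).
    """

    states: np.ndarray
    n_marks: int = 2

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1 or self.states.shape[0] < 1:
            raise ValueError("a chain needs at least one unit")
        if np.any(self.states < 0) or np.any(self.states > self.n_marks):
            raise ValueError("site states must be 0 (unmodified) or a mark index")

    @property
    def n_units(self) -> int:
        return self.states.shape[0]

    def mark_counts(self) -> np.ndarray:
        """Number of units carrying each mark, shape (n_marks,)."""
        return np.bincount(self.states, minlength=self.n_marks + 1)[1:]

    def copy(self) -> "ChainState":
        return ChainState(self.states.copy(), self.n_marks)

    # -- run-length-encoded TSV, for debugging / inspection ----------------
    def to_rle_tsv(self) -> str:
        lines = ["start\tend\tstate"]
        s = self.states
        boundaries = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [s.shape[0]]))
        for a, b in zip(starts, ends):
            lines.append(f"{a}\t{b}\t{int(s[a])}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_rle_tsv(cls, text: str, n_marks: int = 2) -> "ChainState":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        n = max(int(r[1]) for r in rows)
        states = np.zeros(n, dtype=np.int8)
        for a, b, v in rows:
            states[int(a):int(b)] = int(v)
        return cls(states, n_marks)


def init_chain(n_units: int, n_marks: int = 2) -> ChainState:
    """Return a completely unmodified chain of ``n_units`` sites."""
    if n_units < 1:
        raise ValueError(f"chain length must be >= 1, got {n_units}")
    return ChainState(np.zeros(int(n_units), dtype=np.int8), n_marks)


def update_site(
    state: ChainState,
    j: int,
    layout: "NucleationLayout",
    rates: RateParams,
    rng: np.random.Generator,
) -> ChainState:
    """Apply exactly one micro-event at unit ``j`` and return the new state.

    Five uniforms are drawn in the documented order (neighbor choice,
    propagation, deletion, nucleation mark-choice, nucleation accept)
    regardless of which are consumed by the event, so a trajectory is a pure
    function of the seed. At most unit ``j`` and one nearest neighbor change.
    """
    if not 0 <= j < state.n_units:
        raise IndexError(f"site index {j} out of range for chain of {state.n_units}")
    new = state.copy()
    u = rng.random(5)
    apply_event(new.states, int(j), layout.mask(state.n_units),
                rates.p_a, rates.p_d, rates.p_s, u)
    return new


def sweep(
    state: ChainState,
    layout: "NucleationLayout",
    rates: RateParams,
    rng: np.random.Generator,
) -> ChainState:
    """One time step: N micro-events at units drawn uniformly with replacement."""
    n = state.n_units
    new = state.copy()
    mask = layout.mask(n)
    sites = rng.integers(0, n, size=n)
    u = rng.random((n, 5))
    for e in range(n):
        apply_event(new.states, int(sites[e]), mask,
                    rates.p_a, rates.p_d, rates.p_s, u[e])
    return new
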