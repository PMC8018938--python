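"""Exact transforms between the strategy-major and age-major coordinates.

Both systems describe the same joint distribution over (strategy j, age i);
the canonical coordinates are the joint frequencies

    q_j^i = p_j a_j^i = a^i p_j^i.

The transforms divide by class totals (A -> B) or by strategy totals
(B -> A), so they are undefined on boundary states: an empty age class or an
extinct strategy fails loudly rather than being renormalized silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AgerepError, GuardViolationError
from .states import StateA, StateB

__all__ = ["CanonicalFrequencies", "to_canonical", "a_to_b", "b_to_a"]


@dataclass
class CanonicalFrequencies:
    """Joint (strategy, age-class) frequency grid, total mass 1."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q < -1e-12):
            raise AgerepError("canonical frequencies must be non-negative")
        if abs(self.q.sum() - 1.0) > 1e-8:
            raise AgerepError("canonical frequencies must sum to 1")

    def strategy_marginal(self) -> np.ndarray:
        return self.q.sum(axis=1)

    def age_marginal(self) -> np.ndarray:
        return self.q.sum(axis=0)


def to_canonical(state: StateA | StateB) -> CanonicalFrequencies:
    """Joint frequencies q_j^i from either coordinate system."""
    if isinstance(state, StateA):
        return CanonicalFrequencies(state.p[:, None] * state.a)
    if isinstance(state, StateB):
        return CanonicalFrequencies((state.ag[:, None] * state.pc).T)
    raise AgerepError(f"unsupported state type {type(state).__name__}")


def a_to_b(state: StateA) -> StateB:
    """Strategy-major to age-major: ag^i = Σ_j p_j a_j^i, pc rows by class."""
    q = state.p[:, None] * state.a  # (w, m+1)
    ag = q.sum(axis=0)
    empty = np.flatnonzero(ag <= 0)
    if empty.size:
        raise GuardViolationError(f"age class {empty[0]} is empty; strategy mix undefined")
    pc = (q / ag[None, :]).T  # (m+1, w)
    return StateB(ag=ag, pc=pc, n=state.n)


def b_to_a(state: StateB) -> StateA:
    """Age-major to strategy-major: p_j = Σ_i a^i p_j^i, age rows by strategy."""
    q = (state.ag[:, None] * state.pc).T  # (w, m+1)
    p = q.sum(axis=1)
    extinct = np.flatnonzero(p <= 0)
    if extinct.size:
        raise GuardViolationError(f"strategy {extinct[0]} is extinct; its age row is undefined")
    a = q / p[:, None]
    return StateA(p=p, a=a, n=state.n)
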