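"""Age-structured replicator dynamics in both coordinate systems.

The core model: ``w`` strategies, ``m + 1`` unit age classes, and
state-dependent demographic payoffs.  One game round yields fertility
``f_j^i(p, a)`` and death probability ``d_j^i(p, a)`` for a ``j``-strategist
of age ``i``; with interaction rate ``τ`` (fraction of individuals playing one
round per time unit) the vital rates are ``τ f_j^i`` and survival
``s_j^i = 1 - τ d_j^i``.  Recruitment is density-dependent: fertility — never
survival — is multiplied by the logistic factor ``(1 - n/K)``.

Strategy-major form (system Sa), integrating classes 1..m with class 0 the
simplex residual:

    ȧ_j^i = a_j^{i-1} s_j^{i-1} - a_j^i ( f̄_j (1 - n/K) + s̄_j )
    ṗ_j   = p_j ( (f̄_j - f̄)(1 - n/K) + (s̄_j - s̄) )
    ṅ     = n ( f̄ (1 - n/K) + s̄ - 1 )

Age-major form (system Sb), with per-class strategy mixes ``p_j^i`` and
global age structure ``a^i``:

    ṗ_j^0 = (1/a^0) ( Σ_i a^i p_j^i f_j^i - p_j^0 f̄ ) (1 - n/K)
    ṗ_j^i = (a^{i-1}/a^i) ( p_j^{i-1} s_j^{i-1} - p_j^i s̄^{i-1} )
    ȧ^i   = a^{i-1} s̄^{i-1} - a^i ( f̄ (1 - n/K) + s̄ )
    ṅ     = n ( f̄ (1 - n/K) + s̄ - 1 )

The two systems are mutually equivalent under the coordinate transforms; the
recommended practice is to integrate Sa and transform, keeping Sb for
verification and age-major analyses on interior states.  At any rest point of
``ṅ`` with ``f̄ > 0`` the population size satisfies
``n = K (1 - (1 - s̄)/f̄)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np

from . import coordinates
from .errors import AgerepError, GuardViolationError
from .states import StateA, StateB

__all__ = [
    "PayoffModel",
    "constant_payoffs",
    "Averages",
    "StateADot",
    "StateBDot",
    "EquilibriumSize",
    "averages_a",
    "malthusian",
    "rhs_a",
    "rhs_b",
    "equilibrium_size",
]

#: near-empty age-class guard for the divisions in system Sb
EPS_CLASS = 1e-12

RateProvider = Callable[[np.ndarray, np.ndarray, float], tuple[np.ndarray, np.ndarray]]


def constant_payoffs(f, d) -> RateProvider:
    """Rate provider returning fixed per-strategy, per-class payoff arrays."""
    f = np.asarray(f, dtype=float)
    d = np.asarray(d, dtype=float)
    if f.shape != d.shape or f.ndim != 2:
        raise AgerepError("fertility and death payoffs must be equal-shape (w, m+1) arrays")

    def provider(p, a, n):
        return f, d

    return provider


@dataclass
class PayoffModel:
    """Demographic-payoff contract for the replicator systems.

    ``rate_provider(p, a, n)`` must return per-round game payoffs: fertilities
    ``f_j^i >= 0`` and death probabilities ``d_j^i`` as ``(w, m+1)`` arrays.
    The model converts them to vital rates: fertility ``τ f`` (optionally
    pre-multiplied by single-round survival ``1 - d`` when only survivors of
    the round reproduce) and survival ``1 - τ d``, rejecting ``τ d > 1``.
    """

    n_strategies: int
    n_classes: int  # m + 1
    carrying_capacity: float
    rate_provider: RateProvider
    interaction_rate: float = 1.0
    survivors_reproduce: bool = False

    def __post_init__(self) -> None:
        if self.carrying_capacity <= 0:
            raise AgerepError("carrying capacity must be positive (use inf for density-free)")
        if self.interaction_rate <= 0:
            raise AgerepError("interaction rate must be positive")

    @classmethod
    def constant(cls, f, d, *, K: float = np.inf, tau: float = 1.0,
                 survivors_reproduce: bool = False) -> "PayoffModel":
        f = np.asarray(f, dtype=float)
        return cls(
            n_strategies=f.shape[0],
            n_classes=f.shape[1],
            carrying_capacity=K,
            rate_provider=constant_payoffs(f, d),
            interaction_rate=tau,
            survivors_reproduce=survivors_reproduce,
        )

    def rates(self, p: np.ndarray, a: np.ndarray, n: float) -> tuple[np.ndarray, np.ndarray]:
        """Vital rates (F, S) at a population state, τ folded in."""
        f, d = self.rate_provider(np.asarray(p, float), np.asarray(a, float), float(n))
        f = np.asarray(f, dtype=float)
        d = np.asarray(d, dtype=float)
        shape = (self.n_strategies, self.n_classes)
        if f.shape != shape or d.shape != shape:
            raise AgerepError(f"rate provider must return {shape} arrays")
        if np.any(f < 0):
            raise AgerepError("fertility payoffs must be non-negative")
        tau = self.interaction_rate
        S = 1.0 - tau * d
        if np.any(S < 0) or np.any(S > 1):
            raise AgerepError("survival 1 - τd outside [0, 1]: interaction rate too large")
        F = tau * f
        if self.survivors_reproduce:
            F = F * (1.0 - d)
        return F, S

    def density_factor(self, n: float) -> float:
        # (1 - n/K); deliberately unclamped, may go negative if n > K transiently
        return 1.0 - n / self.carrying_capacity


@dataclass
class Averages:
    """Fertility/survival means at one state, in all three aggregations."""

    fbar_j: np.ndarray
    sbar_j: np.ndarray
    fbar_i: np.ndarray
    sbar_i: np.ndarray
    fbar: float
    sbar: float
    rbar_j: np.ndarray = field(default=None)  # Malthusian parameters, if computed


def averages_a(state: StateA, F: np.ndarray, S: np.ndarray) -> Averages:
    """All fertility/survival averages from strategy-major coordinates.

    Per-class means use the age-major strategy mixes, i.e. the B-coordinate
    push-forward of the state; the two routes to the global means agree.
    """
    if F.shape != state.a.shape or S.shape != state.a.shape:
        raise AgerepError("rate arrays must have shape (w, m+1)")
    fbar_j = np.sum(state.a * F, axis=1)
    sbar_j = np.sum(state.a * S, axis=1)
    b = coordinates.a_to_b(state)
    fbar_i = np.sum(b.pc * F.T, axis=1)
    sbar_i = np.sum(b.pc * S.T, axis=1)
    return Averages(
        fbar_j=fbar_j,
        sbar_j=sbar_j,
        fbar_i=fbar_i,
        sbar_i=sbar_i,
        fbar=float(state.p @ fbar_j),
        sbar=float(state.p @ sbar_j),
    )


def malthusian(state: StateA, model: PayoffModel) -> np.ndarray:
    """Per-strategy Malthusian parameters
    ``r̄_j = Σ_i a_j^i ( τ f_j^i (1 - n/K) + s_j^i ) - 1``."""
    F, S = model.rates(state.p, state.a, state.n)
    dens = model.density_factor(state.n)
    return np.sum(state.a * (F * dens + S), axis=1) - 1.0


class StateADot(NamedTuple):
    """Time derivative of a StateA; ``a_dot[:, 0]`` is the residual-implied
    class-0 derivative (not independently integrated)."""

    p_dot: np.ndarray
    a_dot: np.ndarray
    n_dot: float


class StateBDot(NamedTuple):
    pc_dot: np.ndarray
    ag_dot: np.ndarray
    n_dot: float


def rhs_a(state: StateA, model: PayoffModel) -> StateADot:
    """Right-hand side of the strategy-major system Sa."""
    F, S = model.rates(state.p, state.a, state.n)
    dens = model.density_factor(state.n)
    fbar_j = np.sum(state.a * F, axis=1)
    sbar_j = np.sum(state.a * S, axis=1)
    fbar = float(state.p @ fbar_j)
    sbar = float(state.p @ sbar_j)

    p_dot = state.p * ((fbar_j - fbar) * dens + (sbar_j - sbar))
    growth = fbar_j * dens + sbar_j  # = r̄_j + 1
    a_dot = np.empty_like(state.a)
    a_dot[:, 1:] = state.a[:, :-1] * S[:, :-1] - state.a[:, 1:] * growth[:, None]
    a_dot[:, 0] = -a_dot[:, 1:].sum(axis=1)
    n_dot = state.n * (fbar * dens + sbar - 1.0)
    return StateADot(p_dot=p_dot, a_dot=a_dot, n_dot=n_dot)


def rhs_b(state: StateB, model: PayoffModel, *, eps: float = EPS_CLASS) -> StateBDot:
    """Right-hand side of the age-major system Sb.

    Payoffs are evaluated at the strategy-major push-forward of the state
    (the rate contract is written in (p, a) coordinates).  Divisions by the
    class frequencies require every involved class to hold at least ``eps``
    mass.
    """
    small = np.flatnonzero(state.ag < eps)
    if small.size:
        raise GuardViolationError(f"age class {small[0]} below guard {eps}: Sb division undefined")
    sa = coordinates.b_to_a(state)
    F, S = model.rates(sa.p, sa.a, state.n)  # (w, m+1)
    dens = model.density_factor(state.n)
    Ft, St = F.T, S.T  # (m+1, w)
    fbar_i = np.sum(state.pc * Ft, axis=1)
    sbar_i = np.sum(state.pc * St, axis=1)
    fbar = float(state.ag @ fbar_i)
    sbar = float(state.ag @ sbar_i)

    pc_dot = np.empty_like(state.pc)
    pc_dot[0] = (np.sum(state.ag[:, None] * state.pc * Ft, axis=0)
                 - state.pc[0] * fbar) * dens / state.ag[0]
    ratio = state.ag[:-1] / state.ag[1:]
    pc_dot[1:] = ratio[:, None] * (
        state.pc[:-1] * St[:-1] - state.pc[1:] * sbar_i[:-1, None]
    )
    ag_dot = np.empty_like(state.ag)
    ag_dot[1:] = state.ag[:-1] * sbar_i[:-1] - state.ag[1:] * (fbar * dens + sbar)
    ag_dot[0] = -ag_dot[1:].sum()
    n_dot = state.n * (fbar * dens + sbar - 1.0)
    return StateBDot(pc_dot=pc_dot, ag_dot=ag_dot, n_dot=n_dot)


class EquilibriumSize(NamedTuple):
    n: float
    viable: bool


def equilibrium_size(fbar: float, sbar: float, K: float) -> EquilibriumSize:
    """Rest-point population size ``n = K (1 - (1 - s̄)/f̄)``.

    A negative value means the vital rates cannot sustain the population; it
    is returned as-is with ``viable=False``.
    """
    if fbar <= 0:
        raise AgerepError("equilibrium size undefined for f̄ <= 0")
    n = K * (1.0 - (1.0 - sbar) / fbar)
    return EquilibriumSize(n=n, viable=n >= 0)
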