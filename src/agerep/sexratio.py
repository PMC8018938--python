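"""Sex-ratio evolution: the built-in case study of the replicator framework.

A haploid gene carried by both sexes encodes the fraction ``P_j`` of males a
carrier female produces in her brood of ``k`` offspring; offspring inherit
the maternal or paternal gene with probability 1/2.  The baseline (age-free)
model tracks gene frequencies ``G_j`` and carrier sex ratios ``M_j``; its
interior attractor is the Fisherian population sex ratio ``P = 1/2``.

The age-structured extension gives each gene an age structure ``a_j^i`` and a
per-class sex ratio ``M_j^i``, with sex- and age-specific survivals
``s_f^i``/``s_m^i`` and maturation windows (males active in classes
``[a, b]``, females in ``[c, d]``).  Fertility flows through the active
fractions

    S_j^f = Σ_{z=c..d} a_j^z (1 - M_j^z),   S_j^m = Σ_{z=a..b} a_j^z M_j^z,

and a gene's excess fertility payoff reduces to the Shaw-Mohler form

    f_g - f̄ = k [ (S_j^f/S̄^f + S_j^m/S̄^m)/2 - 1 ] S̄^f,

zero for every gene at the Fisherian equilibrium of the unstructured model.
With sex-asymmetric survival the long-run primary sex ratio is still 1/2, but
the Shaw-Mohler term alone no longer vanishes at the attractor: it is exactly
balanced by the survival excess ``s̄_j - s̄``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import AgerepError, GuardViolationError
from .states import AgeSexRatioState

__all__ = [
    "BaselineSexRatioState",
    "SexRatioParams",
    "ActiveFractions",
    "SexRatios",
    "SurvivalMeans",
    "AgePayoffs",
    "AgeSexRatioDot",
    "baseline_payoffs",
    "baseline_rhs",
    "active_fractions",
    "sex_ratios",
    "survival_means",
    "age_payoffs",
    "shaw_mohler",
    "age_sexratio_rhs",
    "age_sexratio_rhs_generic",
    "manifold_age",
    "manifold_sexratio",
]

EPS_CLASS = 1e-12


# ---------------------------------------------------------------------------
# baseline (age-free) model
# ---------------------------------------------------------------------------

@dataclass
class BaselineSexRatioState:
    """Age-free sex-ratio state: gene frequencies ``G_j``, carrier sex ratios
    ``M_j`` and the strategies ``P_j`` the genes encode."""

    G: np.ndarray
    M: np.ndarray
    strategies: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.strategies = np.asarray(self.strategies, dtype=float)
        if not (self.G.shape == self.M.shape == self.strategies.shape):
            raise AgerepError("G, M and strategies must have equal length")
        if abs(self.G.sum() - 1.0) > 1e-8 or np.any(self.G < -1e-12):
            raise AgerepError("G must lie on the simplex")
        if np.any(self.M < 0) or np.any(self.M > 1):
            raise AgerepError("M entries must lie in [0, 1]")
        if np.any(self.strategies < 0) or np.any(self.strategies > 1):
            raise AgerepError("strategies must lie in [0, 1]")

    @property
    def P(self) -> float:
        """Population (secondary) sex ratio ``P = Σ_j G_j M_j``."""
        return float(self.G @ self.M)

    @property
    def P_pr(self) -> float:
        """Primary sex ratio: the female-weighted average strategy."""
        P = self.P
        if not 0 < P < 1:
            raise GuardViolationError("primary sex ratio undefined at boundary P")
        return float(np.sum(self.G * (1.0 - self.M) * self.strategies) / (1.0 - P))


class BaselinePayoffs(NamedTuple):
    f_m: np.ndarray
    f_f: np.ndarray
    f_g: np.ndarray
    fbar_m: float
    fbar: float


def baseline_payoffs(state: BaselineSexRatioState, k: float) -> BaselinePayoffs:
    """Per-gene fertility payoffs of the age-free model.

    Male carriers earn half the broods of their partners (average female
    strategy) plus half those of same-gene females per male; female carriers
    the mirror image.  Averages: ``f̄_m = k P̄_pr (1-P)/P`` and ``f̄ = k(1-P)``.
    """
    P = state.P
    if not 0 < P < 1:
        raise GuardViolationError("payoffs undefined at boundary population sex ratio")
    if np.any(state.M <= 0) or np.any(state.M >= 1):
        raise GuardViolationError("payoffs undefined at boundary carrier sex ratios")
    P_pr = state.P_pr
    Pj, M = state.strategies, state.M
    f_m = (k / 2.0) * ((1 - P) / P * P_pr + (1 - M) / M * Pj)
    f_f = (k / 2.0) * ((1 - Pj) + M / (1 - M) * (1 - P_pr) * (1 - P) / P)
    f_g = (k / 2.0) * (M * (1 - P) / P + (1 - M))
    return BaselinePayoffs(
        f_m=f_m, f_f=f_f, f_g=f_g,
        fbar_m=k * (1 - P) / P * P_pr,
        fbar=k * (1 - P),
    )


def baseline_rhs(state: BaselineSexRatioState, k: float) -> tuple[np.ndarray, np.ndarray]:
    """Selection (``Ġ_j = G_j (f_g - f̄)``) and tug-of-war (``Ṁ_j``) dynamics.

    In closed form ``Ġ_j = G_j k (1/2 - P)(M_j/P - 1)``: gene frequencies move
    only while the population sex ratio differs from 1/2.
    """
    pay = baseline_payoffs(state, k)
    P, P_pr = state.P, state.P_pr
    Pj, M, G = state.strategies, state.M, state.G
    G_dot = G * (pay.f_g - pay.fbar)
    M_dot = (k / 2.0) * (M * (1 - P) / P * (P_pr - M) + (1 - M) * (Pj - M))
    return G_dot, M_dot


# ---------------------------------------------------------------------------
# age-structured model
# ---------------------------------------------------------------------------

@dataclass
class SexRatioParams:
    """Parameters of the age-structured sex-ratio model.

    ``strategies`` are the encoded male fractions ``P_j``; ``k`` the brood
    size; ``s_f``/``s_m`` the female/male per-class survivals (terminal class
    zero); ``male_window``/``female_window`` inclusive class-index ranges of
    sexual activity; ``K`` the carrying capacity.
    """

    strategies: np.ndarray
    k: float
    s_f: np.ndarray
    s_m: np.ndarray
    male_window: tuple[int, int]
    female_window: tuple[int, int]
    K: float

    def __post_init__(self) -> None:
        self.strategies = np.asarray(self.strategies, dtype=float)
        self.s_f = np.asarray(self.s_f, dtype=float)
        self.s_m = np.asarray(self.s_m, dtype=float)
        if np.any(self.strategies < 0) or np.any(self.strategies > 1):
            raise AgerepError("strategies must lie in [0, 1]")
        if self.k <= 0:
            raise AgerepError("brood size must be positive")
        if self.s_f.shape != self.s_m.shape or self.s_f.ndim != 1:
            raise AgerepError("survival schedules must be 1-d arrays of equal length")
        for name, s in (("survival_female", self.s_f), ("survival_male", self.s_m)):
            if np.any(s < 0) or np.any(s > 1):
                raise AgerepError(f"{name} entries must lie in [0, 1]")
            if s[-1] != 0:
                raise AgerepError(f"{name} must be 0 in the terminal age class")
        m = self.s_f.size - 1
        for name, (lo, hi) in (("male_window", self.male_window),
                               ("female_window", self.female_window)):
            if not (0 <= lo <= hi <= m):
                raise AgerepError(f"{name} must satisfy 0 <= lo <= hi <= {m}")
        if self.K <= 0:
            raise AgerepError("carrying capacity must be positive")

    @property
    def w(self) -> int:
        return self.strategies.size

    @property
    def m(self) -> int:
        return self.s_f.size - 1

    def window_mask(self, which: str) -> np.ndarray:
        lo, hi = self.male_window if which == "male" else self.female_window
        mask = np.zeros(self.m + 1, dtype=bool)
        mask[lo:hi + 1] = True
        return mask


class ActiveFractions(NamedTuple):
    S_f: np.ndarray      # per gene
    S_m: np.ndarray
    S_f_bar: float
    S_m_bar: float


def active_fractions(state: AgeSexRatioState, params: SexRatioParams) -> ActiveFractions:
    """Fractions of sexually active females/males among each gene's carriers,
    and their gene-frequency-weighted population averages."""
    fmask = params.window_mask("female")
    mmask = params.window_mask("male")
    S_f = np.sum(state.A[:, fmask] * (1.0 - state.M[:, fmask]), axis=1)
    S_m = np.sum(state.A[:, mmask] * state.M[:, mmask], axis=1)
    return ActiveFractions(
        S_f=S_f, S_m=S_m,
        S_f_bar=float(state.G @ S_f),
        S_m_bar=float(state.G @ S_m),
    )


class SexRatios(NamedTuple):
    P: float          # population (secondary) sex ratio
    P_pr: float       # primary sex ratio, average strategy of active females
    M_op: np.ndarray  # per-gene operational sex ratio
    P_op: float       # population operational sex ratio


def sex_ratios(state: AgeSexRatioState, params: SexRatioParams,
               fractions: ActiveFractions) -> SexRatios:
    """Population, primary and operational sex ratios at a state."""
    P = float(state.G @ np.sum(state.A * state.M, axis=1))
    if fractions.S_f_bar <= 0:
        raise GuardViolationError("no active females: primary sex ratio undefined")
    P_pr = float(np.sum(state.G * fractions.S_f * params.strategies) / fractions.S_f_bar)
    tot = fractions.S_m + fractions.S_f
    if np.any(tot <= 0):
        j = int(np.flatnonzero(tot <= 0)[0])
        raise GuardViolationError(f"gene {j} has no active carriers: M_op undefined")
    M_op = fractions.S_m / tot
    denom = fractions.S_m_bar + fractions.S_f_bar
    if denom <= 0:
        raise GuardViolationError("no active individuals: P_op undefined")
    return SexRatios(P=P, P_pr=P_pr, M_op=M_op, P_op=fractions.S_m_bar / denom)


class SurvivalMeans(NamedTuple):
    s_ji: np.ndarray  # (w, m+1)
    s_j: np.ndarray   # (w,)
    sbar: float


def survival_means(state: AgeSexRatioState, params: SexRatioParams) -> SurvivalMeans:
    """Sex-ratio-weighted survivals ``s̄_j^i = M_j^i s_m^i + (1 - M_j^i) s_f^i``
    and their per-gene and global averages."""
    s_ji = state.M * params.s_m[None, :] + (1.0 - state.M) * params.s_f[None, :]
    s_j = np.sum(state.A * s_ji, axis=1)
    return SurvivalMeans(s_ji=s_ji, s_j=s_j, sbar=float(state.G @ s_j))


class AgePayoffs(NamedTuple):
    f_m_op: np.ndarray  # operational male fertility payoff, per gene
    f_g: np.ndarray     # per-capita gene fertility payoff
    fbar: float         # population mean fertility k S̄^f


def age_payoffs(strategies, fractions: ActiveFractions, ratios: SexRatios,
                k: float) -> AgePayoffs:
    """Fertility payoffs of the age-structured model, per gene.

    ``f_m_op`` is the payoff of an active male (partners at the average
    strategy plus same-gene "sisters"); ``f_g`` the per-capita payoff of the
    gene; ``f̄ = k S̄^f`` the population mean.
    """
    strategies = np.asarray(strategies, dtype=float)
    if not 0 < ratios.P_op < 1:
        raise GuardViolationError("operational payoffs undefined at boundary P_op")
    if np.any(ratios.M_op <= 0) or np.any(ratios.M_op >= 1):
        raise GuardViolationError("male payoff undefined at boundary per-gene M_op")
    f_m_op = (k / 2.0) * (
        (1 - ratios.P_op) / ratios.P_op * ratios.P_pr
        + (1 - ratios.M_op) / ratios.M_op * strategies
    )
    f_g = (k / 2.0) * (fractions.S_f + fractions.S_m
                       * fractions.S_f_bar / fractions.S_m_bar)
    return AgePayoffs(f_m_op=f_m_op, f_g=f_g, fbar=k * fractions.S_f_bar)


def shaw_mohler(fractions: ActiveFractions, k: float) -> np.ndarray:
    """Excess fertility payoff ``f_g - f̄`` in Shaw-Mohler form:
    ``k [ (S_j^f/S̄^f + S_j^m/S̄^m)/2 - 1 ] S̄^f`` per gene."""
    if fractions.S_f_bar <= 0 or fractions.S_m_bar <= 0:
        raise GuardViolationError("Shaw-Mohler form undefined with no active sex")
    return k * (0.5 * (fractions.S_f / fractions.S_f_bar
                       + fractions.S_m / fractions.S_m_bar) - 1.0) * fractions.S_f_bar


class AgeSexRatioDot(NamedTuple):
    """Time derivative; ``A_dot[:, 0]`` is the residual-implied class-0 value."""

    G_dot: np.ndarray
    A_dot: np.ndarray
    M_dot: np.ndarray
    n_dot: float


def age_sexratio_rhs(state: AgeSexRatioState, params: SexRatioParams,
                     *, eps: float = EPS_CLASS) -> AgeSexRatioDot:
    """Right-hand side of the age-structured sex-ratio system (closed form).

    Gene selection combines the Shaw-Mohler fertility excess (density-scaled)
    with the survival excess; age rows follow the strategy-major replicator
    recursion under the sex-averaged survivals; infant sex ratios relax toward
    the brood mix produced by active carriers, and older-class sex ratios
    follow differential male/female survival of the preceding class.
    """
    fr = active_fractions(state, params)
    sm = survival_means(state, params)
    ratios = sex_ratios(state, params, fr)
    k, K = params.k, params.K
    dens = 1.0 - state.n / K

    sm_excess = shaw_mohler(fr, k)
    G_dot = state.G * (sm_excess * dens + (sm.s_j - sm.sbar))

    f_g = (k / 2.0) * (fr.S_f + fr.S_m * fr.S_f_bar / fr.S_m_bar)
    growth = f_g * dens + sm.s_j
    A_dot = np.empty_like(state.A)
    A_dot[:, 1:] = state.A[:, :-1] * sm.s_ji[:, :-1] - state.A[:, 1:] * growth[:, None]
    A_dot[:, 0] = -A_dot[:, 1:].sum(axis=1)

    a0 = state.A[:, 0]
    if np.any(a0 < eps):
        j = int(np.flatnonzero(a0 < eps)[0])
        raise GuardViolationError(f"gene {j} class 0 below guard {eps}: infant sex-ratio dynamics undefined")
    M_dot = np.empty_like(state.M)
    M_dot[:, 0] = (k / (2.0 * a0)) * (
        fr.S_m * (ratios.P_pr - state.M[:, 0]) * fr.S_f_bar / fr.S_m_bar
        + fr.S_f * (params.strategies - state.M[:, 0])
    ) * dens
    inner = state.A[:, 1:]
    if np.any(inner < eps):
        j, i = np.argwhere(inner < eps)[0]
        raise GuardViolationError(
            f"gene {j} class {i + 1} below guard {eps}: sex-ratio dynamics undefined")
    M_dot[:, 1:] = (state.A[:, :-1] / inner) * (
        state.M[:, :-1] * params.s_m[None, :-1] - state.M[:, 1:] * sm.s_ji[:, :-1]
    )

    n_dot = state.n * (k * fr.S_f_bar * dens + sm.sbar - 1.0)
    return AgeSexRatioDot(G_dot=G_dot, A_dot=A_dot, M_dot=M_dot, n_dot=n_dot)


def age_sexratio_rhs_generic(state: AgeSexRatioState, params: SexRatioParams,
                             *, eps: float = EPS_CLASS) -> AgeSexRatioDot:
    """The same right-hand side in its generic payoff-substituted form.

    Written directly in terms of the payoffs ``f_g``, ``f̄`` and the
    operational male payoff ``f_m^op`` rather than their expanded closed
    forms; agrees with :func:`age_sexratio_rhs` to floating-point accuracy and
    is used as its algebraic cross-check.
    """
    fr = active_fractions(state, params)
    sm = survival_means(state, params)
    ratios = sex_ratios(state, params, fr)
    pay = age_payoffs(params.strategies, fr, ratios, params.k)
    dens = 1.0 - state.n / params.K

    G_dot = state.G * ((pay.f_g - pay.fbar) * dens + (sm.s_j - sm.sbar))

    growth = pay.f_g * dens + sm.s_j
    A_dot = np.empty_like(state.A)
    A_dot[:, 1:] = state.A[:, :-1] * sm.s_ji[:, :-1] - state.A[:, 1:] * growth[:, None]
    A_dot[:, 0] = -A_dot[:, 1:].sum(axis=1)

    a0 = state.A[:, 0]
    if np.any(a0 < eps) or np.any(state.A[:, 1:] < eps):
        raise GuardViolationError("near-empty age class: sex-ratio dynamics undefined")
    M_dot = np.empty_like(state.M)
    M_dot[:, 0] = (pay.f_m_op * fr.S_m - state.M[:, 0] * pay.f_g) / a0 * dens
    M_dot[:, 1:] = (state.A[:, :-1] / state.A[:, 1:]) * (
        state.M[:, :-1] * params.s_m[None, :-1] - state.M[:, 1:] * sm.s_ji[:, :-1]
    )

    n_dot = state.n * (pay.fbar * dens + sm.sbar - 1.0)
    return AgeSexRatioDot(G_dot=G_dot, A_dot=A_dot, M_dot=M_dot, n_dot=n_dot)


def manifold_age(state: AgeSexRatioState, params: SexRatioParams) -> np.ndarray:
    """Residuals of the age-structure attractor recursion, per gene and class
    ``i >= 1``:  ``a_j^i - a_j^{i-1} s̄_j^{i-1} / (f_g (1-n/K) + s̄_j)``.

    Zero rows mean the gene's age structure sits on its attracting manifold.
    """
    fr = active_fractions(state, params)
    sm = survival_means(state, params)
    if fr.S_m_bar <= 0:
        raise GuardViolationError("manifold undefined with no active males")
    f_g = (params.k / 2.0) * (fr.S_f + fr.S_m * fr.S_f_bar / fr.S_m_bar)
    dens = 1.0 - state.n / params.K
    denom = f_g * dens + sm.s_j
    if np.any(denom <= 0):
        raise GuardViolationError("non-positive growth denominator in age manifold")
    target = state.A[:, :-1] * sm.s_ji[:, :-1] / denom[:, None]
    return state.A[:, 1:] - target


def manifold_sexratio(state: AgeSexRatioState, params: SexRatioParams) -> np.ndarray:
    """Attracting per-class sex ratios ``M̂_j^i``, shape (w, m+1).

    Class 0: the brood mix of active carriers,
    ``M̂_j^0 = (P̄_pr S_j^m S̄^f/S̄^m + S_j^f P_j) / (S_j^m S̄^f/S̄^m + S_j^f)``;
    classes ``i > 0``: ``M̂_j^i = M_j^{i-1} s_m^{i-1} / s̄_j^{i-1}``.
    """
    fr = active_fractions(state, params)
    sm = survival_means(state, params)
    ratios = sex_ratios(state, params, fr)
    if fr.S_m_bar <= 0:
        raise GuardViolationError("sex-ratio manifold undefined with no active males")
    weight = fr.S_m / fr.S_m_bar * fr.S_f_bar
    denom0 = weight + fr.S_f
    if np.any(denom0 <= 0):
        raise GuardViolationError("sex-ratio manifold undefined for a gene with no active carriers")
    out = np.empty_like(state.M)
    out[:, 0] = (ratios.P_pr * weight + fr.S_f * params.strategies) / denom0
    prev_mean = sm.s_ji[:, :-1]
    if np.any(prev_mean <= 0):
        raise GuardViolationError("zero mean survival: older-class sex-ratio targets undefined")
    out[:, 1:] = state.M[:, :-1] * params.s_m[None, :-1] / prev_mean
    return out
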