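"""Seeded synthetic scenarios and the built-in Fisherian sex-ratio case study.

Everything every test needs is generated here programmatically; no external
data is read.  ``fisher_scenario`` builds the reference simulation of the
framework: three competing sex-ratio strategies in a 26-class population with
sex-asymmetric survival schedules, started from a deliberately young, heavily
skewed population so the transient dynamics of the growing cohort are
visible.
"""

from __future__ import annotations

import numpy as np

from .demography import AgeVitalRates
from .errors import AgerepError
from .replicator import PayoffModel
from .sexratio import SexRatioParams
from .states import AgeSexRatioState, StateA

__all__ = [
    "random_vital_rates",
    "random_interior_state",
    "random_payoff_model",
    "fisher_scenario",
    "degenerate_suite",
]


def random_vital_rates(seed: int, m: int, fertility_range=(0.0, 2.0),
                       survival_range=(0.3, 0.95)) -> AgeVitalRates:
    """Reproducible random vital rates with a closed last class.

    Guarantees at least one positive fertility (resampling if the draw is all
    zero); rejects ranges that make that impossible.
    """
    flo, fhi = fertility_range
    slo, shi = survival_range
    if fhi <= 0:
        raise AgerepError("fertility range admits no positive fertility")
    if not (0 <= slo <= shi <= 1):
        raise AgerepError("survival range must lie within [0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        f = rng.uniform(flo, fhi, size=m + 1)
        if np.any(f > 0):
            break
    else:  # pragma: no cover - only reachable with measure-zero ranges
        raise AgerepError("could not draw a positive fertility")
    s = rng.uniform(slo, shi, size=m + 1)
    return AgeVitalRates(f=f, s=s, closed_last_class=True)


def random_interior_state(seed: int, w: int, m: int, n: float = 100.0) -> StateA:
    """Random strategy-major state with every frequency comfortably interior.

    Simplex rows are independent positive uniforms on [0.5, 1.5] normalized to
    sum 1, so no entry can fall below ``0.5 / (1.5 (m+1))``; all entries are at
    least 1e-3 for the supported sizes, which keeps coordinate transforms and
    Sb divisions well-defined.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.5, 1.5, size=w)
    p /= p.sum()
    a = rng.uniform(0.5, 1.5, size=(w, m + 1))
    a /= a.sum(axis=1, keepdims=True)
    return StateA(p=p, a=a, n=n)


def random_payoff_model(seed: int, w: int, m: int, *, K: float = np.inf,
                        tau: float = 1.0) -> PayoffModel:
    """Constant-payoff model with seeded random fertilities and mortalities."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, 2.0, size=(w, m + 1))
    d = rng.uniform(0.05, 0.7, size=(w, m + 1))
    d[:, -1] = 1.0  # closed last class: survival 1 - τd = 0 at τ = 1
    if tau != 1.0:
        d[:, -1] = 1.0 / tau
    return PayoffModel.constant(f, d, K=K, tau=tau)


def _step_schedule(m: int, early: float, late: float, change_at: int) -> np.ndarray:
    """Survival ``early`` for classes < change_at, ``late`` afterwards, terminal 0."""
    s = np.full(m + 1, late)
    s[:change_at] = early
    s[-1] = 0.0
    return s


def fisher_scenario(brood_size: float = 6.0) -> tuple[SexRatioParams, AgeSexRatioState]:
    """The reference three-strategy sex-ratio simulation.

    Strategies P = (0.05, 0.55, 0.95); 26 age classes (infant class 0 through
    terminal class 25).  Female survival 0.95 in classes 0-9 and 0.80 from
    class 10 on; male survival 0.88 in classes 0-14 and 0.72 from class 15 on;
    terminal-class survival 0.  Females are fertile in classes 8-15, males
    active in 8-20.  The population starts very young: each of the 25
    non-infant classes holds frequency 0.001 (0.025 in total, class 0 the
    0.975 residual), gene frequencies (0.9, 0.05, 0.05), infant sex ratios
    (0.7, 0.1, 0.1), older-class sex ratios (0.9, 0.8, 0.8), n(0) = 40 and
    K = 10000.  The brood size is a free parameter (default 6); the headline
    outcome — primary sex ratio 0.5 — is insensitive to it.
    """
    m = 25
    params = SexRatioParams(
        strategies=np.array([0.05, 0.55, 0.95]),
        k=float(brood_size),
        s_f=_step_schedule(m, 0.95, 0.80, change_at=10),
        s_m=_step_schedule(m, 0.88, 0.72, change_at=15),
        male_window=(8, 20),
        female_window=(8, 15),
        K=10_000.0,
    )
    A = np.full((3, m + 1), 0.001)
    A[:, 0] = 1.0 - 0.001 * m
    M = np.tile(np.array([[0.9], [0.8], [0.8]]), (1, m + 1))
    M[:, 0] = [0.7, 0.1, 0.1]
    state = AgeSexRatioState(
        G=np.array([0.9, 0.05, 0.05]),
        A=A,
        M=M,
        n=40.0,
    )
    return params, state


def degenerate_suite() -> dict[str, dict]:
    """Edge scenarios, each tagged with the invariant it exercises."""
    suite: dict[str, dict] = {}

    # m = 0: one age class; Sa must reduce to the classical replicator
    f = np.array([[1.2], [0.8]])
    d = np.array([[0.3], [0.2]])
    suite["single_class"] = {
        "invariant": "reduces to the age-free fertility/mortality replicator",
        "model": PayoffModel.constant(f, d, K=1000.0),
        "state": StateA(p=np.array([0.4, 0.6]), a=np.ones((2, 1)), n=50.0),
    }

    # equal payoffs: no selection gradient, ṗ = 0
    f2 = np.full((2, 3), 0.9)
    d2 = np.full((2, 3), 0.25)
    d2[:, -1] = 1.0
    suite["equal_payoffs"] = {
        "invariant": "identical rates and age rows give ṗ = 0",
        "model": PayoffModel.constant(f2, d2, K=np.inf),
        "state": StateA(p=np.array([0.3, 0.7]),
                        a=np.tile([[0.5, 0.3, 0.2]], (2, 1)), n=10.0),
    }

    # single strategy: frequency cannot move
    suite["single_strategy"] = {
        "invariant": "w = 1 forces ṗ = 0",
        "model": PayoffModel.constant(np.array([[0.0, 1.5, 0.5]]),
                                      np.array([[0.1, 0.4, 1.0]]), K=np.inf),
        "state": StateA(p=np.array([1.0]),
                        a=np.array([[0.5, 0.3, 0.2]]), n=20.0),
    }

    # sex-symmetric survival: M trajectories become flat across the life cycle
    params, state = fisher_scenario()
    sym = SexRatioParams(
        strategies=params.strategies, k=params.k,
        s_f=params.s_f.copy(), s_m=params.s_f.copy(),
        male_window=params.female_window, female_window=params.female_window,
        K=params.K,
    )
    suite["sex_symmetric"] = {
        "invariant": "equal sex survivals and windows give constant M and Shaw-Mohler-only selection",
        "params": sym,
        "state": state,
    }
    return suite
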