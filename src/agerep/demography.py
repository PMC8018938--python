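"""Classical age-structure machinery.

A population with ``m + 1`` unit age classes (class 0 = newborns) and constant
per-class fertilities ``f^i`` and survival probabilities ``s^i`` follows the
Bernadelli-Lewis-Leslie projection

    n(t+1) = L n(t),   L = [[f^0, ..., f^m],
                            [s^0, 0, ..., 0],
                            ...,
                            [0, ..., s^{m-1}, 0]].

The dominant eigenvalue of ``L`` is the per-step growth multiplier ``λ`` and
its normalized non-negative eigenvector is the stable age distribution.  The
intrinsic growth rate ``r = ln λ`` solves the Euler-Lotka characteristic
equation.  These quantities serve both as standalone demography and as
independent oracles for the dynamic replicator systems: the continuous-time
age dynamics are attracted to the manifold

    â^i ∝ Π_{z<i} s^z / λ^i,

which coincides with the stable age distribution when ``λ`` is the dominant
multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import AgerepError, DegenerateInputError

__all__ = [
    "AgeVitalRates",
    "DemographicEquilibrium",
    "build_leslie",
    "project",
    "dominant_structure",
    "euler_lotka_lhs",
    "solve_intrinsic_rate",
    "stable_manifold",
    "read_vital_rates",
    "write_vital_rates",
]


@dataclass
class AgeVitalRates:
    """Constant vital rates of one strategy (or one sex).

    Parameters
    ----------
    f : array-like, shape (m+1,)
        Expected offspring per individual per time unit, per age class.
    s : array-like, shape (m+1,)
        Probability of surviving one time unit (and hence moving to the next
        class), per age class.
    closed_last_class : bool, default True
        When set, survival of the terminal class is forced to zero: nobody
        outlives class ``m``.
    """

    f: np.ndarray
    s: np.ndarray
    closed_last_class: bool = True
    m: int = field(init=False)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float).copy()
        self.s = np.asarray(self.s, dtype=float).copy()
        if self.f.ndim != 1 or self.s.ndim != 1 or self.f.shape != self.s.shape:
            raise AgerepError("fertility and survival must be 1-d arrays of equal length")
        if self.f.size < 1:
            raise AgerepError("at least one age class is required")
        if not (np.all(np.isfinite(self.f)) and np.all(np.isfinite(self.s))):
            raise AgerepError("vital rates must be finite")
        if np.any(self.f < 0):
            raise AgerepError("fertilities must be non-negative")
        if np.any(self.s < 0) or np.any(self.s > 1):
            raise AgerepError("survival probabilities must lie in [0, 1]")
        if self.closed_last_class:
            self.s[-1] = 0.0
        self.m = self.f.size - 1

    def survivorship(self) -> np.ndarray:
        """Cumulative survival to each class: ``l^i = Π_{z<i} s^z`` (``l^0 = 1``)."""
        return np.concatenate([[1.0], np.cumprod(self.s[:-1])])


@dataclass
class DemographicEquilibrium:
    """Dominant growth structure of a Leslie matrix.

    ``growth_multiplier`` is the spectral radius λ (per-step multiplier),
    ``intrinsic_rate`` is ``r = ln λ``, and ``age_distribution`` the associated
    non-negative eigenvector normalized to sum 1.  ``imprimitive`` flags
    matrices whose dominant eigenvalue is tied in modulus with another
    eigenvalue (cyclic fertility schedules): the stable structure is then not
    globally attracting.
    """

    growth_multiplier: float
    intrinsic_rate: float
    age_distribution: np.ndarray
    imprimitive: bool = False


def build_leslie(rates: AgeVitalRates) -> np.ndarray:
    """Assemble the (m+1)x(m+1) Leslie projection matrix."""
    m1 = rates.m + 1
    L = np.zeros((m1, m1))
    L[0, :] = rates.f
    if m1 > 1:
        L[np.arange(1, m1), np.arange(0, m1 - 1)] = rates.s[:-1]
    return L


def project(rates: AgeVitalRates, counts, steps: int) -> np.ndarray:
    """Advance an age-class census ``steps`` time units with the Leslie matrix."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (rates.m + 1,):
        raise AgerepError(f"counts must have length {rates.m + 1}")
    if np.any(counts < 0):
        raise AgerepError("counts must be non-negative")
    if steps < 1:
        raise AgerepError("steps must be a positive integer")
    L = build_leslie(rates)
    out = counts
    for _ in range(int(steps)):
        out = L @ out
    return out


def _reproductive_ages(rates: AgeVitalRates) -> list[int]:
    """1-based ages at which reproduction is actually reachable."""
    surv = rates.survivorship()
    return [i + 1 for i in range(rates.m + 1) if rates.f[i] > 0 and surv[i] > 0]


def dominant_structure(
    rates: AgeVitalRates,
    *,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> DemographicEquilibrium:
    """Dominant eigenpair of the Leslie matrix by power iteration.

    Starts from the uniform vector and iterates to sup-norm tolerance ``tol``.
    Imprimitive matrices (gcd of reachable reproductive ages > 1) are handled
    by iterating the shifted matrix ``L + I``, whose dominant eigenvalue is
    ``λ + 1`` with the same eigenvector; the returned equilibrium carries the
    ``imprimitive`` flag since the structure is then not attracting.
    """
    ages = _reproductive_ages(rates)
    if not ages:
        raise AgerepError("no reachable positive fertility: growth structure undefined")
    imprimitive = math.gcd(*ages) > 1 if len(ages) >= 1 else True
    L = build_leslie(rates)
    shift = 1.0 if imprimitive else 0.0
    A = L + shift * np.eye(L.shape[0])
    v = np.full(L.shape[0], 1.0 / L.shape[0])
    lam_shifted = 1.0
    for _ in range(max_iter):
        w = A @ v
        lam_shifted = float(np.max(np.abs(w)))
        if lam_shifted == 0.0:
            raise AgerepError("projection collapsed to zero during power iteration")
        w = w / lam_shifted
        if float(np.max(np.abs(w - v))) < tol:
            v = w
            break
        v = w
    else:
        raise AgerepError("power iteration did not converge")
    v = np.abs(v)
    v = v / v.sum()
    lam = float(v @ (L @ v) / (v @ v)) if shift else lam_shifted
    # Rayleigh quotient refinement is exact for the converged eigenvector.
    lam = float(v @ (L @ v) / (v @ v))
    return DemographicEquilibrium(
        growth_multiplier=lam,
        intrinsic_rate=math.log(lam) if lam > 0 else -math.inf,
        age_distribution=v,
        imprimitive=imprimitive,
    )


def euler_lotka_lhs(rates: AgeVitalRates, r: float, *, timing: str = "start") -> float:
    """Left-hand side of the Euler-Lotka characteristic equation.

    Two discount timings are supported, differing in when reproduction by
    class ``i`` is credited:

    ``"start"``
        ``f^0 + Σ_{i=1..m} e^{-i r} f^i Π_{z<i} s^z`` — the classical
        1-based-age renewal sum carried over verbatim to 0-based classes, so
        the infant term enters undiscounted.
    ``"end"``
        ``Σ_{i=0..m} e^{-(i+1) r} f^i Π_{z<i} s^z`` — newborns are counted at
        the census following their parents' class, which makes this exactly
        the characteristic polynomial of the Leslie matrix: it equals 1 at
        ``r = ln λ`` for the dominant multiplier λ, and on the attracting
        manifold of the continuous-time age dynamics.

    The two evaluations differ by the factor ``e^r``; at the attracting
    manifold the start-timing value is the growth multiplier itself.
    """
    surv = rates.survivorship()
    if timing == "start":
        i = np.arange(1, rates.m + 1)
        tail = float(np.sum(np.exp(-i * r) * rates.f[1:] * surv[1:]))
        return float(rates.f[0]) + tail
    if timing == "end":
        i = np.arange(0, rates.m + 1)
        return float(np.sum(np.exp(-(i + 1) * r) * rates.f * surv))
    raise AgerepError("timing must be 'start' or 'end'")


def solve_intrinsic_rate(
    rates: AgeVitalRates,
    *,
    timing: str = "start",
    bracket: tuple[float, float] = (-50.0, 50.0),
    tol: float = 1e-10,
) -> float:
    """Solve the Euler-Lotka equation ``lhs(r) = 1`` for the intrinsic rate.

    With start timing this requires at least one age-dependent term
    (``f^i Π_{z<i} s^z > 0`` for some ``i >= 1``) and ``f^0 < 1`` so the
    left-hand side is strictly decreasing in ``r`` with a unique root, found
    by bracketing.  With end timing every term is discounted and the root is
    ``ln λ`` of the dominant Leslie multiplier.
    """
    surv = rates.survivorship()
    if timing == "start":
        if not np.any(rates.f[1:] * surv[1:] > 0):
            raise DegenerateInputError(
                "Euler-Lotka LHS does not depend on r (no reachable fertility past class 0)"
            )
        if rates.f[0] >= 1:
            raise DegenerateInputError("infant fertility f^0 >= 1: no root of lhs(r) = 1 exists")
    else:
        if not np.any(rates.f * surv > 0):
            raise DegenerateInputError("no reachable fertility: Euler-Lotka root undefined")
    lo, hi = bracket
    g = lambda r: euler_lotka_lhs(rates, r, timing=timing) - 1.0
    if g(lo) < 0 or g(hi) > 0:
        raise AgerepError(f"root of the Euler-Lotka equation not bracketed by {bracket}")
    r = float(brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=300))
    if abs(g(r)) > tol:
        raise AgerepError("Euler-Lotka root refinement failed tolerance")
    return r


def stable_manifold(rates: AgeVitalRates, lam: float) -> np.ndarray:
    """Age distribution on the attracting manifold for growth multiplier ``lam``.

    ``â^i ∝ Π_{z<i} s^z / lam^i``, normalized to the simplex.  When ``lam`` is
    the dominant multiplier this equals the stable age distribution.
    """
    if not lam > 0:
        raise AgerepError("growth multiplier must be positive")
    i = np.arange(rates.m + 1)
    unnorm = rates.survivorship() / lam**i
    return unnorm / unnorm.sum()


def write_vital_rates(rates: AgeVitalRates, path) -> None:
    """Write a vital-rate table as CSV (columns age_class, fertility, survival)."""
    pd.DataFrame(
        {
            "age_class": np.arange(rates.m + 1),
            "fertility": rates.f,
            "survival": rates.s,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_vital_rates(path, *, closed_last_class: bool = True) -> AgeVitalRates:
    """Read a vital-rate table from CSV (columns age_class, fertility, survival)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise AgerepError(f"cannot parse vital-rate CSV {path}: {exc}") from exc
    required = {"age_class", "fertility", "survival"}
    if not required.issubset(df.columns):
        raise AgerepError(f"vital-rate CSV must have columns {sorted(required)}")
    df = df.sort_values("age_class")
    if not np.array_equal(df["age_class"].to_numpy(), np.arange(len(df))):
        raise AgerepError("age_class column must be 0-based and contiguous")
    return AgeVitalRates(
        f=df["fertility"].to_numpy(float),
        s=df["survival"].to_numpy(float),
        closed_last_class=closed_last_class,
    )
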