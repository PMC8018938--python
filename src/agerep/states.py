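"""Population-state containers for the two replicator coordinate systems.

The same population can be described strategy-major (``StateA``: global
strategy frequencies plus one age structure per strategy) or age-major
(``StateB``: global age structure plus one strategy mix per age class).  Both
carry the total population size ``n`` as a scaling coordinate.  The
sex-ratio case study uses a third container (``AgeSexRatioState``) that nests
a per-class sex-ratio grid inside the strategy-major layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import AgerepError

__all__ = ["StateA", "StateB", "AgeSexRatioState", "Trajectory"]

_SIMPLEX_TOL = 1e-8


def _check_simplex(v: np.ndarray, name: str, tol: float = _SIMPLEX_TOL) -> None:
    if np.any(v < -tol):
        raise AgerepError(f"{name} has negative entries")
    sums = v.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise AgerepError(f"{name} rows must sum to 1 (max drift {np.max(np.abs(sums - 1.0)):.3e})")


@dataclass
class StateA:
    """Strategy-major state: frequencies ``p_j``, per-strategy age rows
    ``a_j^i`` (each a simplex, class 0 the newborn class) and size ``n``."""

    p: np.ndarray
    a: np.ndarray
    n: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2 or self.p.ndim != 1 or self.a.shape[0] != self.p.size:
            raise AgerepError("a must be (w, m+1) with w = len(p)")
        if self.n < 0:
            raise AgerepError("population size must be non-negative")
        _check_simplex(self.p, "p")
        _check_simplex(self.a, "age rows")

    @property
    def w(self) -> int:
        return self.p.size

    @property
    def m(self) -> int:
        return self.a.shape[1] - 1


@dataclass
class StateB:
    """Age-major state: global age structure ``a^i``, per-class strategy rows
    ``p_j^i`` and size ``n``."""

    ag: np.ndarray
    pc: np.ndarray
    n: float

    def __post_init__(self) -> None:
        self.ag = np.asarray(self.ag, dtype=float)
        self.pc = np.asarray(self.pc, dtype=float)
        if self.pc.ndim != 2 or self.ag.ndim != 1 or self.pc.shape[0] != self.ag.size:
            raise AgerepError("pc must be (m+1, w) with m+1 = len(ag)")
        if self.n < 0:
            raise AgerepError("population size must be non-negative")
        _check_simplex(self.ag, "ag")
        _check_simplex(self.pc, "per-class strategy rows")

    @property
    def w(self) -> int:
        return self.pc.shape[1]

    @property
    def m(self) -> int:
        return self.ag.size - 1


@dataclass
class AgeSexRatioState:
    """State of the age-structured sex-ratio model.

    ``G`` are gene frequencies, ``A[j]`` the age structure among carriers of
    gene ``j``, ``M[j, i]`` the fraction of males among carriers of gene ``j``
    in age class ``i``, and ``n`` the population size.
    """

    G: np.ndarray
    A: np.ndarray
    M: np.ndarray
    n: float

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.G.size or self.M.shape != self.A.shape:
            raise AgerepError("A and M must be (w, m+1) with w = len(G)")
        if self.n < 0:
            raise AgerepError("population size must be non-negative")
        _check_simplex(self.G, "G")
        _check_simplex(self.A, "age rows")
        if np.any(self.M < -_SIMPLEX_TOL) or np.any(self.M > 1 + _SIMPLEX_TOL):
            raise AgerepError("sex ratios must lie in [0, 1]")

    @property
    def w(self) -> int:
        return self.G.size

    @property
    def m(self) -> int:
        return self.A.shape[1] - 1


@dataclass
class Trajectory:
    """Time-indexed sequence of state snapshots plus run metadata."""

    times: np.ndarray
    states: list
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != len(self.states):
            raise AgerepError("times and states must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise AgerepError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final(self):
        return self.states[-1]
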