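"""Numerical integration of the replicator systems.

Each dynamic system is wrapped in a small adapter that packs its state into a
flat vector (integrating classes 1..m only; class 0 is recovered as the
simplex residual), evaluates the module right-hand side, and unpacks
snapshots back into typed states.  Integration uses an adaptive explicit
Runge-Kutta pair (``DOP853`` by default) via :func:`scipy.integrate.solve_ivp`;
``LSODA`` can be selected for transients with sharply contrasting class
occupancies.  Simplex drift along the trajectory within ``(1e-12, 1e-8]`` is
corrected by rescaling (and counted in the trajectory metadata); larger drift
is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import AgerepError
from .replicator import PayoffModel, rhs_a, rhs_b
from .sexratio import SexRatioParams, age_sexratio_rhs
from .states import AgeSexRatioState, StateA, StateB, Trajectory

__all__ = [
    "SolverSettings",
    "ReplicatorASystem",
    "ReplicatorBSystem",
    "AgeSexRatioSystem",
    "integrate",
    "detect_steady_state",
]

log = logging.getLogger("agerep")

_RESIDUAL_TOL = 1e-9   # tolerated negative class-0 residual during a solver step
_DRIFT_RENORM = 1e-8   # simplex drift correctable by rescaling
_DRIFT_EXACT = 1e-12   # drift below this is left untouched


@dataclass
class SolverSettings:
    """Integrator configuration.

    ``steady_state_tol`` is the sup-norm of the packed derivative below which
    the run may stop early (when ``stop_at_steady_state``); ``output_dt`` the
    spacing of stored snapshots.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    max_time: float = 100.0
    steady_state_tol: float = 1e-9
    output_dt: float = 1.0
    method: str = "DOP853"
    stop_at_steady_state: bool = False

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise AgerepError("tolerances must be positive")
        if self.max_time <= 0 or self.output_dt <= 0:
            raise AgerepError("max_time and output_dt must be positive")


def _residual(rows: np.ndarray) -> np.ndarray:
    """Class-0 residual of simplex rows given classes 1..m; clips tolerated
    negative excursions to 0."""
    r = 1.0 - rows.sum(axis=-1)
    if np.any(r < -_RESIDUAL_TOL):
        raise AgerepError(f"negative class-0 residual {float(np.min(r)):.3e}")
    return np.maximum(r, 0.0)


class ReplicatorASystem:
    """Flat-vector adapter for the strategy-major system Sa."""

    def __init__(self, model: PayoffModel):
        self.model = model
        self.w = model.n_strategies
        self.m = model.n_classes - 1

    def pack(self, state: StateA) -> np.ndarray:
        return np.concatenate([state.p, state.a[:, 1:].ravel(), [state.n]])

    def unpack(self, y: np.ndarray) -> StateA:
        w, m = self.w, self.m
        p = y[:w]
        rows = y[w:w + w * m].reshape(w, m)
        a = np.column_stack([_residual(rows), rows])
        return StateA(p=p, a=a, n=float(max(y[-1], 0.0)))

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        state = self.unpack(y)
        d = rhs_a(state, self.model)
        return np.concatenate([d.p_dot, d.a_dot[:, 1:].ravel(), [d.n_dot]])


class ReplicatorBSystem:
    """Flat-vector adapter for the age-major system Sb."""

    def __init__(self, model: PayoffModel):
        self.model = model
        self.w = model.n_strategies
        self.m = model.n_classes - 1

    def pack(self, state: StateB) -> np.ndarray:
        return np.concatenate([state.ag[1:], state.pc.ravel(), [state.n]])

    def unpack(self, y: np.ndarray) -> StateB:
        w, m = self.w, self.m
        ag_tail = y[:m]
        ag = np.concatenate([_residual(ag_tail[None, :]), ag_tail])
        pc = y[m:m + (m + 1) * w].reshape(m + 1, w)
        # per-class strategy rows are all integrated; correct tiny drift
        pc = np.clip(pc, 0.0, None)
        pc = pc / pc.sum(axis=1, keepdims=True)
        return StateB(ag=ag, pc=pc, n=float(max(y[-1], 0.0)))

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        state = self.unpack(y)
        d = rhs_b(state, self.model)
        return np.concatenate([d.ag_dot[1:], d.pc_dot.ravel(), [d.n_dot]])


class AgeSexRatioSystem:
    """Flat-vector adapter for the age-structured sex-ratio system."""

    def __init__(self, params: SexRatioParams):
        self.params = params
        self.w = params.w
        self.m = params.m

    def pack(self, state: AgeSexRatioState) -> np.ndarray:
        return np.concatenate([
            state.G, state.A[:, 1:].ravel(), state.M.ravel(), [state.n],
        ])

    def unpack(self, y: np.ndarray) -> AgeSexRatioState:
        w, m = self.w, self.m
        G = np.clip(y[:w], 0.0, None)
        G = G / G.sum()
        rows = y[w:w + w * m].reshape(w, m)
        A = np.column_stack([_residual(rows), rows])
        M = y[w + w * m:w + w * m + w * (m + 1)].reshape(w, m + 1)
        if np.any(M < -_RESIDUAL_TOL) or np.any(M > 1 + _RESIDUAL_TOL):
            raise AgerepError("sex ratio left [0, 1] during integration")
        M = np.clip(M, 0.0, 1.0)
        return AgeSexRatioState(G=G, A=A, M=M, n=float(max(y[-1], 0.0)))

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        state = self.unpack(y)
        d = age_sexratio_rhs(state, self.params)
        return np.concatenate([
            d.G_dot, d.A_dot[:, 1:].ravel(), d.M_dot.ravel(), [d.n_dot],
        ])


def _renormalized(system, state):
    """Apply the simplex-drift policy to one snapshot; returns (state, n_fixed)."""
    fixed = 0

    def fix_rows(rows):
        nonlocal fixed
        rows = np.atleast_2d(rows)
        sums = rows.sum(axis=1)
        drift = np.abs(sums - 1.0)
        if np.any(drift > _DRIFT_RENORM):
            raise AgerepError(f"simplex drift {float(drift.max()):.3e} exceeds 1e-8")
        sel = drift > _DRIFT_EXACT
        if np.any(sel):
            rows[sel] = rows[sel] / sums[sel, None]
            fixed += int(sel.sum())
        return rows

    if isinstance(state, StateA):
        state = StateA(p=fix_rows(state.p)[0], a=fix_rows(state.a), n=state.n)
    elif isinstance(state, StateB):
        state = StateB(ag=fix_rows(state.ag)[0], pc=fix_rows(state.pc), n=state.n)
    elif isinstance(state, AgeSexRatioState):
        state = AgeSexRatioState(G=fix_rows(state.G)[0], A=fix_rows(state.A),
                                 M=state.M, n=state.n)
    return state, fixed


def integrate(system, initial_state, settings: SolverSettings,
              metadata: dict | None = None) -> Trajectory:
    """Integrate a system from ``initial_state`` and return a Trajectory.

    Snapshots are stored every ``settings.output_dt`` time units (the initial
    state included).  With ``stop_at_steady_state`` the run terminates at the
    first time the sup-norm of the derivative falls below
    ``settings.steady_state_tol``.
    """
    y0 = system.pack(initial_state)
    t_eval = np.arange(0.0, settings.max_time + 0.5 * settings.output_dt,
                       settings.output_dt)
    events = None
    if settings.stop_at_steady_state:
        def steady(t, y):
            return float(np.max(np.abs(system.rhs(t, y)))) - settings.steady_state_tol
        steady.terminal = True
        steady.direction = -1
        events = [steady]
    sol = solve_ivp(
        system.rhs, (0.0, settings.max_time), y0,
        method=settings.method, rtol=settings.rtol, atol=settings.atol,
        t_eval=t_eval, events=events, dense_output=False,
    )
    if not sol.success:
        raise AgerepError(f"integration failed: {sol.message}")
    states = []
    n_fixed = 0
    for col in sol.y.T:
        st, fixed = _renormalized(system, system.unpack(col))
        n_fixed += fixed
        states.append(st)
    if n_fixed:
        log.info("renormalized %d simplex rows along the trajectory", n_fixed)
    meta = dict(metadata or {})
    meta.setdefault("solver", {
        "method": settings.method, "rtol": settings.rtol, "atol": settings.atol,
        "max_time": settings.max_time, "output_dt": settings.output_dt,
    })
    meta["renormalized_rows"] = n_fixed
    meta["terminated_early"] = bool(sol.status == 1)
    return Trajectory(times=sol.t[:len(states)], states=states, metadata=meta)


def detect_steady_state(traj: Trajectory, system, threshold: float = 1e-9):
    """Index of the first snapshot whose derivative sup-norm is below
    ``threshold``, or ``None``."""
    if len(traj) == 0:
        raise AgerepError("empty trajectory")
    for idx, (t, state) in enumerate(zip(traj.times, traj.states)):
        dy = system.rhs(float(t), system.pack(state))
        if float(np.max(np.abs(dy))) < threshold:
            return idx
    return None
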