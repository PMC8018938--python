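"""Trajectory persistence and scenario configuration.

Trajectories are stored in a tidy CSV schema — one row per scalar coordinate:

    time, system, variable, strategy, age_class, value

with ``system`` one of ``A`` (strategy-major), ``B`` (age-major) or ``S``
(age-structured sex ratio), and ``variable`` one of ``p``, ``a``, ``pc``,
``ag``, ``G``, ``M``, ``n``.  Values are rendered at full precision, so
read ∘ write is the identity on the numeric payload.

Scenario configuration is YAML.  Survival schedules may be given as explicit
per-class lists or as a piecewise step spec such as ``"0.95 until 10 then
0.80"`` (classes 0-9 at 0.95, class 10 onward at 0.80, terminal class 0).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .engine import SolverSettings
from .errors import ConfigError, SchemaError
from .replicator import PayoffModel
from .sexratio import SexRatioParams
from .states import AgeSexRatioState, StateA, StateB, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "Scenario",
    "read_config",
    "write_config",
    "parse_survival_spec",
]

_COLUMNS = ["time", "system", "variable", "strategy", "age_class", "value"]


def _rows_for(t: float, state) -> list[tuple]:
    rows: list[tuple] = []
    if isinstance(state, StateA):
        sys_ = "A"
        for j, v in enumerate(state.p):
            rows.append((t, sys_, "p", j, "", v))
        for j in range(state.w):
            for i in range(state.m + 1):
                rows.append((t, sys_, "a", j, i, state.a[j, i]))
    elif isinstance(state, StateB):
        sys_ = "B"
        for i, v in enumerate(state.ag):
            rows.append((t, sys_, "ag", "", i, v))
        for i in range(state.m + 1):
            for j in range(state.w):
                rows.append((t, sys_, "pc", j, i, state.pc[i, j]))
    elif isinstance(state, AgeSexRatioState):
        sys_ = "S"
        for j, v in enumerate(state.G):
            rows.append((t, sys_, "G", j, "", v))
        for j in range(state.w):
            for i in range(state.m + 1):
                rows.append((t, sys_, "a", j, i, state.A[j, i]))
        for j in range(state.w):
            for i in range(state.m + 1):
                rows.append((t, sys_, "M", j, i, state.M[j, i]))
    else:
        raise SchemaError(f"cannot serialize state type {type(state).__name__}")
    rows.append((t, sys_, "n", "", "", state.n))
    return rows


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory in the tidy CSV schema (full decimal precision)."""
    rows: list[tuple] = []
    for t, state in zip(traj.times, traj.states):
        rows.extend(_rows_for(float(t), state))
    with open(path, "w") as fh:
        fh.write(",".join(_COLUMNS) + "\n")
        for t, sys_, var, j, i, v in rows:
            fh.write(f"{float(t)!r},{sys_},{var},{j},{i},{float(v)!r}\n")


def _state_from_group(sys_: str, g: pd.DataFrame):
    def grid(var: str) -> np.ndarray:
        sub = g[g.variable == var]
        w = int(sub.strategy.astype(int).max()) + 1
        m1 = int(sub.age_class.astype(int).max()) + 1
        out = np.full((w, m1), np.nan)
        out[sub.strategy.astype(int), sub.age_class.astype(int)] = sub.value.to_numpy()
        if np.any(np.isnan(out)):
            raise SchemaError(f"incomplete grid for variable {var}")
        return out

    def vector(var: str, key: str) -> np.ndarray:
        sub = g[g.variable == var].sort_values(key, key=lambda s: s.astype(int))
        return sub.value.to_numpy()

    n = float(g.loc[g.variable == "n", "value"].iloc[0])
    if sys_ == "A":
        return StateA(p=vector("p", "strategy"), a=grid("a"), n=n)
    if sys_ == "B":
        return StateB(ag=vector("ag", "age_class"), pc=grid("pc").T, n=n)
    if sys_ == "S":
        return AgeSexRatioState(G=vector("G", "strategy"), A=grid("a"),
                                M=grid("M"), n=n)
    raise SchemaError(f"unknown system label {sys_!r}")


def read_trajectory(path) -> Trajectory:
    """Read a tidy-CSV trajectory back into typed states."""
    df = pd.read_csv(path, dtype={"strategy": str, "age_class": str},
                     keep_default_na=False, float_precision="round_trip")
    if list(df.columns) != _COLUMNS:
        raise SchemaError(f"expected columns {_COLUMNS}, found {list(df.columns)}")
    if df.empty:
        return Trajectory(times=np.empty(0), states=[])
    times, states = [], []
    for t, g in df.groupby("time", sort=True):
        sys_labels = g.system.unique()
        if len(sys_labels) != 1:
            raise SchemaError("mixed system labels within one time point")
        times.append(float(t))
        states.append(_state_from_group(sys_labels[0], g))
    return Trajectory(times=np.asarray(times), states=states)


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

_STEP_RE = re.compile(
    r"^\s*([0-9.eE+-]+)\s+until\s+(\d+)\s+then\s+([0-9.eE+-]+)\s*$")


def parse_survival_spec(spec, n_classes: int, field: str) -> np.ndarray:
    """Per-class survival from a list or a ``"x until N then y"`` step spec.

    The step spec is inclusive-exclusive: classes ``0..N-1`` at ``x``, class
    ``N`` onward at ``y``.  The terminal class is always 0.
    """
    if isinstance(spec, str):
        match = _STEP_RE.match(spec)
        if not match:
            raise ConfigError(f"{field}: cannot parse step spec {spec!r}")
        early, change, late = float(match[1]), int(match[2]), float(match[3])
        s = np.full(n_classes, late)
        s[:change] = early
    else:
        s = np.asarray(spec, dtype=float)
        if s.shape != (n_classes,):
            raise ConfigError(f"{field}: expected {n_classes} per-class entries")
    if np.any(s < 0) or np.any(s > 1):
        bad = float(s[(s < 0) | (s > 1)][0])
        raise ConfigError(f"{field}: survival entry {bad} outside [0, 1]")
    s[-1] = 0.0
    return s


@dataclass
class Scenario:
    """A validated, runnable scenario: model parameters, initial state and
    solver settings."""

    kind: str
    params: SexRatioParams | PayoffModel
    state: AgeSexRatioState | StateA
    settings: SolverSettings


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise ConfigError(f"missing required key {key!r}")
    return cfg[key]


def _solver_settings(cfg: dict) -> SolverSettings:
    block = cfg.get("solver", {})
    try:
        return SolverSettings(**block)
    except TypeError as exc:
        raise ConfigError(f"solver block: {exc}") from exc


def _sexratio_scenario(cfg: dict) -> Scenario:
    strategies = np.asarray(_require(cfg, "strategies"), dtype=float)
    n_classes = int(_require(cfg, "n_classes"))
    for name, window in (("male_window", cfg.get("male_window")),
                         ("female_window", cfg.get("female_window"))):
        if window is None:
            raise ConfigError(f"missing required key {name!r}")
        lo, hi = window
        if not (0 <= lo <= hi <= n_classes - 1):
            raise ConfigError(f"{name}: window {window} violates 0 <= lo <= hi <= {n_classes - 1}")
    try:
        params = SexRatioParams(
            strategies=strategies,
            k=float(_require(cfg, "brood_size")),
            s_f=parse_survival_spec(_require(cfg, "survival_female"), n_classes,
                                    "survival_female"),
            s_m=parse_survival_spec(_require(cfg, "survival_male"), n_classes,
                                    "survival_male"),
            male_window=tuple(cfg["male_window"]),
            female_window=tuple(cfg["female_window"]),
            K=float(_require(cfg, "carrying_capacity")),
        )
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(str(exc)) from exc

    init = _require(cfg, "initial")
    w, m = strategies.size, n_classes - 1
    adult = float(init.get("adult_class_frequency", 0.0))
    A = np.full((w, n_classes), adult)
    A[:, 0] = 1.0 - adult * m
    if "age_rows" in init:
        A = np.asarray(init["age_rows"], dtype=float)
    M = np.tile(np.asarray(init["adult_sex_ratios"], dtype=float)[:, None],
                (1, n_classes))
    M[:, 0] = np.asarray(init["infant_sex_ratios"], dtype=float)
    try:
        state = AgeSexRatioState(
            G=np.asarray(_require(init, "gene_frequencies"), dtype=float),
            A=A, M=M, n=float(_require(init, "n")),
        )
    except Exception as exc:
        raise ConfigError(f"initial block: {exc}") from exc
    return Scenario(kind="sexratio", params=params, state=state,
                    settings=_solver_settings(cfg))


def _replicator_scenario(cfg: dict) -> Scenario:
    f = np.asarray(_require(cfg, "fertility"), dtype=float)
    d = np.asarray(_require(cfg, "mortality"), dtype=float)
    K = float(cfg.get("carrying_capacity", np.inf))
    tau = float(cfg.get("interaction_rate", 1.0))
    try:
        model = PayoffModel.constant(f, d, K=K, tau=tau)
        init = _require(cfg, "initial")
        state = StateA(p=np.asarray(_require(init, "p"), dtype=float),
                       a=np.asarray(_require(init, "a"), dtype=float),
                       n=float(_require(init, "n")))
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
    return Scenario(kind="replicator", params=model, state=state,
                    settings=_solver_settings(cfg))


def read_config(path) -> Scenario:
    """Load and validate a scenario configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    kind = cfg.get("kind", "sexratio")
    if kind == "sexratio":
        return _sexratio_scenario(cfg)
    if kind == "replicator":
        return _replicator_scenario(cfg)
    raise ConfigError(f"unknown scenario kind {kind!r}")


def write_config(scenario: Scenario, path) -> None:
    """Write a sex-ratio scenario back to YAML (explicit per-class schedules)."""
    if scenario.kind != "sexratio":
        raise ConfigError("only sex-ratio scenarios are written to YAML")
    p: SexRatioParams = scenario.params
    st: AgeSexRatioState = scenario.state
    s = scenario.settings
    cfg = {
        "kind": "sexratio",
        "strategies": p.strategies.tolist(),
        "brood_size": p.k,
        "n_classes": p.m + 1,
        "survival_female": p.s_f.tolist(),
        "survival_male": p.s_m.tolist(),
        "male_window": list(p.male_window),
        "female_window": list(p.female_window),
        "carrying_capacity": p.K,
        "initial": {
            "n": st.n,
            "gene_frequencies": st.G.tolist(),
            "age_rows": st.A.tolist(),
            "infant_sex_ratios": st.M[:, 0].tolist(),
            "adult_sex_ratios": st.M[:, 1].tolist(),
        },
        "solver": {
            "rtol": s.rtol, "atol": s.atol, "max_time": s.max_time,
            "steady_state_tol": s.steady_state_tol, "output_dt": s.output_dt,
            "method": s.method, "stop_at_steady_state": s.stop_at_steady_state,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
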