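import numpy as np
import pytest

from agerep import engine, fixtures, replicator, sexratio


@pytest.fixture(scope="session")
def fisher_steady():
    """Steady states of the built-in sex-ratio case study, keyed by brood size.

    Integrated once per session with early termination at derivative sup-norm
    1e-9; shared by the long-run behavioural tests.
    """
    cache: dict[float, tuple] = {}

    def run(k: float):
        if k not in cache:
            params, state = fixtures.fisher_scenario(brood_size=k)
            system = engine.AgeSexRatioSystem(params)
            settings = engine.SolverSettings(
                max_time=3000.0, output_dt=10.0, method="LSODA",
                stop_at_steady_state=True, steady_state_tol=1e-9,
            )
            traj = engine.integrate(system, state, settings)
            cache[k] = (params, traj)
        return cache[k]

    return run


@pytest.fixture
def two_strategy_model():
    """Constant-payoff two-strategy, three-class model with finite K."""
    return fixtures.random_payoff_model(3, 2, 2, K=500.0)


def count_system_trajectory(model, state, t_eval, rtol=1e-10, atol=1e-12):
    """Independent oracle: integrate the unnormalized per-strategy age-class
    counts (linear aging/death plus logistic recruitment) and renormalize.

    Returns lists of (p, a, n) at the requested times.
    """
    from scipy.integrate import solve_ivp

    w, m1 = model.n_strategies, model.n_classes
    F, S = model.rates(state.p, state.a, state.n)

    def rhs(t, y):
        counts = y.reshape(w, m1)
        n = counts.sum()
        dens = 1.0 - n / model.carrying_capacity
        dn = np.empty_like(counts)
        dn[:, 0] = (counts * F).sum(axis=1) * dens - counts[:, 0]
        dn[:, 1:] = S[:, :-1] * counts[:, :-1] - counts[:, 1:]
        return dn.ravel()

    y0 = (state.p[:, None] * state.a * state.n).ravel()
    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), y0, t_eval=t_eval,
                    method="DOP853", rtol=rtol, atol=atol)
    assert sol.success
    out = []
    for col in sol.y.T:
        counts = col.reshape(w, m1)
        nj = counts.sum(axis=1)
        out.append((nj / nj.sum(), counts / nj[:, None], counts.sum()))
    return out
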