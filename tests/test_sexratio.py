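import numpy as np
import pytest

from agerep import GuardViolationError, sexratio as sr
from agerep.engine import AgeSexRatioSystem, SolverSettings, integrate
from agerep.fixtures import degenerate_suite, fisher_scenario
from agerep.states import AgeSexRatioState


def baseline(G, M, strategies):
    return sr.BaselineSexRatioState(G=np.asarray(G, float), M=np.asarray(M, float),
                                    strategies=np.asarray(strategies, float))


def random_age_state(seed, w=3, m=5, n=100.0):
    rng = np.random.default_rng(seed)
    G = rng.uniform(0.5, 1.5, w)
    G /= G.sum()
    A = rng.uniform(0.5, 1.5, (w, m + 1))
    A /= A.sum(axis=1, keepdims=True)
    M = rng.uniform(0.2, 0.8, (w, m + 1))
    return AgeSexRatioState(G=G, A=A, M=M, n=n)


def random_params(seed, w=3, m=5, k=6.0, K=1000.0):
    rng = np.random.default_rng(seed)
    s_f = rng.uniform(0.5, 0.95, m + 1)
    s_m = rng.uniform(0.5, 0.95, m + 1)
    s_f[-1] = s_m[-1] = 0.0
    return sr.SexRatioParams(
        strategies=rng.uniform(0.1, 0.9, w), k=k, s_f=s_f, s_m=s_m,
        male_window=(1, m), female_window=(1, m - 1), K=K,
    )


class TestBaseline:
    def test_gene_payoff_collapses_to_average_when_ratios_match(self):
        st = baseline([0.4, 0.6], [0.3, 0.3], [0.2, 0.8])
        pay = sr.baseline_payoffs(st, k=6.0)
        np.testing.assert_allclose(pay.f_g, pay.fbar, atol=1e-14)
        assert pay.fbar == pytest.approx(6.0 * (1 - st.P))

    def test_even_population_ratio_halves_brood(self):
        st = baseline([0.5, 0.5], [0.5, 0.5], [0.3, 0.7])
        pay = sr.baseline_payoffs(st, k=6.0)
        np.testing.assert_allclose(pay.f_g, 3.0, atol=1e-14)
        # here P̄_pr = 0.5 as well, so the male average is also k/2
        assert st.P_pr == pytest.approx(0.5)
        assert pay.fbar_m == pytest.approx(3.0)

    def test_boundary_sex_ratio_rejected(self):
        st = baseline([1.0], [1.0], [0.5])
        with pytest.raises(GuardViolationError):
            sr.baseline_payoffs(st, k=6.0)

    def test_even_ratio_freezes_gene_frequencies(self):
        # P = 1/2 is the Fisherian rest point of the gene dynamics
        st = baseline([0.5, 0.5], [0.3, 0.7], [0.2, 0.9])
        assert st.P == pytest.approx(0.5)
        G_dot, _ = sr.baseline_rhs(st, k=6.0)
        np.testing.assert_allclose(G_dot, 0.0, atol=1e-14)

    def test_uniform_state_is_stationary(self):
        st = baseline([0.25, 0.75], [0.4, 0.4], [0.4, 0.4])
        G_dot, M_dot = sr.baseline_rhs(st, k=6.0)
        np.testing.assert_allclose(M_dot, 0.0, atol=1e-14)
        np.testing.assert_allclose(G_dot, 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_selection_gradient_equals_payoff_excess(self, seed):
        # Ġ_j from the closed form equals G_j (f_g - f̄) with payoffs substituted
        rng = np.random.default_rng(seed)
        G = rng.uniform(0.2, 1.0, 3)
        G /= G.sum()
        st = baseline(G, rng.uniform(0.2, 0.8, 3), rng.uniform(0.1, 0.9, 3))
        pay = sr.baseline_payoffs(st, k=5.0)
        G_dot, _ = sr.baseline_rhs(st, k=5.0)
        np.testing.assert_allclose(G_dot, st.G * (pay.f_g - pay.fbar), atol=1e-12)
        # and matches the expanded form G_j k (1/2 - P)(M_j/P - 1)
        expected = st.G * 5.0 * (0.5 - st.P) * (st.M / st.P - 1)
        np.testing.assert_allclose(G_dot, expected, atol=1e-12)


class TestDerivedQuantities:
    def test_all_female_population_has_no_active_males(self):
        state = random_age_state(0)
        state = AgeSexRatioState(G=state.G, A=state.A, M=np.zeros_like(state.M),
                                 n=state.n)
        params = random_params(0)
        fr = sr.active_fractions(state, params)
        np.testing.assert_allclose(fr.S_m, 0.0)
        fmask = params.window_mask("female")
        np.testing.assert_allclose(fr.S_f, state.A[:, fmask].sum(axis=1))

    def test_even_ratios_with_full_windows_split_activity(self):
        m = 4
        params = sr.SexRatioParams(
            strategies=[0.3, 0.6], k=4.0,
            s_f=[0.9, 0.9, 0.9, 0.9, 0.0], s_m=[0.9, 0.9, 0.9, 0.9, 0.0],
            male_window=(0, m), female_window=(0, m), K=100.0)
        state = AgeSexRatioState(G=[0.5, 0.5],
                                 A=np.full((2, m + 1), 1 / (m + 1)),
                                 M=np.full((2, m + 1), 0.5), n=10.0)
        fr = sr.active_fractions(state, params)
        np.testing.assert_allclose(fr.S_f, 0.5)
        np.testing.assert_allclose(fr.S_m, 0.5)
        ratios = sr.sex_ratios(state, params, fr)
        np.testing.assert_allclose(ratios.M_op, 0.5)
        assert ratios.P_op == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_fractions_and_ratios_match_brute_force(self, seed):
        state = random_age_state(seed)
        params = random_params(seed + 10)
        fr = sr.active_fractions(state, params)
        c, d = params.female_window
        a, b = params.male_window
        for j in range(state.w):
            S_f = sum(state.A[j, z] * (1 - state.M[j, z]) for z in range(c, d + 1))
            S_m = sum(state.A[j, z] * state.M[j, z] for z in range(a, b + 1))
            assert fr.S_f[j] == pytest.approx(S_f, abs=1e-14)
            assert fr.S_m[j] == pytest.approx(S_m, abs=1e-14)
        ratios = sr.sex_ratios(state, params, fr)
        P = sum(state.G[j] * sum(state.A[j, i] * state.M[j, i]
                                 for i in range(state.m + 1)) for j in range(state.w))
        assert ratios.P == pytest.approx(P, abs=1e-14)
        P_pr = sum(state.G[j] * fr.S_f[j] * params.strategies[j]
                   for j in range(state.w)) / fr.S_f_bar
        assert ratios.P_pr == pytest.approx(P_pr, abs=1e-14)

    def test_single_gene_primary_ratio_is_its_strategy(self):
        state = random_age_state(1, w=1)
        params = random_params(1, w=1)
        fr = sr.active_fractions(state, params)
        ratios = sr.sex_ratios(state, params, fr)
        assert ratios.P_pr == pytest.approx(params.strategies[0])

    def test_survival_means(self):
        state = random_age_state(2)
        params = random_params(2)
        sm = sr.survival_means(state, params)
        expected = state.M * params.s_m + (1 - state.M) * params.s_f
        np.testing.assert_allclose(sm.s_ji, expected, atol=1e-15)
        # sex-symmetric survival makes the mix irrelevant
        sym = random_params(2)
        sym.s_m[:] = sym.s_f
        np.testing.assert_allclose(
            sr.survival_means(state, sym).s_ji,
            np.tile(sym.s_f, (state.w, 1)), atol=1e-15)
        all_male = AgeSexRatioState(G=state.G, A=state.A,
                                    M=np.ones_like(state.M), n=state.n)
        np.testing.assert_allclose(
            sr.survival_means(all_male, params).s_ji,
            np.tile(params.s_m, (state.w, 1)), atol=1e-15)


class TestPayoffsAndShawMohler:
    def test_average_gene_earns_average_payoff(self):
        # genes with population-average active fractions earn f̄ exactly
        state = random_age_state(4)
        shared_A = state.A[0:1].repeat(state.w, axis=0)
        shared_M = state.M[0:1].repeat(state.w, axis=0)
        st = AgeSexRatioState(G=state.G, A=shared_A, M=shared_M, n=state.n)
        params = random_params(4)
        fr = sr.active_fractions(st, params)
        ratios = sr.sex_ratios(st, params, fr)
        pay = sr.age_payoffs(params.strategies, fr, ratios, params.k)
        np.testing.assert_allclose(pay.f_g, pay.fbar, atol=1e-13)
        np.testing.assert_allclose(sr.shaw_mohler(fr, params.k), 0.0, atol=1e-13)

    @pytest.mark.parametrize("seed", [0, 1, 5])
    def test_shaw_mohler_is_payoff_excess(self, seed):
        state = random_age_state(seed)
        params = random_params(seed + 20)
        fr = sr.active_fractions(state, params)
        ratios = sr.sex_ratios(state, params, fr)
        pay = sr.age_payoffs(params.strategies, fr, ratios, params.k)
        np.testing.assert_allclose(sr.shaw_mohler(fr, params.k),
                                   pay.f_g - pay.fbar, atol=1e-12)
        # expanded identity for the gene payoff
        np.testing.assert_allclose(
            pay.f_g,
            params.k / 2 * (fr.S_f + fr.S_m * fr.S_f_bar / fr.S_m_bar),
            atol=1e-13)


class TestAgeSexRatioRhs:
    @pytest.mark.parametrize("seed", [0, 2, 7])
    def test_gene_frequency_derivatives_conserve_simplex(self, seed):
        state = random_age_state(seed)
        params = random_params(seed + 30)
        d = sr.age_sexratio_rhs(state, params)
        assert abs(d.G_dot.sum()) < 1e-12
        np.testing.assert_allclose(d.A_dot.sum(axis=1), 0.0, atol=1e-12)

    def test_sex_symmetric_world_freezes_older_class_ratios(self):
        sc = degenerate_suite()["sex_symmetric"]
        params = sc["params"]
        state = sc["state"]
        flat = AgeSexRatioState(G=state.G, A=state.A,
                                M=np.tile(state.M[:, :1], (1, state.m + 1)),
                                n=state.n)
        d = sr.age_sexratio_rhs(flat, params)
        np.testing.assert_allclose(d.M_dot[:, 1:], 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 4])
    def test_closed_and_generic_forms_agree(self, seed):
        """The expanded right-hand side and its payoff-substituted generic
        form are the same function, to 1e-10."""
        state = random_age_state(seed)
        params = random_params(seed + 40)
        d1 = sr.age_sexratio_rhs(state, params)
        d2 = sr.age_sexratio_rhs_generic(state, params)
        np.testing.assert_allclose(d1.G_dot, d2.G_dot, atol=1e-10)
        np.testing.assert_allclose(d1.A_dot, d2.A_dot, atol=1e-10)
        np.testing.assert_allclose(d1.M_dot, d2.M_dot, atol=1e-10)
        assert d1.n_dot == pytest.approx(d2.n_dot, abs=1e-10)


class TestManifolds:
    def test_state_on_manifold_has_zero_residual(self):
        params = random_params(3)
        state = random_age_state(3)
        fr = sr.active_fractions(state, params)
        sm = sr.survival_means(state, params)
        f_g = params.k / 2 * (fr.S_f + fr.S_m * fr.S_f_bar / fr.S_m_bar)
        denom = f_g * (1 - state.n / params.K) + sm.s_j
        A = np.empty_like(state.A)
        A[:, 0] = 1.0
        # self-consistent construction is iterative (S, s̄ depend on A); a
        # single fixed-point sweep suffices for the residual check because the
        # residual is evaluated at the constructed state's own coefficients
        for _ in range(200):
            for i in range(1, state.m + 1):
                A[:, i] = A[:, i - 1] * sm.s_ji[:, i - 1] / denom
            A /= A.sum(axis=1, keepdims=True)
            st = AgeSexRatioState(G=state.G, A=A, M=state.M, n=state.n)
            fr = sr.active_fractions(st, params)
            sm = sr.survival_means(st, params)
            f_g = params.k / 2 * (fr.S_f + fr.S_m * fr.S_f_bar / fr.S_m_bar)
            denom = f_g * (1 - st.n / params.K) + sm.s_j
        res = sr.manifold_age(st, params)
        assert np.max(np.abs(res)) < 1e-12

    def test_sexratio_targets_propagate_unchanged_with_symmetric_survival(self):
        params = random_params(5)
        params.s_m[:] = params.s_f
        state = random_age_state(5)
        Mhat = sr.manifold_sexratio(state, params)
        np.testing.assert_allclose(Mhat[:, 1:], state.M[:, :-1], atol=1e-14)

    def test_all_male_class_stays_all_male(self):
        params = random_params(6)
        state = random_age_state(6)
        state.M[:, 2] = 1.0
        Mhat = sr.manifold_sexratio(state, params)
        np.testing.assert_allclose(Mhat[:, 3], 1.0, atol=1e-14)


class TestLongRunBehaviour:
    def test_sex_symmetric_reduction_recovers_unstructured_model(self):
        """With equal survivals and windows for both sexes the age structure
        decouples: per-class sex ratios flatten, genes share one age
        structure, survival excess vanishes, and the primary sex ratio is
        driven to 1/2 by the Shaw-Mohler term alone."""
        sc = degenerate_suite()["sex_symmetric"]
        params, state = sc["params"], sc["state"]
        traj = integrate(AgeSexRatioSystem(params), state,
                         SolverSettings(max_time=3000.0, output_dt=25.0,
                                        method="LSODA",
                                        stop_at_steady_state=True,
                                        steady_state_tol=1e-9))
        fin = traj.final
        # flat sex ratio across the life cycle, per gene
        spread = np.ptp(fin.M, axis=1)
        assert np.max(spread) < 1e-5
        # shared age structure
        assert np.max(np.abs(fin.A - fin.A[0])) < 1e-6
        sm = sr.survival_means(fin, params)
        assert np.max(np.abs(sm.s_j - sm.sbar)) < 1e-8
        fr = sr.active_fractions(fin, params)
        ratios = sr.sex_ratios(fin, params, fr)
        assert ratios.P_pr == pytest.approx(0.5, abs=1e-4)

    def test_operational_ratio_is_selection_threshold(self):
        """With equal windows and sex-symmetric survival the fertility excess
        has the sign of (M_op_j - P_op)(1 - 2 P_op): the strategy
        overproducing the minority sex gains."""
        m = 4
        rng = np.random.default_rng(12)
        params = sr.SexRatioParams(
            strategies=[0.2, 0.5, 0.8], k=6.0,
            s_f=[0.9] * m + [0.0], s_m=[0.9] * m + [0.0],
            male_window=(0, m), female_window=(0, m), K=1000.0)
        for _ in range(20):
            G = rng.uniform(0.2, 1.0, 3)
            G /= G.sum()
            A = rng.uniform(0.5, 1.5, (3, m + 1))
            A /= A.sum(axis=1, keepdims=True)
            M = rng.uniform(0.1, 0.9, (3, m + 1))
            st = AgeSexRatioState(G=G, A=A, M=M, n=100.0)
            fr = sr.active_fractions(st, params)
            ratios = sr.sex_ratios(st, params, fr)
            excess = sr.shaw_mohler(fr, params.k)
            predicted = (ratios.M_op - ratios.P_op) * (1 - 2 * ratios.P_op)
            clear = np.minimum(np.abs(excess), np.abs(predicted)) > 1e-10
            assert np.all(np.sign(excess[clear]) == np.sign(predicted[clear]))

    def test_ratios_and_fractions_stay_in_unit_interval(self, fisher_steady):
        params, traj = fisher_steady(6.0)
        for st in traj.states:
            assert np.all(st.M >= -1e-8) and np.all(st.M <= 1 + 1e-8)
            fr = sr.active_fractions(st, params)
            for v in (fr.S_f, fr.S_m):
                assert np.all(v >= -1e-8) and np.all(v <= 1 + 1e-8)

    def test_steady_state_sits_on_both_manifolds(self, fisher_steady):
        params, traj = fisher_steady(6.0)
        fin = traj.final
        assert np.max(np.abs(sr.manifold_age(fin, params))) < 1e-4
        Mhat = sr.manifold_sexratio(fin, params)
        assert np.max(np.abs(fin.M - Mhat)) < 1e-4
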