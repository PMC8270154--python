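import numpy as np
import pandas as pd
import pytest

from lbblmm import (
    BoostConfig,
    DataError,
    ParamState,
    SimScenario,
    build_correction,
    build_design,
    candidate_update,
    classify_covariates,
    fit,
    initialize,
    random_effects_step,
    select_and_apply,
    simulate,
    update_variance_components,
)

from conftest import make_random_data


def zero_state(data, sigma2=1.0, Q=None):
    return ParamState(
        beta0=0.0,
        beta=np.zeros(data.p),
        gamma=np.zeros(data.n * data.q),
        sigma2=sigma2,
        Q=np.eye(data.q) if Q is None else Q,
    )


class TestInitialize:
    def test_simple_moment_starts(self, rng):
        data = make_random_data(rng, n=3, n_i=1, p=2, q=1)
        data.y = np.array([1.0, 2.0, 3.0])
        state = initialize(data, BoostConfig())
        assert state.beta0 == pytest.approx(2.0)
        assert state.sigma2 == pytest.approx(1.0)  # ddof=1 sample variance
        assert np.all(state.beta == 0.0)
        assert np.all(state.gamma == 0.0)
        assert np.allclose(state.Q, 0.1 * np.eye(data.q))

    def test_zero_variance_response_rejected(self, rng):
        data = make_random_data(rng, n=2, n_i=2, p=1, q=1)
        data.y = np.ones(4)
        with pytest.raises(DataError):
            initialize(data, BoostConfig())

    def test_premodel_recovers_intercept_on_synthetic_data(self):
        g = np.random.default_rng(3).normal
        n, n_i = 40, 6
        cluster = np.repeat(np.arange(n), n_i)
        intercepts = g(0, 0.8, n)
        y = 2.5 + intercepts[cluster] + g(0, 0.3, n * n_i)
        table = pd.DataFrame({"y": y, "id": cluster, "x1": g(0, 1, n * n_i)})
        data = build_design(table, "y", "id", fixed=["x1"])
        state = initialize(data, BoostConfig(start_mode="premodel"))
        assert state.beta0 == pytest.approx(2.5, abs=0.4)
        assert state.sigma2 == pytest.approx(0.09, rel=0.5)
        assert state.Q[0, 0] == pytest.approx(0.64, rel=0.5)
        assert np.all(state.beta == 0.0)


class TestCandidateUpdate:
    def test_zero_residual_gives_zero_update(self, rng):
        data = make_random_data(rng, n=3, n_i=3, p=2, q=1)
        state = zero_state(data)
        data.y = state.eta(data)  # residual identically zero
        data._cache.clear()
        cu = candidate_update(0, state, data)
        assert np.allclose(cu.u, 0.0, atol=1e-12)

    def test_exact_regression_on_centered_covariate(self, rng):
        data = make_random_data(rng, n=3, n_i=4, p=2, q=1)
        data.X[:, 1] -= data.X[:, 1].mean()
        state = zero_state(data)
        data.y = 2.0 * data.X[:, 1]
        data._cache.clear()
        cu = candidate_update(1, state, data)
        assert cu.u == pytest.approx([0.0, 2.0], abs=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        data = make_random_data(rng, n=4, n_i=3, p=3, q=2)
        state = ParamState(
            beta0=0.4, beta=rng.standard_normal(3),
            gamma=0.2 * rng.standard_normal(8), sigma2=0.9, Q=np.eye(2),
        )
        resid = data.y - state.eta(data)
        for r in range(data.p):
            Xt = np.column_stack([np.ones(data.N), data.X[:, r]])
            expected = np.linalg.solve(Xt.T @ Xt, Xt.T @ resid)
            cu = candidate_update(r, state, data)
            assert np.allclose(cu.u, expected, atol=1e-10)

    def test_update_invariant_to_sigma2(self, rng):
        data = make_random_data(rng, n=4, n_i=3, p=3, q=1)
        base = zero_state(data, sigma2=1.0)
        scaled = zero_state(data, sigma2=17.3)
        for r in range(data.p):
            u1 = candidate_update(r, base, data).u
            u2 = candidate_update(r, scaled, data).u
            assert np.allclose(u1, u2, atol=1e-12)


class TestSelectAndApply:
    def test_single_candidate_always_selected(self, rng):
        data = make_random_data(rng, n=4, n_i=3, p=1, q=1)
        state, r = select_and_apply(zero_state(data), data, BoostConfig())
        assert r == 0

    def test_only_selected_coordinate_moves(self, rng):
        sc = SimScenario(p=10, seed=11)
        data, _ = simulate(sc)
        config = BoostConfig()
        state0 = initialize(data, config)
        state, r = select_and_apply(state0, data, config)
        moved = np.flatnonzero(state.beta != state0.beta)
        assert moved.tolist() == [r]

    def test_first_selection_is_exhaustive_ic_argmin(self, rng):
        sc = SimScenario(p=10, seed=5)
        data, _ = simulate(sc)
        config = BoostConfig()
        state0 = initialize(data, config)
        ics = [
            candidate_update(r, state0, data, config.nu, config.criterion)
            .ic.value
            for r in range(data.p)
        ]
        _, r = select_and_apply(state0, data, config)
        assert r == int(np.argmin(ics))

    def test_duplicate_covariates_tie_break_on_lowest_index(self, rng):
        data = make_random_data(rng, n=4, n_i=3, p=3, q=1)
        data.X[:, 2] = data.X[:, 0]  # exact duplicate of candidate 0
        data.y = 3.0 * data.X[:, 0] + 0.01 * rng.standard_normal(data.N)
        data._cache.clear()
        _, r = select_and_apply(zero_state(data), data, BoostConfig())
        assert r == 0


class TestRandomEffectsStep:
    def test_zero_residual_zero_gamma_stays_zero(self, rng):
        data = make_random_data(rng, n=3, n_i=3, p=2, q=1)
        state = zero_state(data)
        data.y = state.eta(data)
        data._cache.clear()
        op = build_correction(data, classify_covariates(data))
        new = random_effects_step(state, data, op, nu=0.1)
        assert np.allclose(new.gamma, 0.0, atol=1e-14)

    def test_scalar_closed_form_per_cluster(self, rng):
        # q=1, equal residual mean rbar in every cluster: the raw step is
        # sigma^-2 n_i rbar / (sigma^-2 n_i + tau^-2), then centered away
        n, n_i, tau2, sigma2, rbar = 5, 4, 0.5, 0.8, 1.3
        data = make_random_data(rng, n=n, n_i=n_i, p=1, q=1)
        state = zero_state(data, sigma2=sigma2, Q=np.array([[tau2]]))
        resid = np.full(data.N, rbar)
        data.y = state.eta(data) + resid
        data._cache.clear()
        op = build_correction(data, classify_covariates(data))
        new = random_effects_step(state, data, op, nu=1.0)
        raw = (n_i * rbar / sigma2) / (n_i / sigma2 + 1.0 / tau2)
        # equal raw steps are removed entirely by the centering correction
        assert np.allclose(new.gamma, raw - raw, atol=1e-12)
        # without centering the raw closed form is reproduced
        op_raw = build_correction(
            data, classify_covariates(data), center_intercept=False
        )
        new_raw = random_effects_step(state, data, op_raw, nu=1.0)
        assert np.allclose(new_raw.gamma, raw, atol=1e-12)

    def test_post_step_orthogonality_to_correction_spaces(self, rng):
        data = make_random_data(
            rng, n=8, n_i=4, p=4, q=2, cluster_constant=(0, 1)
        )
        data.y = rng.standard_normal(data.N) * 2.0
        data._cache.clear()
        op = build_correction(data, classify_covariates(data))
        state = zero_state(data, sigma2=1.3, Q=0.5 * np.eye(2))
        new = random_effects_step(state, data, op, nu=0.7)
        G = new.gamma.reshape(data.n, data.q)
        for s in range(data.q):
            Xc = op.correction_covariates[s]
            assert np.allclose(Xc.T @ G[:, s], 0.0, atol=1e-8)


class TestUpdateVarianceComponents:
    def test_em_formula_arithmetic(self, rng):
        # n=2, q=1, gamma = (1, -1), F_i^{-1} = 0.5 -> Q_hat = 1.5
        data = make_random_data(rng, n=2, n_i=2, p=1, q=1)
        data.Z = np.ones((4, 1))
        data._cache.clear()
        # F_i = n_i / sigma2 + 1/Q = 2/sigma2 + 1/Q; choose so F_i^{-1}=0.5
        # 2/sigma2 + 1/Q = 2  with Q = 1 -> sigma2 = 2
        state = ParamState(
            beta0=0.0, beta=np.zeros(1), gamma=np.array([1.0, -1.0]),
            sigma2=2.0, Q=np.array([[1.0]]),
        )
        new = update_variance_components(state, data)
        assert new.Q[0, 0] == pytest.approx(1.5)

    def test_sigma2_is_sample_variance_of_residuals(self, rng):
        data = make_random_data(rng, n=4, n_i=5, p=2, q=1)
        state = ParamState(
            beta0=0.3, beta=rng.standard_normal(2),
            gamma=rng.standard_normal(4), sigma2=1.0, Q=np.eye(1),
        )
        new = update_variance_components(state, data)
        resid = data.y - state.eta(data)
        assert new.sigma2 == pytest.approx(float(resid.var(ddof=1)))

    def test_Q_symmetric_psd(self, rng):
        data = make_random_data(rng, n=6, n_i=3, p=2, q=3)
        state = ParamState(
            beta0=0.0, beta=np.zeros(2),
            gamma=rng.standard_normal(18), sigma2=0.5,
            Q=np.diag([1.0, 0.5, 0.25]),
        )
        new = update_variance_components(state, data)
        assert np.allclose(new.Q, new.Q.T)
        assert np.linalg.eigvalsh(new.Q).min() >= -1e-12


class TestFit:
    def test_pure_noise_selects_little_and_stops_early(self):
        sc = SimScenario(p=10, tau=0.1, seed=99)
        data, truth = simulate(sc)
        # overwrite the response with noise only (all beta = 0 truth)
        rng = np.random.default_rng(1)
        data.y = (
            1.0
            + np.repeat(rng.normal(0, 0.1, data.n), 5)
            + rng.normal(0, 0.4, data.N)
        )
        data._cache.clear()
        res = fit(data, BoostConfig(m_stop=300))
        # the model stays essentially empty: at most a couple of covariates
        # touched, with negligible coefficients, and the criterion is flat
        # once the intercept-only fit has converged
        assert np.count_nonzero(res.beta) <= 2
        assert np.abs(res.beta).max() < 0.15
        assert res.ic_path[29] - res.ic_path.min() < 2.0

    def test_informative_covariates_all_enter(self):
        data, truth = simulate(SimScenario(p=10, tau=0.4, seed=12))
        res = fit(data, BoostConfig())
        assert set(res.selected_covariates) == {"x1", "x2", "x3", "x4"}
        # cluster-constant informative covariates both selected
        assert {"x1", "x2"} <= set(res.selected_covariates)

    def test_sparsity_along_path(self):
        data, _ = simulate(SimScenario(p=10, seed=4))
        res = fit(data, BoostConfig(m_stop=40))
        for m in range(res.n_iterations):
            nnz = np.count_nonzero(res.beta_path[m])
            assert nnz <= m + 1
            # unselected coordinates are exactly zero
            touched = set(res.selected_path[: m + 1].tolist())
            untouched = set(range(10)) - touched
            assert all(res.beta_path[m][j] == 0.0 for j in untouched)

    def test_replay_determinism_bitwise(self):
        data, _ = simulate(SimScenario(p=10, seed=8))
        r1 = fit(data, BoostConfig(m_stop=60))
        r2 = fit(data, BoostConfig(m_stop=60))
        assert np.array_equal(r1.beta_path, r2.beta_path)
        assert np.array_equal(r1.ic_path, r2.ic_path)
        assert np.array_equal(r1.gamma_path, r2.gamma_path)

    def test_full_step_converges_to_gls(self, rng):
        # nu=1, single informative covariate: beta converges to the GLS
        # solution at the converged variance components
        n, n_i = 30, 5
        cluster = np.repeat(np.arange(n), n_i)
        x = rng.standard_normal(n * n_i)
        y = (
            1.0
            + 2.0 * x
            + np.repeat(rng.normal(0, 0.5, n), n_i)
            + rng.normal(0, 0.4, n * n_i)
        )
        table = pd.DataFrame({"y": y, "id": cluster, "x1": x})
        data = build_design(table, "y", "id", fixed=["x1"])
        res = fit(data, BoostConfig(nu=1.0, m_stop=400))
        final = res.state_at(res.n_iterations)
        V = np.zeros((data.N, data.N))
        starts = data.cluster_starts
        for i, Zi in enumerate(data.Z_blocks):
            sl = slice(starts[i], starts[i + 1])
            V[sl, sl] = Zi @ final.Q @ Zi.T + final.sigma2 * np.eye(len(Zi))
        Xt = np.column_stack([np.ones(data.N), data.X])
        Vi = np.linalg.inv(V)
        gls = np.linalg.solve(Xt.T @ Vi @ Xt, Xt.T @ Vi @ data.y)
        assert final.beta0 == pytest.approx(gls[0], abs=1e-3)
        assert final.beta[0] == pytest.approx(gls[1], abs=1e-3)

    def test_random_intercepts_not_separated_by_constant_dummy(self, rng):
        # the identification property: a cluster-constant informative dummy
        # must land in beta, not in the random intercepts
        n, n_i = 40, 5
        cluster = np.repeat(np.arange(n), n_i)
        dummy = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        y = (
            1.0
            + 2.0 * dummy[cluster]
            + np.repeat(rng.normal(0, 0.4, n), n_i)
            + rng.normal(0, 0.4, n * n_i)
        )
        table = pd.DataFrame(
            {"y": y, "id": cluster, "g": dummy[cluster]}
        )
        data = build_design(table, "y", "id", fixed=["g"])
        res = fit(data, BoostConfig(m_stop=500))
        assert res.beta[0] == pytest.approx(2.0, abs=0.3)
        intercepts = res.gamma.reshape(n, 1)[:, 0]
        gap = abs(
            intercepts[dummy > 0].mean() - intercepts[dummy < 0].mean()
        )
        assert gap < 0.15

    def test_mstop_warning_when_ic_still_decreasing(self):
        data, _ = simulate(SimScenario(p=10, seed=2))
        with pytest.warns(UserWarning, match="still decreasing"):
            fit(data, BoostConfig(m_stop=5))
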