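import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spadinv as sv


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestELM:
    def test_interpolation_capacity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 3))
        y = rng.standard_normal(8)
        model = sv.elm_train(X, y, n_hidden=16, seed=1, ridge=0.0)
        rmse = np.sqrt(np.mean((y - model.predict(X)) ** 2))
        assert rmse <= 1e-6

    def test_linear_activation_recovers_linear_map(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        y = X @ np.array([2.0, -1.0, 0.5, 3.0]) + 7.0
        W = rng.uniform(-1, 1, (4, 4))
        while abs(np.linalg.det(W)) < 1e-3:
            W = rng.uniform(-1, 1, (4, 4))
        model = sv.elm_train(X, y, activation="linear", weights=W,
                             thresholds=np.zeros(4), standardize=False)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_readout_matches_normal_equations_oracle(self):
        X = np.array([[0.1, 0.4], [0.3, 0.2], [0.5, 0.9], [0.7, 0.6]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        W = np.array([[0.5, -0.3], [0.2, 0.8]])
        b = np.array([0.1, -0.2])
        model = sv.elm_train(X, y, weights=W, thresholds=b, ridge=0.0,
                             include_intercept=False, standardize=False)
        H = _sigmoid(X @ W + b)
        beta, *_ = np.linalg.lstsq(H, y, rcond=None)
        np.testing.assert_allclose(model.output_weights, beta, atol=1e-10)

    def test_predict_reproduces_fitted_values(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        model = sv.elm_train(X, y, n_hidden=5, seed=3)
        np.testing.assert_allclose(model.predict(X), model.predict(X))

    def test_zero_weight_model_predicts_constant(self):
        X = np.random.default_rng(3).standard_normal((10, 2))
        y = np.full(10, 5.0)
        model = sv.elm_train(X, y, weights=np.zeros((2, 3)),
                             thresholds=np.zeros(3), standardize=False)
        np.testing.assert_allclose(model.predict(X), 5.0, atol=1e-6)

    def test_hand_computed_forward_pass(self):
        # one sample, one input, two hidden neurons, worked by hand
        model = sv.ELMModel(
            input_weights=np.array([[1.0, -1.0]]),
            hidden_thresholds=np.array([0.0, 0.5]),
            output_weights=np.array([2.0, 3.0]),
            include_intercept=False,
        )
        x = np.array([[0.5]])
        expected = 2.0 * _sigmoid(0.5) + 3.0 * _sigmoid(0.0)
        assert model.predict(x)[0] == pytest.approx(expected, abs=1e-12)

    def test_column_mismatch_rejected(self):
        model = sv.elm_train(np.ones((5, 3)) + np.eye(5, 3), np.arange(5.0),
                             n_hidden=2, seed=0)
        with pytest.raises(ValueError):
            model.predict(np.ones((2, 4)))

    def test_nonfinite_input_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            sv.elm_train(X, np.ones(4), n_hidden=2, seed=0)

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(5).standard_normal((15, 3))
        y = np.random.default_rng(6).standard_normal(15)
        a = sv.elm_train(X, y, n_hidden=4, seed=9)
        b = sv.elm_train(X, y, n_hidden=4, seed=9)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)


class TestEncoding:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(-1, 1, (3, 5))
        b = rng.uniform(-1, 1, 5)
        W2, b2 = sv.decode(sv.encode(W, b), 3, 5)
        np.testing.assert_array_equal(W, W2)
        np.testing.assert_array_equal(b, b2)

    def test_dimension_formula(self):
        W = np.zeros((2, 3))
        b = np.zeros(3)
        assert sv.encode(W, b).size == 3 * (2 + 1)  # D = t (n + 1)

    def test_row_major_layout(self):
        # labelled 2x2 case: weights row-major by input, then thresholds
        W = np.array([[11.0, 12.0], [21.0, 22.0]])
        b = np.array([1.0, 2.0])
        np.testing.assert_array_equal(
            sv.encode(W, b), [11.0, 12.0, 21.0, 22.0, 1.0, 2.0]
        )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            sv.decode(np.zeros(7), 2, 3)

    @given(st.integers(1, 5), st.integers(1, 6), st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, n, t, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(-1, 1, (n, t))
        b = rng.uniform(-1, 1, t)
        W2, b2 = sv.decode(sv.encode(W, b), n, t)
        assert np.array_equal(W, W2) and np.array_equal(b, b2)


class TestPsoStep:
    def test_fixed_point(self):
        pos = np.array([0.3, -0.2])
        p = sv.Particle(pos.copy(), np.zeros(2), pos.copy(), 1.0)
        swarm = sv.Swarm([p], pos.copy(), 1.0, v_clamp=None, x_clamp=None)
        sv.pso_step(swarm, lambda x: float(np.sum(x ** 2)))
        np.testing.assert_array_equal(p.velocity, 0.0)
        np.testing.assert_array_equal(p.position, pos)

    def test_hand_worked_update(self):
        # 1-D: X=0, V=0, Pbest=1, Gbest=2, omega=0.9, c1=c2=1.4, r1=r2=0.5
        p = sv.Particle(np.array([0.0]), np.array([0.0]), np.array([1.0]), 0.5)
        swarm = sv.Swarm([p], np.array([2.0]), 0.1, omega=0.9, c1=1.4, c2=1.4,
                         v_clamp=None, x_clamp=None)
        sv.pso_step(swarm, lambda x: float(x[0] ** 2), r1=0.5, r2=0.5)
        assert p.velocity[0] == pytest.approx(2.1, abs=1e-15)
        assert p.position[0] == pytest.approx(2.1, abs=1e-15)

    def test_sphere_convergence_monte_carlo(self):
        def sphere(x):
            return float(np.sum(x ** 2))
        converged = 0
        for seed in range(20):
            swarm = sv.init_swarm(sphere, dim=2, swarm_size=20, seed=seed,
                                  v_clamp=None, x_clamp=None)
            for _ in range(100):
                sv.pso_step(swarm, sphere)
            converged += swarm.gbest_fitness <= 1e-3
        assert converged >= 19

    def test_gbest_monotone_and_finite(self):
        def rosen(x):
            return float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)
        swarm = sv.init_swarm(rosen, dim=2, swarm_size=10, seed=0)
        prev = swarm.gbest_fitness
        for _ in range(50):
            sv.pso_step(swarm, rosen)
            assert swarm.gbest_fitness <= prev
            prev = swarm.gbest_fitness
            for p in swarm.particles:
                assert np.all(np.isfinite(p.position))
                assert np.all(np.isfinite(p.velocity))

    def test_position_clamp_keeps_weight_domain(self):
        swarm = sv.init_swarm(lambda x: float(np.sum(x ** 2)), dim=3,
                              swarm_size=5, seed=1)  # default clamps on
        for _ in range(20):
            sv.pso_step(swarm, lambda x: float(np.sum(x ** 2)))
        for p in swarm.particles:
            assert np.all(np.abs(p.position) <= 1.0)
            assert np.all(np.abs(p.velocity) <= 1.0)

    def test_nonfinite_fitness_names_particle(self):
        swarm = sv.init_swarm(lambda x: float(np.sum(x ** 2)), dim=1,
                              swarm_size=2, seed=0)
        with pytest.raises(ValueError, match="particle"):
            sv.pso_step(swarm, lambda x: float("nan"))


class TestFitnessRmse:
    def test_perfect_fit_scores_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 2))
        y = X @ np.array([1.0, -2.0])
        W = rng.uniform(-1, 1, (2, 12))
        b = rng.uniform(-1, 1, 12)
        pos = sv.encode(W, b)
        assert sv.fitness_rmse(pos, 2, 12, "sigmoid", X, y, ridge=0.0) <= 1e-6

    def test_equals_manual_elm_pipeline(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        W = rng.uniform(-1, 1, (3, 6))
        b = rng.uniform(-1, 1, 6)
        got = sv.fitness_rmse(sv.encode(W, b), 3, 6, "sigmoid", X, y)
        model = sv.elm_train(X, y, weights=W, thresholds=b)
        want = float(np.sqrt(np.mean((y - model.predict(X)) ** 2)))
        assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 2))
        y = rng.standard_normal(15)
        W = rng.uniform(-1, 1, (2, 4))
        b = rng.uniform(-1, 1, 4)
        pos = sv.encode(W, b)
        perm = rng.permutation(15)
        a = sv.fitness_rmse(pos, 2, 4, "sigmoid", X, y)
        bb = sv.fitness_rmse(pos, 2, 4, "sigmoid", X[perm], y[perm])
        assert a == pytest.approx(bb, abs=1e-9)


class TestPsoElmTrain:
    def test_huge_tol_stops_after_first_stall(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        model, trace = sv.pso_elm_train(X, y, n_hidden=3, swarm_size=5,
                                        max_iter=50, tol=1e9, patience=3, seed=0)
        assert len(trace) <= 1 + 3 + 1  # init + patience window
        assert isinstance(model, sv.ELMModel)

    def test_trace_non_increasing(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + 0.1 * rng.standard_normal(40)
        _, trace = sv.pso_elm_train(X, y, n_hidden=5, swarm_size=10,
                                    max_iter=30, seed=1)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_single_particle_swarm_valid(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        model, trace = sv.pso_elm_train(X, y, n_hidden=3, swarm_size=1,
                                        max_iter=10, seed=2)
        assert np.all(np.isfinite(model.predict(X)))

    def test_model_equals_decoded_gbest_with_refit_readout(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 2))
        y = rng.standard_normal(25)
        model, trace = sv.pso_elm_train(X, y, n_hidden=4, swarm_size=8,
                                        max_iter=15, seed=3)
        refit = sv.elm_train(X, y, weights=model.input_weights,
                             thresholds=model.hidden_thresholds)
        np.testing.assert_allclose(model.output_weights, refit.output_weights,
                                   atol=1e-12)
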