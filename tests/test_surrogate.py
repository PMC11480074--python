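"""MLP forward/Jacobian correctness and Levenberg-Marquardt training."""

import numpy as np
import pytest

from alphamicro import dataset as ds, surrogate as sg


def _toy_params(sizes, seed=0, lo=None, hi=None):
    n_in = sizes[0]
    lo = np.zeros(n_in) if lo is None else lo
    hi = np.ones(n_in) if hi is None else hi
    return sg.init_params(sizes, lo, hi, np.random.default_rng(seed))


class TestForward:
    def test_zero_weights_give_biases(self):
        p = _toy_params((4, 10, 26, 21))
        for w in p.weights:
            w[:] = 0.0
        p.biases[0][:] = 0.0
        p.biases[1][:] = 0.0
        out = sg.forward(p, np.zeros(4))
        assert np.allclose(out, p.biases[-1])

    def test_batch_equals_per_sample(self):
        p = _toy_params((3, 5, 2))
        x = np.random.default_rng(1).random((7, 3))
        batch = sg.forward(p, x)
        single = np.stack([sg.forward(p, xi) for xi in x])
        assert np.allclose(batch, single)

    def test_small_weight_linearisation(self):
        """tanh is odd: scaling first-layer weights by eps makes the output
        linear in the input up to O(eps^3)."""
        p = _toy_params((2, 4, 3))
        p.biases[0][:] = 0.0
        eps = 1e-3
        p.weights[0] *= eps
        x0 = np.array([0.3, 0.4])
        f0 = sg.forward(p, np.zeros(2))
        f1 = sg.forward(p, x0) - f0
        f2 = sg.forward(p, 2 * x0) - f0
        assert np.allclose(f2, 2 * f1, atol=1e-7)

    def test_nonfinite_input_rejected(self):
        p = _toy_params((2, 3, 2))
        with pytest.raises(ValueError):
            sg.forward(p, np.array([np.nan, 1.0]))


class TestJacobian:
    @pytest.mark.parametrize("sizes", [(3, 5, 7, 4), (4, 10, 26, 21), (2, 3), (3, 6, 2)])
    def test_matches_finite_differences(self, sizes):
        p = _toy_params(sizes, seed=2)
        x = np.random.default_rng(3).random((5, sizes[0]))
        jac = sg.jacobian(p, x)
        assert jac.shape == (5 * sizes[-1], p.n_params)
        vec = p.to_vector()
        h = 1e-6
        fd = np.empty_like(jac)
        for i in range(vec.size):
            up, dn = vec.copy(), vec.copy()
            up[i] += h
            dn[i] -= h
            fd[:, i] = ((sg.forward(p.with_vector(up), x)
                         - sg.forward(p.with_vector(dn), x)) / (2 * h)).ravel()
        scale = max(np.abs(fd).max(), 1.0)
        assert np.abs(jac - fd).max() / scale < 1e-6

    def test_zero_weights_gate_deep_columns(self):
        """With zero input weights, tanh(0) = 0 gates every second-layer
        weight column of the Jacobian."""
        p = _toy_params((3, 4, 2))
        p.weights[0][:] = 0.0
        p.biases[0][:] = 0.0
        x = np.random.default_rng(4).random((6, 3))
        jac = sg.jacobian(p, x)
        off = p.weights[0].size + p.biases[0].size
        w2_cols = jac[:, off:off + p.weights[1].size]
        assert np.allclose(w2_cols, 0.0)

    def test_parameter_count(self):
        p = _toy_params((4, 10, 26, 21))
        assert p.n_params == 5 * 10 + 11 * 26 + 27 * 21 == 903


class TestLMStep:
    def test_linear_problem_solved_in_one_step(self):
        """A no-hidden-layer (parameter-linear) net: one accepted LM step
        reaches the normal-equations least-squares solution."""
        rng = np.random.default_rng(5)
        x = rng.random((40, 3))
        y = x @ rng.random((3, 2)) + rng.random(2) + 0.01 * rng.normal(size=(40, 2))
        p = _toy_params((3, 2), seed=6, lo=np.zeros(3), hi=np.ones(3))
        cfg = sg.TrainConfig(lam0=1e-10)
        state = sg.LMState(lam=cfg.lam0)
        p2, state, accepted = sg.lm_step(state, p, x, y, cfg)
        assert accepted
        # normal-equations oracle on the normalised design matrix
        xn = np.hstack([p.normalize(x), np.ones((40, 1))])
        beta = np.linalg.lstsq(xn, y, rcond=None)[0]
        pred_opt = xn @ beta
        assert np.allclose(sg.forward(p2, x), pred_opt, atol=1e-8)

    def test_step_at_optimum_rejected_and_lambda_grows(self):
        rng = np.random.default_rng(7)
        x = rng.random((30, 2))
        p = _toy_params((2, 2), seed=8, lo=np.zeros(2), hi=np.ones(2))
        y = sg.forward(p, x)  # already exact: no step can strictly improve
        cfg = sg.TrainConfig(lam0=1e-3, max_retries=3)
        state = sg.LMState(lam=cfg.lam0)
        p2, state, accepted = sg.lm_step(state, p, x, y, cfg)
        assert not accepted
        assert state.lam > cfg.lam0
        assert np.array_equal(p2.to_vector(), p.to_vector())

    def test_accepted_step_never_increases_mse(self):
        rng = np.random.default_rng(9)
        x = rng.random((50, 3))
        y = np.sin(3 * x[:, :1]) + x[:, 1:2] ** 2
        p = _toy_params((3, 6, 1), seed=10)
        cfg = sg.TrainConfig()
        state = sg.LMState(lam=cfg.lam0)
        for _ in range(20):
            before = sg._mse(p, x, y)
            p, state, accepted = sg.lm_step(state, p, x, y, cfg)
            if accepted:
                assert sg._mse(p, x, y) < before


class TestTrain:
    def test_sine_function_approximation(self):
        x = np.linspace(-3, 3, 200)[:, None]
        xv = np.linspace(-2.9, 2.9, 60)[:, None]
        cfg = sg.TrainConfig(hidden=(10, 26), max_epochs=400, patience=40)
        params, state = sg.train(x, np.sin(x), xv, np.sin(xv), cfg,
                                 np.random.default_rng(11))
        assert np.sqrt(sg._mse(params, x, np.sin(x))) < 1e-3

    def test_deterministic_given_seed(self):
        x = np.linspace(0, 1, 50)[:, None]
        y = x**2
        cfg = sg.TrainConfig(hidden=(4, 4), max_epochs=20, patience=20)
        p1, _ = sg.train(x, y, x, y, cfg, np.random.default_rng(12))
        p2, _ = sg.train(x, y, x, y, cfg, np.random.default_rng(12))
        assert np.array_equal(p1.to_vector(), p2.to_vector())

    def test_best_snapshot_contract(self):
        x = np.linspace(-1, 1, 80)[:, None]
        y = np.cos(2 * x)
        xv = np.linspace(-1, 1, 30)[:, None]
        cfg = sg.TrainConfig(hidden=(5, 5), max_epochs=60, patience=6)
        params, state = sg.train(x, y, xv, np.cos(2 * xv), cfg,
                                 np.random.default_rng(13))
        assert state.best_val_mse <= min(state.val_history) + 1e-15
        assert sg._mse(params, xv, np.cos(2 * xv)) == pytest.approx(
            state.best_val_mse)

    def test_early_stopping_honours_patience(self):
        x = np.linspace(-1, 1, 60)[:, None]
        rng = np.random.default_rng(14)
        y = 0.1 * rng.normal(size=(60, 1))  # pure noise: validation degrades
        xv = np.linspace(-1, 1, 30)[:, None]
        yv = 0.1 * rng.normal(size=(30, 1))
        cfg = sg.TrainConfig(hidden=(8, 8), max_epochs=500, patience=4)
        _, state = sg.train(x, y, xv, yv, cfg, np.random.default_rng(15))
        assert state.epoch < 500

    def test_overfit_capacity_on_small_fixture(self, small_dataset):
        """The default 4-10-26-21 net can drive training MSE below 1e-4 on
        a 50-record fixture (capacity check)."""
        df = small_dataset.head(50)
        x = df[ds.input_columns()].to_numpy(float)
        y = df[ds.target_columns()].to_numpy(float)
        cfg = sg.TrainConfig(max_epochs=300, patience=300, mse_goal=5e-5)
        params, state = sg.train(x, y, x, y, cfg, np.random.default_rng(16))
        assert min(state.train_history) < 1e-4


class TestGridSearchAndPrediction:
    def test_grid_search_table(self, small_dataset):
        cfg = sg.TrainConfig(max_epochs=8, patience=8)
        table, best = sg.grid_search(small_dataset, np.random.default_rng(17),
                                     h1_range=range(4, 6), h2_range=range(5, 8),
                                     config=cfg)
        assert table.shape == (2, 3)
        assert np.isfinite(table.to_numpy(float)).all()
        assert best[0] in table.index and best[1] in table.columns

    def test_predict_spectrum_invariants(self, small_dataset):
        df = small_dataset
        x = df[ds.input_columns()].to_numpy(float)
        y = df[ds.target_columns()].to_numpy(float)
        cfg = sg.TrainConfig(max_epochs=60, patience=10)
        params, _ = sg.train(x, y, x, y, cfg, np.random.default_rng(18))
        row = df.iloc[3]
        design = ds.DesignPoint(int(row.region), row.e0_mev, row.rn_um, row.rc_um)
        spec = sg.predict_spectrum(params, design)
        assert spec.z_max > 0
        assert np.all(spec.f >= 0)
        assert spec.area == pytest.approx(1.0, abs=1e-9)
        raw = sg.predict_spectrum(params, design, renormalize=False)
        assert raw.area != pytest.approx(1.0, abs=1e-12) or np.allclose(raw.f, spec.f)

    def test_model_save_load_roundtrip(self, tmp_path):
        p = _toy_params((4, 10, 26, 21), seed=19)
        path = tmp_path / "model.json"
        sg.save_model(p, path)
        q = sg.load_model(path)
        assert q.sizes == p.sizes
        assert np.array_equal(q.to_vector(), p.to_vector())
        x = np.random.default_rng(20).random((3, 4))
        assert np.allclose(sg.forward(q, x), sg.forward(p, x))
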