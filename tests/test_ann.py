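"""Network and optimizer tests: architecture arithmetic, gradient checks,
Rprop+ reference-trajectory equivalence, closed-form recovery, data splits."""

import dataclasses
import warnings

import numpy as np
import pytest

from serscal import ann
from serscal.ann import (
    GH_ARCHITECTURE,
    TE_ARCHITECTURE,
    MLPArchitecture,
    MLPEnsemble,
    TrainConfig,
    ensemble_forward,
    forward,
    gradients,
    holdout_split,
    init_mlp,
    kfold_indices,
    n_parameters,
    train_ensemble,
    train_rprop_plus,
)


def raw_config(**overrides) -> TrainConfig:
    return TrainConfig(**{"standardize_inputs": False, **overrides})


class TestArchitecture:
    def test_preset_parameter_counts_by_layer_arithmetic(self):
        # 6->12:10:10:10:6->1: 84+130+110+110+66+7
        assert n_parameters(GH_ARCHITECTURE) == 507
        # 6->10:8:8:8:6->1: 70+88+72+72+54+7
        assert n_parameters(TE_ARCHITECTURE) == 363

    def test_preset_shapes(self):
        model = init_mlp(GH_ARCHITECTURE, seed=0)
        assert [w.shape for w in model.weights] == [
            (6, 12), (12, 10), (10, 10), (10, 10), (10, 6), (6, 1),
        ]
        assert all(np.all(b == 0) for b in model.biases)

    def test_same_seed_identical_weights(self):
        a = init_mlp(TE_ARCHITECTURE, seed=11)
        b = init_mlp(TE_ARCHITECTURE, seed=11)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            MLPArchitecture(0, (3,), 1)


class TestForward:
    def test_zero_weights_predict_output_bias(self):
        model = init_mlp(MLPArchitecture(6, (4,), 1), seed=0)
        for w in model.weights:
            w[...] = 0.0
        model.biases[-1][...] = 2.5
        np.testing.assert_allclose(forward(model, np.zeros((3, 6))), 2.5)

    def test_hand_computed_single_hidden_unit(self):
        """w1 = (1, 2, 0, 0, 0, 0), b1 = 0.5, w2 = 2, b2 = -1.
        Input (1,-1,0,0,0,0): z = 1 - 2 + 0.5 = -0.5 -> ReLU 0 -> output -1.
        Input (1, 1,0,0,0,0): z = 3.5 -> output 6."""
        model = init_mlp(MLPArchitecture(6, (1,), 1), seed=0)
        model.weights[0][...] = np.array([[1.0, 2.0, 0, 0, 0, 0]]).T
        model.biases[0][...] = 0.5
        model.weights[1][...] = [[2.0]]
        model.biases[1][...] = -1.0
        x = np.array([[1.0, -1.0, 0, 0, 0, 0], [1.0, 1.0, 0, 0, 0, 0]])
        np.testing.assert_allclose(forward(model, x), [-1.0, 6.0])

    def test_dimension_mismatch_rejected(self):
        model = init_mlp(MLPArchitecture(6, (3,), 1), seed=0)
        with pytest.raises(ValueError, match="features"):
            forward(model, np.ones((2, 4)))


class TestGradients:
    @pytest.mark.parametrize("seed", range(3))
    def test_backprop_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        model = init_mlp(MLPArchitecture(3, (4, 3), 1), seed=seed)
        # evaluate at a generic point: zero biases leave some pre-activations
        # exactly on the ReLU kink, where central differences are undefined
        for p in model.weights + model.biases:
            p += 0.1 * rng.normal(size=p.shape)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        _, grad_w, grad_b = gradients(model, X, y)
        eps = 1e-6
        for params, grads in ((model.weights, grad_w), (model.biases, grad_b)):
            for p, g in zip(params, grads):
                flat = p.ravel()
                for idx in range(flat.size):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up, *_ = gradients(model, X, y)
                    flat[idx] = orig - eps
                    dn, *_ = gradients(model, X, y)
                    flat[idx] = orig
                    numeric = (up - dn) / (2 * eps)
                    analytic = g.ravel()[idx]
                    assert analytic == pytest.approx(
                        numeric, rel=1e-5, abs=1e-8
                    )


def reference_rprop_plus(x0, grad_fn, cfg: TrainConfig, epochs: int):
    """Literal scalar-loop Rprop+ with backtracking (independent oracle)."""
    x = [float(v) for v in x0]
    step = [cfg.delta0] * len(x)
    g_prev = [0.0] * len(x)
    u_prev = [0.0] * len(x)
    history = [list(x)]
    for _ in range(epochs):
        g = grad_fn(np.array(x))
        for i in range(len(x)):
            s = g_prev[i] * g[i]
            if s > 0:
                step[i] = min(step[i] * cfg.eta_plus, cfg.delta_max)
                u = -np.sign(g[i]) * step[i]
                x[i] += u
                u_prev[i], g_prev[i] = u, g[i]
            elif s < 0:
                step[i] = max(step[i] * cfg.eta_minus, cfg.delta_min)
                x[i] -= u_prev[i]
                u_prev[i], g_prev[i] = 0.0, 0.0
            else:
                u = -np.sign(g[i]) * step[i]
                x[i] += u
                u_prev[i], g_prev[i] = u, g[i]
        history.append(list(x))
    return history


class TestRpropPlus:
    def test_step_growth_under_constant_gradient_sign(self):
        """delta0 = 0.1, eta+ = 1.2: step sizes 0.1, 0.12, 0.144."""
        cfg = raw_config(delta0=0.1)
        w = np.array([0.0])
        state = ann._RpropState([w], cfg.delta0)
        seen = []
        for _ in range(3):
            ann._rprop_update([w], [np.array([1.0])], state, cfg)
            seen.append(float(state.step[0][0]))
        assert seen == pytest.approx([0.1, 0.12, 0.144])

    def test_scalar_quadratic_converges_to_minimum(self):
        """d/dw (w-3)^2 drives w to 3 within 1e-4 in at most 200 epochs."""
        cfg = raw_config()
        w = np.array([0.0])
        state = ann._RpropState([w], cfg.delta0)
        for _ in range(200):
            ann._rprop_update([w], [np.array([2 * (w[0] - 3.0)])], state, cfg)
        assert abs(w[0] - 3.0) < 1e-4

    @pytest.mark.parametrize("seed", range(3))
    def test_vectorized_updates_match_scalar_reference_trajectory(self, seed):
        """A <=5-parameter net must follow the literal per-scalar Rprop+
        rule exactly, epoch by epoch."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 1))
        y = rng.normal(size=8)
        arch = MLPArchitecture(1, (1,), 1)  # 4 parameters
        cfg = raw_config(max_epochs=10, patience=10**9, early_stop_tolerance=0.0)

        def flatten(model):
            return np.concatenate(
                [p.ravel() for p in model.weights + model.biases]
            )

        def grad_fn(theta):
            probe = init_mlp(arch, seed=seed)
            probe.weights[0][...] = theta[0]
            probe.weights[1][...] = theta[1]
            probe.biases[0][...] = theta[2]
            probe.biases[1][...] = theta[3]
            _, gw, gb = gradients(probe, X, y)
            return np.concatenate([g.ravel() for g in gw + gb])

        start = flatten(init_mlp(arch, seed=seed))
        expected = reference_rprop_plus(start, grad_fn, cfg, epochs=10)
        for epochs in (1, 4, 10):
            model = init_mlp(arch, seed=seed)
            train_rprop_plus(
                model, X, y, dataclasses.replace(cfg, max_epochs=epochs)
            )
            np.testing.assert_array_equal(flatten(model), expected[epochs])

    def test_linear_network_recovers_least_squares_solution(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.5, -2.0, 0.7]) + 0.3
        model = init_mlp(MLPArchitecture(3, (), 1), seed=0)
        cfg = raw_config(
            max_epochs=30000, delta_min=1e-12,
            early_stop_tolerance=0.0, patience=10**9,
        )
        train_rprop_plus(model, X, y, cfg)
        ols, *_ = np.linalg.lstsq(
            np.column_stack([X, np.ones(len(X))]), y, rcond=None
        )
        got = np.r_[model.weights[0][:, 0], model.biases[0]]
        np.testing.assert_allclose(got, ols, atol=1e-6)

    def test_noise_free_capacity_sanity(self):
        """On clean low-dimensional targets the network reaches near-zero
        training loss (capacity check)."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 6))
        y = 2.0 * np.maximum(X[:, 0], 0) + 0.5 * X[:, 1]
        model = init_mlp(GH_ARCHITECTURE, seed=1)
        train_rprop_plus(model, X, y, raw_config(max_epochs=4000))
        assert model.training_history[-1] < 1e-3

    def test_training_history_is_monotone_enough_to_stop(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2))
        y = X.sum(axis=1)
        model = init_mlp(MLPArchitecture(2, (3,), 1), seed=2)
        cfg = raw_config(max_epochs=50000, early_stop_tolerance=1e-10, patience=25)
        train_rprop_plus(model, X, y, cfg)
        assert len(model.training_history) < 50000  # plateau stop fired

    def test_non_finite_targets_rejected(self):
        model = init_mlp(MLPArchitecture(2, (), 1), seed=0)
        with pytest.raises(ValueError):
            train_rprop_plus(
                model, np.ones((3, 2)), np.array([1.0, np.nan, 2.0]), raw_config()
            )


class TestEnsemble:
    def test_median_prediction_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 6))
        y = X[:, 0] * 3.0 + 1.0
        ens = train_ensemble(
            MLPArchitecture(6, (4,), 1), X, y,
            raw_config(max_epochs=500), n_restarts=3, seed=0,
        )
        pred = ensemble_forward(ens, X)
        stacked = np.array([forward(m, X) for m in ens.members])
        np.testing.assert_array_equal(pred, np.median(stacked, axis=0))
        ens.to_json(tmp_path / "ens.json")
        back = MLPEnsemble.from_json(tmp_path / "ens.json")
        np.testing.assert_allclose(ensemble_forward(back, X), pred, rtol=1e-12)


class TestSplits:
    def test_900_samples_split_675_225_stratified(self):
        levels = np.repeat(np.geomspace(0.01, 60, 30), 30)
        train, test = holdout_split(levels, 0.75, seed=0)
        assert train.size == 675 and test.size == 225
        assert np.intersect1d(train, test).size == 0
        for lv in np.unique(levels):
            assert np.any(levels[train] == lv) and np.any(levels[test] == lv)

    def test_same_seed_same_partition(self):
        levels = np.repeat(np.arange(5), 8)
        a = holdout_split(levels, 0.75, seed=3)
        b = holdout_split(levels, 0.75, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_singleton_stratum_goes_to_training_with_warning(self):
        levels = np.array([1, 1, 1, 1, 2])
        with pytest.warns(UserWarning, match="single sample"):
            train, test = holdout_split(levels, 0.75, seed=0)
        assert 4 in train

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(np.arange(10), 1.0, seed=0)

    def test_kfold_sizes_differ_by_at_most_one(self):
        levels = np.repeat(np.arange(30), 30)
        folds = kfold_indices(levels, 4, seed=1)
        sizes = [f.size for f in folds]
        assert sizes == [225, 225, 225, 225]
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(900))

    def test_leave_one_out_on_six_samples(self):
        folds = kfold_indices(np.arange(6), 6, seed=0)
        assert sorted(f.size for f in folds) == [1] * 6

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(np.arange(4), 5, seed=0)

    def test_kfold_cv_returns_fold_metrics(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(48, 6))
        y = X[:, 0] + 0.1 * rng.normal(size=48)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = ann.kfold_cv(
                X, y, MLPArchitecture(6, (4,), 1),
                raw_config(max_epochs=300), k=3, seed=2,
                strata=np.repeat(np.arange(8), 6),
            )
        assert len(res) == 3
        assert all(set(r) == {"fold", "rmse", "r2", "n"} for r in res)
        assert sum(r["n"] for r in res) == 48
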