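"""FedAvg training: averaging identities, determinism, pooled equivalence."""

import numpy as np
import pytest

from fedsilo.deep import (
    Architecture,
    ModelParams,
    TrainConfig,
    fedavg,
    forward,
    init_params,
    local_update,
    train_federated,
)


def _linear_arch(p=3):
    return Architecture(layer_sizes=(p, 1), activation="identity")


def _regression_data(n, p, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(scale=0.1, size=n)
    return X, y


class TestLocalUpdate:
    def test_zero_learning_rate_is_identity(self):
        arch = Architecture(layer_sizes=(3, 4, 1))
        params = init_params(arch, 0)
        X, y = _regression_data(20, 3, 1)
        cfg = TrainConfig(learning_rate=0.0, batch_size=5)
        out = local_update(params, X, y, arch, cfg, np.random.default_rng(0))
        for w0, w1 in zip(params.weights, out.weights):
            assert np.array_equal(w0, w1)

    def test_linear_full_batch_equals_analytic_gradient_step(self):
        arch = _linear_arch()
        params = init_params(arch, 2)
        X, y = _regression_data(25, 3, 3)
        lr = 0.01
        cfg = TrainConfig(learning_rate=lr, batch_size=25, local_epochs=1)
        out = local_update(
            params, X, y, arch, cfg, np.random.default_rng(0)
        )
        # closed form: grad of mean squared error for w, b
        resid = (X @ params.weights[0] + params.biases[0]) - y[:, None]
        gw = 2 * X.T @ resid / len(y)
        gb = 2 * resid.mean(axis=0)
        assert np.allclose(out.weights[0], params.weights[0] - lr * gw,
                           atol=1e-12)
        assert np.allclose(out.biases[0], params.biases[0] - lr * gb,
                           atol=1e-12)

    def test_bitwise_deterministic(self):
        arch = Architecture(layer_sizes=(3, 8, 1))
        X, y = _regression_data(40, 3, 4)
        cfg = TrainConfig(batch_size=8, local_epochs=3)
        runs = []
        for _ in range(2):
            out = local_update(
                init_params(arch, 9), X, y, arch, cfg,
                np.random.default_rng(11),
            )
            runs.append(out.as_vector())
        assert np.array_equal(runs[0], runs[1])


class TestFedavg:
    def test_identical_params_unchanged(self):
        arch = Architecture(layer_sizes=(2, 3, 1))
        p = init_params(arch, 0)
        avg = fedavg([p.copy(), p.copy(), p.copy()], [10, 20, 30])
        assert np.allclose(avg.as_vector(), p.as_vector())

    def test_opposite_params_cancel(self):
        arch = Architecture(layer_sizes=(2, 1))
        p = init_params(arch, 1)
        neg = p.copy()
        neg.weights = [-w for w in neg.weights]
        neg.biases = [-b for b in neg.biases]
        avg = fedavg([p, neg], [5, 5])
        assert np.allclose(avg.as_vector(), 0.0)

    def test_affine_in_inputs(self):
        arch = Architecture(layer_sizes=(2, 2, 1))
        ps = [init_params(arch, s) for s in range(3)]
        counts = [3, 5, 7]
        a, b = 2.5, -1.25
        scaled = []
        for p in ps:
            q = p.copy()
            q.weights = [a * w + b for w in q.weights]
            q.biases = [a * x + b for x in q.biases]
            scaled.append(q)
        lhs = fedavg(scaled, counts).as_vector()
        rhs = a * fedavg(ps, counts).as_vector() + b
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_output_in_convex_hull(self):
        arch = Architecture(layer_sizes=(3, 1))
        ps = [init_params(arch, s) for s in range(4)]
        avg = fedavg(ps, [1, 2, 3, 4]).as_vector()
        stack = np.stack([p.as_vector() for p in ps])
        assert np.all(avg >= stack.min(axis=0) - 1e-12)
        assert np.all(avg <= stack.max(axis=0) + 1e-12)

    def test_shape_mismatch_rejected(self):
        a = init_params(Architecture(layer_sizes=(2, 1)), 0)
        b = init_params(Architecture(layer_sizes=(3, 1)), 0)
        with pytest.raises(ValueError):
            fedavg([a, b], [1, 1])

    def test_one_step_equals_pooled_gradient_step(self):
        """One full-batch local step + count-weighted averaging is exactly
        one centralized gradient step on the pooled data."""
        arch = Architecture(layer_sizes=(4, 6, 1))
        X, y = _regression_data(60, 4, 5)
        params = init_params(arch, 6)
        cfg = TrainConfig(learning_rate=0.05, batch_size=60, local_epochs=1)
        # arbitrary uneven partition
        parts = [(X[:10], y[:10]), (X[10:25], y[10:25]), (X[25:], y[25:])]
        locals_ = [
            local_update(params, Xi, yi, arch,
                         TrainConfig(learning_rate=0.05,
                                     batch_size=len(yi), local_epochs=1),
                         np.random.default_rng(0))
            for Xi, yi in parts
        ]
        avg = fedavg(locals_, [len(yi) for _, yi in parts])
        central = local_update(
            params, X, y, arch, cfg, np.random.default_rng(0)
        )
        assert np.max(np.abs(avg.as_vector() - central.as_vector())) < 1e-10


class TestTrainFederated:
    def test_single_party_matches_centralized_bitwise(self):
        arch = Architecture(layer_sizes=(3, 5, 1))
        X, y = _regression_data(50, 3, 7)
        cfg = TrainConfig(rounds=5, local_epochs=2, batch_size=10, seed=3)
        fed, _ = train_federated([(X, y)], arch, cfg)
        # centralized reference: same loop with one "party"
        params = init_params(arch, cfg.seed)
        rng = np.random.default_rng(np.random.SeedSequence(3).spawn(1)[0])
        for _ in range(cfg.rounds):
            params = local_update(params, X, y, arch, cfg, rng)
        assert np.array_equal(fed.as_vector(), params.as_vector())

    def test_full_batch_rounds_track_centralized_descent(self):
        arch = _linear_arch(3)
        X, y = _regression_data(60, 3, 8)
        parts = [(X[i::3], y[i::3]) for i in range(3)]
        cfg = TrainConfig(rounds=10, local_epochs=1, batch_size=60,
                          learning_rate=0.05, seed=1)
        fed, _ = train_federated(parts, arch, cfg)
        # centralized full-batch descent with the same initialization
        params = init_params(arch, cfg.seed)
        for _ in range(cfg.rounds):
            params = local_update(
                params, X, y, arch, cfg, np.random.default_rng(0)
            )
        assert np.max(np.abs(fed.as_vector() - params.as_vector())) < 1e-9

    def test_loss_history_decreases_on_easy_problem(self):
        arch = Architecture(layer_sizes=(3, 8, 1))
        X, y = _regression_data(100, 3, 9)
        parts = [(X[:50], y[:50]), (X[50:], y[50:])]
        cfg = TrainConfig(rounds=20, local_epochs=1, batch_size=25,
                          learning_rate=0.05, seed=2)
        _, history = train_federated(parts, arch, cfg)
        assert history[-1] < history[0]

    def test_vector_roundtrip(self):
        arch = Architecture(layer_sizes=(4, 3, 1))
        p = init_params(arch, 10)
        q = ModelParams.from_vector(p.as_vector(), arch)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 4))
        assert np.allclose(forward(p, X, arch), forward(q, X, arch))
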