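"""Math-core oracles: activations, conv/pool brute force, losses, gradients."""

import numpy as np
import pytest

from eegemo.nets import (
    Adadelta,
    Adam,
    Conv1DVertical,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    Network,
    activation,
    binary_crossentropy,
    categorical_crossentropy,
    kl_bernoulli,
    mean_activation,
    sparse_cost,
)
from eegemo.nets.gradcheck import finite_difference_grads, relative_gradient_error
from eegemo.nets.losses import EPS
from eegemo.nets.specs import ConvSpec, DNNSpec, SAESpec
from eegemo.train import build_sae, one_hot


class TestActivations:
    def test_relu_values(self):
        np.testing.assert_array_equal(
            activation(np.array([-1.0, 0.0, 2.0]), "relu"), [0.0, 0.0, 2.0]
        )

    def test_softplus_at_zero_is_ln2(self):
        assert activation(np.array(0.0), "softplus") == pytest.approx(np.log(2.0))

    def test_softplus_dominates_relu_and_converges(self):
        x = np.linspace(-5, 20, 101)
        sp = activation(x, "softplus")
        re = activation(x, "relu")
        assert np.all(sp > re)
        assert sp[-1] - re[-1] < 1e-8

    def test_softmax_rows_on_simplex(self, rng):
        p = activation(rng.standard_normal((7, 3)), "softmax")
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert (p > 0).all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            activation(np.zeros(2), "tanh")


def conv_oracle(x, kernels, bias):
    """Brute-force triple-loop vertical 1-D convolution (valid, stride 1)."""
    n, c, h, w = x.shape
    k_out, _, klen = kernels.shape
    out = np.zeros((n, k_out, h - klen + 1, w))
    for s in range(n):
        for k in range(k_out):
            for i in range(h - klen + 1):
                for j in range(w):
                    acc = bias[k]
                    for ch in range(c):
                        for t in range(klen):
                            acc += kernels[k, ch, t] * x[s, ch, i + t, j]
                    out[s, k, i, j] = acc
    return out


def pool_oracle(x, size):
    n, c, h, w = x.shape
    h2, w2 = h // size, w // size
    out = np.empty((n, c, h2, w2))
    for s in range(n):
        for k in range(c):
            for i in range(h2):
                for j in range(w2):
                    out[s, k, i, j] = x[
                        s, k, i * size : (i + 1) * size, j * size : (j + 1) * size
                    ].max()
    return out


class TestConv:
    def test_matches_brute_force_on_random_input(self, rng):
        layer = Conv1DVertical(2, 4, 3, activation="linear", rng=rng, dtype=np.float64)
        x = rng.standard_normal((3, 2, 6, 6))
        np.testing.assert_allclose(
            layer.forward(x),
            conv_oracle(x, layer.kernels, layer.params["b"]),
            atol=1e-10,
        )

    def test_identity_kernel_preserves_interior_rows(self, rng):
        layer = Conv1DVertical(1, 1, 3, activation="relu", rng=rng, dtype=np.float64)
        layer.params["W"][...] = np.array([[0.0, 1.0, 0.0]])
        layer.params["b"][...] = 0.0
        x = rng.random((1, 1, 5, 4))  # nonnegative, relu transparent
        np.testing.assert_allclose(layer.forward(x)[0, 0], x[0, 0, 1:-1, :], atol=1e-12)

    def test_ones_input_ones_kernel(self):
        layer = Conv1DVertical(1, 1, 3, activation="linear", dtype=np.float64)
        layer.params["W"][...] = 1.0
        layer.params["b"][...] = 0.0
        out = layer.forward(np.ones((1, 1, 4, 3)))
        np.testing.assert_allclose(out, np.full((1, 1, 2, 3), 3.0))

    def test_output_height_boundary(self, rng):
        layer = Conv1DVertical(1, 2, 3, rng=rng)
        assert layer.output_shape((1, 3, 5)) == (2, 1, 5)
        with pytest.raises(ValueError):
            layer.output_shape((1, 2, 5))


class TestMaxPool:
    def test_matches_brute_force(self, rng):
        x = rng.standard_normal((2, 3, 7, 8))
        np.testing.assert_array_equal(MaxPool2D(3).forward(x), pool_oracle(x, 3))

    def test_constant_image(self):
        out = MaxPool2D(3).forward(np.full((1, 1, 6, 6), 2.5))
        np.testing.assert_array_equal(out, np.full((1, 1, 2, 2), 2.5))

    def test_32_to_10_truncation(self, rng):
        assert MaxPool2D(3).forward(rng.random((1, 1, 32, 32))).shape == (1, 1, 10, 10)

    def test_single_block_max(self):
        x = np.zeros((1, 1, 3, 3))
        x[0, 0, 1, 1] = 9.0
        assert MaxPool2D(3).forward(x)[0, 0, 0, 0] == 9.0

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            MaxPool2D(3).output_shape((1, 2, 2))


class TestLosses:
    def test_binary_ce_values(self):
        assert binary_crossentropy(np.array(1.0), np.array(1.0 - 1e-9)) < 1e-6
        assert binary_crossentropy(np.array(1.0), np.array(0.5)) == pytest.approx(np.log(2))
        assert binary_crossentropy(np.array(0.0), np.array(0.5)) == pytest.approx(np.log(2))

    def test_categorical_ce_values(self):
        y = np.array([[0.0, 1.0, 0.0]])
        assert categorical_crossentropy(y, y) < 1e-6
        uniform = np.full((1, 3), 1.0 / 3.0)
        assert categorical_crossentropy(y, uniform) == pytest.approx(np.log(3))

    def test_categorical_ce_class_permutation_symmetry(self, rng):
        y = one_hot(rng.integers(0, 3, 20), 3)
        p = activation(rng.standard_normal((20, 3)), "softmax")
        perm = [2, 0, 1]
        assert categorical_crossentropy(y, p) == pytest.approx(
            categorical_crossentropy(y[:, perm], p[:, perm])
        )

    def test_non_simplex_rows_rejected(self):
        with pytest.raises(ValueError):
            categorical_crossentropy(np.eye(3), np.full((3, 3), 0.5))

    def test_mean_activation(self):
        h = np.array([[0.2], [0.4], [0.6]])
        assert mean_activation(h)[0] == pytest.approx(0.4)
        assert mean_activation(np.array([[0.7, 0.1]]))[1] == pytest.approx(0.1)
        with pytest.raises(ValueError):
            mean_activation(np.empty((0, 3)))

    def test_kl_values(self):
        assert kl_bernoulli(0.3, np.array(0.3)) == pytest.approx(0.0)
        expected = 0.05 * np.log(0.05 / 0.5) + 0.95 * np.log(0.95 / 0.5)
        assert kl_bernoulli(0.05, np.array(0.5)) == pytest.approx(expected)
        assert expected == pytest.approx(0.4946, abs=2e-4)

    def test_kl_increasing_away_from_rho(self):
        grid_up = kl_bernoulli(0.3, np.linspace(0.35, 0.9, 10))
        grid_down = kl_bernoulli(0.3, np.linspace(0.25, 0.05, 10))
        assert np.all(np.diff(grid_up) > 0)
        assert np.all(np.diff(grid_down) > 0)

    def test_kl_domain_errors(self):
        with pytest.raises(ValueError):
            kl_bernoulli(0.0, np.array(0.5))
        with pytest.raises(ValueError):
            kl_bernoulli(0.3, np.array(1.0))

    def test_sparse_cost_arithmetic(self):
        rho_hat = np.array([0.5, 0.2])
        kl = kl_bernoulli(0.05, rho_hat)
        assert sparse_cost(1.0, rho_hat, 0.05, 3.0) == pytest.approx(1.0 + 3.0 * kl.sum())
        assert sparse_cost(1.0, rho_hat, 0.05, 0.0) == 1.0
        assert sparse_cost(0.7, np.full(4, 0.05), 0.05, 10.0) == pytest.approx(0.7)
        # the worked example: J=1, KL terms 0.1 and 0.2, beta=3 -> 1.9
        rho = 0.05
        # construct rho_hat values giving the stated KLs by inversion
        from scipy.optimize import brentq

        rh = [brentq(lambda r: kl_bernoulli(rho, np.array(r)) - t, rho, 0.999) for t in (0.1, 0.2)]
        assert sparse_cost(1.0, np.array(rh), rho, 3.0) == pytest.approx(1.9, abs=1e-6)


class TestGradients:
    """Analytic gradients vs central finite differences (< 1e-4 rel error)."""

    def test_conv_pool_dense_binary_ce(self, rng):
        net = Network(
            [
                Conv1DVertical(2, 3, 3, "softplus", rng, np.float64),
                MaxPool2D(2),
                Flatten(),
                Dense(3 * 2 * 2, 2, "sigmoid", rng, np.float64),
            ],
            loss="binary_ce",
        )
        x = rng.standard_normal((5, 2, 6, 5))
        y = one_hot(rng.integers(0, 2, 5), 2)
        out = net.forward(x)
        _, delta = net.loss_and_delta(y, out)
        net.backward(delta)
        analytic = net.get_flat_grads()
        numeric = finite_difference_grads(net, lambda: net.loss_and_delta(y, net.forward(x))[0])
        assert relative_gradient_error(analytic, numeric) < 1e-4

    def test_conv_dense_categorical_ce(self, rng):
        net = Network(
            [
                Conv1DVertical(1, 2, 2, "softplus", rng, np.float64),
                Flatten(),
                Dense(2 * 4 * 3, 3, "softmax", rng, np.float64),
            ],
            loss="categorical_ce",
        )
        x = rng.standard_normal((4, 1, 5, 3))
        y = one_hot(rng.integers(0, 3, 4), 3)
        out = net.forward(x)
        _, delta = net.loss_and_delta(y, out)
        net.backward(delta)
        analytic = net.get_flat_grads()
        numeric = finite_difference_grads(net, lambda: net.loss_and_delta(y, net.forward(x))[0])
        assert relative_gradient_error(analytic, numeric) < 1e-4

    def test_sparse_autoencoder_cost(self, rng):
        """Reconstruction + KL sparsity through the hidden layer; softplus
        keeps activations off the rectifier kink and inside the KL domain."""
        spec = SAESpec(
            encode_units=7, hidden_units=4, decode_units=6, rho=0.05, beta=3.0,
            activation="softplus",
        )
        sae = build_sae(5, spec, rng, np.float64)
        x = rng.random((8, 5))
        rho, beta = spec.rho, spec.beta

        def loss():
            out = sae.forward(x)
            J, _ = sae.loss_and_delta(x, out)
            return sparse_cost(J, mean_activation(sae.layer_output(1)), rho, beta)

        out = sae.forward(x)
        _, delta = sae.loss_and_delta(x, out)
        hidden = sae.layer_output(1)
        raw = hidden.mean(axis=0)
        inside = (raw > EPS) & (raw < 1 - EPS)  # clipped units: penalty flat
        rho_hat = np.clip(raw, EPS, 1 - EPS)
        d_hidden = np.broadcast_to(
            np.where(inside, beta * (-rho / rho_hat + (1 - rho) / (1 - rho_hat)), 0.0)
            / hidden.shape[0],
            hidden.shape,
        )
        sae.backward(delta, extra={1: d_hidden})
        analytic = sae.get_flat_grads()
        numeric = finite_difference_grads(sae, loss)
        assert relative_gradient_error(analytic, numeric) < 1e-4


class TestPlumbing:
    def test_dropout_eval_identity_and_train_scaling(self, rng):
        d = Dropout(0.5)
        x = np.ones((200, 50))
        np.testing.assert_array_equal(d.forward(x, train=False), x)
        out = d.forward(x, train=True, rng=rng)
        kept = out[out > 0]
        np.testing.assert_allclose(kept, 2.0)  # inverted scaling
        assert abs((out > 0).mean() - 0.5) < 0.05

    def test_optimizers_descend_on_quadratic(self):
        """Both optimizers reduce a simple quadratic via a 1-param dense layer."""
        # Adadelta's effective step ramps up slowly by design, so it gets
        # a longer budget than Adam on the same 1-D quadratic
        for opt, iters in ((Adadelta(lr=1.0), 2000), (Adam(lr=0.05), 200)):
            layer = Dense(1, 1, "linear", dtype=np.float64)
            layer.params["W"][...] = 3.0
            layer.params["b"][...] = 0.0
            net = Network([layer])
            x = np.ones((1, 1))
            for _ in range(iters):
                out = net.forward(x)
                layer.backward_z(2 * out)  # d/dz of z^2
                opt.step(net)
            assert abs(net.forward(x)[0, 0]) < 0.05

    def test_flat_param_round_trip(self, rng):
        net = Network([Dense(3, 4, "relu", rng, np.float64), Dense(4, 2, "sigmoid", rng, np.float64)])
        flat = net.get_flat_params()
        net.set_flat_params(flat * 2.0)
        np.testing.assert_allclose(net.get_flat_params(), flat * 2.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SAESpec(rho=1.5)
        with pytest.raises(ValueError):
            SAESpec(beta=-1.0)
        with pytest.raises(ValueError):
            DNNSpec(layer_units=(512, 256, 5))
        with pytest.raises(ValueError):
            ConvSpec(dropout=1.0)
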