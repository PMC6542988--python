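"""Error signals, gradients and updates under BP, DFA and sparse DFA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdfa import (
    ActivationKind,
    LayerSpec,
    ShapeError,
    UpdateConfig,
    ValidationError,
    bp_errors,
    cross_entropy_loss,
    dfa_errors,
    dfa_layer_error,
    forward,
    init_weights,
    output_error,
    sdfa_neuron_error,
    sgd_step,
    softmax,
    weight_gradients,
)
from sdfa.network import NetworkParams

from conftest import random_net


def numeric_weight_gradients(params, x, target, eps=1e-6):
    """Central-difference oracle for the full softmax-CE parameter gradient."""
    grads = []
    for w in params.weights:
        g = np.zeros_like(w)
        for i in range(w.shape[0]):
            for j in range(w.shape[1]):
                orig = w[i, j]
                w[i, j] = orig + eps
                up = cross_entropy_loss(forward(params, x).output, target)
                w[i, j] = orig - eps
                down = cross_entropy_loss(forward(params, x).output, target)
                w[i, j] = orig
                g[i, j] = (up - down) / (2 * eps)
        grads.append(g)
    return grads


def one_hot(j, n):
    t = np.zeros(n)
    t[j] = 1.0
    return t


class TestOutputError:
    def test_zero_error_at_perfect_prediction(self):
        # logits so extreme the softmax is numerically the target
        a_n = np.array([50.0, -50.0, -50.0])
        e = output_error(a_n, one_hot(0, 3))
        assert np.allclose(e, 0.0, atol=1e-20)

    def test_uniform_softmax_against_class_3(self):
        e = output_error(np.zeros(10), one_hot(3, 10))
        expected = np.full(10, 0.1)
        expected[3] -= 1.0
        assert np.allclose(e, expected)
        assert abs(e.sum()) < 1e-12

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 9), st.integers(0, 2**31 - 1))
    def test_components_sum_to_zero(self, cls, seed):
        a_n = np.random.default_rng(seed).standard_normal(10)
        assert abs(output_error(a_n, one_hot(cls, 10)).sum()) < 1e-12

    def test_rejects_non_one_hot(self):
        with pytest.raises(ValidationError):
            output_error(np.zeros(3), np.array([0.5, 0.5, 0.0]))


class TestBpErrors:
    def test_linear_single_hidden_layer_is_transposed_product(self, rng):
        specs = (LayerSpec(3, 4, "linear"), LayerSpec(4, 2, "linear"))
        params = init_weights(specs, seed=2)
        trace = forward(params, rng.standard_normal(3))
        e = rng.standard_normal(2)
        errs = bp_errors(params, trace, e)
        assert np.allclose(errs.deltas[0], params.weights[1].T @ e, atol=1e-12)
        assert np.array_equal(errs.deltas[-1], e)

    def test_zero_output_error_gives_zero_deltas(self, small_tanh_net, rng):
        params, _ = small_tanh_net
        trace = forward(params, rng.standard_normal(3))
        errs = bp_errors(params, trace, np.zeros(2))
        assert all(np.all(d == 0) for d in errs.deltas)

    def test_hidden_delta_matches_finite_difference_on_y1(self):
        """δa_1 is the loss gradient w.r.t. the first pre-activation y_1."""
        specs = (LayerSpec(2, 3, "tanh"), LayerSpec(3, 2, "linear"))
        params = init_weights(specs, seed=9)
        x = np.array([0.4, -1.1])
        target = one_hot(1, 2)
        trace = forward(params, x)
        e = output_error(trace.output, target)
        delta1 = bp_errors(params, trace, e).deltas[0]

        def loss_from_y1(y1):
            a1 = np.tanh(y1)
            return cross_entropy_loss(params.weights[1] @ a1, target)

        y1 = trace.preactivations[0]
        eps = 1e-6
        for i in range(3):
            d = np.zeros(3)
            d[i] = eps
            fd = (loss_from_y1(y1 + d) - loss_from_y1(y1 - d)) / (2 * eps)
            assert delta1[i] == pytest.approx(fd, abs=1e-6)


class TestDfaErrors:
    def test_one_hidden_layer_with_transposed_weights_equals_bp(self, rng):
        specs = (LayerSpec(4, 5, "tanh"), LayerSpec(5, 3, "linear"))
        params = init_weights(specs, seed=21)
        trace = forward(params, rng.standard_normal(4))
        e = rng.standard_normal(3)
        via_bp = bp_errors(params, trace, e)
        via_dfa = dfa_errors([params.weights[1].T], trace, e, specs=list(specs))
        for a, b in zip(via_bp.deltas, via_dfa.deltas):
            assert np.allclose(a, b, atol=1e-12)

    def test_zero_feedback_annihilates_hidden_error_only(self, rng):
        specs = (LayerSpec(3, 4, "tanh"), LayerSpec(4, 2, "linear"))
        params = init_weights(specs, seed=3)
        trace = forward(params, rng.standard_normal(3))
        e = rng.standard_normal(2)
        errs = dfa_errors([np.zeros((4, 2))], trace, e, specs=list(specs))
        assert np.all(errs.deltas[0] == 0)
        assert np.array_equal(errs.deltas[1], e)

    def test_missing_feedback_raises(self, rng):
        specs = (LayerSpec(3, 4, "tanh"), LayerSpec(4, 2, "linear"))
        params = init_weights(specs, seed=3)
        trace = forward(params, rng.standard_normal(3))
        with pytest.raises(ValidationError):
            dfa_errors([None], trace, np.zeros(2), specs=list(specs))

    def test_locality_no_forward_weight_or_other_layer_read(self, rng):
        """Computing DFA errors must not read any forward weight, and each
        layer's δ must be computable from purely local inputs (B_l, e, a_l).

        Access-tracking double: after the forward pass every forward weight is
        replaced by an array that raises on any use. BP trips the tripwire,
        DFA does not."""

        class Poison(np.ndarray):
            def __array_ufunc__(self, *args, **kwargs):
                raise AssertionError("non-local array was read")

        specs = (LayerSpec(3, 4, "tanh"), LayerSpec(4, 5, "tanh"),
                 LayerSpec(5, 2, "linear"))
        params = init_weights(specs, seed=17)
        trace = forward(params, rng.standard_normal(3))
        e = rng.standard_normal(2)
        feedbacks = [rng.standard_normal((4, 2)), rng.standard_normal((5, 2))]
        expected = dfa_errors(feedbacks, trace, e, specs=list(specs))

        poisoned = NetworkParams(
            [w.copy().view(Poison) for w in params.weights], list(specs)
        )
        # the tripwire works: BP needs the downstream weights
        with pytest.raises(AssertionError, match="non-local"):
            bp_errors(poisoned, trace, e)
        # DFA never touches them (structurally cannot: no params argument)
        got = dfa_errors(feedbacks, trace, e, specs=list(specs))
        for a, b in zip(expected.deltas, got.deltas):
            assert np.array_equal(a, b)
        # and each layer's delta is reproducible from local quantities alone
        for l, B in enumerate(feedbacks):
            local = dfa_layer_error(B, e, trace.activations[l], specs[l].activation)
            assert np.allclose(local, expected.deltas[l], atol=1e-15)


class TestSdfaNeuronError:
    def test_three_scalar_product(self):
        b_row = np.array([0.0, 0.5, 0.0])
        e = np.array([9.9, -0.2, 9.9])
        assert sdfa_neuron_error(b_row, e, 0.7, ActivationKind.LINEAR) == pytest.approx(-0.1)

    def test_dense_row_matches_dfa_component(self, rng):
        specs = (LayerSpec(3, 4, "tanh"), LayerSpec(4, 2, "linear"))
        params = init_weights(specs, seed=5)
        trace = forward(params, rng.standard_normal(3))
        e = rng.standard_normal(2)
        B = rng.standard_normal((4, 2))
        errs = dfa_errors([B], trace, e, specs=list(specs))
        for i in range(4):
            got = sdfa_neuron_error(B[i], e, trace.activations[0][i], ActivationKind.TANH)
            assert got == pytest.approx(errs.deltas[0][i], abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 10))
    def test_sparse_equals_densified_with_mac_count(self, seed, nnz):
        """Sparse path touches only nonzeros; counter charges nnz + 1 ops."""
        rng = np.random.default_rng(seed)
        row = np.zeros(10)
        idx = rng.choice(10, size=nnz, replace=False)
        row[idx] = rng.standard_normal(nnz)
        e = rng.standard_normal(10)
        a = float(np.tanh(rng.standard_normal()))
        counter = [0]
        got = sdfa_neuron_error(row, e, a, ActivationKind.TANH, mac_counter=counter)
        dense = float(row @ e) * (1 - a**2)
        assert got == pytest.approx(dense, abs=1e-12)
        assert counter[0] == np.count_nonzero(row) + 1


class TestWeightGradients:
    def test_zero_deltas_give_zero_gradients(self, small_tanh_net, rng):
        params, _ = small_tanh_net
        trace = forward(params, rng.standard_normal(3))
        errs = bp_errors(params, trace, np.zeros(2))
        assert all(np.all(g == 0) for g in weight_gradients(trace, errs))

    def test_hand_computed_outer_product(self):
        specs = (LayerSpec(2, 2, "linear"), LayerSpec(2, 2, "linear"))
        params = NetworkParams([np.eye(2), np.eye(2)], list(specs))
        trace = forward(params, np.array([2.0, -1.0]))
        e = np.array([0.5, 1.0])
        grads = weight_gradients(trace, bp_errors(params, trace, e))
        # δW_2 = e ⊗ a_1, a_1 = x through identity weights
        assert np.allclose(grads[1], np.outer(e, [2.0, -1.0]))

    def test_bp_full_gradient_matches_finite_differences(self, rng):
        for _ in range(5):
            params, specs = random_net(rng)
            x = rng.standard_normal(specs[0].fan_in)
            target = one_hot(int(rng.integers(specs[-1].fan_out)), specs[-1].fan_out)
            trace = forward(params, x)
            e = output_error(trace.output, target)
            analytic = weight_gradients(trace, bp_errors(params, trace, e))
            numeric = numeric_weight_gradients(params, x, target)
            for a, n in zip(analytic, numeric):
                assert np.abs(a - n).max() < 1e-6

    def test_batch_gradients_average_per_example(self, rng):
        specs = (LayerSpec(3, 4, "tanh"), LayerSpec(4, 2, "linear"))
        params = init_weights(specs, seed=13)
        X = rng.standard_normal((3, 5))
        T = np.zeros((2, 5))
        T[rng.integers(2, size=5), np.arange(5)] = 1.0
        trace = forward(params, X)
        e = output_error(trace.output, T)
        batched = weight_gradients(trace, bp_errors(params, trace, e))
        singles = []
        for k in range(5):
            tr = forward(params, X[:, k])
            ek = output_error(tr.output, T[:, k])
            singles.append(weight_gradients(tr, bp_errors(params, tr, ek)))
        for l in range(2):
            mean = sum(s[l] for s in singles) / 5
            assert np.allclose(batched[l], mean, atol=1e-12)


class TestSgdStep:
    def test_zero_gradients_leave_params_unchanged(self, small_tanh_net):
        params, _ = small_tanh_net
        before = [w.copy() for w in params.weights]
        sgd_step(params, [np.zeros_like(w) for w in params.weights],
                 UpdateConfig(0.1), epoch=0)
        for b, w in zip(before, params.weights):
            assert np.array_equal(b, w)

    def test_identity_gradient_shifts_diagonal(self):
        params = NetworkParams([np.ones((2, 2))], [LayerSpec(2, 2, "linear")])
        sgd_step(params, [np.eye(2)], UpdateConfig(0.1, decay=1.0), epoch=0)
        assert np.allclose(params.weights[0], [[0.9, 1.0], [1.0, 0.9]])

    def test_geometric_decay(self):
        cfg = UpdateConfig(learning_rate=1.0, decay=0.5)
        assert cfg.rate_at(2) == pytest.approx(0.25)

    def test_nonfinite_gradient_raises_with_layer(self, small_tanh_net):
        params, _ = small_tanh_net
        grads = [np.zeros_like(w) for w in params.weights]
        grads[1][0, 0] = np.inf
        with pytest.raises(FloatingPointError, match="layer 2"):
            sgd_step(params, grads, UpdateConfig(0.1), epoch=0)

    def test_invalid_update_config(self):
        with pytest.raises(ValidationError):
            UpdateConfig(learning_rate=-1.0)
        with pytest.raises(ValidationError):
            UpdateConfig(learning_rate=0.1, decay=0.0)
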