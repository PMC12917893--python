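"""The context-attentive LSTM regressor: gradients, contracts, capacity."""

import numpy as np
import pytest

from afbnp._nn import AdamState, ContextLSTMNet, attention_forward
from afbnp.errors import (
    ConfigurationError,
    ContractViolationError,
    InsufficientDataError,
)
from afbnp.features import PatientTensor
from afbnp.model import ContextLSTMRegressor, context_attention, pad_batch


def tiny_net(attention="additive", seed=3):
    return ContextLSTMNet(
        input_dim=3,
        context_dim=2,
        lstm_units=(4, 3),
        attention_dim=3,
        head_hidden=4,
        attention=attention,
        seed=seed,
    )


def random_problem(rng, B=3, T=6, F=3, Cd=2):
    X = rng.standard_normal((B, T, F))
    C = rng.standard_normal((B, Cd))
    mask = np.ones((B, T), dtype=bool)
    mask[0, -2:] = False  # one padded sequence
    y = rng.standard_normal(B)
    return X, C, mask, y


def make_tensor(rng, T, F=3, pid="p", population=("a", "b")):
    mask = np.ones(T, dtype=bool)
    return PatientTensor(
        patient_id=pid,
        sequence_block=rng.standard_normal((T, F)),
        validity_mask=mask,
        context_vector=rng.standard_normal(2),
        sequence_names=tuple(f"s{i}" for i in range(F)),
        static_names=(),
        baseline_ntprobnp=1000.0,
        scaler_population=population,
    )


class TestGradients:
    @pytest.mark.parametrize("attention", ["additive", "bilinear"])
    def test_analytic_matches_numerical(self, attention, rng):
        """Hand-derived BPTT agrees with central finite differences."""
        net = tiny_net(attention)
        X, C, mask, y = random_problem(rng)

        def loss():
            yhat, _, _ = net.forward(X, C, mask)
            return float(np.mean((yhat - y) ** 2))

        yhat, _, cache = net.forward(X, C, mask)
        grads = net.backward(cache, 2.0 * (yhat - y) / y.size)
        eps = 1e-6
        for k, p in net.params.items():
            g = grads[k].reshape(p.shape)
            flat = p.ravel()
            idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert g.ravel()[i] == pytest.approx(num, rel=1e-4, abs=1e-7), k

    def test_single_step_changes_params_by_order_lr(self, rng):
        # gradient-flow sanity: with L2 and dropout off, one Adam step
        # moves each updated parameter by O(lr)
        net = tiny_net()
        X, C, mask, y = random_problem(rng)
        before = net.copy_params()
        yhat, _, cache = net.forward(X, C, mask)
        grads = net.backward(cache, 2.0 * (yhat - y) / y.size)
        lr = 1e-4
        AdamState(net, lr=lr, l2=0.0).step(net, grads)
        deltas = [np.abs(net.params[k] - before[k]).max() for k in before]
        assert max(deltas) <= lr * 1.01  # Adam's first step is +-lr per coord
        assert max(deltas) > 0.0


class TestAttentionContract:
    def test_simplex_and_masked_zeros(self, rng):
        net = tiny_net()
        for _ in range(20):
            B, T = int(rng.integers(1, 5)), int(rng.integers(2, 9))
            h = rng.standard_normal((B, T, 3))
            C = rng.standard_normal((B, 2))
            mask = rng.random((B, T)) < 0.7
            mask[:, 0] = True
            a, _ = attention_forward(
                {"Wh": rng.standard_normal((3, 3)),
                 "Wc": rng.standard_normal((2, 3)),
                 "ba": np.zeros(3),
                 "v": rng.standard_normal(3)},
                h, C, mask,
            )
            assert np.all(a >= 0)
            assert np.allclose(a.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(a[~mask] == 0.0)

    def test_singleton_window(self, rng):
        net = tiny_net()
        h = rng.standard_normal((1, 3))
        out = context_attention(net, h, np.zeros(2), np.array([True]))
        assert out.weights.tolist() == [1.0]
        assert np.allclose(out.pooled_state, h[0])

    def test_identical_states_zero_context_uniform(self):
        net = tiny_net()
        net.params["Wc"][:] = 0.0
        h = np.tile(np.array([0.3, -0.2, 0.1]), (5, 1))
        out = context_attention(net, h, np.ones(2), np.ones(5, dtype=bool))
        assert np.allclose(out.weights, 0.2)

    def test_masked_step_exactly_zero(self, rng):
        net = tiny_net()
        h = rng.standard_normal((3, 3))
        mask = np.array([True, False, True])
        out = context_attention(net, h, np.zeros(2), mask)
        assert out.weights[1] == 0.0
        assert out.weights[0] + out.weights[2] == pytest.approx(1.0)

    def test_all_masked_raises(self, rng):
        net = tiny_net()
        with pytest.raises(InsufficientDataError):
            context_attention(
                net, rng.standard_normal((3, 3)), np.zeros(2),
                np.zeros(3, dtype=bool),
            )


class TestEstimatorContracts:
    def test_build_determinism(self):
        a = tiny_net(seed=7)
        b = tiny_net(seed=7)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_parameter_count_closed_form(self):
        # ECG-only input: 9 sequence features, context dim 2, head 8
        net = ContextLSTMNet(
            input_dim=9, context_dim=2, lstm_units=(64, 32, 16),
            attention_dim=16, head_hidden=8,
        )
        def lstm(d, h):
            return d * 4 * h + h * 4 * h + 4 * h
        expected = (
            lstm(9, 64) + lstm(64, 32) + lstm(32, 16)
            + 16 * 16 + 2 * 16 + 16 + 16          # additive attention
            + (16 + 2) * 8 + 8 + 8 * 1 + 1        # two-layer head
        )
        assert net.n_params == expected

    def test_units_echoed(self):
        est = ContextLSTMRegressor()
        assert tuple(est.get_params()["lstm_units"]) == (64, 32, 16)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ContextLSTMNet(input_dim=3, context_dim=2, attention="fancy")
        with pytest.raises(ConfigurationError):
            ContextLSTMNet(input_dim=0, context_dim=2)

    def test_prediction_deterministic_and_padding_invariant(self, rng):
        est = _quick_fit(rng)
        t = make_tensor(rng, T=7, pid="q")
        p1 = est.predict([t])[0]
        p2 = est.predict([t])[0]
        assert p1 == p2
        # appending masked padding rows must not change the prediction
        padded = PatientTensor(
            patient_id="q",
            sequence_block=np.vstack([t.sequence_block, np.zeros((5, 3))]),
            validity_mask=np.concatenate([t.validity_mask, np.zeros(5, bool)]),
            context_vector=t.context_vector,
            sequence_names=t.sequence_names,
            static_names=t.static_names,
            baseline_ntprobnp=t.baseline_ntprobnp,
            scaler_population=t.scaler_population,
        )
        assert est.predict([padded])[0] == pytest.approx(p1, rel=1e-12)

    def test_fold_mismatch_rejected(self, rng):
        est = _quick_fit(rng)
        alien = make_tensor(rng, T=5, pid="z", population=("other",))
        with pytest.raises(ContractViolationError):
            est.predict([alien])

    def test_same_seed_same_fit(self, rng):
        tensors = [make_tensor(rng, T=int(rng.integers(4, 9)), pid=f"p{i}")
                   for i in range(6)]
        y = rng.normal(0, 100, size=6)
        kw = dict(lstm_units=(6, 4), attention_dim=4, head_hidden=4,
                  max_epochs=5, batch_size=3, random_state=9)
        a = ContextLSTMRegressor(**kw).fit(tensors, y)
        b = ContextLSTMRegressor(**kw).fit(tensors, y)
        assert a.history_ == b.history_
        assert np.array_equal(a.predict(tensors), b.predict(tensors))


def _quick_fit(rng, **overrides):
    tensors = [make_tensor(rng, T=int(rng.integers(4, 9)), pid=f"p{i}")
               for i in range(6)]
    y = rng.normal(0, 100, size=6)
    kw = dict(lstm_units=(6, 4), attention_dim=4, head_hidden=4,
              max_epochs=8, batch_size=3, random_state=1)
    kw.update(overrides)
    return ContextLSTMRegressor(**kw).fit(tensors, y)


class TestTraining:
    def test_early_stopping_contract(self, rng):
        est = _quick_fit(rng, max_epochs=200, patience=5, dropout=0.4)
        hist = np.asarray(est.history_)
        # stop happens <= patience epochs after the last improvement
        assert est.n_epochs_trained_ - 1 - est.best_epoch_ <= 5
        # running minimum is non-increasing by construction
        assert np.all(np.diff(np.minimum.accumulate(hist)) <= 0)

    def test_overfits_single_patient_pair(self, rng):
        # capacity sanity: tiny training set driven to near-zero loss
        tensors = [make_tensor(rng, T=6, pid="a"), make_tensor(rng, T=6, pid="b")]
        y = np.array([500.0, -300.0])
        est = ContextLSTMRegressor(
            lstm_units=(8, 6), attention_dim=4, head_hidden=6,
            dropout=0.0, l2=0.0, lr=0.01, max_epochs=300, patience=50,
            target_transform="scaled_delta", random_state=2, batch_size=2,
        ).fit(tensors, y)
        pred = est.predict(tensors)
        assert np.allclose(pred, y, atol=0.05 * np.abs(y))

    def test_linear_teacher_recovery(self, rng):
        # noiseless linear teacher on mean sequence features: training MSE
        # drops below 10% of its initial value and held-out error is small
        n, T, F = 80, 8, 3
        tensors = [make_tensor(rng, T=T, pid=f"p{i}") for i in range(n)]
        w = np.array([1.0, -2.0, 0.5])
        y = np.array([t.sequence_block.mean(axis=0) @ w for t in tensors])
        est = ContextLSTMRegressor(
            lstm_units=(16, 8), attention_dim=8, head_hidden=8,
            dropout=0.0, l2=0.0, lr=5e-3, max_epochs=400, patience=60,
            target_transform="scaled_delta", random_state=4,
        ).fit(tensors[:64], y[:64])
        assert est.history_[-1] < 0.1 * est.history_[0]
        held_pred = est.predict(tensors[64:])
        resid = held_pred - y[64:]
        assert np.sqrt(np.mean(resid**2)) < 0.5 * np.std(y)

    def test_target_transform_validation(self, rng):
        tensors = [make_tensor(rng, T=4, pid=f"p{i}") for i in range(3)]
        est = ContextLSTMRegressor(target_transform="bogus")
        with pytest.raises(ConfigurationError):
            est.fit(tensors, np.zeros(3))

    def test_too_few_patients_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            ContextLSTMRegressor().fit([make_tensor(rng, 4)], [0.0])


class TestPadBatch:
    def test_padding_shapes_and_masks(self, rng):
        tensors = [make_tensor(rng, T=t, pid=f"p{t}") for t in (3, 7, 5)]
        X, C, mask = pad_batch(tensors)
        assert X.shape == (3, 7, 3) and mask.shape == (3, 7)
        assert mask[0, 3:].sum() == 0 and mask[1].all()

    def test_empty_batch_rejected(self):
        with pytest.raises(InsufficientDataError):
            pad_batch([])
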