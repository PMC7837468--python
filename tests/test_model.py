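"""Network construction, the weighted joint loss, backprop and training."""

from dataclasses import replace

import numpy as np
import pytest

from merdbs.cohort import ConfigurationError
from merdbs.model import (
    LeakageError,
    ModelConfig,
    MultitaskOutcomeModel,
    build_model,
    multitask_loss,
    multitask_loss_grads,
)
from merdbs import nn


def tiny_config(**overrides):
    defaults = dict(
        input_size=(16, 16),
        conv_blocks=((4,),),
        input_pool=0,
        epochs=5,
        batch_size=8,
        seed=3,
        learning_rate=0.05,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


def synthetic_imageset(n_per_patient=6, n_patients=8, size=(16, 16), noise=0.1, seed=0):
    """Linearly separable images: good patients bright on top, moderate below."""
    rng = np.random.default_rng(seed)
    images, y, pids = [], [], []
    for p in range(n_patients):
        label = p % 2
        for _ in range(n_per_patient):
            img = noise * rng.random(size)
            if label:
                img[: size[0] // 2] += 0.8
            else:
                img[size[0] // 2 :] += 0.8
            images.append(np.clip(img, 0, 1))
            y.append(label)
            pids.append(f"p{p:02d}")
    is_test = np.array([pid in ("p00", "p01") for pid in pids])
    return np.stack(images), np.array(y), np.array(pids), is_test


class TestBuildModel:
    def test_multitask_shapes(self):
        net = build_model(tiny_config())
        x = np.random.default_rng(0).random((8, 1, 16, 16)).astype(np.float32)
        outputs = net.forward(x)
        assert len(outputs) == 2
        assert all(o.shape == (8, 2) for o in outputs)

    def test_single_task_mode_has_one_head(self):
        net = build_model(tiny_config(mode="single_task"))
        x = np.random.default_rng(0).random((8, 1, 16, 16)).astype(np.float32)
        outputs = net.forward(x)
        assert len(outputs) == 1 and outputs[0].shape == (8, 2)

    def test_parameter_count_closed_form(self):
        """Trainable parameters match hand arithmetic for the tiny spec."""
        net = build_model(tiny_config())
        conv = 4 * (1 * 3 * 3) + 4  # 4 output channels, 3x3 kernel on 1 channel
        flat = 8 * 8 * 4  # 16x16 halved once by pooling
        head = (flat * 120 + 120) + (120 * 120 + 120) + (120 * 16 + 16) + (16 * 2 + 2)
        assert net.n_params == conv + 2 * head

    def test_input_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model(tiny_config(input_size=(2, 2), conv_blocks=((4,), (4,))))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(loss_weights=(0.0, 0.0))
        with pytest.raises(ConfigurationError):
            tiny_config(loss_weights=(-1.0, 1.0))
        with pytest.raises(ConfigurationError):
            tiny_config(head_widths=(120, 3))

    def test_weight_roundtrip(self, tmp_path):
        net = build_model(tiny_config())
        path = tmp_path / "weights.npz"
        net.save(path)
        other = build_model(tiny_config(seed=99))
        other.load(path)
        for a, b in zip(net.get_weights(), other.get_weights()):
            assert np.array_equal(a, b)


def _logits_with_true_prob(p, labels):
    """Two-class logits giving probability p to the labelled class."""
    d = np.log(p / (1 - p))
    out = np.zeros((len(labels), 2))
    for i, lab in enumerate(labels):
        out[i, lab] = d
    return out


class TestMultitaskLoss:
    def test_degenerates_to_single_task_ce(self, rng):
        logits_c = rng.standard_normal((6, 2))
        logits_i = rng.standard_normal((6, 2))
        y_c = rng.integers(0, 2, 6)
        y_i = rng.integers(0, 2, 6)
        ce, _ = nn.softmax_cross_entropy(logits_c.copy(), y_c)
        assert multitask_loss(logits_c, logits_i, y_c, y_i, 1.0, 0.0) == ce

    def test_hand_value_weights_five_one(self):
        """Both heads at p(true) = e^-1 give CE = 1 each; weights (5,1) -> 6."""
        y = np.array([0, 1, 0, 1])
        logits = _logits_with_true_prob(np.exp(-1.0), y)
        loss = multitask_loss(logits, logits, y, y, 5.0, 1.0)
        assert loss == pytest.approx(6.0, rel=1e-9)

    def test_perfect_predictions_vanishing_loss(self):
        y = np.array([0, 1])
        logits = _logits_with_true_prob(1 - 1e-12, y)
        assert multitask_loss(logits, logits, y, y, 5.0, 1.0) < 1e-9

    def test_scaling_both_weights_scales_loss(self, rng):
        logits_c = rng.standard_normal((5, 2))
        logits_i = rng.standard_normal((5, 2))
        y = rng.integers(0, 2, 5)
        base = multitask_loss(logits_c, logits_i, y, y, 5.0, 1.0)
        scaled = multitask_loss(logits_c, logits_i, y, y, 5.0 * 3.0, 1.0 * 3.0)
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_negative_weights_rejected(self, rng):
        logits = rng.standard_normal((4, 2))
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            multitask_loss(logits, logits, y, y, -1.0, 1.0)
        with pytest.raises(ValueError):
            multitask_loss(logits, logits, y, y, 0.0, 0.0)

    def test_gradients_match_finite_differences(self, rng):
        """Analytic loss gradients vs central differences on a toy batch."""
        logits_c = rng.standard_normal((4, 2))
        logits_i = rng.standard_normal((4, 2))
        y_c = np.array([0, 1, 1, 0])
        y_i = np.array([1, 1, 0, 0])
        w_c, w_i = 5.0, 1.0
        _, grad_c, grad_i = multitask_loss_grads(logits_c, logits_i, y_c, y_i, w_c, w_i)
        h = 1e-6
        for which, logits, grad in (("c", logits_c, grad_c), ("i", logits_i, grad_i)):
            for idx in np.ndindex(logits.shape):
                plus, minus = logits.copy(), logits.copy()
                plus[idx] += h
                minus[idx] -= h
                if which == "c":
                    f_p = multitask_loss(plus, logits_i, y_c, y_i, w_c, w_i)
                    f_m = multitask_loss(minus, logits_i, y_c, y_i, w_c, w_i)
                else:
                    f_p = multitask_loss(logits_c, plus, y_c, y_i, w_c, w_i)
                    f_m = multitask_loss(logits_c, minus, y_c, y_i, w_c, w_i)
                numeric = (f_p - f_m) / (2 * h)
                denom = max(abs(numeric), 1e-8)
                assert abs(numeric - grad[idx]) / denom < 1e-4


class TestBackprop:
    def test_network_gradients_match_finite_differences(self, rng):
        """End-to-end gradient check through conv, pool, dense and both heads."""
        cfg = tiny_config(
            input_size=(8, 8), conv_blocks=((2,),), head_widths=(4, 2), dropout_rate=0.0
        )
        net = build_model(cfg)
        x = rng.random((4, 1, 8, 8)).astype(np.float32)
        y_c = np.array([0, 1, 0, 1])
        y_i = np.array([1, 0, 0, 1])

        def loss_value():
            out = net.forward(x, train=False)
            return multitask_loss(out[0], out[1], y_c, y_i, 2.0, 1.0)

        out = net.forward(x, train=True)
        _, g_c, g_i = multitask_loss_grads(out[0], out[1], y_c, y_i, 2.0, 1.0)
        net.backward([g_c, g_i])
        h = 1e-3
        checked = 0
        for layer in net.all_layers:
            if not layer.trainable:
                continue
            flat_w = layer.weight.reshape(-1)
            flat_g = layer.dweight.reshape(-1)
            for k in rng.choice(flat_w.size, size=min(4, flat_w.size), replace=False):
                orig = flat_w[k]
                flat_w[k] = orig + h
                f_p = loss_value()
                flat_w[k] = orig - h
                f_m = loss_value()
                flat_w[k] = orig
                numeric = (f_p - f_m) / (2 * h)
                if abs(numeric) < 1e-5:
                    continue  # flat direction: below float32 resolution
                assert abs(numeric - flat_g[k]) / max(abs(numeric), 1e-6) < 5e-2
                checked += 1
        assert checked >= 8


class TestTraining:
    def test_descent_on_separable_data(self):
        images, y, pids, is_test = synthetic_imageset()
        cfg = tiny_config(epochs=30)
        res = MultitaskOutcomeModel(images, y, y, pids, is_test, cfg).fit()
        hist = res.history
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
        assert hist["acc_test_contra"].iloc[-1] > 0.9

    def test_same_seed_identical_histories(self):
        images, y, pids, is_test = synthetic_imageset()
        cfg = tiny_config(epochs=6)
        h1 = MultitaskOutcomeModel(images, y, y, pids, is_test, cfg).fit().history
        h2 = MultitaskOutcomeModel(images, y, y, pids, is_test, cfg).fit().history
        assert h1.equals(h2)

    def test_zero_ipsi_weight_equals_single_task_trajectory(self):
        """With w_ipsi = 0 the shared trunk and contra head see identical updates."""
        images, y, pids, is_test = synthetic_imageset()
        y_ipsi = 1 - y  # a different label stream for the second head
        multi = tiny_config(epochs=6, loss_weights=(1.0, 0.0))
        single = tiny_config(epochs=6, mode="single_task")
        h_multi = MultitaskOutcomeModel(images, y, y_ipsi, pids, is_test, multi).fit().history
        h_single = MultitaskOutcomeModel(images, y, y_ipsi, pids, is_test, single).fit().history
        for col in ["train_loss", "acc_train_contra", "acc_test_contra"]:
            assert np.array_equal(h_multi[col].to_numpy(), h_single[col].to_numpy()), col

    def test_patient_leakage_detected_inside_fit(self):
        images, y, pids, is_test = synthetic_imageset()
        is_test = is_test.copy()
        is_test[0] = True  # p00 stays in test...
        leaky = pids.copy()
        leaky[1] = "p07"  # ...but one of p07's segments is in test now
        is_test[1] = True
        model = MultitaskOutcomeModel(images, y, y, leaky, is_test, tiny_config())
        with pytest.raises(LeakageError):
            model.fit()

    def test_empty_split_rejected(self):
        images, y, pids, _ = synthetic_imageset()
        with pytest.raises(ValueError):
            MultitaskOutcomeModel(images, y, y, pids, np.zeros(len(y), bool), tiny_config())

    def test_example_order_invariance(self, rng):
        """Canonical segment ordering makes training order-independent."""
        images, y, pids, is_test = synthetic_imageset()
        sids = np.array([f"s{i:03d}" for i in range(len(y))])
        perm = rng.permutation(len(y))
        cfg = tiny_config(epochs=4)
        h1 = MultitaskOutcomeModel(images, y, y, pids, is_test, cfg, segment_ids=sids).fit().history
        h2 = (
            MultitaskOutcomeModel(
                images[perm], y[perm], y[perm], pids[perm], is_test[perm], cfg, segment_ids=sids[perm]
            )
            .fit()
            .history
        )
        assert h1.equals(h2)
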