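"""Architecture, determinism, freeze and capacity contracts of the 1-D CNN."""
import numpy as np
import pytest

from pcgkit import ConfigError, DataError
from pcgkit.lknet import (
    LKNet,
    LKNetSpec,
    TrainConfig,
    build_lknet,
    expected_parameter_count,
    predict,
    save_model,
    load_model,
    train,
)

SMALL = LKNetSpec(input_channels=4, input_length=100, n_blocks=4, kernel_size=9, base_channels=8)


def _random_set(n=24, spec=SMALL, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, spec.input_channels, spec.input_length)).astype(np.float32)
    y = rng.integers(0, 2, n)
    y[: n // 2] = 0
    y[n // 2 :] = 1
    return x, y


class TestBuild:
    def test_forward_probabilities_sum_to_one(self):
        net = build_lknet(SMALL, seed=0)
        p = net.forward(np.random.default_rng(1).standard_normal((5, 4, 100)))
        assert p.shape == (5, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_initialization(self):
        a, b = build_lknet(SMALL, seed=3), build_lknet(SMALL, seed=3)
        for (_, pa), (_, pb) in zip(a.named_params(), b.named_params()):
            assert np.array_equal(pa.value, pb.value)

    @pytest.mark.parametrize("kernel", [9, 15, 31])
    def test_parameter_count_closed_form(self, kernel):
        """Independent layer-by-layer count matches the built model."""
        spec = LKNetSpec(
            input_channels=4, input_length=128, n_blocks=5, kernel_size=kernel, base_channels=6
        )
        net = build_lknet(spec)
        # independent oracle: enumerate layer shapes by the schedule
        widths = [6 * 2 ** (i // 2) for i in range(5)]
        strides = [2 if (i > 0 and i % 2 == 0) else 1 for i in range(5)]
        count = 4 * 1 * widths[0] + widths[0]  # fc adapter
        c_prev = widths[0]
        for w, s in zip(widths, strides):
            count += (c_prev * kernel * w + w) + 2 * w  # conv1 + bn1
            count += (w * kernel * w + w) + 2 * w  # conv2 + bn2
            if c_prev != w or s != 1:
                count += (c_prev * 1 * w + w) + 2 * w  # projected skip
            c_prev = w
        count += c_prev * 2 + 2  # head
        assert net.n_parameters() == count == expected_parameter_count(spec)

    def test_conv_adapter_variant(self):
        spec = LKNetSpec(4, 100, n_blocks=2, kernel_size=9, base_channels=4, input_adapter="conv")
        net = build_lknet(spec, seed=0)
        assert net.adapter.k == 9
        p = net.forward(np.zeros((2, 4, 100), dtype=np.float32))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert net.n_parameters() == expected_parameter_count(spec)

    def test_invalid_specs_name_violation(self):
        with pytest.raises(ConfigError, match="kernel_size"):
            LKNetSpec(4, 100, kernel_size=8).validate()
        with pytest.raises(ConfigError, match="kernel_size"):
            LKNetSpec(4, 100, kernel_size=7).validate()
        with pytest.raises(ConfigError, match="input_length"):
            LKNetSpec(4, 2, n_blocks=8).validate()


class TestTrain:
    def test_single_class_rejected(self):
        x, _ = _random_set()
        with pytest.raises(DataError):
            train(build_lknet(SMALL), [(xi, 0) for xi in x], TrainConfig(epochs=1))

    def test_history_bounded_and_finite(self):
        x, y = _random_set()
        tm = train(build_lknet(SMALL), list(zip(x, y)), TrainConfig(epochs=3, seed=0))
        assert len(tm.history) <= 3
        assert all(np.isfinite(h["train_loss"]) for h in tm.history)

    def test_fully_frozen_network_is_untouched(self):
        net = build_lknet(SMALL, seed=1)
        net.set_frozen_blocks(range(4))
        for _, p in net.adapter.params():
            p.trainable = False
        for _, p in net.head.params():
            p.trainable = False
        before = {n: p.value.copy() for n, p in net.named_params()}
        x, y = _random_set()
        train(net, list(zip(x, y)), TrainConfig(epochs=2, seed=0, val_fraction=0.0))
        for n, p in net.named_params():
            if n.startswith("block"):
                assert np.array_equal(before[n], p.value), n

    def test_seed_reproducibility(self):
        x, y = _random_set()
        cfg = TrainConfig(epochs=3, seed=7)
        tm1 = train(build_lknet(SMALL, seed=2), list(zip(x, y)), cfg)
        tm2 = train(build_lknet(SMALL, seed=2), list(zip(x, y)), cfg)
        for (n, a), (_, b) in zip(tm1.net.named_params(), tm2.net.named_params()):
            assert np.array_equal(a.value, b.value), n

    def test_memorizes_random_labels(self):
        """Capacity sanity: a small LKNet fits 50 random-label inputs."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal((50, 4, 100)).astype(np.float32)
        y = rng.integers(0, 2, 50)
        cfg = TrainConfig(
            epochs=200, batch_size=16, learning_rate=3e-3,
            val_fraction=0.0, early_stop_patience=1000, seed=0,
        )
        spec = LKNetSpec(4, 100, n_blocks=4, kernel_size=15, base_channels=8)
        tm = train(build_lknet(spec, seed=0), list(zip(x, y)), cfg)
        acc = np.mean(predict(tm, x).argmax(axis=1) == y)
        assert acc >= 0.99


class TestPredict:
    def test_deterministic_and_batched(self):
        net = build_lknet(SMALL, seed=0)
        x, _ = _random_set(8)
        p1, p2 = predict(net, x), predict(net, x)
        assert np.array_equal(p1, p2)
        assert p1.shape == (8, 2)

    def test_batch_permutation_equivariance(self):
        net = build_lknet(SMALL, seed=0)
        x, _ = _random_set(8)
        perm = np.array([3, 1, 7, 0, 5, 2, 6, 4])
        assert np.allclose(predict(net, x)[perm], predict(net, x[perm]), atol=1e-6)

    def test_shape_mismatch_rejected(self):
        net = build_lknet(SMALL, seed=0)
        with pytest.raises(DataError):
            predict(net, np.zeros((3, 2, 100), dtype=np.float32))


def test_checkpoint_roundtrip(tmp_path):
    x, y = _random_set()
    tm = train(build_lknet(SMALL, seed=5), list(zip(x, y)), TrainConfig(epochs=2, seed=0))
    save_model(tm, tmp_path / "m")
    back = load_model(tmp_path / "m")
    assert np.array_equal(predict(back, x), predict(tm, x))
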