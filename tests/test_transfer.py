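"""Block-surgery correctness: plans, copying, freezing, gating."""
import numpy as np
import pytest

from pcgkit import ConfigError, DataError
from pcgkit.lknet import LKNet, LKNetSpec, TrainConfig, train
from pcgkit.transfer import (
    SourceUnderTrainedError,
    TransferPlan,
    build_target_from_source,
    fine_tune,
    train_source,
)

SRC_SPEC = LKNetSpec(input_channels=1, input_length=64, n_blocks=8, kernel_size=9, base_channels=4)
PCG_SPEC = LKNetSpec(input_channels=4, input_length=64, n_blocks=8, kernel_size=9, base_channels=4)


def _ecg_pairs(n=24, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        label = "af" if i % 2 else "normal"
        x = rng.standard_normal((1, 64)).astype(np.float32)
        if label == "af":
            x += 0.5
        pairs.append((x, label))
    return pairs


def _pcg_pairs(n=24, seed=1):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        label = "abnormal" if i % 2 else "normal"
        x = rng.standard_normal((4, 64)).astype(np.float32)
        if label == "abnormal":
            x[3] += 0.5
        pairs.append((x, label))
    return pairs


@pytest.fixture(scope="module")
def source():
    cfg = TrainConfig(epochs=2, batch_size=8, seed=0)
    return train_source(_ecg_pairs(), SRC_SPEC, cfg)


class TestPlan:
    def test_default_geometry(self):
        plan = TransferPlan()
        assert plan.blocks_retained == 4
        assert plan.target_depth == 12

    def test_inconsistent_plan_rejected(self):
        plan = TransferPlan(blocks_removed_from_tail=8, blocks_appended=8)
        with pytest.raises(ConfigError, match="frozen"):
            plan.validate()

    def test_remove_more_than_total_rejected(self):
        with pytest.raises(ConfigError):
            TransferPlan(blocks_removed_from_tail=9).validate()


class TestTrainSource:
    def test_rejects_foreign_labels(self):
        bad = [(np.zeros((1, 64), dtype=np.float32), "abnormal")] * 8
        with pytest.raises(DataError, match="normal"):
            train_source(bad, SRC_SPEC, TrainConfig(epochs=1))

    def test_records_validation_accuracy(self, source):
        assert "source_val_accuracy" in source.meta
        assert 0.0 <= source.meta["source_val_accuracy"] <= 1.0
        assert source.history


class TestSurgery:
    def test_target_geometry_and_frozen_copy(self, source):
        plan = TransferPlan()
        target = build_target_from_source(source, plan, PCG_SPEC, allow_undertrained=True)
        assert len(target.net.blocks) == 12
        assert target.frozen_block_indices == frozenset(range(4))
        for i in range(4):
            src = dict(source.net.blocks[i].params())
            for name, p in target.net.blocks[i].params():
                assert np.array_equal(p.value, src[name].value), (i, name)

    def test_depth_mismatch_rejected(self, source):
        plan = TransferPlan(source_blocks_total=6, blocks_removed_from_tail=2)
        with pytest.raises(ConfigError, match="depth"):
            build_target_from_source(source, plan, PCG_SPEC, allow_undertrained=True)

    def test_undertrained_source_blocks_handoff(self, source):
        poor = type(source)(
            net=source.net, spec=source.spec, history=source.history,
            frozen_block_indices=source.frozen_block_indices,
            meta={**source.meta, "source_ok": False, "source_val_accuracy": 0.5},
        )
        with pytest.raises(SourceUnderTrainedError, match="under-trained"):
            build_target_from_source(poor, TransferPlan(), PCG_SPEC)
        # override allowed
        build_target_from_source(poor, TransferPlan(), PCG_SPEC, allow_undertrained=True)


class TestFineTune:
    def test_frozen_blocks_bit_equal_after_training(self, source):
        target = build_target_from_source(source, TransferPlan(), PCG_SPEC, allow_undertrained=True)
        before = {
            f"{i}.{n}": p.value.copy()
            for i in range(4)
            for n, p in target.net.blocks[i].params()
        }
        tm = fine_tune(target, _pcg_pairs(), TrainConfig(epochs=2, batch_size=8, seed=0))
        # learned parameters are bit-frozen; normalization buffers are domain
        # statistics and deliberately re-estimated on the target data
        for i in range(4):
            for n, p in tm.net.blocks[i].params():
                assert np.array_equal(before[f"{i}.{n}"], p.value), (i, n)

    def test_zero_epochs_is_identity(self, source):
        target = build_target_from_source(source, TransferPlan(), PCG_SPEC, allow_undertrained=True)
        before = {n: p.value.copy() for n, p in target.net.named_params()}
        tm = fine_tune(target, _pcg_pairs(), TrainConfig(epochs=0, seed=0))
        for n, p in tm.net.named_params():
            assert np.array_equal(before[n], p.value), n

    def test_requires_surgical_target(self):
        net = LKNet(PCG_SPEC, seed=0)
        tm = train(net, _pcg_pairs(), TrainConfig(epochs=0, seed=0))
        with pytest.raises(ConfigError):
            fine_tune(tm, _pcg_pairs(), TrainConfig(epochs=1))


def test_no_source_tail_weight_survives(source):
    """Conservation: appended blocks are fresh, not copies of the dropped tail.

    Source blocks 4-7 and target blocks 4-7 share shapes under the doubling
    schedule, so a buggy copy would make them bit-equal.
    """
    target = build_target_from_source(source, TransferPlan(), PCG_SPEC, seed=9,
                                      allow_undertrained=True)
    for i in range(4, 8):
        src = dict(source.net.blocks[i].params())
        for name, p in target.net.blocks[i].params():
            if p.value.size >= 8:
                assert not np.array_equal(p.value, src[name].value), (i, name)
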