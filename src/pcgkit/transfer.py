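"""ECG-to-PCG transfer learning by residual-block surgery.

The source task is 2-class single-lead ECG rhythm classification (normal vs
atrial fibrillation), trained with an 8-block LKNet to at least 90% source
validation accuracy.  The target PCG classifier is then assembled by
dropping the last four source blocks, copying the first four with their
weights fixed, appending eight freshly initialized blocks that continue the
source channel/stride schedule, and attaching a fresh input adapter for the
4-channel envelope stack plus a fresh head.  Only the appended blocks, the
adapter, the head and any retained-but-unfrozen blocks train on PCG data.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ConfigError, DataError
from .lknet import (
    LKNet,
    LKNetSpec,
    TrainConfig,
    TrainedModel,
    predict_probs,
    train,
    _coerce_inputs,
)

__all__ = [
    "TransferPlan",
    "SourceUnderTrainedError",
    "train_source",
    "build_target_from_source",
    "fine_tune",
]


class SourceUnderTrainedError(RuntimeError):
    """Source network failed to reach the required validation accuracy."""


@dataclass(frozen=True)
class TransferPlan:
    """Block-surgery plan mapping a trained source net to a target net."""

    source_blocks_total: int = 8
    blocks_removed_from_tail: int = 4
    blocks_frozen_from_head: int = 4
    blocks_appended: int = 8
    source_min_accuracy: float = 0.90

    @property
    def blocks_retained(self) -> int:
        return self.source_blocks_total - self.blocks_removed_from_tail

    @property
    def target_depth(self) -> int:
        return self.blocks_retained + self.blocks_appended

    def validate(self) -> None:
        if min(self.source_blocks_total, self.blocks_removed_from_tail,
               self.blocks_frozen_from_head, self.blocks_appended) < 0:
            raise ConfigError("plan counts must be non-negative")
        if self.blocks_removed_from_tail > self.source_blocks_total:
            raise ConfigError("cannot remove more blocks than the source has")
        if self.blocks_frozen_from_head > self.blocks_retained:
            raise ConfigError(
                f"inconsistent plan: {self.blocks_frozen_from_head} frozen blocks but "
                f"only {self.blocks_retained} retained"
            )
        if self.target_depth < 1:
            raise ConfigError("target network must have at least one block")
        if not 0 < self.source_min_accuracy <= 1:
            raise ConfigError("source_min_accuracy must be in (0, 1]")


def train_source(
    ecg_data,
    spec: LKNetSpec,
    cfg: TrainConfig,
    plan: TransferPlan | None = None,
) -> TrainedModel:
    """Train the 8-block source LKNet on the ECG task.

    Labels must be ``normal``/``af``.  A stratified hold-out split (taken
    before training, from ``cfg.seed``) measures source validation accuracy;
    the result and whether it clears ``plan.source_min_accuracy`` are stored
    in the model's ``meta`` and enforced at :func:`build_target_from_source`.
    """
    plan = plan or TransferPlan()
    plan.validate()
    cfg.validate()
    if spec.n_blocks != plan.source_blocks_total:
        raise ConfigError(
            f"spec.n_blocks={spec.n_blocks} != plan.source_blocks_total={plan.source_blocks_total}"
        )
    labels = {label for _, label in ecg_data}
    bad = labels - {"normal", "af"}
    if bad:
        raise DataError(f"source labels must be 'normal' or 'af', got {sorted(bad)}")

    x, y = _coerce_inputs(ecg_data)
    rng = np.random.default_rng(cfg.seed)
    hold = np.zeros(x.shape[0], dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        hold[rng.permutation(idx)[: max(int(round(0.2 * idx.size)), 1)]] = True

    net = LKNet(spec, seed=cfg.seed)
    tm = train(net, list(zip(x[~hold], y[~hold])), cfg)
    probs = predict_probs(tm.net, x[hold])
    acc = float(np.mean(probs.argmax(axis=1) == y[hold]))
    tm.meta["source_val_accuracy"] = acc
    tm.meta["source_ok"] = acc >= plan.source_min_accuracy
    tm.meta["plan"] = plan
    return tm


def build_target_from_source(
    source: TrainedModel,
    plan: TransferPlan,
    pcg_input_spec: LKNetSpec,
    seed: int = 0,
    allow_undertrained: bool = False,
) -> TrainedModel:
    """Assemble the target network by block surgery on the trained source.

    The retained head blocks are copied bit-for-bit and the first
    ``plan.blocks_frozen_from_head`` of them are frozen; appended blocks and
    the new PCG input adapter/head are freshly initialized from ``seed``.
    """
    plan.validate()
    if len(source.net.blocks) != plan.source_blocks_total:
        raise ConfigError(
            f"source depth {len(source.net.blocks)} != plan.source_blocks_total "
            f"{plan.source_blocks_total}"
        )
    if not allow_undertrained and source.meta.get("source_ok") is False:
        raise SourceUnderTrainedError(
            f"source under-trained: validation accuracy "
            f"{source.meta.get('source_val_accuracy'):.3f} < {plan.source_min_accuracy}"
        )
    src_spec = source.spec
    target_spec = replace(
        src_spec,
        input_channels=pcg_input_spec.input_channels,
        input_length=pcg_input_spec.input_length,
        input_adapter=pcg_input_spec.input_adapter,
        n_blocks=plan.target_depth,
    )
    target = LKNet(target_spec, seed=seed)
    # copy retained source blocks (the appended blocks continue the same
    # width/stride schedule, so shapes line up by construction)
    for i in range(plan.blocks_retained):
        src_params = dict(source.net.blocks[i].params())
        for name, p in target.blocks[i].params():
            p.value = src_params[name].value.copy()
        src_layers = dict(source.net.blocks[i].layers())
        for ln, layer in target.blocks[i].layers():
            if hasattr(layer, "running_mean"):
                layer.running_mean = src_layers[ln].running_mean.copy()
                layer.running_var = src_layers[ln].running_var.copy()
    target.set_frozen_blocks(range(plan.blocks_frozen_from_head))
    return TrainedModel(
        net=target,
        spec=target_spec,
        history=[],
        frozen_block_indices=target.frozen_blocks,
        meta={"transfer_built": True, "plan": plan},
    )


def fine_tune(target: TrainedModel, pcg_data, cfg: TrainConfig) -> TrainedModel:
    """Fine-tune a surgically built target on PCG data; frozen blocks stay put."""
    if not target.meta.get("transfer_built"):
        raise ConfigError("fine_tune expects a model from build_target_from_source")
    tm = train(target.net, pcg_data, cfg)
    tm.meta.update(target.meta)
    tm.frozen_block_indices = target.net.frozen_blocks
    return tm
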