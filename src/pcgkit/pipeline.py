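"""End-to-end glue: recordings -> preprocessing -> segments -> features -> model.

Stages run in the canonical order (noise reduction, spike removal,
segmentation, feature extraction, classification).  This module turns
labelled recordings into model-ready inputs and exposes ``fit_predict``
factories consumed by :func:`pcgkit.evaluate.cross_validate` and the CLI.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .baselines import BaselineSpec, fit_baseline, predict_baseline
from .boosting import BoostConfig, RecordInput, ensemble_predict, fit_boosting
from .core import ConfigError, Recording, StateAnnotation
from .evaluate import cross_validate
from .features import EnvelopeConfig, engineered_vector, envelope_stack
from .lknet import LKNet, LKNetSpec, TrainConfig, TrainedModel, predict_probs, train
from .preprocess import PreprocessConfig, preprocess
from .segment import aggregate_record, beat_segments, fixed_segments, no_segments, sliding_segments
from .transfer import TransferPlan, build_target_from_source, fine_tune

__all__ = [
    "SegmentationConfig",
    "PipelineConfig",
    "prepare_record_inputs",
    "make_fit_predict",
    "evaluate_pipeline",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation mode and geometry (seconds)."""

    mode: str = "sliding"  # sliding | fixed | beat | none
    stride: float = 1.0
    window: float = 2.0
    beat_target_len: int = 1000

    def validate(self) -> None:
        if self.mode not in ("sliding", "fixed", "beat", "none"):
            raise ConfigError("segmentation mode must be sliding/fixed/beat/none")
        if self.window <= 0 or self.stride <= 0:
            raise ConfigError("window and stride must be > 0")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to train and evaluate one model variant."""

    model: str = "lknet"  # lknet | transfer | boosting | baseline:{svm_linear,rf,gbdt}
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    net: dict = field(default_factory=dict)  # LKNetSpec overrides
    train: TrainConfig = field(default_factory=TrainConfig)
    boost: BoostConfig = field(default_factory=BoostConfig)
    transfer_plan: TransferPlan = field(default_factory=TransferPlan)
    source_model: TrainedModel | None = None  # trained outside folds (ECG task)
    aggregation: str = "mean_prob"

    def validate(self) -> None:
        kinds = ("lknet", "transfer", "boosting",
                 "baseline:svm_linear", "baseline:rf", "baseline:gbdt")
        if self.model not in kinds:
            raise ConfigError(f"model must be one of {kinds}")
        self.preprocess.validate()
        self.segmentation.validate()
        self.envelope.validate()
        self.train.validate()


def _segment(rec: Recording, ann: StateAnnotation | None, seg: SegmentationConfig):
    if seg.mode == "sliding":
        return sliding_segments(rec, seg.stride, seg.window)
    if seg.mode == "fixed":
        return fixed_segments(rec, seg.window)
    if seg.mode == "none":
        return no_segments(rec)
    if ann is None:
        raise ConfigError("beat segmentation needs state annotations")
    return beat_segments(rec, ann, seg.beat_target_len)


def prepare_record_inputs(items, cfg: PipelineConfig) -> list[RecordInput]:
    """Preprocess, segment and envelope-stack each (Recording, annotation) item."""
    out = []
    for rec, ann in items:
        clean = preprocess(rec, cfg.preprocess)
        segset = _segment(clean, ann, cfg.segmentation)
        stacks = np.stack(
            [
                envelope_stack(s, clean.sampling_rate, cfg.envelope, rec.record_id).channels
                for s in segset.segments
            ]
        )
        out.append(RecordInput(rec.record_id, stacks, rec.label))
    return out


def _resample_annotation(ann: StateAnnotation, n_old: int, n_new: int) -> StateAnnotation:
    idx = np.minimum((np.arange(n_new) * n_old / n_new).astype(int), n_old - 1)
    return StateAnnotation(ann.record_id, ann.states[idx])


def _engineered_table(items, cfg: PipelineConfig):
    feats, labels = [], []
    for rec, ann in items:
        if ann is None:
            raise ConfigError("engineered features need state annotations")
        clean = preprocess(rec, cfg.preprocess)
        if clean.samples.size != ann.states.size:
            ann = _resample_annotation(ann, ann.states.size, clean.samples.size)
        feats.append(engineered_vector(clean, ann).values)
        labels.append(1 if rec.label in ("abnormal", "af") else 0)
    return np.stack(feats), np.array(labels)


def _net_spec(cfg: PipelineConfig, input_channels: int, input_length: int) -> LKNetSpec:
    return LKNetSpec(input_channels=input_channels, input_length=input_length, **cfg.net)


def make_fit_predict(cfg: PipelineConfig):
    """A ``fit_predict(train_items, test_items)`` closure for cross-validation.

    Items are (Recording, StateAnnotation-or-None) pairs; the closure trains
    the configured model from scratch on the training records and returns
    binary predictions (1 = abnormal) for the test records.
    """
    cfg.validate()

    def fit_predict(train_items, test_items):
        if cfg.model.startswith("baseline:"):
            x_tr, y_tr = _engineered_table(train_items, cfg)
            x_te, _ = _engineered_table(test_items, cfg)
            model = fit_baseline(x_tr, y_tr, BaselineSpec(kind=cfg.model.split(":")[1],
                                                          seed=cfg.train.seed))
            return predict_baseline(model, x_te)

        train_inputs = prepare_record_inputs(train_items, cfg)
        test_inputs = prepare_record_inputs(test_items, cfg)
        seg_len = train_inputs[0].stacks.shape[2]

        if cfg.model == "boosting":
            ens = fit_boosting(train_inputs, cfg.boost, source_model=cfg.source_model)
            return (ensemble_predict(ens, test_inputs) > 0.5).astype(int)

        if cfg.model == "transfer":
            if cfg.source_model is None:
                raise ConfigError("transfer pipeline needs a pre-trained source_model")
            pcg_spec = _net_spec(cfg, 4, seg_len)
            target = build_target_from_source(
                cfg.source_model, cfg.transfer_plan, pcg_spec, seed=cfg.train.seed
            )
            seg_pairs = [
                (s, r.label) for r in train_inputs for s in r.stacks
            ]
            tm = fine_tune(target, seg_pairs, cfg.train)
        else:  # plain lknet
            spec = _net_spec(cfg, 4, seg_len)
            seg_pairs = [(s, r.label) for r in train_inputs for s in r.stacks]
            tm = train(LKNet(spec, seed=cfg.train.seed), seg_pairs, cfg.train)

        preds = []
        for r in test_inputs:
            p = predict_probs(tm.net, r.stacks.astype(np.float32))[:, 1]
            preds.append(aggregate_record(p, cfg.aggregation) > 0.5)
        return np.array(preds, dtype=int)

    return fit_predict


def evaluate_pipeline(dataset, cfg: PipelineConfig, k: int = 10, seed: int = 0):
    """Record-level stratified k-fold cross-validation of a pipeline config."""
    return cross_validate(dataset, make_fit_predict(cfg), k=k, seed=seed,
                          config_obj={"model": cfg.model, "k": k, "seed": seed})
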