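"""Multi-feature-set LKNet boosting with AdaBoost-style sample re-weighting.

Rounds train one (reduced-depth) LKNet base learner each, cycling through
feature sets — individual envelope channels or the full 4-channel stack — so
successive learners see the signal "from different angles".  Records
misclassified by the current learner gain weight for the next round; the
final decision is a light fusion of the members' record-level probabilities
(weighted log-odds by default, optionally a logistic head calibrated on a
held-out split).

Weighted errors are computed on record-level decisions (segment
probabilities averaged per record), because recordings — not segments — are
the unit of diagnosis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ConfigError, DataError
from .lknet import LKNet, LKNetSpec, TrainConfig, TrainedModel, predict_probs, train, _label_index
from .segment import aggregate_record
from .transfer import build_target_from_source, fine_tune

__all__ = [
    "BoostConfig",
    "RecordInput",
    "Ensemble",
    "adaboost_step",
    "fit_boosting",
    "ensemble_predict",
    "save_ensemble",
    "load_ensemble",
]

#: channel indices of each feature set within the 4-channel envelope stack
FEATURE_SET_CHANNELS = {
    "raw": [0],
    "homomorphic": [1],
    "hilbert": [2],
    "psd": [3],
    "full_stack": [0, 1, 2, 3],
}


@dataclass
class RecordInput:
    """One recording's model-ready segments: (n_segments, 4, L) envelope stacks."""

    record_id: str
    stacks: np.ndarray
    label: str | int

    def __post_init__(self) -> None:
        self.stacks = np.asarray(self.stacks)
        if self.stacks.ndim != 3 or self.stacks.shape[0] < 1 or self.stacks.shape[1] != 4:
            raise DataError(f"{self.record_id}: stacks must be (n_segments, 4, L)")


@dataclass(frozen=True)
class BoostConfig:
    """Boosting hyperparameters.

    ``feature_sets`` is cycled across rounds.  ``epsilon_floor``/``ceiling``
    clamp the weighted error so member weights alpha stay finite and
    positive.  Base learners default to a reduced 4-block LKNet, which keeps
    them weak enough for re-weighting to matter.
    """

    rounds: int = 4
    feature_sets: tuple[str, ...] = ("full_stack", "homomorphic", "hilbert", "psd")
    epsilon_floor: float = 1e-6
    epsilon_ceiling: float = 0.5 - 1e-6
    base_train: TrainConfig = field(default_factory=TrainConfig)
    fusion: str = "weighted_log_odds"  # weighted_log_odds | logistic_head
    member_blocks: int = 4
    member_base_channels: int = 16
    member_kernel_size: int = 15
    aggregation: str = "mean_prob"

    def validate(self) -> None:
        if self.rounds < 1:
            raise ConfigError("rounds must be >= 1")
        if not self.feature_sets:
            raise ConfigError("feature_sets must be non-empty")
        unknown = set(self.feature_sets) - set(FEATURE_SET_CHANNELS)
        if unknown:
            raise ConfigError(f"unknown feature sets {sorted(unknown)}")
        if not 0 < self.epsilon_floor < self.epsilon_ceiling < 0.5:
            raise ConfigError("need 0 < epsilon_floor < epsilon_ceiling < 0.5")
        if self.fusion not in ("weighted_log_odds", "logistic_head"):
            raise ConfigError("fusion must be 'weighted_log_odds' or 'logistic_head'")
        self.base_train.validate()


@dataclass
class Ensemble:
    """Ordered trained members with per-member feature set and weight alpha."""

    members: list  # of (TrainedModel, feature_set: str, alpha: float)
    fusion: str = "weighted_log_odds"
    fusion_head: object | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError("ensemble needs at least one member")
        if not all(np.isfinite(a) for _, _, a in self.members):
            raise DataError("member alphas must be finite")


def adaboost_step(
    w: np.ndarray, misclassified: np.ndarray, floor: float, ceiling: float
) -> tuple[float, float, np.ndarray]:
    """One AdaBoost re-weighting step on normalized sample weights.

    Returns ``(eps_raw, alpha, w_next)`` where ``eps_raw`` is the weighted
    error before clamping, ``alpha = 0.5 ln((1-eps)/eps)`` with ``eps``
    clamped to ``(floor, ceiling)``, and ``w_next`` multiplies misclassified
    weights by ``exp(+alpha)``, correct ones by ``exp(-alpha)``, then
    renormalizes.  When ``eps_raw`` is unclamped the misclassified mass of
    ``w_next`` is exactly one half.
    """
    mis = np.asarray(misclassified, dtype=bool)
    eps_raw = float(np.sum(w[mis]))
    eps = float(np.clip(eps_raw, floor, ceiling))
    alpha = 0.5 * np.log((1 - eps) / eps)
    w_next = w * np.exp(np.where(mis, alpha, -alpha))
    return eps_raw, float(alpha), w_next / w_next.sum()


def _member_record_probs(tm: TrainedModel, data, feature_set: str) -> np.ndarray:
    chs = FEATURE_SET_CHANNELS[feature_set]
    out = np.empty(len(data))
    for i, rec in enumerate(data):
        seg_probs = predict_probs(tm.net, rec.stacks[:, chs, :].astype(np.float32))[:, 1]
        out[i] = aggregate_record(seg_probs, "mean_prob")
    return out


def fit_boosting(
    data: list[RecordInput],
    cfg: BoostConfig,
    source_model: TrainedModel | None = None,
    member_spec: LKNetSpec | None = None,
) -> Ensemble:
    """Sequentially train LKNet members with record-level re-weighting.

    Round m trains on feature set ``feature_sets[m mod k]`` with per-record
    weights (uniform at round 1, normalized to sum 1).  The weighted
    record-level training error ``eps`` is clamped to
    ``(epsilon_floor, epsilon_ceiling)``; the member weight is
    ``alpha = 0.5 ln((1-eps)/eps)`` and record weights are multiplied by
    ``exp(+alpha)`` (misclassified) or ``exp(-alpha)`` (correct) and
    renormalized — the standard AdaBoost update, which puts exactly half the
    mass on misclassified records whenever ``eps`` is unclamped.

    With ``source_model`` given, members are initialized by the ECG-to-PCG
    transfer surgery instead of from scratch.
    """
    cfg.validate()
    y = np.array([_label_index(r.label) for r in data])
    if np.unique(y).size < 2:
        raise DataError("boosting needs both classes present")

    seg_len = data[0].stacks.shape[2]
    cal_idx = np.zeros(len(data), dtype=bool)
    if cfg.fusion == "logistic_head":
        rng = np.random.default_rng(cfg.base_train.seed)
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            cal_idx[rng.permutation(idx)[: max(int(round(0.2 * idx.size)), 1)]] = True
    fit_data = [r for r, c in zip(data, cal_idx) if not c]
    fit_y = y[~cal_idx]

    n = len(fit_data)
    w = np.full(n, 1.0 / n)
    members = []
    weight_history = []
    all_clamped = True
    for m in range(cfg.rounds):
        fs = cfg.feature_sets[m % len(cfg.feature_sets)]
        chs = FEATURE_SET_CHANNELS[fs]
        seed_m = cfg.base_train.seed + 1000 * m
        round_cfg = replace(cfg.base_train, seed=seed_m)

        seg_pairs, seg_w = [], []
        for rec, wi in zip(fit_data, w):
            for s in rec.stacks[:, chs, :]:
                seg_pairs.append((s.astype(np.float32), rec.label))
                seg_w.append(wi / rec.stacks.shape[0])
        seg_w = np.array(seg_w)

        if source_model is not None:
            plan = source_model.meta.get("plan")
            if plan is None:
                raise ConfigError("source_model lacks a transfer plan in meta")
            pcg_spec = replace(
                source_model.spec, input_channels=len(chs), input_length=seg_len
            )
            target = build_target_from_source(source_model, plan, pcg_spec, seed=seed_m)
            tm = fine_tune(target, seg_pairs, round_cfg)
        else:
            ms = member_spec or LKNetSpec(
                input_channels=len(chs),
                input_length=seg_len,
                n_blocks=cfg.member_blocks,
                kernel_size=cfg.member_kernel_size,
                base_channels=cfg.member_base_channels,
            )
            ms = replace(ms, input_channels=len(chs), input_length=seg_len)
            tm = train(LKNet(ms, seed=seed_m), seg_pairs, round_cfg, sample_weights=seg_w)

        rec_probs = _member_record_probs(tm, fit_data, fs)
        mis = (rec_probs > 0.5).astype(int) != fit_y
        eps_raw, alpha, w = adaboost_step(w, mis, cfg.epsilon_floor, cfg.epsilon_ceiling)
        if cfg.epsilon_floor < eps_raw < cfg.epsilon_ceiling:
            all_clamped = False
        members.append((tm, fs, alpha))
        weight_history.append({"round": m, "feature_set": fs, "epsilon": eps_raw,
                               "alpha": alpha, "weights_sum": float(w.sum()),
                               "misclassified_mass": float(np.sum(w[mis]))})

    metadata = {"rounds": weight_history, "final_weights_sum": float(w.sum())}
    if all_clamped:
        metadata["warning"] = "weighted error clamped in every round"
        warnings.warn("boosting: weighted error clamped in every round")

    head = None
    if cfg.fusion == "logistic_head":
        from sklearn.linear_model import LogisticRegression

        cal_data = [r for r, c in zip(data, cal_idx) if c]
        cal_y = y[cal_idx]
        P = np.column_stack([_member_record_probs(tm, cal_data, fs) for tm, fs, _ in members])
        head = LogisticRegression().fit(P, cal_y)
    return Ensemble(members=members, fusion=cfg.fusion, fusion_head=head, metadata=metadata)


def save_ensemble(ens: Ensemble, out_dir) -> None:
    """Directory of member checkpoints plus a manifest JSON."""
    import json
    from pathlib import Path

    from .lknet import save_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"fusion": ens.fusion, "metadata": ens.metadata, "members": []}
    for i, (tm, fs, alpha) in enumerate(ens.members):
        save_model(tm, out / f"member{i:02d}")
        manifest["members"].append({"dir": f"member{i:02d}", "feature_set": fs, "alpha": alpha})
    (out / "ensemble.json").write_text(json.dumps(manifest, indent=2, default=float))


def load_ensemble(in_dir) -> Ensemble:
    import json
    from pathlib import Path

    from .lknet import load_model

    ind = Path(in_dir)
    manifest = json.loads((ind / "ensemble.json").read_text())
    members = [
        (load_model(ind / m["dir"]), m["feature_set"], float(m["alpha"]))
        for m in manifest["members"]
    ]
    return Ensemble(members=members, fusion=manifest["fusion"], metadata=manifest["metadata"])


def ensemble_predict(ens: Ensemble, data: list[RecordInput]) -> np.ndarray:
    """Record-level abnormal-class probabilities from the fused ensemble."""
    for rec in data:
        if rec.stacks.shape[1] != 4:
            raise DataError(f"{rec.record_id}: expected 4 channels")
    P = np.column_stack([_member_record_probs(tm, data, fs) for tm, fs, _ in ens.members])
    if ens.fusion == "logistic_head" and ens.fusion_head is not None:
        return ens.fusion_head.predict_proba(P)[:, 1]
    alphas = np.array([a for _, _, a in ens.members])
    score = 2 * (P @ alphas) - alphas.sum()  # sum_m alpha_m * (2 p_m - 1)
    return 1.0 / (1.0 + np.exp(-score))
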