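"""Boosting weight algebra, fusion symmetry, and ensemble behaviour."""
import numpy as np
import pytest

from pcgkit import ConfigError, DataError
from pcgkit.boosting import (
    BoostConfig,
    Ensemble,
    RecordInput,
    adaboost_step,
    ensemble_predict,
    fit_boosting,
)
from pcgkit.lknet import TrainConfig

FLOOR, CEIL = 1e-6, 0.5 - 1e-6


class TestAdaboostStep:
    def test_weights_stay_normalized(self):
        rng = np.random.default_rng(0)
        w = rng.random(30)
        w /= w.sum()
        for frac in (0.1, 0.3, 0.49):
            mis = rng.random(30) < frac
            if not mis.any() or mis.all():
                continue
            _, _, w2 = adaboost_step(w, mis, FLOOR, CEIL)
            assert w2.sum() == pytest.approx(1.0, abs=1e-9)

    def test_misclassified_mass_is_half_when_unclamped(self):
        """AdaBoost identity: the update puts exactly half the mass on errors."""
        rng = np.random.default_rng(1)
        for seed in range(5):
            w = rng.random(40)
            w /= w.sum()
            mis = rng.random(40) < 0.25
            eps, alpha, w2 = adaboost_step(w, mis, FLOOR, CEIL)
            if FLOOR < eps < CEIL:
                assert np.sum(w2[mis]) == pytest.approx(0.5, abs=1e-9)

    def test_perfect_learner_hits_floor_clamp(self):
        w = np.full(10, 0.1)
        mis = np.zeros(10, dtype=bool)
        eps, alpha, _ = adaboost_step(w, mis, FLOOR, CEIL)
        assert eps == 0.0
        assert alpha == pytest.approx(0.5 * np.log((1 - FLOOR) / FLOOR))


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


class _FixedModel:
    """Stub member whose segment probabilities are pre-set per record id."""

    def __init__(self, probs_by_id):
        self.probs_by_id = probs_by_id
        self.net = self

    def forward(self, x, training=False):  # predict_probs protocol
        p = self._current
        out = np.column_stack([1 - np.full(x.shape[0], p), np.full(x.shape[0], p)])
        return out


def _stub_members(assignments):
    """assignments: list of (probs_by_id dict, alpha)."""
    members = []
    for probs_by_id, alpha in assignments:
        members.append((_FixedModel(probs_by_id), "raw", alpha))
    return members


def _stub_predict(members, record_probs):
    """Evaluate the fusion rule directly on given per-member record probs."""
    alphas = np.array([a for _, _, a in members])
    P = np.asarray(record_probs)
    return _logistic(2 * (P @ alphas) - alphas.sum())


class TestFusionAlgebra:
    def test_single_member_is_monotone(self):
        members = _stub_members([({}, 1.0)])
        p = np.linspace(0, 1, 11)
        fused = _stub_predict(members, p[:, None])
        assert np.all(np.diff(fused) > 0)
        assert np.array_equal(np.argsort(fused), np.argsort(p))

    def test_opposed_equal_members_fuse_to_half(self):
        members = _stub_members([({}, 0.7), ({}, 0.7)])
        p1 = np.array([0.9, 0.2, 0.55])
        fused = _stub_predict(members, np.column_stack([p1, 1 - p1]))
        assert np.allclose(fused, 0.5, atol=1e-9)

    def test_identical_members_match_single_decision(self):
        members3 = _stub_members([({}, 0.8)] * 3)
        members1 = _stub_members([({}, 0.8)])
        p = np.linspace(0.05, 0.95, 7)[:, None]
        fused3 = _stub_predict(members3, np.repeat(p, 3, axis=1))
        fused1 = _stub_predict(members1, p)
        assert np.array_equal(fused3 > 0.5, fused1 > 0.5)


def _toy_records(n=20, seed=0, seg=3, length=64):
    rng = np.random.default_rng(seed)
    data = []
    for i in range(n):
        y = i % 2
        x = rng.standard_normal((seg, 4, length)).astype(np.float32)
        if y:
            x[:, 3, :] += 1.0  # signal in the psd channel
        data.append(RecordInput(f"r{i:03d}", x, y))
    return data


TOY_CFG = BoostConfig(
    rounds=3,
    feature_sets=("full_stack", "psd", "raw"),
    base_train=TrainConfig(epochs=3, batch_size=16, learning_rate=3e-3, seed=0),
    member_blocks=2,
    member_base_channels=4,
    member_kernel_size=9,
)


class TestFitBoosting:
    def test_round_bookkeeping(self):
        ens = fit_boosting(_toy_records(), TOY_CFG)
        assert len(ens.members) == 3
        for r in ens.metadata["rounds"]:
            assert r["weights_sum"] == pytest.approx(1.0, abs=1e-9)
            assert np.isfinite(r["alpha"])
        sets = [fs for _, fs, _ in ens.members]
        assert sets == ["full_stack", "psd", "raw"]

    def test_single_class_rejected(self):
        data = _toy_records()
        for r in data:
            r.label = 0
        with pytest.raises(DataError):
            fit_boosting(data, TOY_CFG)

    def test_predictions_are_probabilities(self):
        data = _toy_records()
        ens = fit_boosting(data, TOY_CFG)
        p = ensemble_predict(ens, data)
        assert p.shape == (len(data),)
        assert np.all((p >= 0) & (p <= 1))

    def test_bad_feature_set_rejected(self):
        with pytest.raises(ConfigError):
            BoostConfig(feature_sets=("wavelet",)).validate()

    def test_checkpoint_roundtrip(self, tmp_path):
        from pcgkit.boosting import load_ensemble, save_ensemble

        data = _toy_records()
        ens = fit_boosting(data, TOY_CFG)
        save_ensemble(ens, tmp_path / "ens")
        back = load_ensemble(tmp_path / "ens")
        assert np.allclose(ensemble_predict(back, data), ensemble_predict(ens, data))
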