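"""Losses, schedules and the trainer: closed forms and pure-function tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgebp.graph import ArchitectureSpec, LayerSpec
from edgebp.preprocess import WINDOW_SAMPLES, SplitDataset, WindowSet
from edgebp.training import (
    EarlyStopper,
    PlateauScheduler,
    TrainConfig,
    TrainingError,
    default_config,
    fast_profile,
    huber_loss,
    mse_loss,
    schedule_trajectory,
    train_model,
)


class TestLosses:
    @pytest.mark.parametrize(
        "e,delta,expected",
        [
            (0.5, 1.0, 0.125),  # quadratic branch
            (1.0, 1.0, 0.5),  # knee: both branches agree
            (3.0, 1.0, 2.5),  # linear branch
            (-3.0, 1.0, 2.5),  # symmetry
        ],
    )
    def test_huber_hand_values(self, e, delta, expected):
        assert huber_loss(np.array([e]), delta) == pytest.approx(expected)

    @pytest.mark.parametrize("e,expected", [([0, 0], 0.0), ([1, -1], 1.0), ([3], 9.0)])
    def test_mse_hand_values(self, e, expected):
        assert mse_loss(np.array(e, dtype=float)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=30))
    def test_huber_equals_half_mse_for_large_delta(self, errors):
        e = np.array(errors)
        delta = float(np.abs(e).max()) + 1.0
        assert huber_loss(e, delta) == pytest.approx(0.5 * mse_loss(e), rel=1e-12, abs=1e-12)

    def test_huber_linear_tail(self):
        e = np.array([1000.0])
        assert huber_loss(e, 1.0) == pytest.approx(1.0 * 1000.0 - 0.5)

    def test_invalid_inputs(self):
        with pytest.raises(TrainingError):
            huber_loss(np.array([np.nan]), 1.0)
        with pytest.raises(TrainingError):
            huber_loss(np.array([1.0]), 0.0)
        with pytest.raises(TrainingError):
            mse_loss(np.array([]))


class TestDefaultConfigs:
    def test_baseline_protocol(self):
        cfg = default_config("baseline_cnn")
        assert cfg.loss == "mse" and cfg.optimizer == "adam"
        assert cfg.learning_rate == 1e-3
        assert cfg.max_epochs == 400 and cfg.early_stop_patience is None

    def test_huber_protocol(self):
        cfg = default_config("residual_cnn_slim")
        assert cfg.loss == "huber" and cfg.optimizer == "adamw"
        assert cfg.learning_rate == 8e-4 and cfg.weight_decay == 1e-4
        assert cfg.huber_delta == 1.0 and cfg.batch_size == 128
        assert cfg.min_lr == 1e-6 and cfg.seed == 42

    def test_micro_tcn_min_lr(self):
        assert default_config("micro_tcn").min_lr == 1e-6

    def test_fast_profile_changes_budget_not_optimizer(self):
        slow, fast = default_config("residual_cnn_slim"), fast_profile("residual_cnn_slim")
        assert fast.max_epochs < slow.max_epochs
        assert (fast.optimizer, fast.learning_rate, fast.loss) == (
            slow.optimizer,
            slow.learning_rate,
            slow.loss,
        )


class TestScheduler:
    def test_scripted_plateau_halvings(self):
        # 3 epochs of improvement, then a 7-epoch plateau with patience 2:
        # halvings fire on the 3rd, 6th ... plateau epochs.
        vals = [1.0, 0.9, 0.8] + [0.8] * 7
        lrs = schedule_trajectory(vals, lr0=1.0, factor=0.5, patience=2, min_lr=0.01)
        assert lrs == [1.0, 1.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.25, 0.25]

    def test_min_lr_floor(self):
        lrs = schedule_trajectory([1.0] + [1.0] * 40, lr0=1e-3, factor=0.5, patience=0, min_lr=1e-6)
        assert min(lrs) == 1e-6

    def test_early_stopper_patience(self):
        stopper = EarlyStopper(patience=2)
        flags = [stopper.update(v, i) for i, v in enumerate([1.0, 0.5, 0.6, 0.6, 0.6])]
        assert flags == [False, False, False, False, True]
        assert stopper.best_epoch == 1


def _toy_split(n=64, label=(120.0, 70.0), seed=0):
    rng = np.random.default_rng(seed)
    def ws(m):
        return WindowSet(
            values=rng.uniform(0, 1, (m, WINDOW_SAMPLES)),
            sbp=np.full(m, label[0]),
            dbp=np.full(m, label[1]),
            record_id=np.array(["r"] * m, dtype=object),
            start=np.zeros(m, dtype=np.int64),
        )
    return SplitDataset(train=ws(n), val=ws(16), test=ws(16))


class TestTrainer:
    def _bias_only_spec(self):
        return ArchitectureSpec(
            "bias_toy",
            [
                LayerSpec("gap", "gap1d", ("input",)),
                LayerSpec("out", "dense", ("gap",), filters=2),
            ],
        )

    def test_convex_toy_recovers_label_mean(self):
        split = _toy_split()
        cfg = TrainConfig(
            optimizer="adam", loss="mse", learning_rate=0.5, max_epochs=300,
            early_stop_patience=None, restore_best=False, batch_size=16,
            plateau_patience=15, min_lr=1e-5,
        )
        res = train_model(self._bias_only_spec(), split, cfg)
        from edgebp.nn import predict

        preds = predict(res.model, split.test.values)
        assert abs(preds[:, 0].mean() - 120.0) < 1e-2
        assert abs(preds[:, 1].mean() - 70.0) < 1e-2

    def test_seeded_training_is_reproducible(self):
        split = _toy_split()
        cfg = TrainConfig(max_epochs=5, early_stop_patience=None, batch_size=32)
        a = train_model(self._bias_only_spec(), split, cfg)
        b = train_model(self._bias_only_spec(), split, cfg)
        assert a.stopped_epoch == b.stopped_epoch
        assert a.history["val_loss"] == b.history["val_loss"]
        for k in a.model.weights:
            assert np.array_equal(a.model.weights[k]["w"], b.model.weights[k]["w"])

    def test_restore_best_returns_minimum_val_epoch_weights(self):
        split = _toy_split()
        cfg = TrainConfig(max_epochs=8, early_stop_patience=None, batch_size=32)
        res = train_model(self._bias_only_spec(), split, cfg)
        from edgebp.nn import forward_batch
        from edgebp.training import _loss_and_grad

        Xva = split.val.values[:, :, None]
        yva = np.column_stack([split.val.sbp, split.val.dbp])
        out, _ = forward_batch(res.model, Xva.astype(np.float64))
        val_loss, _ = _loss_and_grad(out, yva, cfg.loss, cfg.huber_delta)
        assert val_loss == pytest.approx(min(res.history["val_loss"]), rel=1e-5)
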