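"""Loss, augmentation, LR schedule and the seeded training loop."""

from __future__ import annotations

import numpy as np
import pytest

from osteoage import pipeline
from osteoage.networks import build_model
from osteoage.training import (
    PlateauScheduler,
    Sample,
    TrainConfig,
    TrainingDivergedError,
    center_crop,
    evaluate,
    lr_schedule_step,
    mse_loss,
    progressive_pretrain,
    random_crop,
    train,
)


class TestMSE:
    def test_perfect_fit(self):
        assert mse_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_symmetric_errors(self):
        assert mse_loss(np.array([30.0, 50.0]), np.array([35.0, 45.0])) == 25.0

    def test_matches_loop_oracle(self, rng):
        y = rng.uniform(20, 70, 500)
        p = rng.uniform(20, 70, 500)
        oracle = sum((a - b) ** 2 for a, b in zip(y, p)) / len(y)
        assert mse_loss(y, p) == pytest.approx(oracle, rel=1e-12)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            mse_loss(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            mse_loss(np.array([]), np.array([]))


class TestCrops:
    def test_offset_ranges(self, rng):
        src = np.arange(20 * 40 * 40, dtype=np.float32).reshape(20, 40, 40)
        target = (20, 30, 30)
        corners = set()
        for _ in range(200):
            out = random_crop(src, target, rng)
            assert out.shape == target
            # recover the offset from the first element
            flat = int(out[0, 0, 0])
            z, rem = divmod(flat, 1600)
            yy, xx = divmod(rem, 40)
            assert z == 0 and 0 <= yy <= 10 and 0 <= xx <= 10
            corners.add((yy, xx))
        assert len(corners) > 20  # offsets actually vary

    def test_identity_when_target_equals_source(self, rng):
        src = rng.normal(size=(5, 6, 7)).astype(np.float32)
        np.testing.assert_array_equal(random_crop(src, (5, 6, 7), rng), src)

    def test_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="crop too large"):
            random_crop(np.zeros((4, 4, 4)), (5, 4, 4), rng)

    def test_seeded_reproducibility(self):
        src = np.arange(1000, dtype=np.float32).reshape(10, 10, 10)
        a = random_crop(src, (6, 6, 6), np.random.default_rng(3))
        b = random_crop(src, (6, 6, 6), np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_center_crop_deterministic_and_centered(self):
        src = np.arange(64, dtype=np.float32).reshape(4, 4, 4)
        out = center_crop(src, (2, 2, 2))
        np.testing.assert_array_equal(out, src[1:3, 1:3, 1:3])

    def test_channel_axis_untouched(self, rng):
        src = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
        assert random_crop(src, (6, 6, 6), rng).shape == (2, 6, 6, 6)


class TestLRSchedule:
    def test_flat_ten_epochs_reduces(self):
        cfg = TrainConfig()
        assert lr_schedule_step([1.0] * 10, 3e-4, cfg) == pytest.approx(2.4e-4)

    def test_improving_loss_unchanged(self):
        cfg = TrainConfig()
        losses = list(np.linspace(10.0, 1.0, 15))
        assert lr_schedule_step(losses, 3e-4, cfg) == 3e-4

    def test_floor_at_min_lr(self):
        cfg = TrainConfig()
        assert lr_schedule_step([1.0] * 10, 3e-5, cfg) == 3e-5

    def test_scheduler_trace_never_increases(self):
        sched = PlateauScheduler(3e-4, patience=3, min_lr=3e-5)
        rng = np.random.default_rng(0)
        trace = [sched.step(float(v)) for v in rng.uniform(1, 2, 100)]
        assert all(b <= a for a, b in zip(trace, trace[1:]))
        assert min(trace) >= 3e-5


def _tiny_dataset(n, seed=0, modality="femur", shape=(14, 16, 16)):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 70, n)
    samples = []
    for i, age in enumerate(ages):
        # voxel mean encodes age directly: learnable by construction
        level = (age - 20) / 50
        voxel = np.clip(level + 0.05 * rng.normal(size=shape), 0, 1.5).astype(np.float32)
        samples.append(Sample(sid=f"S{i:03d}", age=float(age), sex=int(i % 2), voxels={modality: voxel}))
    return samples


class TestTrainLoop:
    def _cfg(self, epochs=4, seed=1):
        return pipeline.desk_train_config(seed=seed, epochs=epochs)

    def test_same_seed_identical_loss_curves(self, tiny_net_config):
        data = _tiny_dataset(12)
        histories = []
        for _ in range(2):
            model = build_model(tiny_net_config)
            _, hist = train(model, data[:9], data[9:], self._cfg())
            histories.append(hist)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].val_loss == histories[1].val_loss

    def test_overfits_eight_subjects(self, tiny_net_config):
        data = _tiny_dataset(10, seed=4)
        model = build_model(tiny_net_config)
        _, hist = train(model, data[:8], data[8:], self._cfg(epochs=30, seed=2))
        assert hist.train_loss[-1] < 0.1 * hist.train_loss[0]

    def test_lr_trace_monotone_and_floored(self, tiny_net_config):
        data = _tiny_dataset(10)
        model = build_model(tiny_net_config)
        _, hist = train(model, data[:8], data[8:], self._cfg(epochs=8))
        assert all(b <= a for a, b in zip(hist.lr, hist.lr[1:]))
        assert min(hist.lr) >= 2e-3

    def test_empty_training_set_rejected(self, tiny_net_config):
        model = build_model(tiny_net_config)
        with pytest.raises(ValueError):
            train(model, [], _tiny_dataset(2), self._cfg())

    def test_divergence_aborts(self, tiny_net_config):
        data = _tiny_dataset(8)
        model = build_model(tiny_net_config)
        cfg = self._cfg(epochs=6)
        cfg.lr = 1e12
        cfg.min_lr = 1e12
        with pytest.raises(TrainingDivergedError):
            train(model, data[:6], data[6:], cfg)

    def test_single_step_reduces_loss_on_fixed_batch(self, tiny_net_config, rng):
        from osteoage import nn

        model = build_model(tiny_net_config)
        model.set_head_bias(45.0)
        shape = tiny_net_config.input_shapes["femur"]
        batch = {
            "femur": rng.uniform(0, 1, size=(8, 1) + shape).astype(np.float32),
            "sex": np.array([0, 1] * 4),
        }
        y = np.linspace(25, 65, 8)
        opt = nn.Adam(model.parameters(), lr=1e-3)
        before = None
        for _ in range(2):
            yhat = model.forward_batch(batch, train=True)
            loss = float(np.mean((y - yhat) ** 2))
            if before is None:
                before = loss
                opt.zero_grad()
                model.backward(((yhat - y) * (2.0 / len(y))).astype(np.float32))
                opt.step()
        assert loss < before


class TestProgressive:
    def test_transfer_beats_fresh_initial_validation(self, tiny_net_config):
        data = _tiny_dataset(14, seed=9)
        tr, va = data[:10], data[10:]
        cfg_small = tiny_net_config
        rung1 = (cfg_small, pipeline.desk_train_config(seed=1, epochs=10))
        model1, hist1, _ = progressive_pretrain([rung1], [(tr, va)])

        # transfer into an identical architecture and compare initial val loss
        from osteoage import nn

        fresh = build_model(cfg_small)
        warm = build_model(cfg_small)
        nn.transfer_parameters(nn.state_dict(model1), warm)
        tcfg = pipeline.desk_train_config(seed=1, epochs=1)
        ages = np.array([s.age for s in va])
        fresh_loss = mse_loss(ages, evaluate(fresh, va, tcfg))
        warm_loss = mse_loss(ages, evaluate(warm, va, tcfg))
        assert warm_loss < fresh_loss

    def test_single_rung_equals_plain_train(self, tiny_net_config):
        data = _tiny_dataset(12, seed=3)
        tr, va = data[:9], data[9:]
        tcfg = pipeline.desk_train_config(seed=4, epochs=3)
        _, hists, logs = progressive_pretrain([(tiny_net_config, tcfg)], [(tr, va)])
        model = build_model(tiny_net_config)
        _, hist = train(model, tr, va, tcfg)
        assert hists[0].train_loss == hist.train_loss
        assert logs == []

    def test_head_reinitialized_when_width_changes(self, tiny_net_config):
        """Toggling the sex branch changes only the head width: convolutions
        transfer, the head keeps its fresh initialization."""
        import dataclasses

        from osteoage import nn

        data = _tiny_dataset(12, seed=5)
        tr, va = data[:9], data[9:]
        cfg2 = dataclasses.replace(tiny_net_config, use_gender=False)
        rungs = [
            (tiny_net_config, pipeline.desk_train_config(seed=1, epochs=2)),
            (cfg2, pipeline.desk_train_config(seed=1, epochs=2)),
        ]
        model, hists, logs = progressive_pretrain(rungs, [(tr, va), (tr, va)])
        assert len(logs) == 1
        assert "head.weight" in logs[0]["skipped"]
        assert any(name.startswith("backbone.") for name in logs[0]["transferred"])

    def test_mismatched_ladder_rejected(self, tiny_net_config):
        with pytest.raises(ValueError, match="transfer mismatch"):
            progressive_pretrain([(tiny_net_config, pipeline.desk_train_config())], [])
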