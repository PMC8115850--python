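"""Network construction, the sex branch, fusion wiring and checkpoints."""

from __future__ import annotations

import numpy as np
import pytest

from osteoage import nn
from osteoage.networks import (
    BACKBONES,
    BasicBlock3d,
    GenderBranch,
    LateFusionEnsemble,
    MiddleFusionModel,
    NetworkConfig,
    build_backbone,
    build_model,
    fuse_late,
    load_checkpoint,
    predict_single,
    resize_volume,
    save_checkpoint,
)

SMALL = (8, 10, 10)


def zero_params(module) -> None:
    for p in module.parameters():
        p.value[...] = 0.0


class TestGenderBranch:
    def test_width_is_32(self, rng):
        out = GenderBranch(rng).forward(np.array([0, 1]))
        assert out.shape == (2, 32)

    def test_invalid_sex_code(self, rng):
        with pytest.raises(ValueError, match="invalid sex code"):
            GenderBranch(rng).forward(np.array([2]))

    def test_zero_weights_give_identical_embeddings(self, rng):
        branch = GenderBranch(rng)
        zero_params(branch)
        out = branch.forward(np.array([0, 1]))
        np.testing.assert_array_equal(out[0], out[1])
        assert not out.any()


class TestLateFusion:
    def test_examples(self):
        assert fuse_late(40.0, 50.0) == 45.0
        assert fuse_late(33.3, 33.3) == 33.3

    def test_matches_mean_oracle_bitwise(self, rng):
        a = rng.uniform(20, 70, size=1000)
        b = rng.uniform(20, 70, size=1000)
        expected = np.array([(x + y) / 2.0 for x, y in zip(a, b)])
        np.testing.assert_array_equal(fuse_late(a, b), expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fuse_late(np.array([np.nan]), np.array([1.0]))


class TestBackbones:
    @pytest.mark.parametrize("name", sorted(BACKBONES))
    def test_forward_finite_scalar_after_head(self, name, rng):
        cfg = NetworkConfig(
            fusion="none",
            modality="femur",
            backbones={"femur": name},
            input_shapes={"femur": SMALL},
            scale=0.0625,
            seed=2,
        )
        model = build_model(cfg)
        batch = {
            "femur": rng.normal(size=(2, 1) + SMALL).astype(np.float32),
            "sex": np.array([0, 1]),
        }
        out = model.predict(batch)
        assert out.shape == (2,)
        assert np.isfinite(out).all()

    def test_seeded_build_is_deterministic(self):
        a = build_backbone("resnet34_3d", SMALL, scale=0.0625, seed=9)
        b = build_backbone("resnet34_3d", SMALL, scale=0.0625, seed=9)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_feature_width_ladder(self):
        r34 = build_backbone("resnet34_3d", SMALL, scale=0.125)
        r50 = build_backbone("resnet50_3d", SMALL, scale=0.125)
        # 8x the base width; bottleneck expansion multiplies by 4 again
        assert r34.feature_width == 8 * 8
        assert r50.feature_width == 4 * r34.feature_width

    def test_basic_block_identity_path(self, rng):
        block = BasicBlock3d(4, 4, (1, 1, 1), rng)
        zero_params(block)
        x = np.abs(rng.normal(size=(2, 4, 6, 6, 6))).astype(np.float32)
        out = block.forward(x, train=False)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_input_too_small(self):
        with pytest.raises(ValueError, match="input too small"):
            build_backbone("resnet34_3d", (1, 10, 10))

    def test_unknown_backbone(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            build_backbone("vgg_3d", SMALL)


class TestHeads:
    def _model(self, rng, seed=4):
        cfg = NetworkConfig(
            fusion="none",
            modality="femur",
            backbones={"femur": "resnet34_3d"},
            input_shapes={"femur": SMALL},
            scale=0.0625,
            seed=seed,
        )
        return build_model(cfg)

    def test_zero_model_predicts_head_bias(self, rng):
        model = self._model(rng)
        zero_params(model)
        model.set_head_bias(47.5)
        batch = {"femur": np.zeros((3, 1) + SMALL, np.float32), "sex": np.array([0, 1, 0])}
        np.testing.assert_allclose(model.predict(batch), 47.5, atol=1e-6)

    def test_head_linearity(self, rng):
        model = self._model(rng)
        batch = {
            "femur": rng.normal(size=(2, 1) + SMALL).astype(np.float32),
            "sex": np.array([0, 1]),
        }
        base = model.predict(batch)
        bias = model.head.b.value.copy()
        model.head.weight.value *= 2.0
        doubled = model.predict(batch)
        np.testing.assert_allclose(doubled - bias, 2.0 * (base - bias), rtol=1e-4)

    def test_deterministic_inference(self, rng):
        model = self._model(rng)
        batch = {
            "femur": rng.normal(size=(2, 1) + SMALL).astype(np.float32),
            "sex": np.array([1, 0]),
        }
        np.testing.assert_array_equal(model.predict(batch), model.predict(batch))

    def test_predict_single_shape_mismatch(self, rng):
        model = self._model(rng)
        with pytest.raises(ValueError, match="shape mismatch"):
            predict_single(model, np.zeros((4, 4, 4), np.float32), 0)


class TestMiddleFusion:
    def _model(self, seed=6):
        cfg = NetworkConfig(
            fusion="middle",
            backbones={"mandible": "resnet34_3d", "femur": "resnet34_3d"},
            input_shapes={"mandible": SMALL, "femur": SMALL},
            scale=0.0625,
            seed=seed,
        )
        return build_model(cfg)

    def test_concat_width(self):
        model = self._model()
        expected = model.bb_m.feature_width + model.bb_f.feature_width + 32
        assert model.head.fin == expected

    def test_zero_head_predicts_bias_regardless_of_input(self, rng):
        model = self._model()
        model.head.weight.value[...] = 0.0
        model.head.b.value[...] = 31.0
        for _ in range(3):
            batch = {
                "mandible": rng.normal(size=(2, 1) + SMALL).astype(np.float32),
                "femur": rng.normal(size=(2, 1) + SMALL).astype(np.float32),
                "sex": np.array([0, 1]),
            }
            np.testing.assert_allclose(model.predict(batch), 31.0)

    def test_permuted_concat_with_permuted_head_weights(self, rng):
        model = self._model()
        batch = {
            "mandible": rng.normal(size=(1, 1) + SMALL).astype(np.float32),
            "femur": rng.normal(size=(1, 1) + SMALL).astype(np.float32),
            "sex": np.array([1]),
        }
        base = model.predict(batch)
        # swap the two modality feature slabs and the matching head columns
        wm, wf = model.bb_m.feature_width, model.bb_f.feature_width
        w = model.head.weight.value
        permuted = np.concatenate([w[:, wm : wm + wf], w[:, :wm], w[:, wm + wf :]], axis=1)
        model.bb_m, model.bb_f = model.bb_f, model.bb_m
        model._children["backbone_mandible"], model._children["backbone_femur"] = (
            model._children["backbone_femur"],
            model._children["backbone_mandible"],
        )
        model.head.weight.value[...] = permuted
        swapped_batch = dict(batch, mandible=batch["femur"], femur=batch["mandible"])
        np.testing.assert_allclose(model.predict(swapped_batch), base, rtol=1e-5)


class TestEarlyFusion:
    def _model(self, seed=8):
        cfg = NetworkConfig(
            fusion="early",
            backbones={"early": "resnet34_3d"},
            input_shapes={"early": SMALL},
            scale=0.0625,
            seed=seed,
        )
        return build_model(cfg)

    def test_finite_scalar(self, rng):
        model = self._model()
        batch = {
            "early": rng.normal(size=(2, 2) + SMALL).astype(np.float32),
            "sex": np.array([0, 0]),
        }
        out = model.predict(batch)
        assert out.shape == (2,) and np.isfinite(out).all()

    def test_channel_swap_symmetry(self, rng):
        model = self._model()
        stem = model.backbone.net.layers[0]
        batch = {
            "early": rng.normal(size=(1, 2) + SMALL).astype(np.float32),
            "sex": np.array([1]),
        }
        base = model.predict(batch)
        stem.weight.value[...] = stem.weight.value[:, ::-1]
        swapped = dict(batch, early=batch["early"][:, ::-1])
        np.testing.assert_allclose(model.predict(swapped), base, rtol=1e-5)

    def test_resize_volume_hits_target_grid(self, rng):
        out = resize_volume(rng.normal(size=(10, 16, 16)).astype(np.float32), (8, 12, 12))
        assert out.shape == (8, 12, 12)


class TestConfigAndCheckpoints:
    def test_fusion_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(fusion="banana").validate()
        with pytest.raises(ValueError):
            NetworkConfig(fusion="none", modality="early").validate()

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = NetworkConfig(
            fusion="none",
            modality="femur",
            backbones={"femur": "squeezenet_3d"},
            input_shapes={"femur": SMALL},
            scale=0.0625,
            seed=3,
        )
        model = build_model(cfg)
        batch = {
            "femur": rng.normal(size=(2, 1) + SMALL).astype(np.float32),
            "sex": np.array([0, 1]),
        }
        before = model.predict(batch)
        save_checkpoint(model, cfg, tmp_path / "model.npz")
        restored, cfg2 = load_checkpoint(tmp_path / "model.npz")
        np.testing.assert_allclose(restored.predict(batch), before, rtol=1e-6)
        assert cfg2.backbones["femur"] == "squeezenet_3d"

    def test_late_ensemble_checkpoint(self, tmp_path, rng):
        cfg = NetworkConfig(
            fusion="late",
            backbones={"mandible": "resnet34_3d", "femur": "resnet34_3d"},
            input_shapes={"mandible": SMALL, "femur": SMALL},
            scale=0.0625,
            seed=1,
        )
        model = build_model(cfg)
        assert isinstance(model, LateFusionEnsemble)
        batch = {
            "mandible": rng.normal(size=(2, 1) + SMALL).astype(np.float32),
            "femur": rng.normal(size=(2, 1) + SMALL).astype(np.float32),
            "sex": np.array([0, 1]),
        }
        before = model.predict(batch)
        save_checkpoint(model, cfg, tmp_path / "late.npz")
        restored, _ = load_checkpoint(tmp_path / "late.npz")
        np.testing.assert_allclose(restored.predict(batch), before, rtol=1e-6)
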