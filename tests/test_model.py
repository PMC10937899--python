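"""Detector architecture contracts: shapes, masking, determinism."""

import numpy as np
import pytest

from cryopick.io import Micrograph
from cryopick.model import (
    ParticleTransformer,
    ModelConfig,
    backbone_forward,
    init_params,
    load_checkpoint,
    model_forward,
    pad_batch,
    project_and_flatten,
    save_checkpoint,
    sine_positional_encoding,
)

TINY = dict(hidden_dim=64, num_queries=20, encoder_layers=2, decoder_layers=2,
            attention_heads=8)


@pytest.fixture(scope="module")
def tiny_params():
    cfg = ModelConfig(backbone_depth=18, **TINY)
    return cfg, init_params(cfg, seed=0)


class TestBackbone:
    def test_depth18_channel_width_and_stride(self, tiny_params):
        cfg, params = tiny_params
        x = np.random.default_rng(0).normal(size=(1, 3, 64, 64)).astype(np.float32)
        feats, sizes = backbone_forward(params, x, None, cfg)
        assert feats.shape == (1, 512, 2, 2)
        assert sizes == [(2, 2)]

    def test_sub32_input_rejected(self, tiny_params):
        cfg, params = tiny_params
        with pytest.raises(ValueError, match="32"):
            backbone_forward(params, np.zeros((1, 3, 16, 16), np.float32),
                             None, cfg)

    def test_non_square_spatial_scaling(self, tiny_params):
        cfg, params = tiny_params
        x = np.zeros((1, 3, 96, 64), np.float32)
        feats, _ = backbone_forward(params, x, None, cfg)
        assert feats.shape == (1, 512, 3, 2)


class TestProjection:
    def test_token_count_and_width(self, tiny_params):
        cfg, params = tiny_params
        feats = np.random.default_rng(1).normal(
            size=(1, 512, 2, 2)).astype(np.float32)
        tokens = project_and_flatten(params, feats)
        assert tokens.shape == (1, 4, 64)

    def test_identity_projection_recovers_flattened_input(self):
        cfg = ModelConfig(backbone_depth=18, **TINY)
        params = init_params(cfg, seed=0)
        d = 64
        feats = np.random.default_rng(2).normal(size=(1, d, 3, 3)).astype(
            np.float32)
        params = dict(params)
        params["proj"] = {"w": np.eye(d, dtype=np.float32).reshape(d, d, 1, 1)}
        tokens = np.asarray(project_and_flatten(params, feats))
        np.testing.assert_allclose(
            tokens[0], feats[0].reshape(d, 9).T, atol=1e-6)


class TestPositionalEncoding:
    def test_distinct_positions_distinct_codes(self):
        mask = np.ones((1, 4, 5))
        pos = sine_positional_encoding(mask, 64)
        flat = pos.reshape(-1, 64)
        assert len({tuple(np.round(r, 6)) for r in flat}) == 20

    def test_deterministic(self):
        mask = np.ones((1, 3, 3))
        np.testing.assert_array_equal(
            sine_positional_encoding(mask, 32),
            sine_positional_encoding(mask, 32))

    def test_sin_cos_pairs_unit_norm(self):
        mask = np.ones((1, 2, 2))
        pos = sine_positional_encoding(mask, 64)[0, 1, 1]
        pairs = pos.reshape(-1, 2)
        np.testing.assert_allclose((pairs**2).sum(axis=1), 1.0, atol=1e-6)


class TestForward:
    def test_fixed_size_prediction_set(self, tiny_params):
        cfg, params = tiny_params
        x = np.random.default_rng(3).normal(size=(1, 3, 64, 64)).astype(
            np.float32)
        out = model_forward(params, cfg, x)
        assert out["boxes"].shape == (1, 20, 4)
        assert out["class_probs"].shape == (1, 20, 2)
        np.testing.assert_allclose(
            np.asarray(out["class_probs"]).sum(-1), 1.0, atol=1e-6)
        boxes = np.asarray(out["boxes"])
        assert boxes.min() >= 0.0 and boxes.max() <= 1.0

    def test_eval_forward_deterministic(self, tiny_params):
        cfg, params = tiny_params
        x = np.random.default_rng(4).normal(size=(1, 3, 64, 64)).astype(
            np.float32)
        a = model_forward(params, cfg, x)
        b = model_forward(params, cfg, x)
        np.testing.assert_array_equal(np.asarray(a["boxes"]),
                                      np.asarray(b["boxes"]))

    def test_query_permutation_equivariance(self, tiny_params):
        cfg, params = tiny_params
        x = np.random.default_rng(5).normal(size=(1, 3, 64, 64)).astype(
            np.float32)
        ref = model_forward(params, cfg, x)
        perm = np.random.default_rng(6).permutation(cfg.num_queries)
        p2 = dict(params)
        p2["query_embed"] = params["query_embed"][perm]
        out = model_forward(p2, cfg, x)
        np.testing.assert_allclose(np.asarray(out["boxes"])[0],
                                   np.asarray(ref["boxes"])[0][perm], atol=1e-4)


class TestPadBatch:
    def test_max_shape_and_masks(self):
        a = np.ones((100, 100), np.float32)
        b = np.ones((120, 80), np.float32)
        batch, sizes, mask = pad_batch([a, b])
        assert batch.shape == (2, 3, 120, 100)
        assert sizes == [(100, 100), (120, 80)]
        assert mask[0, :100, :100].all() and not mask[0, 100:, :].any()
        assert mask[1, :, :80].all() and not mask[1, :, 80:].any()

    def test_single_image_no_padding(self):
        a = np.ones((64, 64), np.float32)
        batch, sizes, mask = pad_batch([a])
        assert batch.shape == (1, 3, 64, 64)
        assert mask.all()

    def test_padded_batch_matches_unbatched_prediction(self, tiny_params):
        cfg, params = tiny_params
        rng = np.random.default_rng(7)
        small = rng.normal(size=(64, 64)).astype(np.float32)
        large = rng.normal(size=(96, 96)).astype(np.float32)
        batch1, sizes1, _ = pad_batch([small])
        alone = model_forward(params, cfg, batch1, sizes1)
        batch, sizes, _ = pad_batch([small, large])
        together = model_forward(params, cfg, batch, sizes)
        np.testing.assert_allclose(
            np.asarray(together["boxes"])[0], np.asarray(alone["boxes"])[0],
            atol=1e-4)
        np.testing.assert_allclose(
            np.asarray(together["class_probs"])[0],
            np.asarray(alone["class_probs"])[0], atol=1e-4)


class TestCheckpoint:
    def test_round_trip_identical_weights(self, tmp_path, tiny_params):
        cfg, params = tiny_params
        model = ParticleTransformer(cfg, params=params)
        save_checkpoint(tmp_path / "ck.npz", model, extra={"epoch": 3})
        back, extra = load_checkpoint(tmp_path / "ck.npz")
        assert extra["epoch"] == 3
        assert back.config == cfg
        from cryopick.nn.optim import tree_flatten

        for (n1, l1), (n2, l2) in zip(tree_flatten(model.params),
                                      tree_flatten(back.params)):
            assert n1 == n2
            np.testing.assert_array_equal(l1, l2)


class TestConfigValidation:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(hidden_dim=65, attention_heads=8)

    def test_unknown_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            ModelConfig(backbone_depth=20)
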