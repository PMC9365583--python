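"""Architecture contracts: census, parameter count, shapes, determinism."""

import numpy as np
import pytest

import lodoct as L
from lodoct import autodiff as ad
from lodoct.errors import ShapeError
from lodoct.network import ImprovedResidualDenseBlock

from conftest import tiny_network_config


def closed_form_parameter_count(cfg: L.NetworkConfig) -> int:
    """Independent hand count: sum (out*in*k*k + out) per conv layer plus
    2 * channels per batch norm, following the block structure."""

    def conv(out_ch, in_ch, k):
        return out_ch * in_ch * k * k + out_ch

    c, g, d, b = (
        cfg.stem_channels,
        cfg.growth_channels,
        cfg.dense_layers_per_block,
        cfg.bottleneck_channels,
    )
    n = conv(c, 1, 7)  # stem
    per_block = sum(conv(g, c + i * g, 3) for i in range(d))  # dense chain
    per_block += conv(b, c + d * g, 1)  # local fusion
    if cfg.use_irdb:
        per_block += 2 * conv(b, b, 3)  # enhanced residual
    per_block += conv(c, b, 1)  # projection
    n += cfg.n_levels * per_block
    per_decoder = conv(cfg.decoder_channels, 2 * c, 5) + 2 * cfg.decoder_channels
    per_decoder += conv(c, cfg.decoder_channels, 1) + 2 * c
    n += cfg.n_levels * per_decoder
    n += conv(1, c, 1)  # head
    return n


class TestBuildModel:
    def test_default_census_matches_design(self):
        census = L.layer_census(L.build_model(seed=0))
        assert census == {
            "stem_convolutions": 1,
            "max_pools": 4,
            "irdb_blocks": 4,
            "upsamplings": 4,
            "deconvolutions": 8,
            "head_kernel": 1,
            "head_channels": 1,
        }

    def test_parameter_count_matches_hand_count(self):
        cfg = L.NetworkConfig(
            stem_channels=4,
            growth_channels=4,
            dense_layers_per_block=2,
            bottleneck_channels=12,
            n_levels=2,
            decoder_channels=8,
        )
        model = L.build_model(cfg, seed=0)
        assert L.count_parameters(model) == closed_form_parameter_count(cfg)

    def test_parameter_count_without_irdb(self):
        cfg = tiny_network_config(use_irdb=False)
        model = L.build_model(cfg, seed=0)
        assert L.count_parameters(model) == closed_form_parameter_count(cfg)

    def test_test_scale_model_is_small(self):
        assert L.count_parameters(L.build_model(tiny_network_config(), seed=0)) <= 50_000

    def test_seeded_build_determinism(self):
        m1 = L.build_model(tiny_network_config(), seed=3)
        m2 = L.build_model(tiny_network_config(), seed=3)
        for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_gaussian_init_statistics(self):
        model = L.build_model(L.NetworkConfig(), seed=0)
        stem = model.stem.weight.data
        assert abs(stem.std() - 0.1) < 0.02  # variance 0.01
        assert not model.stem.bias.data.any()


class TestForward:
    @pytest.mark.parametrize("size", [32, 64])
    def test_output_shape_equals_input_shape(self, tiny_model, size):
        x = np.random.default_rng(0).uniform(0, 1, (1, 1, size, size))
        assert tiny_model(x).shape == x.shape

    def test_indivisible_size_names_divisor(self, tiny_model):
        with pytest.raises(ShapeError, match="divisible by 4"):
            tiny_model(np.zeros((1, 1, 30, 30)))

    def test_eval_forward_is_deterministic(self, tiny_model):
        x = np.random.default_rng(1).uniform(0, 1, (1, 1, 32, 32))
        np.testing.assert_array_equal(tiny_model(x).data, tiny_model(x).data)

    def test_finite_output(self, tiny_model):
        x = np.random.default_rng(2).uniform(0, 1, (2, 1, 32, 32))
        assert np.isfinite(tiny_model(x).data).all()


class TestIrdb:
    def _block(self, use_irdb=True, seed=0):
        cfg = L.NetworkConfig(
            stem_channels=4,
            growth_channels=4,
            dense_layers_per_block=2,
            bottleneck_channels=12,
            n_levels=1,
            decoder_channels=8,
            use_irdb=use_irdb,
        )
        return ImprovedResidualDenseBlock(4, cfg, np.random.default_rng(seed))

    def test_channels_preserved(self):
        block = self._block()
        x = ad.Tensor(np.random.default_rng(3).normal(size=(1, 4, 8, 8)))
        assert block(x).shape == (1, 4, 8, 8)

    def test_zero_input_zero_weights_gives_zero(self):
        block = self._block()
        for p in block.parameters():
            p.data[...] = 0.0
        x = ad.Tensor(np.zeros((1, 4, 8, 8)))
        assert not block(x).data.any()

    def test_zeroed_enhanced_residual_leaves_input_plus_dense_path(self):
        block = self._block(seed=5)
        block.eres1.weight.data[...] = 0.0
        block.eres1.bias.data[...] = 0.0
        block.eres2.weight.data[...] = 0.0
        block.eres2.bias.data[...] = 0.0
        x = ad.Tensor(np.random.default_rng(6).normal(size=(1, 4, 8, 8)))
        out = block(x)
        # dense path alone: replay the chain without the residual sub-block
        feats = x
        for conv in block.dense:
            feats = ad.concat_channels(feats, ad.relu(conv(feats)))
        dense_out = block.project(ad.relu(block.fuse(feats)))
        np.testing.assert_allclose(out.data, x.data + dense_out.data, atol=1e-12)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            self._block()(ad.Tensor(np.zeros((1, 3, 8, 8))))


class TestTrainingStep:
    def test_single_step_decreases_composite_loss(self, sim_pair):
        """Gradient flow: one small Adam step lowers the loss on one pair."""
        from lodoct.nn import Adam

        model = L.build_model(tiny_network_config(), seed=2)
        model.train()
        x = sim_pair.ldct[None, None]
        y = sim_pair.ndct[None, None]
        opt = Adam(model.parameters(), lr=1e-4)
        loss0, _ = L.composite_loss(model(x), y, ms_params=L.MsSsimParams(n_scales=3))
        loss0.backward()
        opt.step()
        model.eval()
        loss1, _ = L.composite_loss(model(x), y, ms_params=L.MsSsimParams(n_scales=3))
        assert loss1.item() < loss0.item()


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_config(self, tmp_path, tiny_model):
        path = tmp_path / "model.ckpt"
        L.save_checkpoint(path, tiny_model, rng_state={"epoch": 3})
        restored, rng_state = L.load_checkpoint(path)
        assert rng_state == {"epoch": 3}
        assert restored.config == tiny_model.config
        x = np.random.default_rng(4).uniform(0, 1, (1, 1, 32, 32))
        np.testing.assert_array_equal(
            restored.eval()(x).data, tiny_model(x).data
        )
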