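"""The mask-guided correction mechanism and two-phase training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lodoct as L
from lodoct.errors import ConfigurationError, ShapeError
from lodoct.local_filter import _stack

from conftest import scaled_down_run_config, simulate_dataset, tiny_network_config

MS3 = L.MsSsimParams(n_scales=3)


class TestDifferenceImage:
    def test_identical_images_give_zero(self):
        x = np.random.default_rng(0).uniform(0, 1, (8, 8))
        assert not L.difference_image(x, x).any()

    def test_constants(self):
        d = L.difference_image(np.ones((4, 4)), np.full((4, 4), 0.25))
        np.testing.assert_allclose(d, 0.75)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, (8, 8)), rng.uniform(0, 1, (8, 8))
        np.testing.assert_array_equal(L.difference_image(a, b), -L.difference_image(b, a))

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            L.difference_image(np.zeros((4, 4)), np.zeros((4, 5)))


class TestMakeMask:
    def test_huge_threshold_blanks_mask(self):
        d = np.random.default_rng(2).normal(0, 0.1, (8, 8))
        assert not L.make_mask(d, np.abs(d).max() + 1).mask.any()

    def test_zero_threshold_keeps_all_nonzero_pixels(self):
        d = np.full((4, 4), 0.2)
        assert L.make_mask(d, 0.0).mask.all()

    def test_elementwise_absolute_threshold(self):
        d = np.array([[0.05, 0.01], [-0.06, 0.0]])
        np.testing.assert_array_equal(L.make_mask(d, 0.04).mask, [[1, 0], [1, 0]])

    def test_ties_are_filtered(self):
        d = np.array([[0.04, 0.05]])
        np.testing.assert_array_equal(L.make_mask(d, 0.04).mask, [[0, 1]])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            L.make_mask(np.zeros((2, 2)), -0.1)


class TestApplyMask:
    def test_all_one_mask_is_identity(self):
        x = np.random.default_rng(3).uniform(0, 1, (8, 8))
        np.testing.assert_array_equal(L.apply_mask(x, L.MaskImage(np.ones((8, 8)))), x)

    def test_all_zero_mask_blanks_image(self):
        x = np.random.default_rng(4).uniform(0, 1, (8, 8))
        assert not L.apply_mask(x, L.MaskImage(np.zeros((8, 8)))).any()

    def test_elementwise_product(self):
        img = np.array([[0.2, 0.4], [0.6, 0.8]])
        mask = L.MaskImage(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_array_equal(
            L.apply_mask(img, mask), [[0.2, 0.0], [0.0, 0.8]]
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.2))
    def test_mask_idempotence(self, seed, threshold):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (8, 8))
        mask = L.make_mask(rng.normal(0, 0.1, (8, 8)), threshold)
        once = L.apply_mask(img, mask)
        np.testing.assert_array_equal(L.apply_mask(once, mask), once)


class TestMechanismStep:
    def test_all_pass_identity_in_eval_mode(self, tiny_model, sim_pair):
        """Threshold 0 on strictly nonzero differences: the correction pass
        sees the very same input, so I2 == I1 bitwise and total = 2x original."""
        res = L.mechanism_step(tiny_model, sim_pair, L.MechanismConfig(threshold=0.0),
                               ms_params=MS3)
        assert np.abs(res.difference).min() > 0.0  # premise: strictly nonzero
        assert res.mask.mask.all()
        np.testing.assert_array_equal(res.filtered_denoised, res.denoised)
        assert res.total == 2.0 * res.original_loss
        assert res.correction_loss == res.original_loss

    def test_blanking_threshold_zeroes_filtered_images(self, tiny_model, sim_pair):
        big = float(np.abs(
            L.difference_image(sim_pair.ndct, tiny_model.denoise(sim_pair.ldct))
        ).max()) + 1.0
        res = L.mechanism_step(tiny_model, sim_pair, L.MechanismConfig(threshold=big),
                               ms_params=MS3)
        assert not res.mask.mask.any()
        assert not res.filtered_ldct.any() and not res.filtered_ndct.any()
        assert res.total == pytest.approx(res.original_loss + res.correction_loss)

    def test_losses_recomputable_from_intermediates(self, tiny_model, sim_pair):
        res = L.mechanism_step(tiny_model, sim_pair, L.MechanismConfig(threshold=0.04),
                               ms_params=MS3)
        orig, _ = L.composite_loss(res.denoised, sim_pair.ndct[None], ms_params=MS3)
        corr, _ = L.composite_loss(res.filtered_denoised, res.filtered_ndct, ms_params=MS3)
        assert res.original_loss == pytest.approx(orig.item(), rel=1e-12)
        assert res.correction_loss == pytest.approx(corr.item(), rel=1e-12)
        assert res.total == pytest.approx(orig.item() + corr.item(), rel=1e-12)
        np.testing.assert_array_equal(
            res.filtered_ldct, sim_pair.ldct[None] * res.mask.mask
        )
        np.testing.assert_array_equal(
            res.filtered_ndct, sim_pair.ndct[None] * res.mask.mask
        )

    def test_gradient_coupling(self, sim_pair):
        """A partial mask changes the parameter gradient vs. mechanism off."""
        def grads(with_mechanism):
            model = L.build_model(tiny_network_config(), seed=9)
            model.train()
            if with_mechanism:
                res = L.mechanism_step(model, sim_pair,
                                       L.MechanismConfig(threshold=0.04), ms_params=MS3)
                res.loss_graph.backward()
            else:
                l1, n1 = _stack(sim_pair)
                loss, _ = L.composite_loss(model(l1), n1, ms_params=MS3)
                loss.backward()
            return np.concatenate([p.grad.ravel() for p in model.parameters()])

        model = L.build_model(tiny_network_config(), seed=9).eval()
        res = L.mechanism_step(model, sim_pair, L.MechanismConfig(threshold=0.04),
                               ms_params=MS3)
        frac = res.mask.retained_fraction
        assert 0.0 < frac < 1.0  # mask is partial on this seeded case
        assert np.abs(grads(True) - grads(False)).max() > 1e-9


class TestThresholdScan:
    def test_zero_threshold_retains_everything(self, tiny_model, sim_pair):
        table = L.threshold_scan(tiny_model, [sim_pair], [0.0])
        assert table.retained_fraction.iloc[0] == 1.0

    def test_monotone_non_increasing_over_grid(self, tiny_model):
        pairs = simulate_dataset(4, 30, 40)
        table = L.threshold_scan(tiny_model, pairs, [0.01, 0.04, 0.07, 0.10])
        fracs = table.retained_fraction.to_numpy()
        assert (np.diff(fracs) <= 0).all()

    def test_dumps_panels(self, tiny_model, sim_pair, tmp_path):
        L.threshold_scan(tiny_model, [sim_pair], [0.04], dump_dir=tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert {"difference_t0p04.png", "mask_t0p04.png",
                "filtered_ldct_t0p04.png", "filtered_ndct_t0p04.png"} <= names

    def test_empty_inputs_rejected(self, tiny_model, sim_pair):
        with pytest.raises(ConfigurationError):
            L.threshold_scan(tiny_model, [sim_pair], [])
        with pytest.raises(ConfigurationError):
            L.threshold_scan(tiny_model, [], [0.04])

    def test_suggest_threshold_prefers_band(self, tiny_model):
        pairs = simulate_dataset(4, 30, 40)
        table = L.threshold_scan(tiny_model, pairs, [0.01, 0.04, 0.07, 0.10])
        t = L.suggest_threshold(table)
        row = table[table.threshold == t].iloc[0]
        in_band = (table.retained_fraction >= 0.05) & (table.retained_fraction <= 0.20)
        if in_band.any():
            assert row.retained_fraction <= 0.20
            assert t == table.threshold[in_band].min()


class TestTrain:
    def test_descent_smoke(self, sim_pair):
        """Two pretraining epochs on one pair: epoch-2 loss <= epoch-1 loss."""
        run = scaled_down_run_config()
        run.mechanism.pretrain_epochs = 2
        run.mechanism.mechanism_epochs = 0
        run.trainer.batch_size = 1
        model = L.build_model(run.network, seed=4)
        _, log = L.train(model, [sim_pair], run)
        assert log.loss_total.iloc[1] <= log.loss_total.iloc[0]

    def test_mechanism_disabled_degenerates_to_pretraining(self, sim_pair):
        run = scaled_down_run_config()
        run.mechanism = L.MechanismConfig(
            threshold=0.04, enabled=False, pretrain_epochs=1, mechanism_epochs=1
        )
        run.trainer.batch_size = 1
        model = L.build_model(run.network, seed=4)
        _, log = L.train(model, [sim_pair], run)
        # phase 2 logs no correction loss when the mechanism is off
        assert log.loss_correction.iloc[1] == 0.0
        assert (log.phase == ["pretrain", "mechanism"]).all()

    def test_empty_dataset_rejected(self):
        run = scaled_down_run_config()
        model = L.build_model(run.network, seed=4)
        with pytest.raises(ConfigurationError):
            L.train(model, [], run)

    def test_writes_log_and_checkpoint(self, sim_pair, tmp_path):
        run = scaled_down_run_config()
        run.mechanism.pretrain_epochs = 1
        run.mechanism.mechanism_epochs = 1
        run.trainer.batch_size = 1
        model = L.build_model(run.network, seed=4)
        L.train(model, [sim_pair], run, out_dir=tmp_path)
        assert (tmp_path / "training_log.csv").exists()
        restored, _ = L.load_checkpoint(tmp_path / "model.ckpt")
        x = sim_pair.ldct[None, None]
        np.testing.assert_array_equal(restored.eval()(x).data, model.eval()(x).data)

    def test_learning_rate_drop_applied(self, sim_pair):
        run = scaled_down_run_config()
        run.mechanism.pretrain_epochs = 1
        run.mechanism.mechanism_epochs = 3
        run.trainer.lr_drop_epoch = 2
        run.trainer.batch_size = 1
        model = L.build_model(run.network, seed=4)
        _, log = L.train(model, [sim_pair], run)
        mech = log[log.phase == "mechanism"].reset_index()
        assert mech.lr.iloc[0] == run.trainer.learning_rate
        assert (mech.lr.iloc[1:] == run.trainer.lr_after_drop).all()
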