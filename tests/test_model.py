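import numpy as np
import pytest

from ramanprep.io import PairCollection, Spectrum, TrainingPair, ValidationError, WavenumberAxis
from ramanprep.model import (
    ModelConfig,
    PatchesConfig,
    SpectralPreprocessor,
    TrainedPreprocessor,
    estimate_background,
    forward_preprocess,
    loss_background,
    loss_total,
    make_patches,
    overlap_average,
    train_model,
)


def _pair_collection(n=16, L=128, rng=None, background="mixed"):
    rng = rng or np.random.default_rng(0)
    ax = WavenumberAxis(np.linspace(400, 1800, L))
    pairs = []
    for _ in range(n):
        y = np.zeros(L)
        for _ in range(3):
            c = rng.integers(10, L - 10)
            y += rng.uniform(0.3, 1.0) * np.exp(-0.5 * ((np.arange(L) - c) / 3.0) ** 2)
        if background == "constant":
            x = y + 5.0
        else:
            x = y + rng.uniform(0.5, 2.0) * np.linspace(1, 2, L) + 0.05 * rng.standard_normal(L)
        pairs.append(TrainingPair(x, y))
    return PairCollection(ax, pairs, {"mode": "test"})


def _tiny_cfg(**kw):
    defaults = dict(grid_len=128, base_channels=4, epochs_be=2, epochs_full=3,
                    batch=4, seed=0, patches=PatchesConfig(window=32, step=16))
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestPatches:
    def test_enumerated_patch_starts(self):
        x = np.arange(16.0)
        cfg = PatchesConfig(window=8, step=4)
        patches = make_patches(x, cfg)
        assert patches.shape == (3, 8)
        np.testing.assert_array_equal(patches[0], x[0:8])
        np.testing.assert_array_equal(patches[1], x[4:12])
        np.testing.assert_array_equal(patches[2], x[8:16])

    def test_whole_signal_single_patch(self):
        x = np.arange(16.0)
        cfg = PatchesConfig(window=16, step=16)
        patches = make_patches(x, cfg)
        assert patches.shape == (1, 16)
        np.testing.assert_array_equal(patches[0], x)

    def test_overlap_average_inverts_exactly(self, rng):
        x = rng.standard_normal(100)
        cfg = PatchesConfig(window=16, step=8)
        rec = overlap_average(make_patches(x, cfg), len(x), cfg)
        assert np.max(np.abs(rec - x)) <= 1e-12

    def test_replication_padding_on_ragged_length(self):
        x = np.arange(20.0)
        cfg = PatchesConfig(window=8, step=3)
        patches = make_patches(x, cfg)
        assert patches[-1][-1] == x[-1]
        rec = overlap_average(patches, len(x), cfg)
        np.testing.assert_allclose(rec, x, atol=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            PatchesConfig(window=4, step=8)
        with pytest.raises(ValidationError):
            make_patches(np.arange(4.0), PatchesConfig(window=8, step=4))


class TestLosses:
    def test_background_loss_zero_at_target(self, rng):
        x, y = rng.standard_normal(32), rng.standard_normal(32)
        assert loss_background(x, y, x - y) == 0.0

    def test_huber_branch_values(self):
        # single point, r = 0.5 -> 0.125 ; r = 2 -> 1.5
        assert loss_background([0.5], [0.0], [1.0]) == pytest.approx(0.125)
        assert loss_background([2.0], [0.0], [4.0]) == pytest.approx(1.5)

    def test_total_loss_weighted_identity(self):
        # lambda=0.2, mean reconstruction term 1.0, L_BE = 0.5 -> 0.6
        # single point: |P - y| = 1.5 -> z = 1.0 ; |B - (x-y)| = 1 -> L_BE = 0.5
        x, y = [10.0], [2.0]
        bx = [9.0]  # x - y = 8, r = 1 -> 0.5
        px = [3.5]  # r = 1.5 -> 1.0
        assert loss_total(x, y, bx, px, lam=0.2) == pytest.approx(0.2 * 1.0 + 0.8 * 0.5)

    def test_total_loss_zero_when_both_targets_met(self, rng):
        x, y = rng.standard_normal(16), rng.standard_normal(16)
        for lam in (0.0, 0.2, 1.0):
            assert loss_total(x, y, x - y, y, lam=lam) == 0.0

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            loss_total([1.0], [1.0], [0.0], [1.0], lam=1.5)


class TestArchitecture:
    def test_stage_shape_trace_1024_c4(self):
        cfg = ModelConfig(grid_len=1024, base_channels=4, seed=0)
        net = SpectralPreprocessor(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal(1024)
        _, trace = forward_preprocess(x, net, want_trace=True)
        stages = {name: (c, l) for name, c, l in trace}
        assert stages["stem"] == (16, 256)
        assert stages["reduction_a"] == (32, 128)
        assert stages["reduction_b"] == (64, 64)
        assert stages["output"] == (1, 1024)

    def test_inception_stages_preserve_dimensions(self):
        cfg = ModelConfig(grid_len=1024, base_channels=4, seed=0)
        net = SpectralPreprocessor(cfg, np.random.default_rng(0))
        _, trace = forward_preprocess(np.zeros(1024), net, want_trace=True)
        stages = {name: (c, l) for name, c, l in trace}
        assert stages["inception_a"] == stages["stem"]
        assert stages["inception_b"] == stages["reduction_a"]
        assert stages["inception_c"] == stages["reduction_b"]

    def test_grid_not_divisible_by_16_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(grid_len=100)

    def test_untrained_background_estimate_is_zero(self):
        cfg = _tiny_cfg()
        net = SpectralPreprocessor(cfg, np.random.default_rng(0))
        x = np.random.default_rng(2).standard_normal(128)
        np.testing.assert_array_equal(estimate_background(x, net), 0.0)

    def test_output_length_matches_input_for_random_x(self, rng):
        net = SpectralPreprocessor(_tiny_cfg(), np.random.default_rng(0))
        p = forward_preprocess(rng.standard_normal(128), net)
        assert p.shape == (128,)
        assert np.all(np.isfinite(p))


class TestTraining:
    def test_smoke_training_contract(self, tmp_path):
        pairs = _pair_collection(16, 128)
        model = train_model(pairs, _tiny_cfg())
        assert len(model.losses["be"]) == 2
        assert len(model.losses["full"]) == 3
        assert all(np.isfinite(v) for v in model.losses["full"])
        path = tmp_path / "model.npz"
        model.save(path)
        back = TrainedPreprocessor.load(path)
        x = np.random.default_rng(3).standard_normal(128)
        np.testing.assert_array_equal(forward_preprocess(x, back), forward_preprocess(x, model))

    def test_same_seed_identical_losses(self):
        pairs = _pair_collection(16, 128)
        m1 = train_model(pairs, _tiny_cfg())
        m2 = train_model(pairs, _tiny_cfg())
        assert m1.losses == m2.losses

    def test_constant_background_pairs_improve_over_raw(self):
        """On x = y + 5 pairs the trained model must beat the identity."""
        train = _pair_collection(32, 128, np.random.default_rng(5), background="constant")
        held = _pair_collection(8, 128, np.random.default_rng(6), background="constant")
        model = train_model(train, _tiny_cfg(epochs_be=6, epochs_full=10))
        X = held.x_matrix()
        Y = held.y_matrix()
        P = model._grid_apply(X)
        rmse_model = np.sqrt(np.mean((P - Y) ** 2, axis=1))
        rmse_raw = np.sqrt(np.mean((X - Y) ** 2, axis=1))
        assert np.median(rmse_model) < np.median(rmse_raw)

    def test_be_pretraining_loss_decreases_on_constant_background(self):
        pairs = _pair_collection(32, 128, np.random.default_rng(7), background="constant")
        model = train_model(pairs, _tiny_cfg(epochs_be=6, epochs_full=1))
        be = model.losses["be"]
        assert be[-1] < be[0]

    def test_too_few_pairs_rejected(self):
        pairs = _pair_collection(6, 128)
        with pytest.raises(ValidationError, match="2\\*batch"):
            train_model(pairs, _tiny_cfg(batch=4))

    def test_grid_mismatch_rejected(self):
        pairs = _pair_collection(16, 128)
        with pytest.raises(ValidationError, match="grid"):
            train_model(pairs, _tiny_cfg(grid_len=256, patches=PatchesConfig(window=32, step=16)))


@pytest.fixture(scope="module")
def trained():
    return train_model(_pair_collection(16, 128), _tiny_cfg())


class TestPreprocessApplication:

    def test_output_on_native_axis(self, trained, rng):
        ax = WavenumberAxis(np.linspace(500, 1700, 200))  # different axis than the grid
        s = Spectrum(ax, rng.uniform(0, 1, 200))
        out = trained.preprocess(s)
        np.testing.assert_array_equal(out.axis.values, ax.values)
        assert "model_hash" in out.meta

    def test_scale_consistency_under_max_normalization(self, trained, rng):
        ax = WavenumberAxis(np.linspace(400, 1800, 128))
        x = rng.uniform(0.1, 1.0, 128)
        outs = [trained.preprocess(Spectrum(ax, c * x)).intensity for c in (0.5, 1.0, 2.0)]
        np.testing.assert_allclose(outs[0] * 2, outs[1], rtol=2e-5, atol=1e-7)
        np.testing.assert_allclose(outs[2], outs[1] * 2, rtol=2e-5, atol=1e-7)

    def test_batch_order_preserved(self, trained, rng):
        ax = WavenumberAxis(np.linspace(400, 1800, 128))
        spectra = [Spectrum(ax, rng.uniform(0, 1, 128)) for _ in range(10)]
        batch = trained.preprocess_batch(spectra)
        singles = [trained.preprocess(s) for s in spectra]
        for b, s in zip(batch, singles):
            np.testing.assert_allclose(b.intensity, s.intensity, atol=1e-6)
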