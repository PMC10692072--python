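"""Multi-Otsu baseline, U-Net harness and volume monitoring."""

import itertools

import numpy as np
import pytest

from orgamri import (
    ModelArtifact,
    PhantomSpec,
    TrainConfig,
    VolumeImage,
    dice,
    generate_cohort,
    generate_phantom,
    minmax_normalize,
    multi_otsu_segment,
    multi_otsu_thresholds,
    predict_mask,
    train_unet3d,
    volume_curve,
)


def _between_class_variance(values, thresholds):
    """Brute-force objective: weighted between-class variance of the split.

    Class assignment follows the digitize convention (a value equal to a
    threshold belongs to the upper class), matching how Multi-Otsu
    thresholds are applied to images.
    """
    classes = np.digitize(values, thresholds)
    total_mean = values.mean()
    bcv = 0.0
    for k in range(len(thresholds) + 1):
        cls = values[classes == k]
        if cls.size:
            w = cls.size / values.size
            bcv += w * (cls.mean() - total_mean) ** 2
    return bcv


class TestMultiOtsu:
    def test_thresholds_match_exhaustive_search_on_64_bins(self, rng):
        """Multi-Otsu thresholds maximize between-class variance: compare
        against exhaustive search over all 64-bin threshold pairs."""
        for _ in range(5):
            # three-population sample quantized to 64 integer levels, so the
            # 64-bin histogram represents the data exactly
            vals = np.concatenate([
                rng.normal(10, 2, 400), rng.normal(30, 3, 300), rng.normal(52, 2, 300),
            ])
            vals = np.clip(np.round(vals), 0, 63).astype(int)
            counts = np.bincount(vals, minlength=64)
            best = -1.0
            for t1, t2 in itertools.combinations(range(1, 64), 2):
                bcv = _between_class_variance(vals, (t1, t2))
                best = max(best, bcv)
            got = multi_otsu_thresholds(n_classes=3, hist=(counts, np.arange(64)))
            got_bcv = _between_class_variance(vals, got + 0.5)  # centers -> digitize cut
            assert got_bcv == pytest.approx(best, rel=1e-9)

    def test_noise_free_phantom_dice(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), organoid_radius_vox=10.0,
                           noise_sigma=0.0, seed=1)
        s = generate_phantom(spec)
        pred = multi_otsu_segment(minmax_normalize(s.volume))
        assert dice(s.organoid_mask, pred) >= 0.90

    def test_noisy_phantom_dice_still_high(self, noncystic_sample):
        pred = multi_otsu_segment(minmax_normalize(noncystic_sample.volume))
        assert dice(noncystic_sample.organoid_mask, pred) >= 0.85

    def test_two_value_volume_rejected(self):
        v = VolumeImage(np.where(np.arange(64).reshape(4, 4, 4) < 32, 0.0, 1.0))
        with pytest.raises(ValueError, match="distinct values"):
            multi_otsu_segment(v)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            multi_otsu_segment(VolumeImage(np.full((4, 4, 4), 2.0)))


class TestTrainConfig:
    def test_zero_loss_weights_rejected(self):
        with pytest.raises(ValueError, match="loss weight"):
            TrainConfig(bce_weight=0.0, dice_weight=0.0)

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            TrainConfig(iterations=0)

    def test_defaults_follow_training_protocol(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 1e-3
        assert cfg.weight_decay == 1e-7
        assert cfg.iterations == 2000
        assert cfg.batch_size == 1
        assert (cfg.bce_weight, cfg.dice_weight) == (1.0, 10.0)


@pytest.fixture(scope="module")
def overfit_artifact():
    """Tiny overfit run on a single 32³ phantom (shared across tests)."""
    spec = PhantomSpec(grid_shape=(32, 32, 32), organoid_radius_vox=7.0, seed=31)
    s = generate_phantom(spec)
    v = minmax_normalize(s.volume)
    cfg = TrainConfig(iterations=120, model_scale=0.25, seed=2, val_every=40)
    art = train_unet3d([(v, s.organoid_mask)], [(v, s.organoid_mask)], cfg)
    return art, v, s


class TestUnetHarness:
    def test_overfit_single_phantom(self, overfit_artifact):
        art, v, s = overfit_artifact
        pred = predict_mask(art, v)
        assert dice(s.organoid_mask, pred) >= 0.95

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty training"):
            train_unet3d([], [], TrainConfig(iterations=1))

    def test_fixed_seed_reproduces_loss_trajectory(self, noncystic_sample):
        v = minmax_normalize(noncystic_sample.volume)
        pairs = [(v, noncystic_sample.organoid_mask)]
        cfg = TrainConfig(iterations=8, model_scale=0.25, seed=9, val_every=100)
        a = train_unet3d(pairs, [], cfg)
        b = train_unet3d(pairs, [], cfg)
        assert a.loss_history == b.loss_history

    def test_artifact_roundtrip_identical_prediction(self, tmp_path, overfit_artifact):
        art, v, _ = overfit_artifact
        path = tmp_path / "model.npz"
        art.save(path)
        loaded = ModelArtifact.load(path)
        np.testing.assert_array_equal(
            predict_mask(art, v).data, predict_mask(loaded, v).data
        )
        assert loaded.config == art.config

    def test_prediction_pads_non_multiple_of_four_shapes(self, overfit_artifact):
        art, v, _ = overfit_artifact
        odd = VolumeImage(v.data[:30, :29, :31], v.spacing_um)
        pred = predict_mask(art, odd)
        assert pred.shape == (30, 29, 31)

    def test_best_checkpoint_tracked(self, overfit_artifact):
        art, _, _ = overfit_artifact
        assert art.best_iteration > 0
        assert any(it == art.best_iteration for it, _ in art.val_dice_history)
        assert art.best_val_dice == max(d for _, d in art.val_dice_history)


@pytest.fixture(scope="module")
def organoid_series():
    spec = PhantomSpec(grid_shape=(32, 32, 32), organoid_radius_vox=8.0)
    cohort = generate_cohort(2, [10, 20, 30], 0.0, base_spec=spec, seed=6)
    return [s for s in cohort if s.organoid_id == "org0"]


class TestVolumeCurve:
    def test_monotone_growth(self, organoid_series):
        df = volume_curve(organoid_series)
        assert list(df["day"]) == [10, 20, 30]
        assert df["volume_mm3"].is_monotonic_increasing

    def test_single_time_point(self, organoid_series):
        df = volume_curve(organoid_series[:1])
        assert len(df) == 1

    def test_sphere_volume_close_to_analytic(self):
        spec = PhantomSpec(grid_shape=(64, 64, 64), organoid_radius_vox=10.0, seed=8)
        s = generate_phantom(spec)
        s.organoid_id, s.day = "orgX", 5
        df = volume_curve([s])
        analytic = 4 / 3 * np.pi * (10 * 0.08) ** 3  # radius 10 voxels at 80 µm
        assert df["volume_mm3"].iloc[0] == pytest.approx(analytic, rel=0.05)

    def test_duplicate_day_rejected(self, organoid_series):
        with pytest.raises(ValueError, match="duplicate"):
            volume_curve([organoid_series[0], organoid_series[0]])

    def test_mixed_organoids_rejected(self):
        spec = PhantomSpec(grid_shape=(16, 16, 16), organoid_radius_vox=4.0)
        cohort = generate_cohort(2, [10], 0.0, base_spec=spec, seed=6)
        with pytest.raises(ValueError, match="one organoid"):
            volume_curve(cohort)
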