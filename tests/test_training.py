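"""Self-training: patch pairing, normalization, and the fitting loop."""

import numpy as np
import pytest

from eclare import (
    AcquisitionGeometry,
    SRModelConfig,
    TrainConfig,
    Volume,
    gaussian_profile,
    hr_patch_length,
    patch_intensity_normalization,
    sample_patch_pairs,
    simulate_acquisition,
    train,
)
from eclare.errors import DataError, InvalidArgumentError
from eclare.grids import resample_matrix
from eclare.training import _degrade_batch

TINY_MODEL = dict(n_blocks=2, n_channels=8, expansion=2)


class TestPatchGeometry:
    @pytest.mark.parametrize("r, length", [(5.2, 42), (3.0, 24), (5.0, 40), (4.0, 32)])
    def test_hr_patch_length_rule(self, r, length):
        assert hr_patch_length(r) == length

    def test_lr_patch_is_patch_size(self, phantom64):
        lr, geom = simulate_acquisition(phantom64, 4.0, 1.2)
        pair = next(sample_patch_pairs(lr, gaussian_profile(5.2, 21, 1.0), geom, 1))
        assert pair.hr_patch.shape == (42, 8)
        assert pair.lr_patch.shape == (8, 8)


class TestPairingConsistency:
    def test_lr_equals_degrade_then_downsample_bitexact(self, phantom64):
        """Every simulated LR patch must be exactly the profile blur plus
        FOV-aware downsampling of its own HR patch."""
        lr, geom = simulate_acquisition(phantom64, 4.0, 1.0)
        prof = gaussian_profile(4.0, 21, 1.0)
        down = resample_matrix(hr_patch_length(geom.ratio), geom.ratio)
        for pair in sample_patch_pairs(lr, prof, geom, 25, seed=4):
            expected = _degrade_batch(pair.hr_patch[None], prof.taps, down)[0]
            np.testing.assert_array_equal(pair.lr_patch, expected)

    def test_stream_is_seed_reproducible(self, phantom64):
        lr, geom = simulate_acquisition(phantom64, 4.0, 1.0)
        prof = gaussian_profile(4.0, 21, 1.0)
        a = next(sample_patch_pairs(lr, prof, geom, 1, seed=9))
        b = next(sample_patch_pairs(lr, prof, geom, 1, seed=9))
        np.testing.assert_array_equal(a.hr_patch, b.hr_patch)
        np.testing.assert_array_equal(a.lr_patch, b.lr_patch)

    def test_volume_too_small_raises(self):
        tiny = Volume(np.zeros((16, 16, 8)), (1, 1, 4.0), through_axis=2)
        geom = AcquisitionGeometry(4.0, 0.0, 1.0)
        with pytest.raises(DataError):
            next(sample_patch_pairs(tiny, gaussian_profile(4.0, 21, 1.0), geom, 1))


class TestIntensityNormalization:
    def test_forward_then_inverse_is_identity(self, phantom32):
        norm, inverse = patch_intensity_normalization(phantom32)
        np.testing.assert_allclose(inverse(norm.data), phantom32.data, atol=1e-12)

    def test_range_endpoints(self, phantom32):
        norm, _ = patch_intensity_normalization(phantom32)
        assert norm.data.min() == 0.0
        assert norm.data.max() == 1.0

    def test_constant_volume_no_division_by_zero(self, constant_volume):
        norm, inverse = patch_intensity_normalization(constant_volume)
        np.testing.assert_allclose(norm.data, 0.0)
        np.testing.assert_allclose(inverse(norm.data), 7.0)


@pytest.fixture(scope="module")
def small_setup():
    from eclare import PhantomSpec, make_phantom

    hr = make_phantom(PhantomSpec(shape=(32, 32, 32), seed=3))
    lr, geom = simulate_acquisition(hr, 2.0, 0.0)
    norm, _ = patch_intensity_normalization(lr)
    prof = gaussian_profile(2.0, 21, 1.0)
    return norm, prof, geom


class TestTrain:
    def test_loss_decreases_on_textured_phantom(self, small_setup):
        norm, prof, geom = small_setup
        cfg = TrainConfig(n_patches=3200, batch_size=32, seed=0)
        result = train(norm, prof, geom, SRModelConfig(scale=2.0, **TINY_MODEL), cfg)
        assert result.loss_trace.shape == (100,)
        assert result.loss_trace[-10:].mean() < result.loss_trace[:10].mean()

    def test_training_is_seed_reproducible(self, small_setup):
        norm, prof, geom = small_setup
        cfg = TrainConfig(n_patches=320, batch_size=32, seed=1)
        mc = SRModelConfig(scale=2.0, **TINY_MODEL)
        a = train(norm, prof, geom, mc, cfg)
        b = train(norm, prof, geom, mc, cfg)
        assert a.loss_trace[-1] == b.loss_trace[-1]
        for (pa, _), (pb, _) in zip(a.model.parameters(), b.model.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_constant_volume_trains_at_near_zero_loss(self):
        const = Volume(np.zeros((24, 24, 12)), (1, 1, 2.0), through_axis=2)
        geom = AcquisitionGeometry(2.0, 0.0, 1.0)
        cfg = TrainConfig(n_patches=64, batch_size=32, seed=0)
        result = train(
            const, gaussian_profile(2.0, 21, 1.0), geom,
            SRModelConfig(scale=2.0, **TINY_MODEL), cfg,
        )
        assert result.loss_trace.max() < 1e-10

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidArgumentError):
            TrainConfig(n_patches=0)
        with pytest.raises(InvalidArgumentError):
            TrainConfig(optimizer="sgd")
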