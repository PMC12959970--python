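"""SR network: scale decomposition, head behavior, shape laws, covariance."""

import numpy as np
import pytest

from eclare import SRModelConfig, WideActivationSR, count_parameters, decompose_scale
from eclare.errors import InvalidArgumentError
from eclare.grids import boundary_anchored_matrix, resample_matrix

TINY = dict(n_blocks=2, n_channels=6, expansion=2)


class TestDecomposeScale:
    @pytest.mark.parametrize(
        "r, up, post", [(3.2, 4, 0.8), (4.0, 4, 1.0), (6.5, 7, 6.5 / 7), (1.0, 1, 1.0)]
    )
    def test_examples(self, r, up, post):
        u, p = decompose_scale(r)
        assert u == up
        assert np.isclose(p, post)
        assert u * p == pytest.approx(r, abs=1e-12)

    def test_below_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            decompose_scale(0.9)


class TestForwardShapes:
    def test_noninteger_scale_output_length(self):
        net = WideActivationSR(SRModelConfig(scale=3.2, **TINY), seed=0)
        out = net.forward(np.zeros((2, 50, 64)))
        assert out.shape == (2, 160, 64)

    def test_integer_scale_output_length(self):
        net = WideActivationSR(SRModelConfig(scale=4.0, **TINY), seed=0)
        assert net.forward(np.zeros((1, 8, 8))).shape == (1, 32, 8)

    @pytest.mark.parametrize("r", [1.0, 1.5, 2.0, 3.0, 3.7, 4.0, 5.2, 6.5, 8.0])
    @pytest.mark.parametrize("n_in", [1, 5, 13, 37])
    def test_output_length_law(self, r, n_in):
        """N_out = round(N_in * r) for all scales, integer or not."""
        net = WideActivationSR(SRModelConfig(scale=r, n_blocks=1, n_channels=2), seed=0)
        out = net.forward(np.zeros((1, n_in, 4)))
        expected = int(np.floor(n_in * r + 0.5))
        assert out.shape[1] == expected

    def test_non_batch_input_rejected(self):
        net = WideActivationSR(SRModelConfig(scale=2.0, **TINY), seed=0)
        with pytest.raises(InvalidArgumentError):
            net.forward(np.zeros((8, 8)))


class TestZeroTrunkAnchor:
    def test_zero_trunk_equals_fov_cubic_upsampler_bitexact(self, rng):
        """At initialization the residual trunk is zeroed, so the network
        must reproduce FOV-aware cubic upsampling of its input exactly."""
        cfg = SRModelConfig(scale=3.2, dtype="float64", **TINY)
        net = WideActivationSR(cfg, seed=0)
        x = rng.normal(size=(3, 10, 12))
        expected = np.einsum("oi,biw->bow", resample_matrix(10, 1 / 3.2), x)
        np.testing.assert_array_equal(net.forward(x), expected)

    def test_integer_scale_skips_post_downsample_bitexact(self, rng):
        cfg = SRModelConfig(scale=4.0, dtype="float64", **TINY)
        net = WideActivationSR(cfg, seed=0)
        post, _ = net._head_matrices(10)
        assert post is None  # the downsample step is skipped entirely
        x = rng.normal(size=(2, 10, 8))
        expected = np.einsum("oi,biw->bow", resample_matrix(10, 0.25), x)
        np.testing.assert_array_equal(net.forward(x), expected)

    def test_boundary_convention_zero_trunk(self, rng):
        cfg = SRModelConfig(
            scale=3.2, resample_convention="boundary", dtype="float64", **TINY
        )
        net = WideActivationSR(cfg, seed=0)
        x = rng.normal(size=(1, 10, 8))
        expected = np.einsum("oi,biw->bow", boundary_anchored_matrix(10, 1 / 3.2), x)
        np.testing.assert_array_equal(net.forward(x), expected)

    def test_float32_default_close_to_float64(self, rng):
        x = rng.normal(size=(1, 10, 8))
        out32 = WideActivationSR(SRModelConfig(scale=3.2, **TINY), seed=0).forward(x)
        out64 = WideActivationSR(
            SRModelConfig(scale=3.2, dtype="float64", **TINY), seed=0
        ).forward(x)
        np.testing.assert_allclose(out32, out64, atol=1e-5)


class TestConvolutionalStructure:
    def test_translation_covariance_in_plane(self, rng):
        """Fully convolutional along the in-plane axis: shifting the input
        shifts the output identically away from boundaries."""
        cfg = SRModelConfig(scale=2.0, **TINY)
        net = WideActivationSR(cfg, seed=0)
        # give the trunk nonzero weights so the test is nontrivial
        r = np.random.default_rng(5)
        net.tail_conv.w[...] = r.normal(0, 0.1, net.tail_conv.w.shape).astype(
            net.tail_conv.w.dtype
        )
        x = rng.normal(size=(1, 12, 40))
        shifted = np.roll(x, 7, axis=2)
        out, out_shifted = net.forward(x), net.forward(shifted)
        # stay clear of the wrap region plus the 6-conv receptive field
        interior = slice(14, 34)
        np.testing.assert_allclose(
            np.roll(out, 7, axis=2)[:, :, interior],
            out_shifted[:, :, interior],
            atol=1e-5,
        )

    def test_batch_composition_consistent(self, rng):
        net = WideActivationSR(SRModelConfig(scale=2.5, **TINY), seed=0)
        x = rng.normal(size=(4, 8, 8))
        full = net.forward(x)
        singles = np.concatenate([net.forward(x[i:i + 1]) for i in range(4)])
        np.testing.assert_allclose(full, singles, atol=1e-6)


class TestCountParameters:
    def test_deterministic_and_matches_model(self):
        cfg = SRModelConfig(scale=3.0, n_blocks=3, n_channels=8, expansion=2)
        n = count_parameters(cfg)
        assert n == count_parameters(cfg)
        model = WideActivationSR(cfg, seed=0)
        assert n == sum(p.size for p, _ in model.parameters())

    def test_monotone_in_width_and_depth(self):
        base = SRModelConfig(scale=3.0, n_blocks=4, n_channels=16)
        deeper = SRModelConfig(scale=3.0, n_blocks=8, n_channels=16)
        narrower = SRModelConfig(scale=3.0, n_blocks=4, n_channels=8)
        assert count_parameters(deeper) > count_parameters(base)
        assert count_parameters(narrower) < count_parameters(base)


class TestStateDict:
    def test_roundtrip(self, rng):
        cfg = SRModelConfig(scale=2.0, **TINY)
        a = WideActivationSR(cfg, seed=1)
        b = WideActivationSR(cfg, seed=2)
        b.load_state_dict(a.state_dict())
        x = rng.normal(size=(1, 6, 6))
        np.testing.assert_array_equal(a.forward(x), b.forward(x))
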