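"""FOV-aware resampling: grid arithmetic, kernels, and conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eclare
from eclare import SamplingGrid1D, output_count, resample_1d, resampled_grid
from eclare.errors import ConfigurationError, InvalidArgumentError
from eclare.grids import (
    boundary_anchored_matrix,
    effective_boundary_anchored_spacing,
    resample_boundary_anchored,
    resample_matrix,
    round_half_away,
)


class TestSamplingGrid:
    def test_six_sample_unit_grid_geometry(self):
        """The canonical worked example: 6 unit-spaced samples starting at 0
        have FOV center 2.5 and extents [-0.5, 5.5]."""
        g = SamplingGrid1D(6, 1.0, 0.0)
        assert g.center == 2.5
        assert g.lower_extent == -0.5
        assert g.upper_extent == 5.5
        assert g.last_pos == 5.0

    def test_invariants_enforced(self):
        with pytest.raises(InvalidArgumentError):
            SamplingGrid1D(0, 1.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            SamplingGrid1D(5, -1.0, 0.0)

    @given(st.integers(1, 200), st.floats(0.05, 10.0), st.floats(-50, 50))
    @settings(max_examples=100, derandomize=True)
    def test_center_is_midpoint(self, n, d, first):
        g = SamplingGrid1D(n, d, first)
        assert np.isclose(g.center, (g.first_pos + g.last_pos) / 2)
        assert np.isclose(g.upper_extent - g.lower_extent, d * n)


class TestOutputCount:
    @pytest.mark.parametrize(
        "n, d, expected",
        [(6, 0.7, 9), (6, 1.429, 4), (10, 1.0, 10), (64, 5.0, 13), (64, 5.2, 12)],
    )
    def test_rounding_rule(self, n, d, expected):
        assert output_count(n, d) == expected

    def test_rounds_half_away_from_zero(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3
        assert round_half_away(2.4) == 2

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            output_count(0, 1.0)
        with pytest.raises(InvalidArgumentError):
            output_count(5, -0.5)


class TestResampledGrid:
    def test_upsampling_example(self):
        """Requested spacing 0.7 on the 6-sample grid: 9 samples, first at
        -0.3, center still exactly 2.5."""
        out = resampled_grid(SamplingGrid1D(6, 1.0, 0.0), 0.7)
        assert out.count == 9
        assert out.spacing == 0.7
        assert np.isclose(out.first_pos, -0.3)
        assert out.center == 2.5

    def test_downsampling_example(self):
        out = resampled_grid(SamplingGrid1D(6, 1.0, 0.0), 1.429)
        assert out.count == 4
        assert out.spacing == 1.429
        assert np.isclose(out.first_pos, 2.5 - 1.429 * 1.5)
        assert out.center == 2.5

    def test_identity(self):
        g = SamplingGrid1D(5, 1.0, 0.0)
        out = resampled_grid(g, 1.0)
        assert out == g

    @given(st.integers(1, 300), st.floats(0.05, 8.0))
    @settings(max_examples=200, derandomize=True)
    def test_center_preserved_and_spacing_exact(self, n, d):
        g = SamplingGrid1D(n, 1.0, 0.0)
        out = resampled_grid(g, d)
        assert out.spacing == d  # never adjusted
        assert np.isclose(out.center, g.center, atol=1e-12)

    @given(st.integers(2, 100), st.floats(0.2, 5.0))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_center(self, n, d):
        g = SamplingGrid1D(n, 1.0, 0.0)
        back = resampled_grid(resampled_grid(g, d), 1.0)
        assert np.isclose(back.center, g.center, atol=1e-12)


class TestResample1d:
    def test_constant_reproduction(self):
        out = resample_1d(np.full(6, 5.0), 0.7)
        assert out.shape == (9,)
        np.testing.assert_allclose(out, 5.0, atol=1e-12)

    def test_identity_spacing_returns_input(self):
        x = np.arange(7.0)
        np.testing.assert_array_equal(resample_1d(x, 1.0), x)

    def test_linear_ramp_reproduced_at_new_positions(self):
        ramp = np.arange(6.0)
        out = resample_1d(ramp, 0.5)
        pos = resampled_grid(SamplingGrid1D(6, 1.0, 0.0), 0.5).positions()
        np.testing.assert_allclose(out, np.clip(pos, 0, 5), atol=1e-12)

    def test_sinusoid_matches_analytic(self):
        n = 64
        f = 3 / n
        sig = np.sin(2 * np.pi * f * np.arange(n))
        out = resample_1d(sig, 0.5)
        pos = resampled_grid(SamplingGrid1D(n, 1.0, 0.0), 0.5).positions()
        ref = np.sin(2 * np.pi * f * np.clip(pos, 0, n - 1))
        np.testing.assert_allclose(out, ref, atol=5e-3)

    @pytest.mark.parametrize("kernel", ["nearest", "linear", "cubic"])
    def test_all_kernels_preserve_constants(self, kernel):
        out = resample_1d(np.full(10, 2.5), 0.8, kernel=kernel)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_unsupported_kernel(self):
        with pytest.raises(ConfigurationError):
            resample_1d(np.arange(5.0), 0.5, kernel="sinc")

    def test_empty_input(self):
        with pytest.raises(InvalidArgumentError):
            resample_1d(np.array([]), 0.5)


class TestBoundaryAnchored:
    @pytest.mark.parametrize(
        "n, d, n_out, eff",
        [(6, 0.7, 9, 0.625), (6, 1.429, 4, 5 / 3), (6, 1.0, 6, 1.0)],
    )
    def test_effective_spacing(self, n, d, n_out, eff):
        """The competing convention pins boundary samples and therefore
        produces an adjusted effective spacing (N-1)/(N'-1)."""
        assert output_count(n, d) == n_out
        assert np.isclose(effective_boundary_anchored_spacing(n, d), eff)

    def test_boundary_samples_pinned(self):
        x = np.sin(np.arange(6.0))
        out = resample_boundary_anchored(x, 0.7)
        assert out.shape == (9,)
        np.testing.assert_allclose(out[[0, -1]], x[[0, -1]], atol=1e-12)

    def test_requires_two_samples(self):
        with pytest.raises(InvalidArgumentError):
            resample_boundary_anchored(np.array([1.0]), 0.5)

    def test_differs_from_fov_aware_interior(self):
        x = np.arange(6.0) ** 2
        fov = resample_matrix(6, 0.7) @ x
        anch = boundary_anchored_matrix(6, 0.7) @ x
        assert not np.allclose(fov, anch)


class TestResampleAxis:
    def test_shape_and_spacing_update(self, constant_volume):
        out = eclare.resample_axis(constant_volume, 2, 0.5)
        assert out.data.shape == (16, 16, 48)
        assert out.spacing_mm == (1.0, 1.0, 0.5)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-12)

    def test_world_center_preserved(self, phantom32):
        out = eclare.resample_axis(phantom32, 2, 0.4)
        assert np.isclose(out.axis_center_world(2), phantom32.axis_center_world(2))

    def test_impulse_stays_centered(self):
        data = np.zeros((5, 5, 33))
        data[2, 2, 16] = 1.0
        vol = eclare.Volume(data, (1, 1, 1), through_axis=2)
        out = eclare.resample_axis(vol, 2, 0.5)
        line = out.data[2, 2]
        # upsampled impulse response peaks at the same world coordinate
        assert out.data.shape[2] == 66
        peak_world = out.origin[2] + 0.5 * np.argmax(line)
        assert np.isclose(peak_world, vol.origin[2] + 16.0, atol=0.26)

    def test_unknown_axis(self, constant_volume):
        with pytest.raises(InvalidArgumentError):
            eclare.resample_axis(constant_volume, 3, 0.5)
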