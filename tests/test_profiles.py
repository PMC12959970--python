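"""Slice-profile constructors, tap tables and FWHM measurement."""

import numpy as np
import pytest

from eclare import SliceProfile, fwhm, gaussian_profile, load_profile, rect_profile
from eclare.errors import FormatError, InvalidArgumentError
from eclare.profiles import save_profile

SIGMA_TO_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TestGaussianProfile:
    def test_sigma_fwhm_relation(self):
        prof = gaussian_profile(SIGMA_TO_FWHM * 1.0, 21, 1.0)
        c = 10
        # taps proportional to exp(-x^2/2) at sigma=1
        expected = np.exp(-0.5 * (np.arange(21) - c) ** 2)
        np.testing.assert_allclose(prof.taps, expected / expected.sum(), atol=1e-12)

    def test_unit_sum_and_symmetry(self):
        prof = gaussian_profile(3.7, 21, 1.0)
        assert np.isclose(prof.taps.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(prof.taps, prof.taps[::-1])
        assert np.argmax(prof.taps) == 10

    @pytest.mark.parametrize("target", [3.0, 4.0, 5.0])
    def test_measured_fwhm_matches_request(self, target):
        prof = gaussian_profile(target, 21, 1.0)
        assert abs(fwhm(prof) - target) < 1.0  # within one tap spacing

    def test_even_taps_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gaussian_profile(4.0, 20, 1.0)


class TestRectProfile:
    def test_width_three_is_three_thirds(self):
        prof = rect_profile(3.0, 21, 1.0)
        np.testing.assert_allclose(prof.taps[9:12], 1 / 3, atol=1e-12)
        assert np.isclose(prof.taps.sum(), 1.0)
        np.testing.assert_allclose(prof.taps[:9], 0.0)

    def test_width_one_is_identity_tap(self):
        prof = rect_profile(1.0, 21, 1.0)
        assert prof.taps[10] == 1.0
        assert np.count_nonzero(prof.taps) == 1

    def test_fractional_overlap_weights(self):
        # box of width 2.5 covers the center tap fully, neighbors by 0.75
        prof = rect_profile(2.5, 21, 1.0)
        expected = np.zeros(21)
        expected[10] = 1.0 / 2.5
        expected[9] = expected[11] = 0.75 / 2.5
        np.testing.assert_allclose(prof.taps, expected, atol=1e-12)

    def test_measured_fwhm(self):
        assert abs(fwhm(rect_profile(3.0, 21, 1.0)) - 3.0) < 1.0


class TestLoadProfile:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "taps.txt"
        path.write_text("0.25\n0.5\n0.25\n")
        prof = load_profile(path)
        np.testing.assert_allclose(prof.taps, [0.25, 0.5, 0.25])

    def test_normalizes_unnormalized_taps(self, tmp_path):
        path = tmp_path / "taps.txt"
        path.write_text("1\n2\n1\n")
        np.testing.assert_allclose(load_profile(path).taps, [0.25, 0.5, 0.25])

    def test_save_then_load(self, tmp_path):
        prof = gaussian_profile(4.0, 21, 1.0)
        save_profile(prof, tmp_path / "p.txt")
        np.testing.assert_allclose(load_profile(tmp_path / "p.txt").taps, prof.taps)

    @pytest.mark.parametrize("content", ["", "0\n0\n0\n", "a\nb\nc\n"])
    def test_bad_files_rejected(self, tmp_path, content):
        path = tmp_path / "taps.txt"
        path.write_text(content)
        with pytest.raises(FormatError):
            load_profile(path)


class TestFwhm:
    def test_symmetric_triangle(self):
        prof = SliceProfile(np.array([0.0, 0.5, 1.0, 0.5, 0.0]), 1.0)
        assert np.isclose(fwhm(prof), 2.0)

    def test_gaussian_closed_form(self):
        # dense tap sampling converges to the continuous value
        prof = gaussian_profile(SIGMA_TO_FWHM, 201, 0.05)
        assert np.isclose(fwhm(prof), SIGMA_TO_FWHM, atol=0.05)

    def test_tap_spacing_scales_width(self):
        prof = SliceProfile(np.array([0.0, 0.5, 1.0, 0.5, 0.0]), 2.0)
        assert np.isclose(fwhm(prof), 4.0)

    def test_flat_profile_undefined(self):
        with pytest.raises(InvalidArgumentError):
            fwhm(SliceProfile(np.ones(5), 1.0))


class TestSliceProfileInvariants:
    def test_even_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SliceProfile(np.ones(4), 1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SliceProfile(np.array([1.0, np.nan, 1.0]), 1.0)

    def test_positions_centered(self):
        prof = gaussian_profile(2.0, 5, 1.5)
        np.testing.assert_allclose(prof.positions_mm(), [-3.0, -1.5, 0.0, 1.5, 3.0])
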