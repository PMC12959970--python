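"""Slice-selection profiles.

A slice-selection profile is the through-plane sensitivity of one excited
slice.  Relative to a through-plane position it acts as a low-pass blur
kernel, and its full width at half maximum (FWHM) is the physical slice
thickness.  Profiles here are discrete tap sequences at the HR sample
spacing, normalized to unit sum so that blurring preserves mean tissue
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, InvalidArgumentError

__all__ = ["SliceProfile", "gaussian_profile", "rect_profile", "load_profile", "fwhm"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SliceProfile:
    """Discrete slice profile: odd-length unit-sum taps at ``tap_spacing_mm``."""

    taps: np.ndarray
    tap_spacing_mm: float
    name: str = "profile"

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        if taps.ndim != 1 or taps.size % 2 == 0:
            raise InvalidArgumentError("taps must be a 1-D sequence of odd length")
        if not np.all(np.isfinite(taps)):
            raise InvalidArgumentError("taps must be finite")
        total = taps.sum()
        if total <= 0:
            raise InvalidArgumentError("taps must have positive sum")
        object.__setattr__(self, "taps", taps / total)
        if not self.tap_spacing_mm > 0:
            raise InvalidArgumentError("tap_spacing_mm must be > 0")

    @property
    def n_taps(self) -> int:
        return self.taps.size

    @property
    def fwhm_mm(self) -> float:
        return fwhm(self)

    def positions_mm(self) -> np.ndarray:
        """Tap positions in mm, centered on the middle tap."""
        half = (self.n_taps - 1) // 2
        return self.tap_spacing_mm * (np.arange(self.n_taps) - half)


def gaussian_profile(
    fwhm_mm: float, n_taps: int = 21, tap_spacing_mm: float = 1.0
) -> SliceProfile:
    """Truncated Gaussian profile with the requested FWHM.

    sigma = FWHM / (2 sqrt(2 ln 2)); taps are sampled at the tap spacing,
    centered on the middle tap, and normalized to unit sum.
    """
    if not fwhm_mm > 0:
        raise InvalidArgumentError("fwhm_mm must be > 0")
    if n_taps % 2 == 0 or n_taps < 1:
        raise InvalidArgumentError("n_taps must be a positive odd integer")
    sigma = fwhm_mm * _FWHM_TO_SIGMA
    half = (n_taps - 1) // 2
    x = tap_spacing_mm * (np.arange(n_taps) - half)
    taps = np.exp(-0.5 * (x / sigma) ** 2)
    return SliceProfile(taps, tap_spacing_mm, name=f"gaussian-fwhm{fwhm_mm:g}")


def rect_profile(
    width_mm: float, n_taps: int = 21, tap_spacing_mm: float = 1.0
) -> SliceProfile:
    """Discretized rect of the given width.

    Each tap receives the fraction of the box overlapping its pixel
    (exact box–pixel integration), so partially covered edge taps get
    fractional weight and the tap sum is the box area before
    normalization.
    """
    if not width_mm > 0:
        raise InvalidArgumentError("width_mm must be > 0")
    if n_taps % 2 == 0 or n_taps < 1:
        raise InvalidArgumentError("n_taps must be a positive odd integer")
    half = (n_taps - 1) // 2
    centers = tap_spacing_mm * (np.arange(n_taps) - half)
    lo = centers - tap_spacing_mm / 2.0
    hi = centers + tap_spacing_mm / 2.0
    overlap = np.clip(np.minimum(hi, width_mm / 2.0) - np.maximum(lo, -width_mm / 2.0), 0.0, None)
    if overlap.sum() <= 0:
        raise InvalidArgumentError("rect width does not overlap the tap support")
    return SliceProfile(overlap, tap_spacing_mm, name=f"rect-w{width_mm:g}")


def load_profile(path, tap_spacing_mm: float = 1.0) -> SliceProfile:
    """Load a tap table (one float per line, '#' comments allowed)."""
    text = Path(path).read_text()
    taps = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            taps.append(float(line))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: not a number: {line!r}") from exc
    if not taps:
        raise FormatError(f"{path}: no taps found")
    taps = np.asarray(taps, dtype=float)
    if taps.size % 2 == 0:
        raise FormatError(f"{path}: tap count must be odd, got {taps.size}")
    if taps.sum() <= 0:
        raise FormatError(f"{path}: taps must have positive sum")
    return SliceProfile(taps, tap_spacing_mm, name=str(path))


def save_profile(profile: SliceProfile, path) -> None:
    """Write a tap table consumable by :func:`load_profile`."""
    Path(path).write_text("".join(f"{t:.17g}\n" for t in profile.taps))


def fwhm(profile: SliceProfile) -> float:
    """Full width at half maximum of the tap sequence, in mm.

    Half-max crossings are located by linear interpolation between taps;
    the outermost crossings bracket the width.  Profiles with no crossing
    on either side of the peak (flat or monotone tap sequences) have no
    defined FWHM.
    """
    taps = profile.taps
    peak = taps.max()
    if peak <= 0 or np.allclose(taps, taps[0]):
        raise InvalidArgumentError("FWHM undefined for flat profile")
    half = peak / 2.0
    above = taps >= half
    idx = np.nonzero(above)[0]
    i_lo, i_hi = idx[0], idx[-1]
    if i_lo == 0 or i_hi == taps.size - 1:
        raise InvalidArgumentError(
            "FWHM undefined: profile does not fall below half max inside the support"
        )
    # interpolate crossing positions on each flank
    left = (i_lo - 1) + (half - taps[i_lo - 1]) / (taps[i_lo] - taps[i_lo - 1])
    right = i_hi + (half - taps[i_hi]) / (taps[i_hi + 1] - taps[i_hi])
    return float((right - left) * profile.tap_spacing_mm)
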