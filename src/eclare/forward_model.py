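"""2D-multislice acquisition forward model.

An observed anisotropic volume y is modeled as the unobserved isotropic
volume x blurred along the through-plane axis by the slice-selection
profile h and subsampled by the anisotropy ratio r:

    y = (x * h) "down-arrow" r

If the FWHM of h is smaller than the slice separation s this models a
slice gap; an FWHM equal to or greater than s models adjacent or
overlapping slices.  The gap is therefore carried entirely by the profile
shape versus the subsampling distance — taps are never zeroed.
Subsampling uses the FOV-aware grid so the simulated LR volume shares its
FOV center with the HR volume.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate1d

from .errors import InvalidArgumentError
from .grids import resample_axis
from .profiles import SliceProfile, gaussian_profile, rect_profile
from .volume import AcquisitionGeometry, Volume

__all__ = ["blur_through_plane", "degrade_volume", "simulate_acquisition"]


def blur_through_plane(x: Volume, profile: SliceProfile) -> Volume:
    """Convolve along the through-plane axis with the profile taps.

    Boundaries are edge-replicated, which avoids dark rims at the volume
    ends given unit-sum taps.
    """
    if not np.isclose(profile.tap_spacing_mm, x.spacing_mm[x.through_axis]):
        raise InvalidArgumentError(
            f"profile tap spacing {profile.tap_spacing_mm} mm does not match "
            f"through-plane spacing {x.spacing_mm[x.through_axis]} mm"
        )
    blurred = correlate1d(
        x.data, profile.taps[::-1], axis=x.through_axis, mode="nearest"
    )
    return x.copy_with(data=blurred)


def degrade_volume(
    x: Volume, profile: SliceProfile, geometry: AcquisitionGeometry
) -> Volume:
    """Apply the forward model: profile blur, then FOV-aware subsampling by r.

    ``x`` must be sampled at the HR separation s* along its through-plane
    axis and the profile taps must be at that same spacing.  The output has
    through-plane spacing s = T + G and round(N / r) slices.
    """
    s_star = x.spacing_mm[x.through_axis]
    if not np.isclose(s_star, geometry.hr_separation_mm):
        raise InvalidArgumentError(
            f"through-plane spacing {s_star} mm must equal the HR separation "
            f"{geometry.hr_separation_mm} mm"
        )
    blurred = blur_through_plane(x, profile)
    return resample_axis(
        blurred, x.through_axis, geometry.lr_separation_mm, kernel="cubic"
    )


def simulate_acquisition(
    x: Volume,
    thickness_mm: float,
    gap_mm: float = 0.0,
    profile_kind: str = "gaussian",
    n_taps: int = 21,
    profile: SliceProfile | None = None,
) -> tuple[Volume, AcquisitionGeometry]:
    """Simulate a T-parallel-G 2D acquisition from an isotropic volume.

    Builds a profile whose FWHM equals the requested slice thickness
    (``profile_kind`` "gaussian" or "rect", or pass a ready-made profile
    e.g. loaded from a tap table), sets the slice separation to
    thickness + gap and degrades ``x`` with the forward model.
    """
    s_star = x.spacing_mm[x.through_axis]
    if thickness_mm < s_star:
        raise InvalidArgumentError(
            f"slice thickness {thickness_mm} mm below HR separation {s_star} mm"
        )
    geometry = AcquisitionGeometry(
        thickness_mm=float(thickness_mm),
        gap_mm=float(gap_mm),
        hr_separation_mm=float(s_star),
    )
    if profile is None:
        if profile_kind == "gaussian":
            profile = gaussian_profile(thickness_mm, n_taps, s_star)
        elif profile_kind == "rect":
            profile = rect_profile(thickness_mm, n_taps, s_star)
        else:
            raise InvalidArgumentError(
                f"profile_kind must be 'gaussian' or 'rect', got {profile_kind!r}"
            )
    return degrade_volume(x, profile, geometry), geometry
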