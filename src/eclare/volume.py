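"""In-memory 3-D volume and acquisition geometry containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["Volume", "AcquisitionGeometry"]


@dataclass
class Volume:
    """A 3-D intensity array with per-axis spacing and a designated
    through-plane (slice-stacking) axis.

    ``origin`` is the world coordinate of the center of voxel (0, 0, 0);
    axes are assumed world-aligned (no rotation), which is sufficient for
    the axis-wise resampling this package performs.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    through_axis: int
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError(f"data must be 3-D, got {self.data.ndim}-D")
        if self.through_axis not in (0, 1, 2):
            raise InvalidArgumentError(f"through_axis must be 0..2, got {self.through_axis}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidArgumentError(f"spacings must be positive, got {self.spacing_mm}")

    @property
    def in_plane_axes(self) -> tuple[int, int]:
        return tuple(a for a in (0, 1, 2) if a != self.through_axis)

    def axis_center_world(self, axis: int) -> float:
        """World coordinate of the FOV center along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing_mm[axis] * (n - 1) / 2.0

    def copy_with(self, **kwargs) -> "Volume":
        params = dict(
            data=self.data,
            spacing_mm=self.spacing_mm,
            through_axis=self.through_axis,
            origin=self.origin,
        )
        params.update(kwargs)
        return Volume(**params)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Slice geometry of a 2D-multislice acquisition.

    thickness T is the FWHM of the slice-selection profile; the slice
    separation s = T + G (G the gap); r = s / s* is the anisotropy ratio
    relative to the high-resolution separation s* and is the net
    super-resolution factor (possibly noninteger).
    """

    thickness_mm: float
    gap_mm: float
    hr_separation_mm: float

    def __post_init__(self) -> None:
        if not self.thickness_mm > 0:
            raise InvalidArgumentError("thickness_mm must be > 0")
        if self.gap_mm < 0:
            raise InvalidArgumentError("gap_mm must be >= 0")
        if not self.hr_separation_mm > 0:
            raise InvalidArgumentError("hr_separation_mm must be > 0")
        if self.lr_separation_mm < self.hr_separation_mm:
            raise InvalidArgumentError(
                "LR slice separation must be >= HR separation (ratio >= 1)"
            )

    @property
    def lr_separation_mm(self) -> float:
        return self.thickness_mm + self.gap_mm

    @property
    def ratio(self) -> float:
        """Anisotropy ratio r = s / s* (>= 1)."""
        return self.lr_separation_mm / self.hr_separation_mm
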