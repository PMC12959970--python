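"""FOV-aware 1-D resampling grids and axis-wise regridding.

Resampling a discrete signal onto a new sample spacing cannot simultaneously
preserve (1) the field-of-view (FOV) center, (2) the requested spacing and
(3) the boundary sample locations, because the output must have an integer
number of samples.  The convention implemented here keeps the requested
spacing *exact* and the FOV center *fixed*, compromising only the boundary
sample positions.  The competing boundary-anchored convention (first and
last sample centers pinned, spacing adjusted — the behavior of classic
``zoom``-style resamplers) is provided for comparison and ablation.

All grid arithmetic is done in a normalized coordinate system where the
input grid has its first sample centered at 0 and spacing 1; each sample
owns a pixel of width equal to the spacing, so an ``N``-sample unit-spacing
signal extends from -0.5 to N - 0.5 and its FOV center is (N - 1) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import solve_banded

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "SamplingGrid1D",
    "round_half_away",
    "output_count",
    "resampled_grid",
    "resample_matrix",
    "boundary_anchored_matrix",
    "resample_1d",
    "resample_boundary_anchored",
    "resample_axis",
    "KERNELS",
]

#: Supported interpolation kernels.  "cubic" is an interpolating cubic
#: B-spline (coefficients obtained by solving the banded spline system),
#: which is the package default everywhere.
KERNELS = ("cubic", "linear", "nearest")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    This single rounding rule is used for every output-sample-count
    computation in the package (resampling, patch sizing, slice counts).
    """
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass(frozen=True)
class SamplingGrid1D:
    """A 1-D lattice of sample centers.

    Parameters
    ----------
    count : int
        Number of samples, >= 1.
    spacing : float
        Distance between adjacent sample centers (also the pixel width).
    first_pos : float
        Coordinate of the first sample center.
    """

    count: int
    spacing: float
    first_pos: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise InvalidArgumentError(f"count must be >= 1, got {self.count}")
        if not self.spacing > 0:
            raise InvalidArgumentError(f"spacing must be > 0, got {self.spacing}")

    @property
    def last_pos(self) -> float:
        return self.first_pos + self.spacing * (self.count - 1)

    @property
    def center(self) -> float:
        """FOV center: midpoint of the first and last sample centers."""
        return 0.5 * (self.first_pos + self.last_pos)

    @property
    def lower_extent(self) -> float:
        return self.first_pos - 0.5 * self.spacing

    @property
    def upper_extent(self) -> float:
        return self.last_pos + 0.5 * self.spacing

    def positions(self) -> np.ndarray:
        return self.first_pos + self.spacing * np.arange(self.count)


def output_count(count_in: int, new_spacing: float) -> int:
    """Number of output samples when regridding ``count_in`` samples.

    ``new_spacing`` is expressed in units of the input spacing.  The count
    is round(count_in / new_spacing) under :func:`round_half_away`, clipped
    below at 1 so a grid always remains.
    """
    if count_in < 1:
        raise InvalidArgumentError(f"count_in must be >= 1, got {count_in}")
    if not new_spacing > 0:
        raise InvalidArgumentError(f"new_spacing must be > 0, got {new_spacing}")
    return max(1, round_half_away(count_in / new_spacing))


def resampled_grid(grid_in: SamplingGrid1D, new_spacing: float) -> SamplingGrid1D:
    """FOV-aware output grid: exact requested spacing, identical FOV center.

    The first output sample sits at ``c - (new_spacing / 2) * (N' - 1)``
    where ``c`` is the input grid center, which places the output lattice
    symmetrically about the input FOV center.
    """
    n_out = output_count(grid_in.count, new_spacing / grid_in.spacing)
    first = grid_in.center - 0.5 * new_spacing * (n_out - 1)
    return SamplingGrid1D(n_out, new_spacing, first)


# ---------------------------------------------------------------------------
# interpolation matrices
#
# Every kernel is realized as a dense (n_out, n_in) matrix so that the exact
# adjoint (the transpose) is available to backpropagation in the SR network.
# Positions outside the input lattice are clamped to the edge samples
# (edge replication).


def _bspline3(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    out = np.zeros_like(ax)
    m1 = ax < 1
    out[m1] = 2.0 / 3.0 - ax[m1] ** 2 + 0.5 * ax[m1] ** 3
    m2 = (ax >= 1) & (ax < 2)
    out[m2] = (2.0 - ax[m2]) ** 3 / 6.0
    return out


def _spline_coeff_matrix(n: int) -> np.ndarray:
    """Inverse of the cubic-B-spline interpolation system with natural
    boundary (zero second derivative at the end nodes, i.e. the virtual
    coefficients are linear extrapolations c[-1] = 2c[0] - c[1] and
    c[n] = 2c[n-1] - c[n-2]), as a dense (n, n) array.

    This boundary reproduces constant and linear signals to machine
    precision all the way to the edges.
    """
    if n == 1:
        return np.ones((1, 1))
    ab = np.zeros((3, n))
    ab[0, 1:] = 1.0 / 6.0       # superdiagonal
    ab[1, :] = 4.0 / 6.0        # diagonal
    ab[2, :-1] = 1.0 / 6.0      # subdiagonal
    # fold the extrapolated virtual coefficients into the end rows:
    # row 0 becomes c[0] = v[0], row n-1 becomes c[n-1] = v[n-1]
    ab[1, 0] += 2.0 / 6.0
    ab[0, 1] -= 1.0 / 6.0
    ab[1, -1] += 2.0 / 6.0
    ab[2, -2] -= 1.0 / 6.0
    return solve_banded((1, 1), ab, np.eye(n))


def _kernel_matrix_at(positions: np.ndarray, n_in: int, kernel: str) -> np.ndarray:
    """(len(positions), n_in) matrix evaluating the interpolant of an
    ``n_in``-sample unit-spacing signal at ``positions``."""
    if kernel not in KERNELS:
        raise ConfigurationError(
            f"unsupported kernel {kernel!r}; choose one of {KERNELS}"
        )
    # edge replication: clamp evaluation positions into the sample support
    pos = np.clip(np.asarray(positions, dtype=float), 0.0, n_in - 1.0)
    n_out = pos.size
    if kernel == "nearest":
        mat = np.zeros((n_out, n_in))
        idx = np.clip(np.rint(pos).astype(int), 0, n_in - 1)
        mat[np.arange(n_out), idx] = 1.0
        return mat
    if kernel == "linear":
        mat = np.zeros((n_out, n_in))
        lo = np.clip(np.floor(pos).astype(int), 0, n_in - 1)
        hi = np.clip(lo + 1, 0, n_in - 1)
        frac = pos - lo
        mat[np.arange(n_out), lo] += 1.0 - frac
        mat[np.arange(n_out), hi] += frac
        return mat
    # cubic interpolating B-spline: weights act on spline coefficients,
    # with out-of-range coefficients linearly extrapolated (natural
    # boundary, matching _spline_coeff_matrix)
    weights = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    base = np.floor(pos).astype(int)
    for off in (-1, 0, 1, 2):
        j = base + off
        w = _bspline3(pos - j)
        if n_in == 1:
            np.add.at(weights, (rows, np.zeros_like(j)), w)
            continue
        inside = (j >= 0) & (j <= n_in - 1)
        np.add.at(weights, (rows[inside], j[inside]), w[inside])
        low = j < 0  # c[j] = (1-j)*c[0] + j*c[1] for j < 0 (j = -1 here)
        np.add.at(weights, (rows[low], np.zeros(low.sum(), int)), (1 - j[low]) * w[low])
        np.add.at(weights, (rows[low], np.ones(low.sum(), int)), j[low] * w[low])
        high = j > n_in - 1  # c[j] extrapolated from c[n-2], c[n-1]
        excess = j[high] - (n_in - 1)
        np.add.at(
            weights, (rows[high], np.full(high.sum(), n_in - 1)), (1 + excess) * w[high]
        )
        np.add.at(
            weights, (rows[high], np.full(high.sum(), n_in - 2)), -excess * w[high]
        )
    return weights @ _spline_coeff_matrix(n_in)


def interpolation_matrix(positions, n_in: int, kernel: str = "cubic") -> np.ndarray:
    """Public access to the kernel evaluation operator: a
    (len(positions), n_in) matrix interpolating a unit-spacing signal at
    arbitrary positions (edge-replicated outside the support)."""
    return _kernel_matrix_at(np.asarray(positions, dtype=float), n_in, kernel)


@lru_cache(maxsize=512)
def resample_matrix(n_in: int, new_spacing: float, kernel: str = "cubic") -> np.ndarray:
    """Dense FOV-aware resampling operator for an ``n_in``-sample signal.

    The returned (n_out, n_in) matrix maps samples on the unit-spacing input
    grid to samples on the FOV-aware output grid at ``new_spacing`` (in input
    spacing units).  Cached: the operator depends only on (n_in, spacing,
    kernel).
    """
    grid_out = resampled_grid(SamplingGrid1D(n_in, 1.0, 0.0), new_spacing)
    return _kernel_matrix_at(grid_out.positions(), n_in, kernel)


@lru_cache(maxsize=512)
def boundary_anchored_matrix(
    n_in: int, new_spacing: float, kernel: str = "cubic"
) -> np.ndarray:
    """Boundary-anchored resampling operator (comparison convention).

    The output count follows the same rounding rule, but the first and last
    sample centers are pinned to the input's, so the *effective* spacing is
    (n_in - 1) / (n_out - 1) rather than the requested one.
    """
    if n_in < 2:
        raise InvalidArgumentError("boundary-anchored resampling needs >= 2 samples")
    n_out = output_count(n_in, new_spacing)
    if n_out < 2:
        n_out = 2  # both boundary samples are always retained
    positions = np.linspace(0.0, n_in - 1.0, n_out)
    return _kernel_matrix_at(positions, n_in, kernel)


def resample_1d(
    values: np.ndarray, new_spacing: float, kernel: str = "cubic"
) -> np.ndarray:
    """FOV-aware resampling of a 1-D signal to ``new_spacing`` (input units).

    At ``new_spacing == 1`` the input is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise InvalidArgumentError("values must be a nonempty 1-D sequence")
    if kernel not in KERNELS:
        raise ConfigurationError(
            f"unsupported kernel {kernel!r}; choose one of {KERNELS}"
        )
    if new_spacing == 1.0:
        return values.copy()
    return resample_matrix(values.size, float(new_spacing), kernel) @ values


def resample_boundary_anchored(
    values: np.ndarray, new_spacing: float, kernel: str = "cubic"
) -> np.ndarray:
    """Resample with the boundary-anchored convention (tests/ablation only)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise InvalidArgumentError("values must be a 1-D sequence of length >= 2")
    if new_spacing == 1.0:
        return values.copy()
    return boundary_anchored_matrix(values.size, float(new_spacing), kernel) @ values


def effective_boundary_anchored_spacing(n_in: int, new_spacing: float) -> float:
    """Spacing actually produced by the boundary-anchored convention."""
    if n_in < 2:
        raise InvalidArgumentError("need >= 2 samples")
    n_out = max(2, output_count(n_in, new_spacing))
    return (n_in - 1) / (n_out - 1)


def apply_matrix_along_axis(mat: np.ndarray, arr: np.ndarray, axis: int) -> np.ndarray:
    """Apply an (n_out, n_in) operator along one axis of an N-D array."""
    moved = np.moveaxis(arr, axis, 0)
    out = np.tensordot(mat, moved, axes=(1, 0))
    return np.moveaxis(out, 0, axis)


def resample_axis(volume, axis: int, new_spacing_mm: float, kernel: str = "cubic"):
    """FOV-aware resampling of one axis of a :class:`~eclare.volume.Volume`.

    The spacing along ``axis`` becomes exactly ``new_spacing_mm`` and the
    world-space FOV center along that axis is preserved via the volume
    origin; other axes are untouched.
    """
    from .volume import Volume  # local import to avoid a cycle

    if axis not in (0, 1, 2):
        raise InvalidArgumentError(f"axis must be 0, 1 or 2, got {axis}")
    if not new_spacing_mm > 0:
        raise InvalidArgumentError("new_spacing_mm must be > 0")
    old_spacing = volume.spacing_mm[axis]
    d = new_spacing_mm / old_spacing
    n_in = volume.data.shape[axis]
    if d == 1.0:
        data = volume.data.copy()
    else:
        mat = resample_matrix(n_in, float(d), kernel)
        data = apply_matrix_along_axis(mat, volume.data, axis)
    spacing = list(volume.spacing_mm)
    spacing[axis] = float(new_spacing_mm)
    # world center of the axis stays put: origin' = center - d'*(N'-1)/2
    center_world = volume.origin[axis] + old_spacing * (n_in - 1) / 2.0
    origin = list(volume.origin)
    origin[axis] = center_world - new_spacing_mm * (data.shape[axis] - 1) / 2.0
    return Volume(
        data=data,
        spacing_mm=tuple(spacing),
        through_axis=volume.through_axis,
        origin=tuple(origin),
    )
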