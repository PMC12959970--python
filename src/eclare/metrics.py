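"""Reference-based image-quality metrics."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .errors import InvalidArgumentError
from .grids import apply_matrix_along_axis, interpolation_matrix
from .volume import Volume

__all__ = ["psnr", "ssim", "dice", "regrid_like"]


def regrid_like(test: Volume, ref: Volume, kernel: str = "cubic") -> Volume:
    """Interpolate ``test`` onto ``ref``'s sample grid, axis by axis, using
    world coordinates (both volumes must share in-plane shapes or be
    regriddable along each differing axis).

    Needed for evaluation: the super-resolved through-plane count is
    round(round(N / r) * r), which can differ from the reference N by a
    sample, and the FOV-centered grids are then offset by half a sample.
    """
    data = test.data
    spacing = list(test.spacing_mm)
    origin = list(test.origin)
    for axis in range(3):
        n_ref = ref.data.shape[axis]
        if data.shape[axis] == n_ref and np.isclose(
            origin[axis], ref.origin[axis]
        ) and np.isclose(spacing[axis], ref.spacing_mm[axis]):
            continue
        world = ref.origin[axis] + ref.spacing_mm[axis] * np.arange(n_ref)
        pos = (world - origin[axis]) / spacing[axis]
        mat = interpolation_matrix(pos, data.shape[axis], kernel)
        data = apply_matrix_along_axis(mat, data, axis)
        spacing[axis] = ref.spacing_mm[axis]
        origin[axis] = ref.origin[axis]
    return Volume(
        data=data,
        spacing_mm=tuple(spacing),
        through_axis=test.through_axis,
        origin=tuple(origin),
    )


def _pair_arrays(ref, test) -> tuple[np.ndarray, np.ndarray]:
    a = ref.data if isinstance(ref, Volume) else np.asarray(ref, dtype=float)
    b = test.data if isinstance(test, Volume) else np.asarray(test, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(ref, test, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio, 20*log10(data_range / RMSE), in dB.

    ``data_range`` defaults to the reference's max - min.  Identical
    inputs give +inf.
    """
    a, b = _pair_arrays(ref, test)
    if data_range is None:
        data_range = float(a.max() - a.min())
    if not data_range > 0:
        raise InvalidArgumentError("data_range must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(data_range / np.sqrt(mse)))


def ssim(
    ref, test, data_range: float | None = None, window: int = 7, slicewise: bool = False
) -> float:
    """Structural similarity (scikit-image implementation).

    By default SSIM is computed in 3-D with a ``window``-voxel cube;
    ``slicewise=True`` averages 2-D SSIM over the last axis instead.
    Gaussian weighting off, K1=0.01, K2=0.03 (the library defaults).
    """
    a, b = _pair_arrays(ref, test)
    if data_range is None:
        data_range = float(a.max() - a.min())
    if not data_range > 0:
        raise InvalidArgumentError("data_range must be positive")
    if slicewise and a.ndim == 3:
        vals = [
            structural_similarity(
                a[..., k], b[..., k], data_range=data_range, win_size=window
            )
            for k in range(a.shape[-1])
        ]
        return float(np.mean(vals))
    return float(
        structural_similarity(a, b, data_range=data_range, win_size=window)
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)
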