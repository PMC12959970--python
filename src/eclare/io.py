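"""NIfTI volume I/O with spacing and through-plane-axis bookkeeping."""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataError, FormatError
from .volume import Volume

__all__ = ["read_volume", "write_volume"]

#: spacings whose max/min ratio is below this are "near isotropic" and the
#: through-plane axis cannot be inferred from the header alone
_NEAR_ISO_RATIO = 1.05


def read_volume(path, through_axis: int | None = None) -> Volume:
    """Read a NIfTI-1/2 volume.

    Spacings come from the header zooms and the origin from the affine
    translation (axes are treated as world-aligned; oblique affines are
    accepted with a warning since only axis-wise geometry is used).  The
    through-plane axis defaults to the axis of largest spacing; for
    near-isotropic volumes it must be given explicitly.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    spacing = tuple(float(z) for z in zooms)
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: nonpositive voxel spacing {spacing}")
    rot = np.asarray(img.affine)[:3, :3]
    if not np.allclose(np.abs(rot), np.diag(np.diagonal(np.abs(rot))), atol=1e-3):
        warnings.warn(
            f"{path}: oblique affine; only axis-aligned geometry is tracked",
            stacklevel=2,
        )
    if through_axis is None:
        smax, smin = max(spacing), min(spacing)
        if smax / smin < _NEAR_ISO_RATIO:
            raise DataError(
                f"{path}: spacings {spacing} are near-isotropic; pass the "
                "through-plane axis explicitly (e.g. --through-axis 2)"
            )
        through_axis = int(np.argmax(spacing))
    elif spacing[through_axis] < max(spacing) - 1e-9:
        warnings.warn(
            f"{path}: through-plane spacing {spacing[through_axis]} mm is "
            "smaller than an in-plane spacing; is the axis flag correct?",
            stacklevel=2,
        )
    origin = tuple(float(t) for t in np.asarray(img.affine)[:3, 3])
    return Volume(
        data=data, spacing_mm=spacing, through_axis=through_axis, origin=origin
    )


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI with a diagonal affine built from its spacing
    and origin, so the world-space FOV center survives spacing changes."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing_mm
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing_mm)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
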