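"""Dual-axis slice-wise inference and fusion.

The trained network is 2-D, so the volume is super-resolved slice by
slice.  There are two orthogonal slice orientations that contain the
through-plane direction (for an axial LR stack: the sagittal and coronal
planes); the volume is processed once per orientation — every slice is
extracted with the through-plane (LR) axis first, passed through the
network, and restacked on the FOV-aware HR grid — and the two resulting
volumes are averaged voxel-wise (an unweighted mean) to form the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InvalidArgumentError
from .network import WideActivationSR
from .volume import Volume

__all__ = ["SRResult", "superresolve_axis", "fuse", "superresolve_volume"]


@dataclass
class SRResult:
    """Final fused volume, the two per-orientation intermediates, and run
    provenance (configs, seeds, profile taps)."""

    volume: Volume
    intermediates: tuple[Volume, Volume]
    provenance: dict[str, Any] = field(default_factory=dict)


def _hr_volume_like(y: Volume, n_out: int, hr_spacing: float) -> dict:
    """Spacing/origin bookkeeping for the through-plane HR grid (FOV center
    preserved in world coordinates)."""
    k = y.through_axis
    spacing = list(y.spacing_mm)
    old_spacing = spacing[k]
    spacing[k] = hr_spacing
    center = y.origin[k] + old_spacing * (y.data.shape[k] - 1) / 2.0
    origin = list(y.origin)
    origin[k] = center - hr_spacing * (n_out - 1) / 2.0
    return dict(spacing_mm=tuple(spacing), origin=tuple(origin), through_axis=k)


def superresolve_axis(
    y: Volume,
    model: WideActivationSR,
    plane_axis: int,
    batch_size: int = 32,
) -> Volume:
    """Super-resolve every 2-D slice of one orientation containing the
    through-plane direction.

    ``plane_axis`` is the in-plane axis held fixed while slicing; each
    slice therefore spans (through_axis, other in-plane axis) and is fed
    to the network with the LR axis first.  Results are independent of
    ``batch_size``.
    """
    k = y.through_axis
    if plane_axis == k or plane_axis not in (0, 1, 2):
        raise InvalidArgumentError(
            f"plane_axis must be an in-plane axis, got {plane_axis} "
            f"(through_axis={k})"
        )
    other = next(a for a in (0, 1, 2) if a not in (plane_axis, k))
    # (n_slices, H_lr, W) with the LR axis first within each slice
    stack = np.transpose(y.data, (plane_axis, k, other))
    n_slices = stack.shape[0]
    n_out = model.output_length(stack.shape[1])
    out = np.empty((n_slices, n_out, stack.shape[2]))
    for start in range(0, n_slices, batch_size):
        out[start:start + batch_size] = model.forward(stack[start:start + batch_size])
    # restack to the original axis order
    inv = np.argsort((plane_axis, k, other))
    data = np.transpose(out, inv)
    hr_spacing = y.spacing_mm[k] / model.cfg.scale
    return Volume(data=data, **_hr_volume_like(y, n_out, hr_spacing))


def fuse(v1: Volume, v2: Volume) -> Volume:
    """Unweighted voxel-wise mean of two volumes on identical grids."""
    if v1.data.shape != v2.data.shape:
        raise InvalidArgumentError(
            f"shape mismatch: {v1.data.shape} vs {v2.data.shape}"
        )
    if not (
        np.allclose(v1.spacing_mm, v2.spacing_mm)
        and np.allclose(v1.origin, v2.origin)
    ):
        raise InvalidArgumentError("grid mismatch between volumes to fuse")
    return v1.copy_with(data=0.5 * (v1.data + v2.data))


def superresolve_volume(
    y: Volume, model: WideActivationSR, batch_size: int = 32
) -> SRResult:
    """Run both orientations and fuse (the full inference path)."""
    a1, a2 = y.in_plane_axes
    v1 = superresolve_axis(y, model, a1, batch_size)
    v2 = superresolve_axis(y, model, a2, batch_size)
    fused = fuse(v1, v2)
    return SRResult(volume=fused, intermediates=(v1, v2))
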