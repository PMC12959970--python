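"""Per-volume self-training.

Supervision comes from the anisotropic volume itself: its in-plane slices
are fully sampled, so 2-D patches cut from them serve as HR targets, and
degrading those patches with the (estimated) slice profile plus FOV-aware
downsampling by the anisotropy ratio r manufactures the paired LR inputs.
The SR network is then fit from scratch with Adam on mean squared error
under a one-cycle learning-rate schedule.

HR patches are ``round(8 r) x 8`` so that their degraded counterparts are
exactly 8 x 8; the same rounding operator as the resampling grid is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np
from scipy.ndimage import correlate1d

from .errors import DataError, InvalidArgumentError, TrainingDivergedError
from .grids import boundary_anchored_matrix, resample_matrix, round_half_away
from .network import SRModelConfig, WideActivationSR
from .nn import Adam, OneCycleSchedule
from .profiles import SliceProfile
from .volume import AcquisitionGeometry, Volume

__all__ = [
    "PatchPair",
    "TrainConfig",
    "TrainResult",
    "hr_patch_length",
    "sample_patch_pairs",
    "train",
    "patch_intensity_normalization",
]


@dataclass(frozen=True)
class PatchPair:
    """An HR in-plane patch and its simulated LR counterpart."""

    hr_patch: np.ndarray  # (round(patch_size * r), patch_size)
    lr_patch: np.ndarray  # (patch_size, patch_size)


@dataclass
class TrainConfig:
    """Self-training hyperparameters.

    Defaults are the full-scale settings (1,000,000 patches, batch 128,
    Adam at 1e-3 with a one-cycle schedule, MSE loss).  ``desk()`` returns
    a CPU-sized preset used throughout the test suite.
    """

    n_patches: int = 1_000_000
    batch_size: int = 128
    lr: float = 1e-3
    optimizer: str = "adam"
    schedule: str = "one-cycle"
    loss: str = "mse"
    seed: int = 0
    patch_size: int = 8

    def __post_init__(self) -> None:
        if self.n_patches < 1 or self.batch_size < 1 or self.patch_size < 1:
            raise InvalidArgumentError("counts must be positive")
        if self.optimizer != "adam" or self.loss != "mse":
            raise InvalidArgumentError("supported: optimizer='adam', loss='mse'")
        if self.schedule not in ("one-cycle", "constant"):
            raise InvalidArgumentError("schedule must be 'one-cycle' or 'constant'")

    @classmethod
    def desk(cls, seed: int = 0) -> "TrainConfig":
        """CPU-scale preset: 10,000 patches in batches of 32."""
        return cls(n_patches=10_000, batch_size=32, seed=seed)


@dataclass
class TrainResult:
    model: WideActivationSR
    loss_trace: np.ndarray
    profile: SliceProfile
    geometry: AcquisitionGeometry


def hr_patch_length(ratio: float, patch_size: int = 8) -> int:
    """LR-axis extent of an HR training patch: round(patch_size * r)."""
    return round_half_away(patch_size * ratio)


def _down_matrix(n_in: int, ratio: float, convention: str) -> np.ndarray:
    if convention == "fov":
        return resample_matrix(n_in, float(ratio), "cubic")
    return boundary_anchored_matrix(n_in, float(ratio), "cubic")


def _degrade_batch(hr: np.ndarray, taps: np.ndarray, down: np.ndarray) -> np.ndarray:
    """Blur (edge-replicated) and downsample a (B, L, W) batch along axis 1."""
    blurred = correlate1d(hr, taps[::-1], axis=1, mode="nearest")
    return np.einsum("oi,biw->bow", down, blurred)


class _PatchSampler:
    """Uniform sampler of oriented HR windows from the in-plane slices.

    Each draw picks a through-plane slice index, one of the two in-plane
    directions as the degradation axis (the window's first axis), a flip,
    and a uniformly random window position.
    """

    def __init__(self, y: Volume, ratio: float, patch_size: int, seed: int):
        self.length = hr_patch_length(ratio, patch_size)
        self.width = patch_size
        # stack in-plane slices as (n_slices, in1, in2)
        self.slices = np.moveaxis(y.data, y.through_axis, 0)
        n1, n2 = self.slices.shape[1], self.slices.shape[2]
        if min(n1, n2) < self.length or min(n1, n2) < self.width:
            raise DataError(
                f"in-plane extent {(n1, n2)} too small for "
                f"{self.length}x{self.width} patches"
            )
        self.rng = np.random.default_rng(seed)

    def draw(self, batch: int) -> np.ndarray:
        out = np.empty((batch, self.length, self.width))
        ns, n1, n2 = self.slices.shape
        for b in range(batch):
            k = self.rng.integers(ns)
            sl = self.slices[k]
            if self.rng.integers(2):  # degrade along the other in-plane axis
                sl = sl.T
            h, w = sl.shape
            i = self.rng.integers(h - self.length + 1)
            j = self.rng.integers(w - self.width + 1)
            win = sl[i:i + self.length, j:j + self.width]
            if self.rng.integers(2):
                win = win[::-1]
            if self.rng.integers(2):
                win = win[:, ::-1]
            out[b] = win
        return out


def sample_patch_pairs(
    y: Volume,
    profile: SliceProfile,
    geometry: AcquisitionGeometry,
    n: int,
    seed: int = 0,
    patch_size: int = 8,
    convention: str = "fov",
) -> Iterator[PatchPair]:
    """Stream ``n`` seeded HR/LR patch pairs from the volume's in-plane data.

    Every LR patch is exactly the profile blur (edge-replicated) followed
    by FOV-aware downsampling by r of its HR patch.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    sampler = _PatchSampler(y, geometry.ratio, patch_size, seed)
    down = _down_matrix(sampler.length, geometry.ratio, convention)
    for _ in range(n):
        hr = sampler.draw(1)
        lr = _degrade_batch(hr, profile.taps, down)
        yield PatchPair(hr_patch=hr[0], lr_patch=lr[0])


def patch_intensity_normalization(
    volume: Volume,
) -> tuple[Volume, Callable[[np.ndarray], np.ndarray]]:
    """Affine map of intensities to [0, 1] plus the exact inverse transform.

    Constant volumes map to zeros (no division by zero); the inverse
    restores the original value.
    """
    data = volume.data
    if not np.all(np.isfinite(data)):
        raise DataError("volume contains non-finite intensities")
    vmin = float(data.min())
    scale = float(data.max()) - vmin
    if scale == 0.0:
        scale = 1.0

    def inverse(arr: np.ndarray) -> np.ndarray:
        return arr * scale + vmin

    return volume.copy_with(data=(data - vmin) / scale), inverse


def train(
    y: Volume,
    profile: SliceProfile,
    geometry: AcquisitionGeometry,
    model_cfg: SRModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    progress: Callable[[int, float], None] | None = None,
) -> TrainResult:
    """Fit the SR network on the volume's own paired patches.

    ``y`` should already be intensity-normalized (see
    :func:`patch_intensity_normalization`); training is bit-reproducible
    for a fixed seed on CPU.  Raises :class:`TrainingDivergedError` if the
    loss goes non-finite.
    """
    train_cfg = train_cfg if train_cfg is not None else TrainConfig()
    if model_cfg is None:
        model_cfg = SRModelConfig(scale=geometry.ratio)
    elif model_cfg.scale != geometry.ratio:
        model_cfg = replace(model_cfg, scale=geometry.ratio)

    sampler = _PatchSampler(y, geometry.ratio, train_cfg.patch_size, train_cfg.seed)
    down = _down_matrix(sampler.length, geometry.ratio, model_cfg.resample_convention)

    model = WideActivationSR(model_cfg, seed=train_cfg.seed)
    n_steps = max(1, train_cfg.n_patches // train_cfg.batch_size)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    sched = (
        OneCycleSchedule(train_cfg.lr, n_steps)
        if train_cfg.schedule == "one-cycle"
        else None
    )
    trace = np.empty(n_steps)
    for step in range(n_steps):
        hr = sampler.draw(train_cfg.batch_size)
        lr_batch = _degrade_batch(hr, profile.taps, down)
        pred = model.forward(lr_batch, train=True)
        diff = pred - hr
        loss = float(np.mean(diff * diff))
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at step {step}: {loss!r} "
                f"(lr={opt.lr:g}, batch={train_cfg.batch_size})"
            )
        trace[step] = loss
        model.backward(2.0 * diff / diff.size)
        opt.lr = sched.lr_at(step) if sched is not None else train_cfg.lr
        opt.step()
        if progress is not None:
            progress(step, loss)
    return TrainResult(model=model, loss_trace=trace, profile=profile, geometry=geometry)
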