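"""Synthetic isotropic phantoms for end-to-end testing.

Digital phantoms containing edges, curvature and texture stand in for real
isotropic acquisitions, so every stage — profile estimation, self-training,
inference, evaluation — is exercisable without downloads.  The structures
are deliberately oblique (tilted rods, nested shells) so that degrading the
through-plane axis produces visible aliasing and super-resolution gains are
measurable; purely axis-aligned content would understate them.  All shapes
are analytic functions evaluated on the integer grid with a seeded
generator, so a phantom is bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidArgumentError
from .forward_model import simulate_acquisition
from .profiles import SliceProfile
from .volume import AcquisitionGeometry, Volume

__all__ = ["PhantomSpec", "make_phantom", "make_pair"]


@dataclass
class PhantomSpec:
    """Recipe for a synthetic isotropic volume.

    ``structures`` selects which analytic elements are drawn; texture is
    band-limited smoothed noise; ``noise_sd`` adds i.i.d. Gaussian noise.
    Intensities land in roughly [0, 1.2] before noise.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    structures: tuple[str, ...] = ("gradient", "ellipsoids", "shells", "rods")
    texture_amplitude: float = 0.08
    noise_sd: float = 0.0
    n_lesions: int = 0
    lesion_radius_mm: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise InvalidArgumentError(f"degenerate shape {self.shape}")
        known = {"gradient", "ellipsoids", "shells", "rods"}
        bad = set(self.structures) - known
        if bad:
            raise InvalidArgumentError(f"unknown structures {sorted(bad)}")


def _coords(shape, spacing):
    axes = [spacing * (np.arange(n) - (n - 1) / 2.0) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def make_phantom(spec: PhantomSpec) -> Volume:
    """Generate the phantom volume (isotropic, through_axis=2 by default)."""
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = _coords(spec.shape, spec.spacing_mm)
    half = [spec.spacing_mm * (n - 1) / 2.0 for n in spec.shape]
    vol = np.zeros(spec.shape)

    if "gradient" in spec.structures:
        vol += 0.15 + 0.1 * (xx / (2 * half[2]) + yy / (2 * half[1]) + 0.5)

    if "ellipsoids" in spec.structures:
        for _ in range(3):
            c = [rng.uniform(-0.4, 0.4) * 2 * h for h in half]
            ax = [rng.uniform(0.15, 0.45) * 2 * h for h in half]
            amp = rng.uniform(0.25, 0.6)
            q = (
                ((zz - c[0]) / ax[0]) ** 2
                + ((yy - c[1]) / ax[1]) ** 2
                + ((xx - c[2]) / ax[2]) ** 2
            )
            vol += amp * (q <= 1.0)

    if "shells" in spec.structures:
        # nested spherical shells: strong curved edges in every direction
        rr = np.sqrt(zz**2 + yy**2 + xx**2)
        rmax = 0.85 * min(half)
        band = 0.12 * rmax
        for kshell, frac in enumerate((0.45, 0.7, 0.95)):
            ring = np.abs(rr - frac * rmax) < band / 2.0
            vol += (0.35 if kshell % 2 else 0.2) * ring

    if "rods" in spec.structures:
        # oblique cylinders: high-frequency through-plane content
        for _ in range(4):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            point = np.array([rng.uniform(-0.3, 0.3) * 2 * h for h in half])
            radius = rng.uniform(1.2, 2.5) * spec.spacing_mm
            px, py, pz = zz - point[0], yy - point[1], xx - point[2]
            t = px * direction[0] + py * direction[1] + pz * direction[2]
            d2 = (px - t * direction[0]) ** 2 + (py - t * direction[1]) ** 2 + (
                pz - t * direction[2]
            ) ** 2
            vol += 0.45 * (d2 <= radius**2)

    for _ in range(spec.n_lesions):
        c = [rng.uniform(-0.6, 0.6) * h for h in half]
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        vol += 0.8 * (d2 <= spec.lesion_radius_mm**2)

    if spec.texture_amplitude > 0:
        noise = rng.standard_normal(spec.shape)
        texture = gaussian_filter(noise, sigma=1.2, mode="nearest")
        texture /= max(texture.std(), 1e-12)
        vol += spec.texture_amplitude * texture

    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=spec.shape)

    return Volume(
        data=np.clip(vol, 0.0, None),
        spacing_mm=(spec.spacing_mm,) * 3,
        through_axis=2,
    )


def make_pair(
    spec: PhantomSpec,
    thickness_mm: float,
    gap_mm: float = 0.0,
    profile_kind: str = "gaussian",
    profile: SliceProfile | None = None,
) -> tuple[Volume, Volume, AcquisitionGeometry]:
    """Phantom plus its simulated anisotropic acquisition (shared FOV center)."""
    hr = make_phantom(spec)
    lr, geometry = simulate_acquisition(
        hr, thickness_mm, gap_mm, profile_kind, profile=profile
    )
    return hr, lr, geometry
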