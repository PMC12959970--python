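"""Top-level estimator API.

The method is fit/transform shaped: a model is fit to a single anisotropic
volume (profile estimation + self-training on its own in-plane patches) and
then transforms that volume (or another volume with the same geometry) into
its super-resolved counterpart.  The two stages are exposed as
scikit-learn-style estimators with ``get_params``/``set_params`` and
trailing-underscore fitted attributes, so they compose with sklearn
tooling; the functional API in the other modules stays available
underneath.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .errors import ConfigurationError, InvalidArgumentError
from .inference import SRResult, superresolve_volume
from .network import SRModelConfig, count_parameters
from .profile_estimation import (
    ProfileEstimatorConfig,
    estimate_profile,
    fallback_profile,
)
from .profiles import SliceProfile, load_profile
from .training import TrainConfig, patch_intensity_normalization, train
from .volume import AcquisitionGeometry, Volume

__all__ = ["AdversarialProfileEstimator", "EclareSuperResolver"]

#: preset -> (n_blocks, n_channels, n_patches, batch_size)
_PRESETS = {
    "paper": (16, 256, 1_000_000, 128),
    "desk": (4, 32, 10_000, 32),
}


def _infer_geometry(y: Volume) -> AcquisitionGeometry:
    """Geometry when only the header is known: HR separation = largest
    in-plane spacing, slice separation = through-plane spacing, thickness
    assumed equal to the separation (no-gap assumption)."""
    k = y.through_axis
    s_star = max(s for i, s in enumerate(y.spacing_mm) if i != k)
    s = y.spacing_mm[k]
    return AcquisitionGeometry(thickness_mm=s, gap_mm=0.0, hr_separation_mm=s_star)


class AdversarialProfileEstimator(BaseEstimator):
    """Estimate the relative slice profile of an anisotropic volume.

    ``fit(volume)`` runs the adversarial estimation; the result is
    available as ``profile_`` (a :class:`SliceProfile`) and ``taps_``.
    """

    def __init__(
        self,
        n_taps: int = 21,
        patch_size: int = 8,
        n_iterations: int = 1500,
        batch_size: int = 32,
        g_lr: float = 3e-4,
        d_lr: float = 5e-4,
        smoothness: float = 1e-3,
        seed: int = 0,
    ):
        self.n_taps = n_taps
        self.patch_size = patch_size
        self.n_iterations = n_iterations
        self.batch_size = batch_size
        self.g_lr = g_lr
        self.d_lr = d_lr
        self.smoothness = smoothness
        self.seed = seed

    def fit(self, X: Volume, y=None) -> "AdversarialProfileEstimator":
        if not isinstance(X, Volume):
            raise InvalidArgumentError("X must be an eclare Volume")
        cfg = ProfileEstimatorConfig(
            n_taps=self.n_taps,
            patch_size=self.patch_size,
            n_iterations=self.n_iterations,
            batch_size=self.batch_size,
            g_lr=self.g_lr,
            d_lr=self.d_lr,
            smoothness=self.smoothness,
            seed=self.seed,
        )
        self.profile_ = estimate_profile(X, cfg)
        self.taps_ = self.profile_.taps
        self.fwhm_mm_ = self.profile_.fwhm_mm
        return self


class EclareSuperResolver(BaseEstimator):
    """Self-supervised through-plane super-resolution of one volume.

    ``fit(volume)`` estimates (or builds) the slice profile and trains the
    SR network on patch pairs simulated from the volume's own in-plane
    slices; ``transform(volume)`` applies the trained network slice-wise
    along both orientations containing the through-plane axis and averages.

    Parameters
    ----------
    profile : "estimate", "fallback", a SliceProfile, or a tap-table path.
        "estimate" runs the adversarial estimator; "fallback" uses a
        Gaussian with FWHM equal to the slice separation.
    resample_convention : "fov" or "boundary"
        Resampling convention used in the network head, skip path and LR
        patch simulation ("boundary" exists for ablation).
    head : "shuffle" or "interp"
        Modified sub-pixel head versus plain resampling of the trunk
        output (ablation).
    preset : "desk" or "paper"
        Network/training sizes; individual values can be overridden.
    """

    def __init__(
        self,
        profile: str | SliceProfile = "estimate",
        resample_convention: str = "fov",
        head: str = "shuffle",
        preset: str = "desk",
        n_blocks: int | None = None,
        n_channels: int | None = None,
        n_patches: int | None = None,
        batch_size: int | None = None,
        learning_rate: float = 1e-3,
        profile_iterations: int = 1500,
        seed: int = 0,
    ):
        self.profile = profile
        self.resample_convention = resample_convention
        self.head = head
        self.preset = preset
        self.n_blocks = n_blocks
        self.n_channels = n_channels
        self.n_patches = n_patches
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.profile_iterations = profile_iterations
        self.seed = seed

    # -- configuration ------------------------------------------------------
    def _resolved_sizes(self) -> tuple[int, int, int, int]:
        if self.preset not in _PRESETS:
            raise ConfigurationError(
                f"unknown preset {self.preset!r}; choose from {sorted(_PRESETS)}"
            )
        blocks, channels, patches, batch = _PRESETS[self.preset]
        return (
            self.n_blocks or blocks,
            self.n_channels or channels,
            self.n_patches or patches,
            self.batch_size or batch,
        )

    def _resolve_profile(
        self, y_norm: Volume, geometry: AcquisitionGeometry
    ) -> SliceProfile:
        if isinstance(self.profile, SliceProfile):
            return self.profile
        if self.profile == "fallback":
            return fallback_profile(geometry)
        if self.profile == "estimate":
            cfg = ProfileEstimatorConfig(
                n_iterations=self.profile_iterations, seed=self.seed
            )
            return estimate_profile(y_norm, cfg, ratio=geometry.ratio)
        # otherwise treat as a tap-table path
        return load_profile(self.profile, tap_spacing_mm=geometry.hr_separation_mm)

    # -- estimator API ------------------------------------------------------
    def fit(self, X: Volume, y=None, geometry: AcquisitionGeometry | None = None):
        if not isinstance(X, Volume):
            raise InvalidArgumentError("X must be an eclare Volume")
        geometry = geometry if geometry is not None else _infer_geometry(X)
        blocks, channels, patches, batch = self._resolved_sizes()
        y_norm, self._denorm = patch_intensity_normalization(X)
        profile = self._resolve_profile(y_norm, geometry)
        model_cfg = SRModelConfig(
            scale=geometry.ratio,
            n_blocks=blocks,
            n_channels=channels,
            head=self.head,
            resample_convention=self.resample_convention,
        )
        train_cfg = TrainConfig(
            n_patches=patches,
            batch_size=batch,
            lr=self.learning_rate,
            seed=self.seed,
        )
        result = train(y_norm, profile, geometry, model_cfg, train_cfg)
        self.profile_ = profile
        self.geometry_ = geometry
        self.model_ = result.model
        self.loss_trace_ = result.loss_trace
        self.n_parameters_ = count_parameters(model_cfg)
        return self

    def transform(self, X: Volume) -> Volume:
        return self.transform_result(X).volume

    def transform_result(self, X: Volume) -> SRResult:
        """Like :meth:`transform` but returns intermediates and provenance."""
        if not hasattr(self, "model_"):
            raise ConfigurationError("call fit before transform")
        y_norm, denorm = patch_intensity_normalization(X)
        result = superresolve_volume(y_norm, self.model_)
        out = result.volume.copy_with(data=denorm(result.volume.data))
        inter = tuple(v.copy_with(data=denorm(v.data)) for v in result.intermediates)
        provenance = {
            "params": self.get_params(),
            "profile_taps": self.profile_.taps.tolist(),
            "ratio": self.geometry_.ratio,
            "seed": self.seed,
            "final_loss": float(self.loss_trace_[-1]),
        }
        return SRResult(volume=out, intermediates=inter, provenance=provenance)

    def fit_transform(self, X: Volume, y=None, **fit_kwargs) -> Volume:
        return self.fit(X, **fit_kwargs).transform(X)
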