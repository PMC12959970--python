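"""Wide-activation residual SR network with a noninteger-scale head.

The network maps a single LR 2-D slice (through-plane axis first) to an HR
slice.  A first convolution lifts the slice to ``n_channels`` feature maps;
``n_blocks`` wide-activation residual blocks follow (expand by ``expansion``
with a 3x3 conv, ReLU, contract back, identity skip); a final convolution
produces ``ceil(r)`` channels that a 1-D sub-pixel shuffle rearranges into
an integer upsampling of the through-plane axis.  Because the anisotropy
ratio r is generally noninteger, the integer factor is decomposed as

    r = ceil(r) * (r / ceil(r))

so the shuffle output is FOV-aware downsampled by r/ceil(r) to land on the
target HR grid.  A global skip adds the FOV-aware cubic upsampling of the
input on that same grid; the last trunk convolution is zero-initialized, so
at initialization the network *is* the cubic upsampler.

Resampling inside the head runs through dense linear operators from
:mod:`eclare.grids`, whose transposes provide the exact gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .grids import boundary_anchored_matrix, output_count, resample_matrix
from .nn import Conv2d, ReLU

__all__ = ["SRModelConfig", "decompose_scale", "WideActivationSR", "count_parameters"]


def decompose_scale(r: float) -> tuple[int, float]:
    """Split a scale factor r >= 1 into (ceil(r), r / ceil(r)).

    The integer part is realized by sub-pixel shuffle, the residual factor
    in (0, 1] by FOV-aware downsampling; their product is exactly r.  When
    r is integer the residual factor is exactly 1 and the downsampling
    step is skipped bit-exactly.
    """
    if not r >= 1:
        raise InvalidArgumentError(f"scale must be >= 1, got {r}")
    up = int(math.ceil(r))
    return up, r / up


@dataclass
class SRModelConfig:
    """Hyperparameters of the SR network.

    Defaults follow the wide-activation design: 16 residual blocks of 256
    channels, 4x expansion inside each block, 3x3 convolutions.  ``scale``
    is the anisotropy ratio r.  ``head`` selects the modified sub-pixel
    head ("shuffle") or plain resampling of the trunk output ("interp",
    the ablation alternative); ``resample_convention`` selects FOV-aware
    ("fov") or boundary-anchored ("boundary") resampling throughout the
    head and skip path.
    """

    scale: float = 1.0
    n_blocks: int = 16
    n_channels: int = 256
    expansion: float = 4.0
    residual_scale: float = 1.0
    head: str = "shuffle"
    resample_convention: str = "fov"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_channels < 1:
            raise InvalidArgumentError("n_blocks and n_channels must be >= 1")
        if self.head not in ("shuffle", "interp"):
            raise InvalidArgumentError(f"unknown head {self.head!r}")
        if self.resample_convention not in ("fov", "boundary"):
            raise InvalidArgumentError(
                f"unknown resample convention {self.resample_convention!r}"
            )
        if self.dtype not in ("float32", "float64"):
            raise InvalidArgumentError("dtype must be 'float32' or 'float64'")
        decompose_scale(self.scale)  # validates scale >= 1

    @property
    def int_scale(self) -> int:
        return decompose_scale(self.scale)[0]


def _up_matrix(n_in: int, factor_num: float, convention: str) -> np.ndarray:
    """Operator taking n_in samples to round(n_in * factor_num) samples."""
    d = 1.0 / factor_num
    if convention == "fov":
        return resample_matrix(n_in, d, "cubic")
    return boundary_anchored_matrix(n_in, d, "cubic")


class WideActivationSR:
    """The SR network; operates on batches of 2-D slices stacked as
    (B, H, W), where H — the first axis of each slice — is the LR
    (through-plane) axis being super-resolved."""

    def __init__(self, cfg: SRModelConfig, seed: int = 0):
        self.cfg = cfg
        self.dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(seed)
        c, e = cfg.n_channels, int(round(cfg.n_channels * cfg.expansion))
        self.head_conv = Conv2d(1, c, 3, rng=rng, dtype=self.dtype)
        self.blocks = []
        for _ in range(cfg.n_blocks):
            self.blocks.append(
                (
                    Conv2d(c, e, 3, rng=rng, dtype=self.dtype),
                    ReLU(),
                    Conv2d(e, c, 3, rng=rng, dtype=self.dtype),
                )
            )
        out_ch = cfg.int_scale if cfg.head == "shuffle" else 1
        # zero-init: at initialization the trunk contributes nothing and the
        # network equals its skip-path upsampler
        self.tail_conv = Conv2d(c, out_ch, 3, zero_init=True, dtype=self.dtype)
        self._mat_cache: dict[int, tuple] = {}

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        yield from self.head_conv.parameters()
        for c1, _, c2 in self.blocks:
            yield from c1.parameters()
            yield from c2.parameters()
        yield from self.tail_conv.parameters()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.copy() for i, (p, _) in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (p, _) in enumerate(self.parameters()):
            p[...] = state[f"p{i}"]

    # -- forward / backward -------------------------------------------------
    def _head_matrices(self, h: int) -> tuple[np.ndarray | None, np.ndarray]:
        """(post-shuffle downsample operator or None, skip upsample operator)
        for an input with ``h`` samples along the LR axis, at the model
        dtype (cached per input length)."""
        if h in self._mat_cache:
            return self._mat_cache[h]
        cfg = self.cfg
        conv = cfg.resample_convention
        skip = _up_matrix(h, cfg.scale, conv)
        if cfg.head == "interp":
            post = _up_matrix(h, cfg.scale, conv)
        else:
            up, factor = decompose_scale(cfg.scale)
            if factor == 1.0:
                post = None
            else:
                d = 1.0 / factor  # spacing ceil(r)/r on the shuffled lattice
                if conv == "fov":
                    post = resample_matrix(h * up, d, "cubic")
                else:
                    post = boundary_anchored_matrix(h * up, d, "cubic")
        pair = (
            None if post is None else post.astype(self.dtype),
            skip.astype(self.dtype),
        )
        self._mat_cache[h] = pair
        return pair

    def output_length(self, h: int) -> int:
        return output_count(h, 1.0 / self.cfg.scale)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, H, W) -> (B, round(H*r), W)."""
        if x.ndim != 3:
            raise InvalidArgumentError("expected a batch of 2-D slices (B, H, W)")
        cfg = self.cfg
        x = np.asarray(x, dtype=self.dtype)
        b, h, w = x.shape
        post_mat, skip_mat = self._head_matrices(h)
        feat = self.head_conv.forward(x[:, None, :, :])
        cache_feats = []
        for c1, relu, c2 in self.blocks:
            res = c2.forward(relu.forward(c1.forward(feat)))
            cache_feats.append(feat)
            feat = feat + cfg.residual_scale * res
        trunk = self.tail_conv.forward(feat)  # (B, S or 1, H, W)
        if cfg.head == "shuffle":
            s = cfg.int_scale
            # interleave channel s at through-plane position i*S + s
            shuffled = trunk.transpose(0, 2, 1, 3).reshape(b, h * s, w)
            pre_skip = shuffled if post_mat is None else np.einsum(
                "oi,biw->bow", post_mat, shuffled
            )
        else:
            pre_skip = np.einsum("oi,biw->bow", post_mat, trunk[:, 0])
        skip = np.einsum("oi,biw->bow", skip_mat, x)
        out = pre_skip + skip
        if train:
            self._cache = (x.shape, post_mat, skip_mat)
        return out

    def backward(self, grad: np.ndarray) -> None:
        """Accumulate parameter gradients for the last ``forward(train=True)``."""
        (b, h, w), post_mat, _ = self._cache
        cfg = self.cfg
        if cfg.head == "shuffle":
            s = cfg.int_scale
            g = grad if post_mat is None else np.einsum("oi,bow->biw", post_mat, grad)
            gtrunk = g.reshape(b, h, s, w).transpose(0, 2, 1, 3)
        else:
            gtrunk = np.einsum("oi,bow->biw", post_mat, grad)[:, None]
        gfeat = self.tail_conv.backward(gtrunk)
        for c1, relu, c2 in reversed(self.blocks):
            gres = cfg.residual_scale * gfeat
            gfeat = gfeat + c1.backward(relu.backward(c2.backward(gres)))
        self.head_conv.backward(gfeat)

    __call__ = forward


def count_parameters(cfg: SRModelConfig) -> int:
    """Total trainable parameter count for a configuration."""
    c, k = cfg.n_channels, 3
    e = int(round(cfg.n_channels * cfg.expansion))
    out_ch = cfg.int_scale if cfg.head == "shuffle" else 1
    n = (1 * k * k) * c + c                      # head conv
    n += cfg.n_blocks * (((c * k * k) * e + e) + ((e * k * k) * c + c))
    n += (c * k * k) * out_ch + out_ch           # tail conv
    return n
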