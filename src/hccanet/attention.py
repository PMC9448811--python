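"""Multi-channel fused channel/spatial attention (MCCBAM).

The mechanism refines a convolutional feature map FM ∈ R^{H×W×C} in two
stages:

1. Three selective-kernel (SK) channel-attention blocks run in parallel at
   reduction ratios r = 4, 8, 16.  Each block convolves FM with a 3×3 and a
   5×5 channel-preserving kernel (U3, U5), squeezes the summed branches by
   global average pooling, passes the C-vector through a two-layer
   bottleneck (C → ⌈C/r⌉ → C, rectifier between, sigmoid at the end) to get
   the gate Ma, sets Mb = 1 − Ma, and mixes the branches as
   Ma ⊗ U3 ⊕ Mb ⊗ U5 so every channel picks its own receptive-field scale.
2. The three refined maps are concatenated along channels (H×W×3C) and
   multiplied elementwise with FM replicated three times along channels.
   A spatial-attention map — sigmoid of a k×k convolution (k = 7) over the
   channelwise average- and max-pooled product — is then multiplied back
   into the product, giving the final H×W×3C output.

All convolutions are stride 1 with zero 'same' padding so the elementwise
products are well defined.  Every operation is differentiable through the
package's autodiff engine; the functional entry points below accept and
return plain numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _engine as eg
from ._engine import Tensor

__all__ = [
    "MCCBAMConfig",
    "SKBranchWeights",
    "AttentionWeights",
    "ChannelGate",
    "MCCBAMLayer",
    "sk_channel_gate",
    "sk_channel_attention",
    "spatial_attention_map",
    "mccbam",
]


# ---------------------------------------------------------------------------
# configuration and weight containers


@dataclass(frozen=True)
class MCCBAMConfig:
    """Hyperparameters of the attention block.

    reduction_ratios: bottleneck factors of the three parallel SK blocks.
    branch_kernels:   kernel sizes of the two SK convolution branches.
    spatial_kernel:   kernel size of the spatial-attention convolution.
    """

    reduction_ratios: tuple[int, ...] = (4, 8, 16)
    branch_kernels: tuple[int, int] = (3, 5)
    spatial_kernel: int = 7

    def __post_init__(self):
        for r in self.reduction_ratios:
            if r < 1:
                raise ValueError(f"reduction ratio must be >= 1, got {r}")
        for k in (*self.branch_kernels, self.spatial_kernel):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")


def _bottleneck_dim(c: int, r: int) -> int:
    d = math.ceil(c / r)
    if d < 1:
        raise ValueError(f"reduction ratio {r} empties the bottleneck for C={c}")
    return d


@dataclass
class SKBranchWeights:
    """Weights of one selective-kernel block (one reduction ratio)."""

    w3: np.ndarray  # (k1, k1, C, C) first branch kernel
    w5: np.ndarray  # (k2, k2, C, C) second branch kernel
    fc1_w: np.ndarray  # (C, ⌈C/r⌉)
    fc1_b: np.ndarray  # (⌈C/r⌉,)
    fc2_w: np.ndarray  # (⌈C/r⌉, C)
    fc2_b: np.ndarray  # (C,)


@dataclass
class AttentionWeights:
    """All weights of an MCCBAM block: one SK branch per ratio + spatial conv."""

    branches: dict[int, SKBranchWeights] = field(default_factory=dict)
    spatial_w: np.ndarray | None = None  # (k, k, 2, 1)
    spatial_b: np.ndarray | None = None  # (1,)

    @classmethod
    def initialize(cls, channels: int, cfg: MCCBAMConfig = MCCBAMConfig(),
                   seed: int = 0) -> "AttentionWeights":
        """Seed-controlled uniform fan-in initialisation."""
        if channels < 1:
            raise ValueError("channels must be >= 1")
        rng = np.random.default_rng(seed)
        k1, k2 = cfg.branch_kernels
        branches = {}
        for r in cfg.reduction_ratios:
            d = _bottleneck_dim(channels, r)
            branches[r] = SKBranchWeights(
                w3=eg.uniform_fan_in(rng, (k1, k1, channels, channels), k1 * k1 * channels),
                w5=eg.uniform_fan_in(rng, (k2, k2, channels, channels), k2 * k2 * channels),
                fc1_w=eg.uniform_fan_in(rng, (channels, d), channels),
                fc1_b=np.zeros(d),
                fc2_w=eg.uniform_fan_in(rng, (d, channels), d),
                fc2_b=np.zeros(channels),
            )
        ks = cfg.spatial_kernel
        return cls(
            branches=branches,
            spatial_w=eg.uniform_fan_in(rng, (ks, ks, 2, 1), ks * ks * 2),
            spatial_b=np.zeros(1),
        )

    def branch(self, r: int) -> SKBranchWeights:
        if r not in self.branches:
            raise KeyError(f"no SK branch initialised for reduction ratio {r}")
        return self.branches[r]


@dataclass
class ChannelGate:
    """Complementary per-channel gates of one SK block: Mb = 1 - Ma."""

    ma: np.ndarray
    mb: np.ndarray

    def __post_init__(self):
        if not (np.all(self.ma > 0) and np.all(self.ma < 1)):
            raise ValueError("Ma must lie strictly in (0, 1)")
        if not np.all(self.ma + self.mb == 1.0):
            raise ValueError("gate complement violated: Ma + Mb != 1")


# float saturation guard for sigmoid outputs exposed through the
# functional API (the trainable layer keeps raw values)
_GATE_EPS = 1e-12


# ---------------------------------------------------------------------------
# graph builders (single source of truth for functional API and model layer)


def _validate_fm(fm: np.ndarray) -> np.ndarray:
    fm = np.asarray(fm, dtype=np.float64)
    if fm.ndim != 3 or min(fm.shape) < 1:
        raise ValueError(f"feature map must be H x W x C with positive dims, got {fm.shape}")
    if not np.all(np.isfinite(fm)):
        raise ValueError("feature map contains non-finite values")
    return fm


def _sk_gate_graph(fm: Tensor, bw) -> tuple[Tensor, Tensor, Tensor]:
    """Returns (Ma, U3, U5); fm is (N, H, W, C)."""
    u3 = eg.conv2d(fm, bw.w3)
    u5 = eg.conv2d(fm, bw.w5)
    s = eg.mean_axes(u3 + u5, (1, 2))            # GAP -> (N, C)
    z = eg.relu(eg.matmul(s, bw.fc1_w) + bw.fc1_b)
    ma = eg.sigmoid(eg.matmul(z, bw.fc2_w) + bw.fc2_b)
    return ma, u3, u5


def _sk_attention_graph(fm: Tensor, bw) -> Tensor:
    ma, u3, u5 = _sk_gate_graph(fm, bw)
    n, c = ma.shape
    ma_b = eg.reshape(ma, (n, 1, 1, c))
    mb_b = eg.rsub_const(1.0, ma_b)
    return (ma_b * u3) + (mb_b * u5)


def _spatial_graph(fm: Tensor, w, b) -> Tensor:
    avg = eg.mean_axes(fm, (3,), keepdims=True)
    mx = eg.max_axis(fm, 3, keepdims=True)
    stacked = eg.concat([avg, mx], axis=3)
    return eg.sigmoid(eg.conv2d(stacked, w, b))


def _mccbam_graph(fm: Tensor, ratios, branches, sw, sb) -> Tensor:
    refined = [_sk_attention_graph(fm, branches[r]) for r in ratios]
    cat = eg.concat(refined, axis=3)                       # (N, H, W, 3C)
    rep = eg.concat([fm] * len(ratios), axis=3)            # FM replicated
    prod = cat * rep
    smap = _spatial_graph(prod, sw, sb)
    return prod * smap


def _lift(w: AttentionWeights, ratios) -> tuple[dict, Tensor, Tensor]:
    branches = {}
    for r in ratios:
        bw = w.branch(r)
        branches[r] = SKBranchWeights(
            *(Tensor(a) for a in (bw.w3, bw.w5, bw.fc1_w, bw.fc1_b, bw.fc2_w, bw.fc2_b))
        )
    return branches, Tensor(w.spatial_w), Tensor(w.spatial_b)


# ---------------------------------------------------------------------------
# functional operations (numpy in, numpy out)


def sk_channel_gate(fm: np.ndarray, r: int, weights: AttentionWeights) -> ChannelGate:
    """Per-channel selective-kernel gate at reduction ratio ``r``.

    Ma = sigmoid(FC2(relu(FC1(GAP(U3 + U5))))), Mb = 1 - Ma, both length C.
    """
    fm = _validate_fm(fm)
    _bottleneck_dim(fm.shape[2], r)
    branches, _, _ = _lift_single(weights, r)
    ma_t, _, _ = _sk_gate_graph(Tensor(fm[None]), branches)
    # saturated sigmoids round to exactly 0/1 in floats; nudge back into
    # the open interval (well below any oracle tolerance)
    ma = np.clip(ma_t.data[0], _GATE_EPS, 1.0 - _GATE_EPS)
    return ChannelGate(ma=ma, mb=1.0 - ma)


def _lift_single(weights: AttentionWeights, r: int) -> tuple[SKBranchWeights, None, None]:
    bw = weights.branch(r)
    lifted = SKBranchWeights(
        *(Tensor(a) for a in (bw.w3, bw.w5, bw.fc1_w, bw.fc1_b, bw.fc2_w, bw.fc2_b))
    )
    return lifted, None, None


def sk_channel_attention(fm: np.ndarray, r: int, weights: AttentionWeights) -> np.ndarray:
    """Channel-refined map Ma ⊗ U3 ⊕ Mb ⊗ U5; same shape as the input."""
    fm = _validate_fm(fm)
    _bottleneck_dim(fm.shape[2], r)
    branches, _, _ = _lift_single(weights, r)
    out = _sk_attention_graph(Tensor(fm[None]), branches)
    return out.data[0]


def spatial_attention_map(fm: np.ndarray, k: int, weights: AttentionWeights) -> np.ndarray:
    """Sigmoid(k×k conv over [channel-avg; channel-max]); shape H×W×1, values in (0,1)."""
    fm = _validate_fm(fm)
    if k % 2 == 0 or k < 1:
        raise ValueError(f"spatial kernel must be odd and >= 1, got {k}")
    sw = np.asarray(weights.spatial_w, dtype=np.float64)
    if sw.shape[:2] != (k, k):
        raise ValueError(f"spatial weights are {sw.shape[0]}x{sw.shape[1]}, expected {k}x{k}")
    out = _spatial_graph(Tensor(fm[None]), Tensor(sw), Tensor(weights.spatial_b))
    return np.clip(out.data[0], _GATE_EPS, 1.0 - _GATE_EPS)


def mccbam(fm: np.ndarray, cfg: MCCBAMConfig, weights: AttentionWeights) -> np.ndarray:
    """Full attention block; input H×W×C, output H×W×3C."""
    fm = _validate_fm(fm)
    for r in cfg.reduction_ratios:
        _bottleneck_dim(fm.shape[2], r)
    branches, sw, sb = _lift(weights, cfg.reduction_ratios)
    out = _mccbam_graph(Tensor(fm[None]), cfg.reduction_ratios, branches, sw, sb)
    return out.data[0]


# ---------------------------------------------------------------------------
# trainable model layer


class MCCBAMLayer(eg.Module):
    """MCCBAM as a trainable layer for the grading network.

    Input (N, H, W, C), output (N, H, W, 3C).
    """

    def __init__(self, channels: int, cfg: MCCBAMConfig = MCCBAMConfig(),
                 rng: np.random.Generator | None = None, seed: int = 0):
        self.cfg = cfg
        self.channels = channels
        if rng is None:
            rng = np.random.default_rng(seed)
        init = AttentionWeights.initialize(channels, cfg, seed=int(rng.integers(2**31)))
        self.branches = {
            r: SKBranchWeights(
                *(eg.Parameter(a) for a in (bw.w3, bw.w5, bw.fc1_w, bw.fc1_b,
                                            bw.fc2_w, bw.fc2_b))
            )
            for r, bw in init.branches.items()
        }
        self.spatial_w = eg.Parameter(init.spatial_w)
        self.spatial_b = eg.Parameter(init.spatial_b)

    @property
    def out_channels(self) -> int:
        return self.channels * len(self.cfg.reduction_ratios)

    def __call__(self, fm: Tensor) -> Tensor:
        return _mccbam_graph(fm, self.cfg.reduction_ratios, self.branches,
                             self.spatial_w, self.spatial_b)

    def weights_view(self) -> AttentionWeights:
        """Current weights as a plain-array container (shared memory)."""
        return AttentionWeights(
            branches={
                r: SKBranchWeights(bw.w3.data, bw.w5.data, bw.fc1_w.data,
                                   bw.fc1_b.data, bw.fc2_w.data, bw.fc2_b.data)
                for r, bw in self.branches.items()
            },
            spatial_w=self.spatial_w.data,
            spatial_b=self.spatial_b.data,
        )
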