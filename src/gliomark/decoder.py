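"""Hierarchical segmentation decoder.

Three upsampling blocks climb from the /8 latent back to full resolution,
each doubling the spatial size with trilinear interpolation, concatenating
the same-resolution encoder skip, and refining with a residual
convolution-BN-ReLU unit.  A squeeze-and-excitation block recalibrates the
final feature channels, optional additive attention gates filter the skips,
and a 1x1x1 head produces per-voxel class probabilities over the five
classes (background + ET/NETC/SNFH/RC).  Deep supervision emits auxiliary
logits at /2 and /4 during training.  Post-processing is argmax plus
removal of small connected components per tumor class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import NUM_CLASSES, LabelVolume
from .nn import (
    BatchNorm3d,
    Conv3d,
    Linear,
    Module,
    PointwiseConv3d,
    Tensor,
    as_tensor,
    concatenate,
)
from .nn import functional as F

__all__ = ["DecoderConfig", "SegmentationOutput", "SegDecoder", "SEBlock", "AttentionGate", "postprocess"]


@dataclass
class DecoderConfig:
    latent_channels: int = 128
    skip_channels: tuple[int, int, int] = (32, 32, 64)  # at /1, /2, /4
    widths: tuple[int, int, int] = (96, 64, 32)  # blocks at /4, /2, /1
    num_classes: int = NUM_CLASSES
    se_ratio: int = 4
    attention_gates: bool = False
    deep_supervision: bool = True
    aux_weights: tuple[float, float] = (0.5, 0.25)  # at /2 and /4
    lambda_dice: float = 1.0
    lambda_ce: float = 1.0
    min_component: int = 20

    def __post_init__(self):
        if self.lambda_dice < 0 or self.lambda_ce < 0 or (self.lambda_dice == 0 and self.lambda_ce == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")
        if any(w < 0 for w in self.aux_weights):
            raise ValueError("auxiliary weights must be >= 0")


@dataclass
class SegmentationOutput:
    """Per-voxel class probabilities + auxiliary logits + discrete labels."""

    probabilities: Tensor  # (N, K, H, W, D), simplex per voxel
    aux_logits: list  # [(N, K, H/2...), (N, K, H/4...)] when deep supervision on
    label_map: np.ndarray | None = None  # (N, H, W, D) after postprocess


class SEBlock(Module):
    """Squeeze-and-excitation channel gate.

    Squeeze is the spatial mean per channel; excitation is a two-layer
    bottleneck with a sigmoid gate in (0, 1) multiplied back onto the input.
    With zeroed excitation weights the gate is sigmoid(0) = 0.5 exactly.
    """

    def __init__(self, channels: int, ratio: int, rng):
        super().__init__()
        if channels % ratio:
            raise ValueError(f"channels {channels} not divisible by se ratio {ratio}")
        self.fc1 = Linear(channels, channels // ratio, rng)
        self.fc2 = Linear(channels // ratio, channels, rng)

    def forward(self, x):
        s = x.mean(axis=(2, 3, 4))  # (N, C) squeeze
        g = self.fc2(self.fc1(s).relu()).sigmoid()
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1, 1)


class AttentionGate(Module):
    """Additive attention gate on a skip connection.

    gate = sigmoid(psi(ReLU(Wx . skip + Wg . upsample(gating)))) in (0, 1),
    broadcast over channels and multiplied onto the skip.
    """

    def __init__(self, skip_channels: int, gating_channels: int, inter: int, rng):
        super().__init__()
        self.wx = PointwiseConv3d(skip_channels, inter, rng)
        self.wg = PointwiseConv3d(gating_channels, inter, rng)
        self.psi = PointwiseConv3d(inter, 1, rng)

    def forward(self, skip, gating):
        g = F.resize_trilinear(gating, skip.shape[2:])
        a = self.psi((self.wx(skip) + self.wg(g)).relu()).sigmoid()
        return skip * a


class UpsampleBlock(Module):
    """Trilinear x2 upsampling, skip concatenation, conv-BN-ReLU with an
    internal residual projection of the interpolated input."""

    def __init__(self, c_in: int, c_skip: int, c_out: int, rng, gate: bool):
        super().__init__()
        self.gate = AttentionGate(c_skip, c_in, max(c_skip // 2, 1), rng) if gate else None
        self.conv = Conv3d(c_in + c_skip, c_out, 3, rng)
        self.bn = BatchNorm3d(c_out)
        self.res_proj = PointwiseConv3d(c_in, c_out, rng, bias=False)

    def forward(self, x, skip):
        up = F.upsample_trilinear(x, 2)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"skip resolution {skip.shape[2:]} does not match upsampled {up.shape[2:]}"
            )
        s = self.gate(skip, x) if self.gate is not None else skip
        h = self.bn(self.conv(concatenate([up, s], axis=1))).relu()
        return h + self.res_proj(up)


class SegDecoder(Module):
    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        sc = cfg.skip_channels
        w = cfg.widths
        self.up0 = UpsampleBlock(cfg.latent_channels, sc[2], w[0], rng, cfg.attention_gates)  # /8 -> /4
        self.up1 = UpsampleBlock(w[0], sc[1], w[1], rng, cfg.attention_gates)  # /4 -> /2
        self.up2 = UpsampleBlock(w[1], sc[0], w[2], rng, cfg.attention_gates)  # /2 -> /1
        self.se = SEBlock(w[2], cfg.se_ratio, rng)
        self.head = PointwiseConv3d(w[2], cfg.num_classes, rng)
        if cfg.deep_supervision:
            self.aux_head1 = PointwiseConv3d(w[1], cfg.num_classes, rng)  # /2
            self.aux_head0 = PointwiseConv3d(w[0], cfg.num_classes, rng)  # /4
        # zero-init the class heads: training starts from uniform class
        # probabilities instead of saturated softmax logits
        heads = [self.head] + ([self.aux_head1, self.aux_head0] if cfg.deep_supervision else [])
        for h in heads:
            h.weight.data[...] = 0.0
            h.bias.data[...] = 0.0

    def forward(self, latent, skips: list) -> SegmentationOutput:
        """`skips` is the encoder pyramid [/1, /2, /4]."""
        d4 = self.up0(as_tensor(latent), as_tensor(skips[2]))
        d2 = self.up1(d4, as_tensor(skips[1]))
        d1 = self.up2(d2, as_tensor(skips[0]))
        d1 = self.se(d1)
        logits = self.head(d1)
        probs = logits.softmax(axis=1)
        aux = []
        if self.cfg.deep_supervision and self.training:
            aux = [self.aux_head1(d2), self.aux_head0(d4)]
        return SegmentationOutput(probabilities=probs, aux_logits=aux)


def postprocess(probs: np.ndarray | Tensor, min_component: int = 20) -> np.ndarray:
    """Voxel-wise argmax, then reassign connected components of each tumor
    class smaller than `min_component` voxels to background.

    `probs` is (K, H, W, D) or (N, K, H, W, D); returns int labels without
    the leading class axis.
    """
    p = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
    if p.ndim == 5:
        return np.stack([postprocess(q, min_component) for q in p])
    labels = p.argmax(axis=0).astype(np.int16)
    if min_component > 0:
        for cls in range(1, p.shape[0]):
            comp, n = ndimage.label(labels == cls)
            if not n:
                continue
            sizes = np.bincount(comp.ravel())
            small = np.flatnonzero(sizes < min_component)
            small = small[small > 0]
            if small.size:
                labels[np.isin(comp, small)] = 0
    return labels
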