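"""Cross-modality attention fusion (CMAF).

Each of the four MRI sequences is embedded by a *shared* convolutional
operator into a common C'-channel feature space.  A lightweight per-voxel
MLP then scores the concatenated modality features and a softmax turns the
four scores into voxel-wise modality weights, so the fused volume

    F(i,j,k) = sum_m alpha_m(i,j,k) * F_m(i,j,k)

is a convex combination of the modality embeddings at every voxel.  The
attention field itself is exportable as four NIfTI maps, one per modality,
summing to one voxel-wise — a direct readout of which sequence the network
relies on where.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from . import MODALITIES
from .nn import (
    BatchNorm3d,
    Conv3d,
    Dropout,
    Module,
    PointwiseConv3d,
    Tensor,
    as_tensor,
    concatenate,
)

__all__ = ["CmafConfig", "CMAF", "fuse", "export_attention_maps"]


@dataclass
class CmafConfig:
    channels: int = 32  # C', the common embedding width
    embed_kernel: int = 3  # 3 or 1
    extra_hidden: bool = False  # optional second hidden layer of width C'/2
    dropout: float = 0.2
    dropout_position: str = "after_relu"  # or "before_relu"
    batchnorm: bool = True

    def __post_init__(self):
        if self.embed_kernel not in (1, 3):
            raise ValueError("embed_kernel must be 1 or 3")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")


class CMAF(Module):
    def __init__(self, cfg: CmafConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        if cfg.embed_kernel == 1:
            self.embed_conv = PointwiseConv3d(1, c, rng)
        else:
            self.embed_conv = Conv3d(1, c, cfg.embed_kernel, rng)
        if cfg.batchnorm:
            self.embed_norm = BatchNorm3d(c)
        self.mlp_in = PointwiseConv3d(4 * c, 4 * c, rng)
        # identity init: the hidden layer starts as a pass-through of the
        # (non-negative) modality embeddings, so the logit layer can learn
        # direct correlations between embedding channels and modality
        # relevance from the first step
        self.mlp_in.weight.data[...] = np.eye(4 * c)
        self.mlp_in.bias.data[...] = 0.0
        self.drop = Dropout(cfg.dropout, rng)
        if cfg.extra_hidden:
            self.mlp_mid = PointwiseConv3d(4 * c, max(c // 2, 1), rng)
            self.mlp_out = PointwiseConv3d(max(c // 2, 1), 4, rng)
        else:
            self.mlp_mid = None
            self.mlp_out = PointwiseConv3d(4 * c, 4, rng)
        # start from uniform modality weights (zero logits)
        self.mlp_out.weight.data[...] = 0.0
        self.mlp_out.bias.data[...] = 0.0

    # -- core operations ----------------------------------------------

    def embed_modalities(self, stack) -> list[Tensor]:
        """Shared embedding of each modality: one C'-channel volume per
        sequence.  `stack` is a Tensor/array of shape (N, 4, H, W, D)."""
        x = as_tensor(stack)
        if x.ndim != 5 or x.shape[1] != len(MODALITIES):
            raise ValueError(f"expected (N, 4, H, W, D) input, got shape {x.shape}")
        n, _, h, w, d = x.shape
        flat = x.reshape(n * 4, 1, h, w, d)  # shared weights across modalities
        f = self.embed_conv(flat)
        if self.cfg.batchnorm:
            f = self.embed_norm(f)
        f = f.relu()
        f = f.reshape(n, 4, self.cfg.channels, h, w, d)
        return [f[:, m] for m in range(4)]

    def attention_weights(self, features: list[Tensor]) -> Tensor:
        """Per-voxel softmax over 4 modality logits -> (N, 4, H, W, D)."""
        shapes = {f.shape for f in features}
        if len(shapes) != 1:
            raise ValueError(f"modality feature shapes differ: {shapes}")
        z = concatenate(features, axis=1)  # (N, 4C', H, W, D)
        h = self.mlp_in(z)
        if self.cfg.dropout_position == "before_relu":
            h = self.drop(h).relu()
        else:
            h = self.drop(h.relu())
        if self.mlp_mid is not None:
            h = self.mlp_mid(h).relu()
        logits = self.mlp_out(h)
        return logits.softmax(axis=1)

    def forward(self, stack) -> tuple[Tensor, Tensor]:
        """Returns (F_fused (N,C',H,W,D), attention (N,4,H,W,D))."""
        feats = self.embed_modalities(stack)
        attn = self.attention_weights(feats)
        return fuse(feats, attn), attn


def fuse(features: list[Tensor], attn: Tensor, tol: float = 1e-6) -> Tensor:
    """Attention-weighted convex combination of the four modality features."""
    a = attn.data if isinstance(attn, Tensor) else np.asarray(attn)
    sums = a.sum(axis=1)
    if np.any(a < -tol) or np.max(np.abs(sums - 1.0)) > max(tol, 1e-6):
        raise ValueError("attention field violates the simplex invariant")
    attn = as_tensor(attn)
    out = None
    for m, f in enumerate(features):
        term = as_tensor(f) * attn[:, m : m + 1]
        out = term if out is None else out + term
    return out


def export_attention_maps(attn: np.ndarray | Tensor, affine: np.ndarray | None = None,
                          directory=None, prefix: str = "attention"):
    """One scalar NIfTI map per modality, voxel-aligned with the input.

    `attn` is (4, H, W, D) (or (1, 4, H, W, D)); returns the four
    `Nifti1Image`s and writes them to `directory` when given.
    """
    a = attn.data if isinstance(attn, Tensor) else np.asarray(attn)
    if a.ndim == 5:
        a = a[0]
    affine = np.eye(4) if affine is None else affine
    images = {m: nib.Nifti1Image(np.ascontiguousarray(a[i]), affine) for i, m in enumerate(MODALITIES)}
    if directory is not None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for m, img in images.items():
            nib.save(img, directory / f"{prefix}_{m}.nii.gz")
    return images
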