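"""Molecular marker prediction head.

The latent volume is gated by the predicted tumor extent (binary mask or
soft tumor probability, downsampled to latent resolution), pooled into a
patient-level vector by attention-based global pooling (AGP), and passed to
three independent two-layer heads with sigmoid outputs — one each for IDH
mutation, 1p/19q co-deletion and TERT promoter mutation.  Decision
thresholds per marker come from Youden's J or a sensitivity floor.

AGP computes softmax weights over all voxels from a tanh-bottlenecked score.
When a gate is present its value multiplies the attention weights
(`gate_prior`), so gated-out voxels receive zero pooled contribution even
though the softmax itself runs over the full volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import MARKERS
from .nn import Dropout, Linear, Module, Tensor, as_tensor
from .nn import functional as F

log = logging.getLogger(__name__)

__all__ = [
    "MarkerHeadConfig",
    "MarkerProbabilities",
    "gate_features",
    "AttentionPool",
    "MarkerHead",
    "optimize_threshold",
]


@dataclass
class MarkerHeadConfig:
    latent_channels: int = 128
    attn_hidden: int = 64  # tanh bottleneck width of the AGP score
    head_hidden: int = 64  # per-marker hidden width
    dropout: float = 0.3
    gate_mode_train: str = "soft"  # differentiable gate during training
    gate_mode_eval: str = "binary"
    gate_prior: bool = True


@dataclass
class MarkerProbabilities:
    """Calibratable per-marker probabilities with decision thresholds."""

    probabilities: dict[str, float]
    thresholds: dict[str, float] | None = None

    def calls(self) -> dict[str, int]:
        thr = self.thresholds or {m: 0.5 for m in MARKERS}
        return {m: int(self.probabilities[m] >= thr[m]) for m in MARKERS}


def gate_features(latent: Tensor, seg_probs, mode: str = "soft") -> tuple[Tensor, Tensor | None]:
    """Mask the latent volume with the predicted tumor extent.

    `seg_probs` is (N, K, H, W, D) full-resolution class probabilities with
    channel 0 = background.  mode "binary": the union of tumor classes,
    max-pooled down to latent resolution (preserves small lesions);
    mode "soft": per-voxel tumor probability (1 - background probability),
    average-pooled down, kept differentiable.  A gate that is identically
    zero falls back to ungated pooling with a warning.

    Returns (gated latent, gate at latent resolution or None on fallback).
    """
    latent = as_tensor(latent)
    n, _, h, w, d = latent.shape
    if mode == "binary":
        p = seg_probs.data if isinstance(seg_probs, Tensor) else np.asarray(seg_probs)
        tumor = (p.argmax(axis=1) > 0).astype(float)  # (N, H*, W*, D*)
        k = tumor.shape[1] // h
        t = tumor.reshape(n, h, k, w, k, d, k)
        gate = Tensor(t.max(axis=(2, 4, 6))[:, None])  # max-pool
    elif mode == "soft":
        sp = as_tensor(seg_probs)
        tumor = 1.0 - sp[:, 0:1]  # (N, 1, H*, W*, D*)
        k = tumor.shape[2] // h
        gate = F.avg_pool3d(tumor, k) if k > 1 else tumor
    else:
        raise ValueError(f"unknown gate mode {mode!r}")
    if np.all(gate.data == 0):
        log.warning("segmentation gate is identically zero; pooling ungated features")
        return latent, None
    return latent * gate, gate


class AttentionPool(Module):
    """Attention-based global pooling: z = sum_ijk w_ijk F_ijk with
    w = softmax(W_a tanh(W_f F))."""

    def __init__(self, channels: int, hidden: int, rng):
        super().__init__()
        self.wf = Linear(channels, hidden, rng)
        self.wa = Linear(hidden, 1, rng, bias=False)
        # zero-init the score layer: pooling starts as the (gated) spatial
        # mean — the composition statistic — and sharpens as W_a trains
        self.wa.weight.data[...] = 0.0

    def forward(self, latent: Tensor, gate: Tensor | None = None) -> Tensor:
        n, c = latent.shape[:2]
        tokens = latent.reshape(n, c, -1).transpose(0, 2, 1)  # (N, V, C)
        scores = self.wa(self.wf(tokens).tanh())  # (N, V, 1)
        w = scores.softmax(axis=1)
        if gate is not None:
            gv = gate.reshape(n, -1, 1)
            w = w * gv
            total = w.sum(axis=1, keepdims=True)
            if np.any(total.data <= 0):
                log.warning("attention mass vanished under the gate prior; renormalizing without it")
                w = scores.softmax(axis=1)
            else:
                w = w / total
        return (w * tokens).sum(axis=1)  # (N, C)


class MarkerHead(Module):
    """Three independent sigmoid heads over the pooled patient vector."""

    def __init__(self, cfg: MarkerHeadConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.pool = AttentionPool(cfg.latent_channels, cfg.attn_hidden, rng)
        for m in MARKERS:
            safe = m.replace("/", "")
            setattr(self, f"drop_{safe}", Dropout(cfg.dropout, rng))
            setattr(self, f"fc1_{safe}", Linear(cfg.latent_channels, cfg.head_hidden, rng))
            fc2 = Linear(cfg.head_hidden, 1, rng)
            # zero-init output layer: every marker starts at probability 0.5
            fc2.weight.data[...] = 0.0
            fc2.bias.data[...] = 0.0
            setattr(self, f"fc2_{safe}", fc2)

    def predict_markers(self, z: Tensor) -> dict[str, Tensor]:
        """Per-marker positive-class probability tensors (N, 1)."""
        out = {}
        for m in MARKERS:
            safe = m.replace("/", "")
            h = getattr(self, f"fc1_{safe}")(z).relu()
            h = getattr(self, f"drop_{safe}")(h)
            out[m] = getattr(self, f"fc2_{safe}")(h).sigmoid()
        return out

    def forward(self, latent: Tensor, seg_probs=None) -> dict[str, Tensor]:
        mode = self.cfg.gate_mode_train if self.training else self.cfg.gate_mode_eval
        if seg_probs is None:
            gated, gate = as_tensor(latent), None  # single-task mode: ungated
        else:
            gated, gate = gate_features(latent, seg_probs, mode)
        z = self.pool(gated, gate if self.cfg.gate_prior else None)
        return self.predict_markers(z)


def optimize_threshold(scores, labels, method: str = "youden", sensitivity_floor: float = 0.9):
    """Decision-threshold selection on held-out scores.

    "youden": maximize sensitivity + specificity - 1 over candidate
    thresholds (midpoints between adjacent distinct scores, plus 0 and 1),
    ties broken toward higher sensitivity (lower threshold).
    "sensitivity_floor": smallest threshold with sensitivity >= the floor.

    Returns (threshold, stats dict with J/sensitivity/specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    for cls in (0, 1):
        if not np.any(labels == cls):
            raise ValueError(f"labels contain no class-{cls} samples")

    uniq = np.unique(scores)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq.min() / 2.0], [1.0]))
    candidates = np.unique(candidates)
    pos = labels == 1
    best_t, best_stats = None, None
    for t in candidates:
        pred = scores >= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        j = sens + spec - 1.0
        stats = {"j": float(j), "sensitivity": float(sens), "specificity": float(spec)}
        if method == "youden":
            if best_stats is None or j > best_stats["j"] + 1e-12 or (
                abs(j - best_stats["j"]) <= 1e-12 and sens > best_stats["sensitivity"] + 1e-12
            ):
                best_t, best_stats = float(t), stats
        elif method == "sensitivity_floor":
            if sens >= sensitivity_floor and (best_t is None or t > best_t):
                best_t, best_stats = float(t), stats
        else:
            raise ValueError(f"unknown method {method!r}")
    if best_t is None:  # sensitivity floor unattainable above threshold 0
        best_t, best_stats = 0.0, {"j": 0.0, "sensitivity": 1.0, "specificity": 0.0}
    return best_t, best_stats
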