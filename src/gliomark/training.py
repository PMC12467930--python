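"""Loss functions and the optimization loop.

Segmentation uses the compound loss L = lambda_Dice * L_Dice +
lambda_CE * L_CE (soft Dice averaged over foreground classes + voxel-mean
multi-class cross-entropy), with deep-supervision terms at /2 and /4.
Marker classification uses label-smoothed binary cross-entropy per marker
(optional focal modulation), weighted by beta and masked over missing (NA)
labels.  The total is L_seg + gamma * L_clf.  Optimization is AdamW with a
cosine learning-rate schedule, validation-based early stopping, and
best-validation checkpointing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import MARKERS
from .data import NUM_CLASSES
from .model import GliomaNet
from .nn import AdamW, Tensor, as_tensor, cosine_lr, no_grad
from .preprocess import AugmentConfig, augment, one_hot, sample_tumor_patch

log = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "TrainConfig",
    "dice_loss",
    "cross_entropy_loss",
    "compound_seg_loss",
    "marker_loss",
    "total_loss",
    "train",
]

DICE_SMOOTH = 1e-5


@dataclass
class LossWeights:
    lambda_dice: float = 1.0
    lambda_ce: float = 1.0
    beta: tuple[float, float, float] = (1.0, 1.0, 1.0)  # IDH, 1p/19q, TERT
    gamma: float = 1.0  # segmentation-vs-classification balance
    label_smoothing: float = 0.1
    focal: bool = False
    focal_gamma: float = 2.0
    aux_weights: tuple[float, float] = (0.5, 0.25)

    def __post_init__(self):
        if min(self.lambda_dice, self.lambda_ce, self.gamma, *self.beta) < 0:
            raise ValueError("loss weights must be non-negative")
        if not 0.0 <= self.label_smoothing < 0.5:
            raise ValueError("label smoothing must lie in [0, 0.5)")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 2
    max_epochs: int = 150
    steps_per_epoch: int | None = None  # default: ceil(n_train / batch)
    patience: int = 20  # early stopping, epochs without val improvement
    patch_size: int = 128
    patch_center: str = "tumor_voxel"  # or "centroid"
    val_fraction: float = 0.2
    seed: int = 0
    min_lr: float = 0.0
    augment: AugmentConfig | None = None

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.patch_size < 1:
            raise ValueError("rates and sizes must be positive")


# ------------------------------------------------------------- losses


def dice_loss(probs: Tensor, onehot_truth, smooth: float = DICE_SMOOTH) -> Tensor:
    """1 - soft Dice, computed per class then averaged over foreground classes.

    probs: (N, K, ...) simplex-valid; onehot_truth same shape.
    """
    probs = as_tensor(probs)
    truth = as_tensor(onehot_truth)
    if probs.shape != truth.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {truth.shape}")
    axes = tuple(range(2, probs.ndim))
    inter = (probs * truth).sum(axis=axes)
    denom = probs.sum(axis=axes) + truth.sum(axis=axes)
    dice = (2.0 * inter + smooth) / (denom + smooth)  # (N, K)
    return 1.0 - dice[:, 1:].mean()


def cross_entropy_loss(probs: Tensor, truth_labels, clamp: float = 1e-12) -> Tensor:
    """Mean over voxels of -log p_truth; `truth_labels` are int labels (N, ...)."""
    probs = as_tensor(probs)
    truth = np.asarray(truth_labels, dtype=int)
    oh = (truth[:, None] == np.arange(probs.shape[1]).reshape(1, -1, *([1] * truth[0].ndim))).astype(float)
    p_truth = (probs * Tensor(oh)).sum(axis=1)
    if np.any(p_truth.data < clamp):
        log.debug("clamping zero predicted probability on a truth class")
        p_truth = p_truth.clip(clamp, 1.0)
    return -(p_truth.log().mean())


def compound_seg_loss(seg_output, truth_labels, weights: LossWeights) -> Tensor:
    """lambda_Dice * Dice + lambda_CE * CE on the main output, plus
    auxiliary-scale terms weighted per `weights.aux_weights`."""
    truth = np.asarray(truth_labels, dtype=int)
    k = seg_output.probabilities.shape[1]
    oh = np.stack([one_hot(t, k) for t in truth])

    def seg_term(probs, oh_t, lab_t):
        term = 0.0
        if weights.lambda_dice > 0:
            term = term + weights.lambda_dice * dice_loss(probs, oh_t)
        if weights.lambda_ce > 0:
            term = term + weights.lambda_ce * cross_entropy_loss(probs, lab_t)
        return term

    loss = seg_term(seg_output.probabilities, Tensor(oh), truth)
    for aux_logits, w in zip(seg_output.aux_logits, weights.aux_weights):
        if w == 0:
            continue
        # nearest-neighbour downsampled ground truth at the auxiliary scale
        factor = truth.shape[1] // aux_logits.shape[2]
        small = truth[:, ::factor, ::factor, ::factor]
        oh_small = np.stack([one_hot(t, k) for t in small])
        probs = aux_logits.softmax(axis=1)
        loss = loss + w * seg_term(probs, Tensor(oh_small), small)
    return loss


def _bce(p: Tensor, target: float, weights: LossWeights) -> Tensor:
    eps = weights.label_smoothing
    t = target * (1.0 - eps) + (1.0 - target) * eps
    p = p.clip(1e-12, 1.0 - 1e-12)
    loss = -(t * p.log() + (1.0 - t) * (1.0 - p).log())
    if weights.focal:
        p_t = p.data if target >= 0.5 else 1.0 - p.data
        loss = loss * Tensor((1.0 - p_t) ** weights.focal_gamma)
    return loss


def marker_loss(marker_probs: dict[str, Tensor], labels: dict[str, int | None],
                weights: LossWeights) -> Tensor:
    """Weighted label-smoothed BCE over present markers; NA labels are
    masked and the weights renormalized over the present set."""
    present = [m for m in MARKERS if labels.get(m) is not None]
    if not present:
        log.warning("all marker labels are missing; classification loss is 0")
        return Tensor(0.0)
    beta = dict(zip(MARKERS, weights.beta))
    present_w = sum(beta[m] for m in present)
    if present_w == 0:
        return Tensor(0.0)
    # renormalize so the total weight matches the all-present case (Eq. 13
    # reduces to the plain beta-weighted sum when no label is missing)
    scale = sum(weights.beta) / present_w
    loss = 0.0
    for m in present:
        term = _bce(marker_probs[m].mean(), float(labels[m]), weights)
        loss = loss + (beta[m] * scale) * term
    return loss


def total_loss(seg_loss, clf_loss, weights: LossWeights) -> Tensor:
    return as_tensor(seg_loss) + weights.gamma * as_tensor(clf_loss)


# ------------------------------------------------------------ training


def _case_markers(case) -> dict:
    return {m: case.markers.get(m) for m in MARKERS}


def _forward_loss(model, batch_cases, patches, weights: LossWeights) -> tuple[Tensor, dict]:
    imgs = np.stack([p.images for p in patches])
    labs = np.stack([p.labels for p in patches])
    seg, markers, _ = model(imgs)
    seg_l = compound_seg_loss(seg, labs, weights)
    clf_terms = []
    for i, case in enumerate(batch_cases):
        probs_i = {m: markers[m][i] for m in MARKERS}
        clf_terms.append(marker_loss(probs_i, _case_markers(case), weights))
    clf_l = clf_terms[0]
    for t in clf_terms[1:]:
        clf_l = clf_l + t
    clf_l = clf_l * (1.0 / len(clf_terms))
    tot = total_loss(seg_l, clf_l, weights)
    return tot, {"seg": float(seg_l.data), "clf": float(clf_l.data), "total": float(tot.data)}


def train(model: GliomaNet, cohort: list, cfg: TrainConfig, weights: LossWeights | None = None,
          max_steps: int | None = None, callback=None) -> dict:
    """Train on a phantom (or preprocessed real) cohort.

    Splits the cohort into train/validation, optimizes with AdamW under a
    cosine schedule, early-stops on validation total loss and returns
    {"history": per-epoch records, "best_state": parameters of the best
    validation epoch, "best_val": loss}.  `max_steps` caps total optimizer
    steps (useful for fixed-budget runs).
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    weights = weights or LossWeights()
    rng = np.random.default_rng(cfg.seed)

    n_val = max(1, int(round(len(cohort) * cfg.val_fraction))) if len(cohort) > 1 else 0
    order = rng.permutation(len(cohort))
    val_cases = [cohort[i] for i in order[:n_val]]
    train_cases = [cohort[i] for i in order[n_val:]] or list(cohort)

    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    steps_per_epoch = cfg.steps_per_epoch or -(-len(train_cases) // cfg.batch_size)
    total_steps = max_steps if max_steps is not None else cfg.max_epochs * steps_per_epoch

    history = []
    best_val, best_state, best_epoch = np.inf, model.state_dict(), -1
    step = 0
    since_best = 0

    for epoch in range(cfg.max_epochs):
        if step >= total_steps:
            break
        model.train()
        ep_losses = []
        for _ in range(steps_per_epoch):
            if step >= total_steps:
                break
            idx = rng.integers(0, len(train_cases), size=cfg.batch_size)
            batch = [train_cases[i] for i in idx]
            patches = []
            for case in batch:
                p = sample_tumor_patch(case.images, case.labels, size=cfg.patch_size,
                                       rng=rng, center=cfg.patch_center)
                if cfg.augment is not None:
                    p = augment(p, cfg.augment, rng=rng)
                patches.append(p)
            lr = cosine_lr(step, total_steps, cfg.lr, cfg.min_lr)
            opt.lr = lr
            opt.zero_grad()
            loss, parts = _forward_loss(model, batch, patches, weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at step {step}: loss={loss.data}")
            loss.backward()
            opt.step()
            parts["lr"] = lr
            parts["step"] = step
            ep_losses.append(parts)
            if callback is not None:
                callback(step, parts)
            step += 1

        record = {
            "epoch": epoch,
            "train_total": float(np.mean([p["total"] for p in ep_losses])) if ep_losses else np.nan,
            "train_seg": float(np.mean([p["seg"] for p in ep_losses])) if ep_losses else np.nan,
            "train_clf": float(np.mean([p["clf"] for p in ep_losses])) if ep_losses else np.nan,
            "steps": ep_losses,
        }

        if val_cases:
            model.eval()
            vals = []
            with no_grad():
                for case in val_cases:
                    p = sample_tumor_patch(case.images, case.labels, size=cfg.patch_size,
                                           rng=np.random.default_rng(cfg.seed + 1),
                                           center=cfg.patch_center)
                    _, parts = _forward_loss(model, [case], [p], weights)
                    vals.append(parts["total"])
            record["val_total"] = float(np.mean(vals))
            if record["val_total"] < best_val:
                best_val, best_state, best_epoch = record["val_total"], model.state_dict(), epoch
                since_best = 0
            else:
                since_best += 1
        history.append(record)
        log.info("epoch %d: train %.4f val %s", epoch, record["train_total"],
                 record.get("val_total"))
        if val_cases and since_best >= cfg.patience:
            log.info("early stopping at epoch %d (best %d)", epoch, best_epoch)
            break

    if best_epoch < 0:  # no validation: keep final weights
        best_state, best_val = model.state_dict(), float("nan")
    return {"history": history, "best_state": best_state, "best_val": best_val,
            "best_epoch": best_epoch}
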