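"""Desk-scale end-to-end study on synthetic phantoms.

This is the package's stand-in for GPU-scale benchmark training: a tiny
model (8 fusion channels, 16 latent channels, one transformer stage) is
trained for a few hundred AdamW steps on a small cohort of 48^3 phantoms
and then evaluated on a held-out cohort.  The phantom cohort plants the
edema halo (SNFH) with contrast in FLAIR only, so the study can also read
out whether the learned cross-modality attention concentrates on FLAIR
inside the halo — the qualitative modality-attribution behaviour the
fusion module is designed for.

Problem sizes (48^3 volumes, 32^3 patches, 20 training / 40 held-out
cases, 300 steps) are the package's chosen desk-scale defaults; they are
small enough for a single CPU while keeping every stage of the method
exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import MARKERS
from .data import ModalityStack
from .metrics import classification_metrics, segmentation_metrics
from .model import GliomaNet, tiny_config
from .nn import no_grad
from .decoder import postprocess
from .phantom import MarkerCoupling, PhantomCase, PhantomSpec, generate_cohort
from .preprocess import AugmentConfig, zscore_normalize
from .training import LossWeights, TrainConfig, train

log = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "study_phantom_base",
    "study_spec_sampler",
    "study_marker_coupling",
    "run_learnability_study",
]

#: two-phenotype geometry bands: each factor is drawn from one of two
#: disjoint ranges (a coin flip per factor), giving each marker a clean,
#: deterministic imaging correlate with a margin around its threshold —
#: the desk-scale analogue of molecular subtypes with distinct phenotypes.
OUTER_RADIUS_BANDS = ((8.0, 9.5), (11.0, 12.5))  # R, voxels
RIM_RATIO_BANDS = ((0.15, 0.25), (0.50, 0.65))  # u = rim thickness / core radius
HALO_RATIO_BANDS = ((0.30, 0.40), (0.55, 0.70))  # v = halo width / inner radius


def _band_mid_gap(bands) -> float:
    return (bands[0][1] + bands[1][0]) / 2.0


def study_marker_coupling(volume_shape) -> dict[str, MarkerCoupling]:
    """Deterministic couplings, one independent geometry factor per marker.

    IDH+  <- larger tumor (volume fraction above the outer-radius band gap;
             a larger tumor carries a larger necrotic core here),
    TERT+ <- thicker enhancing rim (rim share of the ET+NETC core complex),
    1p19q+ <- wider FLAIR halo (halo share of the whole tumor).
    Every descriptor is recomputable from the label volume alone, and the
    band gaps leave a margin around each threshold.
    """
    v_total = float(np.prod(volume_shape))
    r_gap = _band_mid_gap(OUTER_RADIUS_BANDS)
    u_gap = _band_mid_gap(RIM_RATIO_BANDS)
    v_gap = _band_mid_gap(HALO_RATIO_BANDS)
    return {
        "idh": MarkerCoupling(
            "tumor_fraction",
            threshold=4.0 / 3.0 * np.pi * r_gap**3 / v_total,
            slope=np.inf,
        ),
        "tert": MarkerCoupling(
            "et_core_complex_share", threshold=1.0 - 1.0 / (1.0 + u_gap) ** 3,
            slope=np.inf,
        ),
        "1p19q": MarkerCoupling(
            "snfh_share", threshold=1.0 - 1.0 / (1.0 + v_gap) ** 3, slope=np.inf
        ),
    }


def study_spec_sampler(base: PhantomSpec, center_jitter: float = 3.0):
    """Draw tumors from the two-phenotype geometry bands."""

    def sample(index: int, rng: np.random.Generator) -> PhantomSpec:
        shape = np.asarray(base.volume_shape)
        center = shape / 2.0 + rng.uniform(-center_jitter, center_jitter, size=3)
        outer = rng.uniform(*OUTER_RADIUS_BANDS[rng.integers(0, 2)])
        u = rng.uniform(*RIM_RATIO_BANDS[rng.integers(0, 2)])
        v = rng.uniform(*HALO_RATIO_BANDS[rng.integers(0, 2)])
        inner = outer / (1.0 + v)  # core + rim radius
        core = inner / (1.0 + u)
        return replace(
            base,
            center=tuple(center),
            core_radius=float(core),
            rim_thickness=float(inner - core),
            halo_width=float(outer - inner),
        )

    return sample


def study_phantom_base(volume: int = 48) -> PhantomSpec:
    """Phantom spec for the study: the SNFH halo is visible only in FLAIR
    (its T1/T1ce/T2 means equal the background), markers are coupled
    deterministically to the planted geometry."""
    # one subregion per modality: the hypointense core shows only in T1, the
    # enhancing rim only in T1ce, the cavity only in T2, the halo only in
    # FLAIR — so segmenting each class requires its modality's signal
    # balanced contrast magnitudes (|delta| ~ 1 against the background of 1)
    means = {
        "t1": (1.0, 1.0, 0.0, 1.0, 1.0),
        "t1ce": (1.0, 2.1, 1.0, 1.0, 1.0),
        "t2": (1.0, 1.0, 1.0, 1.0, 2.1),
        "flair": (1.0, 1.0, 1.0, 2.1, 0.4),
    }
    shape = (volume,) * 3
    return PhantomSpec(
        volume_shape=shape,
        modality_means=means,
        # moderate per-voxel noise: with independent per-modality noise,
        # uniform fusion dilutes the one informative sequence, so modality
        # weighting matters without drowning the segmentation signal
        noise_sd={m: (0.08,) * 5 for m in ("t1", "t1ce", "t2", "flair")},
        marker_coupling=study_marker_coupling(shape),
    )


@dataclass
class StudyConfig:
    n_train: int = 20
    n_eval: int = 40
    steps: int = 300
    volume: int = 48
    patch_size: int = 32
    lr: float = 3e-3
    batch_size: int = 1
    seed: int = 0


@dataclass
class StudyResult:
    seg_loss_first: float
    seg_loss_last: float
    seg_loss_reduction: float  # fractional drop from the first step
    dice: dict  # class -> mean held-out Dice
    marker_auc: dict  # marker -> AUC on held-out cohort
    mean_marker_auc: float
    attention_by_modality: dict  # mean CMAF weight inside the halo
    flair_attention_margin: float  # FLAIR minus best other modality
    history: list = field(default_factory=list)
    model: GliomaNet | None = None
    eval_cohort: list = field(default_factory=list)


def _normalized(case: PhantomCase) -> PhantomCase:
    imgs = np.stack([zscore_normalize(v) for v in case.images.images])
    stack = ModalityStack(imgs, case.images.spacing, case.images.affine)
    return replace_images(case, stack)


def replace_images(case: PhantomCase, stack: ModalityStack) -> PhantomCase:
    return PhantomCase(case.case_id, stack, case.labels, case.markers,
                       case.truth_descriptors, spec=case.spec)


def _make_cohorts(cfg: StudyConfig):
    base = study_phantom_base(cfg.volume)
    sampler = study_spec_sampler(base)
    train_cohort = generate_cohort(sampler, cfg.n_train, seed=cfg.seed)
    eval_cohort = generate_cohort(sampler, cfg.n_eval, seed=cfg.seed + 1_000_000)
    return ([_normalized(c) for c in train_cohort], [_normalized(c) for c in eval_cohort])


def _centroid_patch(case: PhantomCase, size: int) -> np.ndarray:
    """Tumor-centroid-centered patch of the training patch size (images only)."""
    lab = case.labels.labels
    idx = np.argwhere(lab > 0)
    center = (idx.mean(axis=0).round().astype(int) if len(idx)
              else np.asarray(lab.shape) // 2)
    corner = np.clip(center - size // 2, 0, np.asarray(lab.shape) - size)
    sl = (slice(None),) + tuple(slice(c, c + size) for c in corner)
    return case.images.images[sl]


def run_learnability_study(cfg: StudyConfig | None = None) -> StudyResult:
    cfg = cfg or StudyConfig()
    train_cohort, eval_cohort = _make_cohorts(cfg)

    model = GliomaNet(tiny_config(cfg.seed), build_shape=(cfg.patch_size,) * 3)
    weights = LossWeights()
    tc = TrainConfig(
        lr=cfg.lr,
        batch_size=cfg.batch_size,
        max_epochs=10_000,
        steps_per_epoch=25,  # frequent validation: 12 selection points
        patience=10_000,  # fixed-budget run: no early stop
        patch_size=cfg.patch_size,
        # centroid-centered patches keep each tumor fully inside its patch,
        # so the visible composition matches the labels' planted phenotype
        patch_center="centroid",
        val_fraction=0.2,
        seed=cfg.seed,
        augment=AugmentConfig(
            elastic_prob=0.0,
            flip_prob=0.5,
            intensity_scale=0.05,
            intensity_shift=0.05,
            modality_dropout_prob=0.0,
        ),
    )
    step_log: list[dict] = []
    result = train(model, train_cohort, tc, weights, max_steps=cfg.steps,
                   callback=lambda s, parts: step_log.append(parts))

    seg_first = step_log[0]["seg"]
    seg_last = float(np.mean([p["seg"] for p in step_log[-10:]]))
    reduction = (seg_first - seg_last) / seg_first

    # evaluate the best-validation checkpoint (validation-based selection is
    # part of the training recipe and guards against late-run overfitting on
    # a cohort this small)
    model.load_state_dict(result["best_state"])

    # held-out evaluation: whole-volume forward passes for segmentation and
    # attention; markers scored on a tumor-centroid patch of the training
    # patch size (matching the distribution the marker heads were fit on)
    model.eval()
    dice_acc: dict[int, list[float]] = {}
    scores = {m: [] for m in MARKERS}
    labels = {m: [] for m in MARKERS}
    attn_sums = np.zeros(4)
    halo_total = 0.0
    min_comp = model.cfg.decoder.min_component
    with no_grad():
        for case in eval_cohort:
            seg, _, extras = model(case.images.images[None])
            pred = postprocess(seg.probabilities.data[0], min_comp)
            m = segmentation_metrics(pred, case.labels, case.images.spacing)
            for c, vals in m.items():
                dice_acc.setdefault(c, []).append(vals["dice"])
            _, markers, _ = model(_centroid_patch(case, cfg.patch_size)[None])
            for mk in MARKERS:
                scores[mk].append(float(markers[mk].data.ravel()[0]))
                labels[mk].append(case.markers[mk])
            halo = case.labels.labels == 3
            if halo.any():
                attn = extras["cmaf_attention"].data[0]  # (4, H, W, D)
                attn_sums += attn[:, halo].sum(axis=1)
                halo_total += halo.sum()

    dice = {c: float(np.mean(v)) for c, v in dice_acc.items()}
    aucs = {}
    for mk in MARKERS:
        y = np.asarray(labels[mk])
        if len(np.unique(y)) < 2:
            log.warning("held-out cohort has single-class %s labels; AUC skipped", mk)
            continue
        aucs[mk] = classification_metrics(scores[mk], y)["auc"]
    mean_auc = float(np.mean(list(aucs.values()))) if aucs else float("nan")

    attn_mean = attn_sums / max(halo_total, 1.0)
    by_mod = dict(zip(("t1", "t1ce", "t2", "flair"), attn_mean.tolist()))
    margin = by_mod["flair"] - max(by_mod["t1"], by_mod["t1ce"], by_mod["t2"])

    return StudyResult(
        seg_loss_first=float(seg_first),
        seg_loss_last=seg_last,
        seg_loss_reduction=float(reduction),
        dice=dice,
        marker_auc=aucs,
        mean_marker_auc=mean_auc,
        attention_by_modality=by_mod,
        flair_attention_margin=float(margin),
        history=step_log,
        model=model,
        eval_cohort=eval_cohort,
    )
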