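"""NIfTI I/O and the preprocessing pipeline.

Pipeline order is resample -> normalize -> pad/crop.  Z-scoring uses the
nonzero voxels of each modality as the foreground (the standard brain-MRI
convention after skull stripping); background voxels are set to 0.  Bias
field correction and atlas registration are accepted as already applied to
the inputs — :func:`external_preprocessing_hook` is a documented no-op seam
for them.  All coordinates are 0-based with half-open intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from . import MODALITIES
from .data import NUM_CLASSES, LabelVolume, ModalityStack, Patch

log = logging.getLogger(__name__)

__all__ = [
    "read_case",
    "write_case",
    "zscore_normalize",
    "resample_isotropic",
    "pad_or_crop",
    "uncrop",
    "one_hot",
    "sample_tumor_patch",
    "AugmentConfig",
    "augment",
    "external_preprocessing_hook",
]


def external_preprocessing_hook(stack: ModalityStack) -> ModalityStack:
    """Seam for N4 bias-field correction / atlas registration.

    Those steps are expected to have been run by external tooling before the
    volumes enter this package; this hook is the identity and exists so a
    deployment can splice its own implementation into the pipeline.
    """
    return stack


# ---------------------------------------------------------------- I/O


def read_case(image_paths: dict[str, str], label_path: str | None = None):
    """Load the four modality NIfTIs (+ optional label NIfTI) of one case.

    `image_paths` maps modality name (t1, t1ce, t2, flair) to file path.
    Shapes and affines must agree across files.
    """
    imgs, affine, shape = {}, None, None
    for m in MODALITIES:
        if m not in image_paths:
            raise ValueError(f"missing modality {m!r} in image_paths")
        nii = nib.load(str(image_paths[m]))
        data = np.asarray(nii.dataobj, dtype=np.float64)
        if shape is None:
            shape, affine = data.shape, nii.affine
        else:
            if data.shape != shape:
                raise ValueError(
                    f"{image_paths[m]}: shape {data.shape} != {shape} of other modalities"
                )
            if not np.allclose(nii.affine, affine, atol=1e-4):
                raise ValueError(f"{image_paths[m]}: affine differs from other modalities")
        imgs[m] = data
    zooms = nib.affines.voxel_sizes(affine)
    stack = ModalityStack(
        np.stack([imgs[m] for m in MODALITIES]),
        spacing=tuple(float(z) for z in zooms),
        affine=affine,
    )
    labels = None
    if label_path is not None:
        lnii = nib.load(str(label_path))
        ldata = np.asarray(lnii.dataobj)
        if ldata.shape != shape:
            raise ValueError(f"{label_path}: label shape {ldata.shape} != image shape {shape}")
        ldata = np.rint(ldata).astype(np.int64)
        labels = LabelVolume(ldata)  # validates the 5-symbol alphabet
    return stack, labels


def write_case(directory, case_id: str, stack: ModalityStack, labels: LabelVolume | None = None):
    """Write one case as per-modality NIfTI files (+ optional label volume)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for mi, m in enumerate(MODALITIES):
        p = directory / f"{case_id}_{m}.nii.gz"
        nib.save(nib.Nifti1Image(stack.images[mi], stack.affine), p)
        paths[m] = str(p)
    if labels is not None:
        p = directory / f"{case_id}_seg.nii.gz"
        nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), stack.affine), p)
        paths["seg"] = str(p)
    return paths


# ------------------------------------------------------- normalization


def zscore_normalize(volume: np.ndarray, foreground_mask: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean unit-variance over foreground voxels; background set to 0.

    Uses the population standard deviation. Raises on constant foreground.
    """
    volume = np.asarray(volume, dtype=np.float64)
    mask = (volume != 0) if foreground_mask is None else np.asarray(foreground_mask, bool)
    if not mask.any():
        raise ValueError("foreground mask is empty")
    fg = volume[mask]
    sd = fg.std()
    if sd == 0:
        raise ValueError("degenerate input: constant foreground (sd = 0)")
    out = np.zeros_like(volume)
    out[mask] = (fg - fg.mean()) / sd
    return out


def resample_isotropic(
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    target_spacing: float | tuple[float, float, float] = 1.0,
    mode: str = "trilinear",
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample to `target_spacing` (mm); trilinear for images, nearest for labels."""
    spacing = np.asarray(spacing, dtype=float)
    target = np.asarray(
        (target_spacing,) * 3 if np.isscalar(target_spacing) else target_spacing, dtype=float
    )
    if np.any(spacing <= 0) or np.any(target <= 0):
        raise ValueError("voxel spacings must be positive")
    zoom = spacing / target
    if mode == "trilinear":
        out = ndimage.zoom(np.asarray(volume, dtype=np.float64), zoom, order=1, mode="nearest", grid_mode=True)
    elif mode == "nearest":
        out = ndimage.zoom(volume, zoom, order=0, mode="nearest", grid_mode=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out, tuple(target)


# ---------------------------------------------------------- pad / crop


def pad_or_crop(volume: np.ndarray, target_shape=(240, 240, 155)):
    """Center pad/crop the trailing 3 axes to `target_shape`.

    Centering is symmetric with the extra voxel on the high side when the
    difference is odd.  Returns (output, meta); `meta` records per-axis
    (pad_low, crop_low, source_extent) so :func:`uncrop` can invert it.
    """
    volume = np.asarray(volume)
    lead = volume.ndim - 3
    out = volume
    meta = []
    pads = [(0, 0)] * lead
    crops = [slice(None)] * lead
    for ax in range(3):
        s = volume.shape[lead + ax]
        t = target_shape[ax]
        if t >= s:
            lo = (t - s) // 2
            pads.append((lo, t - s - lo))
            crops.append(slice(None))
            meta.append({"pad_low": lo, "crop_low": 0, "source": s})
        else:
            lo = (s - t) // 2
            pads.append((0, 0))
            crops.append(slice(lo, lo + t))
            meta.append({"pad_low": 0, "crop_low": lo, "source": s})
    out = np.pad(out, pads)[tuple(crops)]
    return out, meta


def uncrop(volume: np.ndarray, meta) -> np.ndarray:
    """Invert :func:`pad_or_crop` (cropped-away regions are zero-filled)."""
    volume = np.asarray(volume)
    lead = volume.ndim - 3
    sl = [slice(None)] * lead
    pads = [(0, 0)] * lead
    for ax, m in enumerate(meta):
        t = volume.shape[lead + ax]
        if m["crop_low"] == 0 and m["source"] <= t:
            # axis was padded: slice the original extent back out
            sl.append(slice(m["pad_low"], m["pad_low"] + m["source"]))
            pads.append((0, 0))
        else:
            # axis was cropped: zero-fill back to the source extent
            sl.append(slice(None))
            pads.append((m["crop_low"], m["source"] - m["crop_low"] - t))
    return np.pad(volume[tuple(sl)], pads)


# ------------------------------------------------------------ encoding


def one_hot(labels: LabelVolume | np.ndarray, num_classes: int = NUM_CLASSES) -> np.ndarray:
    """(H,W,D) int labels -> (K,H,W,D) binary float volume."""
    arr = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    if arr.max(initial=0) >= num_classes or arr.min(initial=0) < 0:
        raise ValueError(f"label values outside [0, {num_classes})")
    return (arr[None] == np.arange(num_classes)[:, None, None, None]).astype(np.float64)


# ------------------------------------------------------ patch sampling


def sample_tumor_patch(
    stack: ModalityStack,
    labels: LabelVolume | None,
    size: int = 128,
    rng: np.random.Generator | int | None = None,
    center: str = "tumor_voxel",
) -> Patch:
    """Extract a tumor-centered cubic patch.

    With ``center="tumor_voxel"`` (default) the center is a uniformly drawn
    tumor voxel (classes 1-4); ``center="centroid"`` uses the tumor's center
    of mass, which keeps a tumor no larger than the patch fully inside it.
    The center is clamped so the patch fits inside the volume; volumes
    smaller than the patch are zero-padded symmetrically first.  Without any
    tumor voxel the center is drawn uniformly over the volume (logged).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    imgs = stack.images
    lab = labels.labels if labels is not None else None

    pads = [(0, 0)]
    for ax in range(3):
        short = max(0, size - imgs.shape[1 + ax])
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads[1:]):
        imgs = np.pad(imgs, pads)
        if lab is not None:
            lab = np.pad(lab, pads[1:])
    shape = np.asarray(imgs.shape[1:])

    if center not in ("tumor_voxel", "centroid"):
        raise ValueError(f"unknown patch center mode {center!r}")
    tumor = np.argwhere(lab > 0) if lab is not None else np.empty((0, 3), int)
    if tumor.shape[0] == 0:
        log.warning("no tumor voxels found; falling back to a uniform patch center")
        center_vox = np.array([rng.integers(0, s) for s in shape])
    elif center == "centroid":
        center_vox = tumor.mean(axis=0).round().astype(int)
    else:
        center_vox = tumor[rng.integers(0, tumor.shape[0])]
    center = center_vox

    corner = np.clip(center - size // 2, 0, shape - size)
    sl = tuple(slice(c, c + size) for c in corner)
    patch_imgs = imgs[(slice(None),) + sl].copy()
    patch_lab = lab[sl].copy() if lab is not None else None
    return Patch(patch_imgs, patch_lab, corner=tuple(int(c) for c in corner))


# --------------------------------------------------------- augmentation


@dataclass
class AugmentConfig:
    """Training-time augmentation: elastic deformation, axis flips, intensity
    perturbation, and whole-channel modality dropout."""

    elastic_prob: float = 0.2
    elastic_spacing: int = 16  # control-point spacing (voxels)
    elastic_sd: float = 2.0  # displacement sd (voxels)
    flip_axes: tuple[int, ...] = (0, 1, 2)
    flip_prob: float = 0.5
    intensity_scale: float = 0.1  # multiplicative range +-
    intensity_shift: float = 0.1  # additive range +-
    modality_dropout_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for p in (self.elastic_prob, self.flip_prob, self.modality_dropout_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("augmentation probabilities must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        d = dict(d)
        if "flip_axes" in d:
            d["flip_axes"] = tuple(d["flip_axes"])
        return cls(**d)


def _elastic_displacement(shape, cfg: AugmentConfig, rng) -> list[np.ndarray]:
    nodes = [max(2, int(np.ceil(s / cfg.elastic_spacing)) + 1) for s in shape]
    disp = []
    for _ in range(3):
        coarse = rng.normal(0.0, cfg.elastic_sd, size=nodes)
        disp.append(ndimage.zoom(coarse, [s / n for s, n in zip(shape, nodes)], order=3))
    return disp


def augment(patch: Patch, config: AugmentConfig, rng=None) -> Patch:
    """Apply the configured augmentations; spatial transforms hit images and
    labels identically (nearest-neighbor for labels).  With all probabilities
    0 and zero displacement the patch is returned bit-identical."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    imgs = patch.images.copy()
    lab = patch.labels.copy() if patch.labels is not None else None
    shape = imgs.shape[1:]

    # elastic deformation
    if config.elastic_prob > 0 and config.elastic_sd > 0 and rng.random() < config.elastic_prob:
        disp = _elastic_displacement(shape, config, rng)
        base = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        coords = [b + d for b, d in zip(base, disp)]
        imgs = np.stack(
            [ndimage.map_coordinates(c, coords, order=1, mode="nearest") for c in imgs]
        )
        if lab is not None:
            lab = ndimage.map_coordinates(lab, coords, order=0, mode="nearest")

    # axis flips
    for ax in config.flip_axes:
        if rng.random() < config.flip_prob:
            imgs = np.flip(imgs, axis=1 + ax)
            if lab is not None:
                lab = np.flip(lab, axis=ax)

    # intensity perturbation (per modality)
    if config.intensity_scale > 0 or config.intensity_shift > 0:
        scale = 1.0 + rng.uniform(-config.intensity_scale, config.intensity_scale, size=(4, 1, 1, 1))
        shift = rng.uniform(-config.intensity_shift, config.intensity_shift, size=(4, 1, 1, 1))
        imgs = imgs * scale + shift

    # modality dropout: zero whole channels (never all four)
    if config.modality_dropout_prob > 0:
        drop = rng.random(4) < config.modality_dropout_prob
        if drop.all():
            drop[rng.integers(0, 4)] = False
        imgs[drop] = 0.0

    return Patch(np.ascontiguousarray(imgs), np.ascontiguousarray(lab) if lab is not None else None,
                 case_id=patch.case_id, corner=patch.corner)
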