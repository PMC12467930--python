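"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import CLASS_NAMES, MODALITIES

NUM_CLASSES = len(CLASS_NAMES)  # background + ET/NETC/SNFH/RC


@dataclass
class ModalityStack:
    """The four co-registered MRI volumes of one subject.

    ``images`` has shape (4, H, W, D) ordered as (T1, T1ce, T2, FLAIR);
    ``spacing`` is the voxel size in mm and ``affine`` the voxel-to-world
    transform shared by all four volumes.
    """

    images: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.images = np.asarray(self.images)
        if self.images.ndim != 4 or self.images.shape[0] != len(MODALITIES):
            raise ValueError(
                f"expected images of shape (4, H, W, D), got {self.images.shape}"
            )
        if not np.all(np.isfinite(self.images)):
            raise ValueError("modality stack contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.images.shape[1:]

    def modality(self, name: str) -> np.ndarray:
        return self.images[MODALITIES.index(name.lower())]


@dataclass
class LabelVolume:
    """Integer subregion labels: 0=background, 1=ET, 2=NETC, 3=SNFH, 4=RC."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = np.setdiff1d(np.unique(self.labels), np.arange(NUM_CLASSES))
        if bad.size:
            raise ValueError(f"label volume contains invalid values {bad.tolist()}")
        self.labels = self.labels.astype(np.int16)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=NUM_CLASSES)


@dataclass
class Patch:
    """A training sub-volume with provenance back to its source case.

    ``corner`` uses 0-based, half-open coordinates into the (possibly padded)
    source volume: the patch spans ``corner[i] : corner[i] + size``.
    """

    images: np.ndarray  # (4, S, S, S)
    labels: np.ndarray | None  # (S, S, S) or None
    case_id: str = ""
    corner: tuple[int, int, int] = (0, 0, 0)

    @property
    def size(self) -> int:
        return self.images.shape[1]
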