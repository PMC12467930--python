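"""Synthetic multi-modal glioma phantoms.

Each phantom plants a concentric tumor in a homogeneous "brain": a spherical
non-enhancing core (NETC) wrapped by an enhancing rim (ET) and an edema halo
(SNFH), plus an offset ellipsoidal resection cavity (RC).  Every subregion
carries a modality-specific contrast signature — the enhancing rim is bright
in T1ce, edema is bright in FLAIR/T2, the necrotic core is hypo-intense in
T1 — and per-subject binary molecular marker labels (IDH, 1p/19q, TERT) are
drawn from probabilities coupled to planted imaging phenotypes, so marker
prediction from images is learnable by construction.

Geometry is deliberately simple (spheres, shells, one ellipsoid): every
planted quantity has a closed-form check, which is what makes the phantoms
usable as ground truth for the whole pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import MARKERS, MODALITIES
from .data import NUM_CLASSES, LabelVolume, ModalityStack

log = logging.getLogger(__name__)

__all__ = [
    "MarkerCoupling",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "phantom_truth_stats",
    "default_spec",
    "default_spec_sampler",
    "case_seed",
]

#: default per-(modality, class) intensity means, arbitrary units.
#: rows: background, ET, NETC, SNFH, RC; columns: T1, T1ce, T2, FLAIR.
DEFAULT_MEANS = {
    "t1": (1.0, 1.2, 0.5, 0.9, 0.3),
    "t1ce": (1.0, 2.2, 0.7, 0.9, 0.3),
    "t2": (1.0, 1.3, 1.5, 1.8, 2.2),
    "flair": (1.0, 1.3, 1.4, 2.2, 0.4),
}


@dataclass(frozen=True)
class MarkerCoupling:
    """Map from a planted phenotype descriptor to a label probability.

    With ``descriptor`` set, P(y=1) = sigmoid(slope * (value - threshold));
    ``slope=inf`` gives a deterministic step (value > threshold -> 1).
    With ``descriptor=None`` the probability is the constant ``baseline``.
    """

    descriptor: str | None = None
    baseline: float = 0.5
    threshold: float = 0.0
    slope: float = 0.0

    def probability(self, descriptors: dict[str, float]) -> float:
        if self.descriptor is None:
            p = self.baseline
        else:
            v = descriptors[self.descriptor]
            if np.isinf(self.slope):
                p = 1.0 if v > self.threshold else 0.0
            else:
                p = float(1.0 / (1.0 + np.exp(-self.slope * (v - self.threshold))))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"marker probability {p} outside [0, 1]")
        return p


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: tumor center in voxels (fractions of the volume if all < 1)
    center: tuple[float, float, float] = (0.5, 0.5, 0.5)
    core_radius: float = 6.0  # NETC sphere radius (voxels)
    rim_thickness: float = 2.5  # ET shell around the core
    halo_width: float = 4.0  # SNFH shell around the rim
    rc_center: tuple[float, float, float] | None = None  # RC ellipsoid center
    rc_semiaxes: tuple[float, float, float] = (0.0, 0.0, 0.0)  # 0 => no RC
    #: per-modality per-class intensity means (see DEFAULT_MEANS layout)
    modality_means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    #: per-modality per-class noise standard deviations
    noise_sd: dict = field(
        default_factory=lambda: {m: (0.08,) * NUM_CLASSES for m in MODALITIES}
    )
    marker_coupling: dict = field(
        default_factory=lambda: {
            "idh": MarkerCoupling("netc_fraction", threshold=0.004, slope=600.0),
            "tert": MarkerCoupling("et_fraction", threshold=0.006, slope=600.0),
            "1p19q": MarkerCoupling("snfh_fraction", threshold=0.022, slope=300.0),
        }
    )
    bias_field: bool = False  # smooth low-order polynomial gain, off by default
    seed: int = 0

    def resolved_center(self) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        if np.all(c < 1.0):
            c = c * np.asarray(self.volume_shape)
        return c

    def validate(self):
        shape = np.asarray(self.volume_shape)
        if self.core_radius < 0 or self.rim_thickness < 0 or self.halo_width < 0:
            raise ValueError("subregion radii/thicknesses must be non-negative")
        outer = self.core_radius + self.rim_thickness + self.halo_width
        c = self.resolved_center()
        if outer > 0 and (np.any(c - outer < 0) or np.any(c + outer > shape)):
            raise ValueError("tumor geometry does not fit inside volume_shape")
        for m in MODALITIES:
            if len(self.modality_means[m]) != NUM_CLASSES:
                raise ValueError(f"modality_means[{m!r}] must list {NUM_CLASSES} classes")


@dataclass
class PhantomCase:
    case_id: str
    images: ModalityStack
    labels: LabelVolume
    markers: dict[str, int]
    truth_descriptors: dict[str, float]
    spec: PhantomSpec | None = None


def _rasterize(spec: PhantomSpec) -> np.ndarray:
    """Paint the 5-class label volume; raises if RC overlaps the tumor shells."""
    h, w, d = spec.volume_shape
    c = spec.resolved_center()
    grid = np.stack(
        np.meshgrid(np.arange(h), np.arange(w), np.arange(d), indexing="ij"), axis=-1
    ).astype(float)
    r = np.linalg.norm(grid - c, axis=-1)

    labels = np.zeros((h, w, d), dtype=np.int16)
    r_core = spec.core_radius
    r_rim = r_core + spec.rim_thickness
    r_halo = r_rim + spec.halo_width
    labels[r < r_halo] = 3  # SNFH
    labels[r < r_rim] = 1  # ET
    labels[r < r_core] = 2  # NETC

    if spec.rc_semiaxes and max(spec.rc_semiaxes) > 0:
        rc_c = np.asarray(
            spec.rc_center if spec.rc_center is not None else c + np.array([r_halo + max(spec.rc_semiaxes) + 1, 0, 0])
        )
        ax = np.maximum(np.asarray(spec.rc_semiaxes, dtype=float), 1e-9)
        rc_mask = (((grid - rc_c) / ax) ** 2).sum(axis=-1) < 1.0
        overlap = rc_mask & (labels > 0)
        if overlap.any():
            hit = sorted({"ET", "NETC", "SNFH"} & {
                {1: "ET", 2: "NETC", 3: "SNFH"}[v] for v in np.unique(labels[overlap])
            })
            raise ValueError(
                f"resection cavity overlaps subregion(s) {hit}; geometry cannot be "
                "rasterized disjointly"
            )
        labels[rc_mask] = 4  # RC
    return labels


def _descriptors(labels: np.ndarray) -> dict[str, float]:
    total = labels.size
    counts = np.bincount(labels.ravel(), minlength=NUM_CLASSES)
    tumor = counts[1:].sum()
    return {
        "et_fraction": counts[1] / total,
        "netc_fraction": counts[2] / total,
        "snfh_fraction": counts[3] / total,
        "rc_fraction": counts[4] / total,
        "tumor_fraction": tumor / total,
        # within-tumor composition shares (0 when no tumor is present)
        "et_share": counts[1] / tumor if tumor else 0.0,
        "netc_share": counts[2] / tumor if tumor else 0.0,
        "snfh_share": counts[3] / tumor if tumor else 0.0,
        # rim share of the solid core complex (ET + NETC)
        "et_core_complex_share": (
            counts[1] / (counts[1] + counts[2]) if counts[1] + counts[2] else 0.0
        ),
        # equivalent-sphere rim thickness and halo width (voxels): the
        # difference of the equivalent radii of nested subregion volumes
        "rim_equivalent_thickness": _r_eq(counts[2] + counts[1]) - _r_eq(counts[2]),
        "halo_equivalent_width": (
            _r_eq(counts[2] + counts[1] + counts[3]) - _r_eq(counts[2] + counts[1])
        ),
    }


def _r_eq(volume: float) -> float:
    """Radius of a sphere with the given volume (voxels)."""
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def _bias_field(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative gain: a random second-order polynomial in (x,y,z)."""
    coords = [np.linspace(-1, 1, s) for s in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    c = rng.normal(0, 0.05, size=9)
    field = (
        c[0] * X + c[1] * Y + c[2] * Z
        + c[3] * X * Y + c[4] * X * Z + c[5] * Y * Z
        + c[6] * X**2 + c[7] * Y**2 + c[8] * Z**2
    )
    return 1.0 + field


def generate_phantom(spec: PhantomSpec, case_id: str = "case_0000") -> PhantomCase:
    """Deterministically generate one phantom from its spec (and spec.seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = _rasterize(spec)
    desc = _descriptors(labels)

    h, w, d = spec.volume_shape
    images = np.zeros((len(MODALITIES), h, w, d))
    onehot = labels[None] == np.arange(NUM_CLASSES)[:, None, None, None]
    for mi, m in enumerate(MODALITIES):
        means = np.asarray(spec.modality_means[m], dtype=float)
        sds = np.asarray(spec.noise_sd[m], dtype=float)
        vol = (means[:, None, None, None] * onehot).sum(axis=0)
        noise = rng.normal(size=(h, w, d)) * (sds[:, None, None, None] * onehot).sum(axis=0)
        img = vol + noise
        if spec.bias_field:
            img = img * _bias_field((h, w, d), rng)
        images[mi] = img

    markers = {
        m: int(rng.random() < spec.marker_coupling[m].probability(desc))
        for m in MARKERS
    }
    stack = ModalityStack(images, spacing=spec.voxel_spacing)
    return PhantomCase(case_id, stack, LabelVolume(labels), markers, desc, spec=spec)


def case_seed(master_seed: int, index: int) -> int:
    """Per-case seed from the master seed via a splittable counter scheme."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % 2**31)


def generate_cohort(spec_sampler, n: int, seed: int) -> list[PhantomCase]:
    """Generate ``n`` phantoms; ``spec_sampler(index, rng)`` returns the spec
    of case ``index`` (its ``seed`` field is overwritten with the derived
    per-case seed)."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    cases = []
    for i in range(n):
        s = case_seed(seed, i)
        rng = np.random.default_rng(s)
        spec = spec_sampler(i, rng)
        spec = replace(spec, seed=s)
        cases.append(generate_phantom(spec, case_id=f"case_{i:04d}"))
    return cases


def phantom_truth_stats(case: PhantomCase) -> dict:
    """Per-class voxel counts + descriptors recomputed from the label volume."""
    counts = case.labels.class_counts()
    return {
        "class_counts": counts,
        "descriptors": _descriptors(case.labels.labels),
    }


def default_spec(**overrides) -> PhantomSpec:
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


def balanced_deterministic_coupling(
    volume_shape: tuple[int, int, int],
    core_radius_range: tuple[float, float] = (3.0, 8.0),
    rim_thickness_range: tuple[float, float] = (1.0, 4.0),
    halo_width_range: tuple[float, float] = (2.0, 6.0),
) -> dict[str, MarkerCoupling]:
    """Deterministic (step-function) marker coupling on within-tumor
    composition shares, with thresholds placed at the shares of the median
    geometry so a cohort drawn uniformly from these ranges has roughly
    balanced marker prevalence at any volume size.

    Shares rather than absolute volumes are used because they are the
    phenotype a normalized (attention-pooled) representation of the tumor
    can express directly; a larger core still raises the IDH probability, a
    thicker rim the TERT probability, a wider halo the 1p/19q probability.
    """
    del volume_shape  # shares are size-free; kept for signature stability
    sphere = lambda radius: 4.0 / 3.0 * np.pi * radius**3  # noqa: E731
    r = sum(core_radius_range) / 2.0
    t = sum(rim_thickness_range) / 2.0
    hw = sum(halo_width_range) / 2.0
    core = sphere(r)
    rim = sphere(r + t) - sphere(r)
    halo = sphere(r + t + hw) - sphere(r + t)
    tumor = core + rim + halo
    return {
        "idh": MarkerCoupling("netc_share", threshold=core / tumor, slope=np.inf),
        "tert": MarkerCoupling("et_share", threshold=rim / tumor, slope=np.inf),
        "1p19q": MarkerCoupling("snfh_share", threshold=halo / tumor, slope=np.inf),
    }


def default_spec_sampler(
    base: PhantomSpec | None = None,
    core_radius_range: tuple[float, float] = (3.0, 8.0),
    rim_thickness_range: tuple[float, float] = (1.0, 4.0),
    halo_width_range: tuple[float, float] = (2.0, 6.0),
    center_jitter: float = 3.0,
):
    """Cohort sampler varying tumor geometry (and hence the phenotype
    descriptors that drive the marker labels)."""
    base = base or PhantomSpec()

    def sample(index: int, rng: np.random.Generator) -> PhantomSpec:
        shape = np.asarray(base.volume_shape)
        center = shape / 2.0 + rng.uniform(-center_jitter, center_jitter, size=3)
        return replace(
            base,
            center=tuple(center),
            core_radius=float(rng.uniform(*core_radius_range)),
            rim_thickness=float(rng.uniform(*rim_thickness_range)),
            halo_width=float(rng.uniform(*halo_width_range)),
        )

    return sample
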