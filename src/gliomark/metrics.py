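"""Evaluation metrics.

Segmentation: per-class Dice, 95th-percentile symmetric surface distance
(HD95, spacing-aware, 6-connectivity boundaries), sensitivity, specificity.
Classification: Mann-Whitney AUC (ties get half credit), accuracy, F1,
precision, recall, Brier score, equal-width-bin calibration curves, and
McNemar's paired test (continuity-corrected chi-square for >= 25 discordant
pairs, exact two-sided binomial otherwise).

Conventions for degenerate classes follow segmentation-challenge practice:
a class absent in both volumes scores Dice 1 / HD95 0; absent in exactly
one scores Dice 0 / HD95 = the volume diagonal (configurable penalty).
These cases are logged per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn import metrics as skm

from .data import NUM_CLASSES

log = logging.getLogger(__name__)

__all__ = [
    "segmentation_metrics",
    "hd95",
    "classification_metrics",
    "calibration_curve",
    "mcnemar_test",
    "evaluate_cohort",
    "EvalReport",
]


def _surface(mask: np.ndarray) -> np.ndarray:
    """6-connectivity boundary voxels of a binary mask."""
    er = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return mask & ~er


def hd95(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of the symmetric surface distance between binary masks."""
    sa, sb = _surface(a), _surface(b)
    if not sa.any() or not sb.any():
        raise ValueError("hd95 requires non-empty masks")
    # distance from every voxel to the nearest surface voxel of the other mask
    da = ndimage.distance_transform_edt(~sb, sampling=spacing)
    db = ndimage.distance_transform_edt(~sa, sampling=spacing)
    dists = np.concatenate([da[sa], db[sb]])
    return float(np.percentile(dists, 95))


def segmentation_metrics(pred, truth, spacing=(1.0, 1.0, 1.0),
                         num_classes: int = NUM_CLASSES,
                         absent_penalty: float | None = None) -> dict:
    """Per-class Dice / HD95 / sensitivity / specificity for label volumes."""
    from .data import LabelVolume

    p = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    t = truth.labels if isinstance(truth, LabelVolume) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    if absent_penalty is None:
        absent_penalty = float(np.linalg.norm(np.asarray(p.shape) * np.asarray(spacing)))
    out = {}
    for c in range(1, num_classes):
        pm, tm = p == c, t == c
        np_, nt = pm.sum(), tm.sum()
        if nt == 0 and np_ == 0:
            log.info("class %d absent in both volumes: Dice := 1, HD95 := 0", c)
            dice, h = 1.0, 0.0
            sens = 1.0
        elif nt == 0 or np_ == 0:
            log.info("class %d absent in one volume: Dice := 0, HD95 := penalty", c)
            dice, h = 0.0, absent_penalty
            sens = 0.0 if nt else 1.0
        else:
            inter = (pm & tm).sum()
            dice = 2.0 * inter / (np_ + nt)
            h = hd95(pm, tm, spacing)
            sens = inter / nt
        tn = (~pm & ~tm).sum()
        spec = tn / max((~tm).sum(), 1)
        out[c] = {"dice": float(dice), "hd95": float(h),
                  "sensitivity": float(sens), "specificity": float(spec)}
    return out


def classification_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """AUC (Mann-Whitney), accuracy, F1, precision, recall, Brier."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    out = {
        "accuracy": float(skm.accuracy_score(labels, pred)),
        "f1": float(skm.f1_score(labels, pred, zero_division=0)),
        "precision": float(skm.precision_score(labels, pred, zero_division=0)),
        "recall": float(skm.recall_score(labels, pred, zero_division=0)),
        "brier": float(np.mean((scores - labels) ** 2)),
        "threshold": float(threshold),
        "n": int(labels.size),
    }
    if len(np.unique(labels)) < 2:
        raise ValueError(
            f"AUC undefined: labels contain a single class; other metrics: {out}"
        )
    out["auc"] = float(skm.roc_auc_score(labels, scores))
    return out


def calibration_curve(scores, labels, n_bins: int = 10) -> dict:
    """Equal-width bins on [0, 1]; empty bins carry count 0 and NaN frequency."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mean_pred = np.full(n_bins, np.nan)
    observed = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            mean_pred[b] = scores[sel].mean()
            observed[b] = labels[sel].mean()
    return {"edges": edges, "mean_predicted": mean_pred,
            "observed_frequency": observed, "counts": counts}


def mcnemar_test(correct_a, correct_b) -> dict:
    """Paired McNemar test on per-sample correctness indicators.

    b = A right & B wrong, c = A wrong & B right.  Continuity-corrected
    chi-square when b + c >= 25, exact two-sided binomial otherwise;
    b + c = 0 gives p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    n = b + c
    if n == 0:
        return {"b": b, "c": c, "statistic": 0.0, "p_value": 1.0, "method": "degenerate"}
    if n >= 25:
        chi2 = (abs(b - c) - 1) ** 2 / n
        p = float(stats.chi2.sf(chi2, df=1))
        return {"b": b, "c": c, "statistic": float(chi2), "p_value": p,
                "method": "chi2_continuity"}
    p = float(stats.binomtest(min(b, c), n, 0.5, alternative="two-sided").pvalue)
    return {"b": b, "c": c, "statistic": float(min(b, c)), "p_value": p,
            "method": "exact_binomial"}


@dataclass
class EvalReport:
    per_case: list = field(default_factory=list)
    segmentation: dict = field(default_factory=dict)  # class -> mean metrics
    markers: dict = field(default_factory=dict)  # marker -> classification metrics
    calibration: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return conv({"per_case": self.per_case, "segmentation": self.segmentation,
                     "markers": self.markers, "calibration": self.calibration})


def evaluate_cohort(predictions: list, cohort: list, spacing=(1.0, 1.0, 1.0),
                    thresholds: dict | None = None, n_bins: int = 10) -> EvalReport:
    """Aggregate metrics over (label_map, marker_probs) predictions vs truth.

    `predictions[i]` is a dict with keys "labels" (predicted label volume)
    and "markers" (dict of probabilities); `cohort[i]` supplies ground truth.
    """
    from . import MARKERS

    if not cohort:
        raise ValueError("empty cohort")
    if len(predictions) != len(cohort):
        raise ValueError("predictions and cohort lengths differ")
    report = EvalReport()
    seg_acc: dict = {}
    for pred, case in zip(predictions, cohort):
        per = {"case_id": getattr(case, "case_id", "")}
        if pred.get("labels") is not None:
            m = segmentation_metrics(pred["labels"], case.labels, spacing)
            per["segmentation"] = m
            for c, vals in m.items():
                seg_acc.setdefault(c, []).append(vals)
        report.per_case.append(per)
    for c, rows in seg_acc.items():
        report.segmentation[c] = {
            k: float(np.mean([r[k] for r in rows])) for k in rows[0]
        }
    for m in MARKERS:
        scores = np.array([p["markers"][m] for p in predictions if p.get("markers")])
        labels = np.array([case.markers[m] for case, p in zip(cohort, predictions)
                           if p.get("markers")])
        if scores.size == 0:
            continue
        thr = (thresholds or {}).get(m, 0.5)
        try:
            report.markers[m] = classification_metrics(scores, labels, thr)
        except ValueError as e:
            report.markers[m] = {"error": str(e)}
        cal = calibration_curve(scores, labels, n_bins)
        report.calibration[m] = cal
    return report
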