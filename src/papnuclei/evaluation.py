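"""Evaluation metrics: mask similarity, classification scores, feature
significance and object-level matching.

The Tanimoto coefficient (Jaccard index) of two binary masks is
Nc / (Na + Nb + Nc), with Nc the common foreground pixels and Na, Nb the
pixels exclusive to each mask.  Classification of overlapped (positive)
versus single nuclei is scored with precision, recall and F1.  Feature
discriminativeness uses the independent two-sample signal-to-noise score
|mean1 - mean2| / sqrt(var1/n1 + var2/n2) per feature, after Weiss and
Indurkhya.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from papnuclei.clustering import OverlapCall
from papnuclei.segmentation import NucleusRegion
from papnuclei.synthetic_data import GroundTruth

__all__ = [
    "EvalReport",
    "MatchResult",
    "tanimoto",
    "classification_metrics",
    "feature_significance",
    "match_regions",
    "roc_sweep",
]

POSITIVE = "overlapped"


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    counts: dict[str, int]
    tanimoto_mean: float = float("nan")
    tanimoto_std: float = float("nan")
    located_fraction: float = float("nan")
    per_feature_significance: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class MatchResult:
    """Greedy one-to-one matching of predicted regions to truth objects."""

    located_fraction: float
    matches: list[tuple[int, int, float]]   # (truth label, region label, T)
    unmatched_truth: list[int]
    unmatched_predictions: list[int]
    tanimoto_mean: float
    tanimoto_std: float

    def region_truth_labels(self) -> dict[int, int]:
        """Map region label -> matched truth label."""
        return {r: t for t, r, _ in self.matches}


def tanimoto(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Nc / (Na + Nb + Nc) for two equal-shape binary masks.

    Two empty masks compare as identical (1.0, with a warning).
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    nc = int((a & b).sum())
    na = int((a & ~b).sum())
    nb = int((b & ~a).sum())
    if nc + na + nb == 0:
        warnings.warn("both masks empty; Tanimoto defined as 1",
                      stacklevel=2)
        return 1.0
    return nc / (na + nb + nc)


def classification_metrics(
    predicted: list[OverlapCall],
    truth: dict[int, str],
) -> tuple[float, float, float, dict[str, int]]:
    """(precision, recall, f1, counts) with overlapped as positive class.

    Zero denominators yield 0 with a warning rather than an error, so an
    all-single prediction is scoreable.
    """
    if not predicted:
        raise ValueError("empty prediction list")
    missing = [c.region_label for c in predicted if c.region_label not in truth]
    if missing:
        raise KeyError(f"labels absent from truth map: {missing}")
    tp = fp = tn = fn = 0
    for call in predicted:
        is_pos = call.predicted == POSITIVE
        truth_pos = truth[call.region_label] == POSITIVE
        if is_pos and truth_pos:
            tp += 1
        elif is_pos:
            fp += 1
        elif truth_pos:
            fn += 1
        else:
            tn += 1
    counts = {"Tp": tp, "Tn": tn, "Fp": fp, "Fn": fn}

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); "
                          "reported as 0", stacklevel=3)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1, counts


def feature_significance(features: np.ndarray,
                         class_labels: np.ndarray) -> np.ndarray:
    """Per-feature |mean1 - mean2| / sqrt(var1/n1 + var2/n2).

    Higher scores mark features whose class means separate further than
    their sampling noise.  Zero pooled variance with distinct means
    yields +inf with a warning.
    """
    x = np.asarray(features, float)
    y = np.asarray(class_labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    a = x[y == classes[0]]
    b = x[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per class")
    num = np.abs(a.mean(axis=0) - b.mean(axis=0))
    denom = np.sqrt(a.var(axis=0, ddof=1) / len(a)
                    + b.var(axis=0, ddof=1) / len(b))
    out = np.empty_like(num)
    zero = denom == 0
    if zero.any():
        warnings.warn("zero pooled variance; significance reported as inf "
                      "where means differ", stacklevel=2)
    out[~zero] = num[~zero] / denom[~zero]
    out[zero] = np.where(num[zero] > 0, np.inf, 0.0)
    return out


def match_regions(
    predicted_regions: list[NucleusRegion],
    truth: GroundTruth,
    min_iou: float = 0.5,
) -> MatchResult:
    """Greedy best-Tanimoto one-to-one matching against truth instances.

    A truth object counts as located when its matched Tanimoto reaches
    ``min_iou``.  Reported mean/std are over the located matches.
    """
    inst = truth.instance_mask
    truth_labels = sorted(int(v) for v in np.unique(inst) if v != 0)
    pairs = []
    for t in truth_labels:
        tm = inst == t
        for reg in predicted_regions:
            r0, c0, r1, c1 = reg.bounding_box
            if not tm[r0:r1, c0:c1].any():
                continue
            val = tanimoto(tm, reg.filled_mask)
            if val > 0:
                pairs.append((val, t, reg.label))
    # best score first; deterministic tie-break by labels
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_t: set[int] = set()
    used_r: set[int] = set()
    matches = []
    for val, t, r in pairs:
        if t in used_t or r in used_r or val < min_iou:
            continue
        used_t.add(t)
        used_r.add(r)
        matches.append((t, r, val))
    matches.sort()
    scores = np.array([v for _, _, v in matches])
    n_truth = len(truth_labels)
    return MatchResult(
        located_fraction=(len(matches) / n_truth) if n_truth else 0.0,
        matches=matches,
        unmatched_truth=[t for t in truth_labels if t not in used_t],
        unmatched_predictions=[r.label for r in predicted_regions
                               if r.label not in used_r],
        tanimoto_mean=float(scores.mean()) if len(scores) else float("nan"),
        tanimoto_std=float(scores.std(ddof=0)) if len(scores) else float("nan"),
    )


def roc_sweep(calls: list[OverlapCall], truth: dict[int, str],
              n_thresholds: int = 21) -> list[dict[str, float]]:
    """(threshold, recall, false-positive-rate) table over the overlap
    confidence.  A region is called overlapped at threshold t when its
    overlap membership (confidence if predicted overlapped, else
    1 - confidence) reaches t."""
    rows = []
    scores = {c.region_label: (c.confidence if c.predicted == POSITIVE
                               else 1.0 - c.confidence) for c in calls}
    pos = sum(1 for v in truth.values() if v == POSITIVE)
    neg = sum(1 for v in truth.values() if v != POSITIVE)
    for t in np.linspace(0.0, 1.0, n_thresholds):
        tp = sum(1 for lab, s in scores.items()
                 if s >= t and truth[lab] == POSITIVE)
        fp = sum(1 for lab, s in scores.items()
                 if s >= t and truth[lab] != POSITIVE)
        rows.append({
            "threshold": float(t),
            "recall": tp / pos if pos else 0.0,
            "false_positive_rate": fp / neg if neg else 0.0,
        })
    return rows
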