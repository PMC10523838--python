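"""Evaluation protocol for soma instance segmentation.

Implements pixel-overlap scores (Dice, IOU), the ground-truth matching
rule, detection categories (TP / FP with sub-types / FN), precision,
recall and yield rate, somatic areas with ordinary-least-squares area
agreement, and confidence-threshold sweeps.

Matching rule: for each ground-truth soma the candidate is the unassigned
prediction with the highest Dice coefficient; the pair is a true positive
only when its IOU exceeds the threshold (default 0.5), otherwise the
ground truth is a miss and the candidate stays available.  Assignment is
one-to-one.  Unmatched predictions are false positives, sub-typed as
wrong-boundary (best IOU with any ground truth in (0, 0.5]), doublet
(overlapping two or more ground truths, each with IOU > 0.2) or
background; when both sub-type rules apply, wrong-boundary wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MaskPair", "GTRecord", "PredRecord", "MatchResult", "EvalSummary",
    "dice", "iou", "match_instances", "precision", "recall", "yield_rate",
    "soma_area", "area_agreement", "threshold_sweep",
]

FP_WRONG_BOUNDARY = "FP_wrong_boundary"
FP_BACKGROUND = "FP_background"
FP_DOUBLET = "FP_doublet"


def _counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    inter = int(np.logical_and(x, y).sum())
    return inter, int(x.sum()), int(y.sum())


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice coefficient 2|X n Y| / (|X| + |Y|); undefined for two empty masks."""
    inter, nx, ny = _counts(x, y)
    if nx + ny == 0:
        raise ValueError("Dice is undefined when both masks are empty")
    return 2.0 * inter / (nx + ny)


def iou(x: np.ndarray, y: np.ndarray) -> float:
    """Intersection over union |X n Y| / |X u Y|; undefined for two empty masks."""
    inter, nx, ny = _counts(x, y)
    union = nx + ny - inter
    if union == 0:
        raise ValueError("IOU is undefined when both masks are empty")
    return inter / union


@dataclass
class MaskPair:
    x: np.ndarray
    y: np.ndarray
    dice: float = field(init=False)
    iou: float = field(init=False)

    def __post_init__(self):
        self.dice = dice(self.x, self.y)
        self.iou = iou(self.x, self.y)


@dataclass
class GTRecord:
    index: int
    matched_pred: int | None
    dice: float
    iou: float
    verdict: str  # "TP" or "FN"


@dataclass
class PredRecord:
    index: int
    matched_gt: int | None
    verdict: str  # "TP", "FP_wrong_boundary", "FP_background", "FP_doublet"


@dataclass
class MatchResult:
    gt_records: list[GTRecord]
    pred_records: list[PredRecord]
    tp: int
    fp: int
    fn: int

    @property
    def fp_by_type(self) -> dict[str, int]:
        out = {FP_WRONG_BOUNDARY: 0, FP_BACKGROUND: 0, FP_DOUBLET: 0}
        for r in self.pred_records:
            if r.verdict in out:
                out[r.verdict] += 1
        return out


def _pairwise(gt_masks, pred_masks) -> tuple[np.ndarray, np.ndarray]:
    nd = np.zeros((len(gt_masks), len(pred_masks)))
    ni = np.zeros_like(nd)
    for g, gm in enumerate(gt_masks):
        gm = np.asarray(gm, dtype=bool)
        for p, pm in enumerate(pred_masks):
            pm = np.asarray(pm, dtype=bool)
            if gm.shape != pm.shape:
                raise ValueError("ground-truth and prediction masks must share one shape")
            inter = int(np.logical_and(gm, pm).sum())
            ng, npx = int(gm.sum()), int(pm.sum())
            nd[g, p] = 2.0 * inter / (ng + npx) if ng + npx else 0.0
            ni[g, p] = inter / (ng + npx - inter) if ng + npx - inter else 0.0
    return nd, ni


def match_instances(gt_masks, pred_masks, iou_threshold: float = 0.5,
                    doublet_iou: float = 0.2) -> MatchResult:
    """Match predictions to ground truths and categorise every instance.

    Ground truths are processed in descending order of their best Dice
    against any prediction (ties by lower index), which resolves
    contention deterministically while keeping the per-ground-truth
    highest-Dice selection.
    """
    nd, ni = _pairwise(gt_masks, pred_masks)
    n_gt, n_pred = nd.shape
    gt_order = sorted(range(n_gt),
                      key=lambda g: (-(nd[g].max() if n_pred else 0.0), g))
    assigned_pred: dict[int, int] = {}
    gt_records: list[GTRecord] = [None] * n_gt  # type: ignore[list-item]
    for g in gt_order:
        best_p, best_d = None, 0.0
        for p in range(n_pred):
            if p in assigned_pred:
                continue
            if nd[g, p] > best_d:
                best_p, best_d = p, nd[g, p]
        if best_p is not None and ni[g, best_p] > iou_threshold:
            assigned_pred[best_p] = g
            gt_records[g] = GTRecord(g, best_p, float(nd[g, best_p]),
                                     float(ni[g, best_p]), "TP")
        else:
            gt_records[g] = GTRecord(g, None,
                                     float(nd[g].max()) if n_pred else 0.0,
                                     float(ni[g].max()) if n_pred else 0.0, "FN")
    pred_records: list[PredRecord] = []
    for p in range(n_pred):
        if p in assigned_pred:
            pred_records.append(PredRecord(p, assigned_pred[p], "TP"))
            continue
        best = ni[:, p].max() if n_gt else 0.0
        if 0.0 < best <= iou_threshold:
            verdict = FP_WRONG_BOUNDARY
        elif int((ni[:, p] > doublet_iou).sum()) >= 2:
            verdict = FP_DOUBLET
        else:
            verdict = FP_BACKGROUND
        pred_records.append(PredRecord(p, None, verdict))
    tp = sum(1 for r in pred_records if r.verdict == "TP")
    fp = n_pred - tp
    fn = sum(1 for r in gt_records if r.verdict == "FN")
    return MatchResult(gt_records, pred_records, tp, fp, fn)


def precision(tp: int, fp: int) -> float:
    if tp < 0 or fp < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fp == 0:
        raise ZeroDivisionError("precision undefined: no detections")
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    if tp < 0 or fn < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn == 0:
        raise ZeroDivisionError("recall undefined: no ground-truth instances")
    return tp / (tp + fn)


def yield_rate(n_correct: int, n_gt: int) -> float:
    """Correctly detected somas over total ground-truth somas."""
    if n_gt <= 0:
        raise ZeroDivisionError("yield rate undefined without ground-truth neurons")
    if not 0 <= n_correct <= n_gt:
        raise ValueError("n_correct must lie in [0, n_gt]")
    return n_correct / n_gt


def soma_area(mask: np.ndarray, pixel_size_um: float) -> float:
    """Somatic area in um^2: true-pixel count times the squared pixel size."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return float(np.asarray(mask, dtype=bool).sum()) * pixel_size_um ** 2


def area_agreement(paired_areas) -> dict:
    """Agreement between predicted and manual areas.

    Returns the mean and SD of (predicted - manual), the OLS slope and
    intercept of predicted on manual, and the squared Pearson correlation.
    ``r_squared`` and ``slope`` are NaN when the manual areas are constant.
    """
    pairs = np.asarray(list(paired_areas), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (predicted, manual) pairs")
    predicted, manual = pairs[:, 0], pairs[:, 1]
    diff = predicted - manual
    out = {"mean_diff": float(diff.mean()),
           "sd_diff": float(diff.std(ddof=1)),
           "n": int(len(diff))}
    if np.allclose(manual, manual[0]):
        out.update(slope=float("nan"), intercept=float("nan"), r_squared=float("nan"))
        return out
    fit = stats.linregress(manual, predicted)
    out.update(slope=float(fit.slope), intercept=float(fit.intercept),
               r_squared=float(fit.rvalue ** 2))
    return out


@dataclass
class SweepRow:
    threshold: float
    total_detected: int
    tp: int
    fn: int
    pct_correct: float
    pct_wrong_boundary: float
    pct_background_doublet: float


@dataclass
class EvalSummary:
    precision: float
    recall: float
    yield_rate: float
    rows: list[SweepRow] = field(default_factory=list)


def threshold_sweep(predictions_by_image: dict, gt_by_image: dict,
                    thresholds, iou_threshold: float = 0.5) -> EvalSummary:
    """Re-match at each confidence threshold and tabulate detection categories.

    ``predictions_by_image`` maps image id -> list of (mask, score);
    ``gt_by_image`` maps image id -> list of masks.  Row percentages are
    taken over that row's total detections.  The summary's headline
    precision / recall / yield are computed at the lowest threshold.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    n_gt_total = sum(len(v) for v in gt_by_image.values())
    rows = []
    headline = None
    for t in thresholds:
        tp = fp = fn = 0
        fp_types = {FP_WRONG_BOUNDARY: 0, FP_BACKGROUND: 0, FP_DOUBLET: 0}
        total = 0
        for image_id, gts in gt_by_image.items():
            preds = [m for m, s in predictions_by_image.get(image_id, []) if s >= t]
            total += len(preds)
            res = match_instances(gts, preds, iou_threshold)
            tp += res.tp
            fp += res.fp
            fn += res.fn
            for k, v in res.fp_by_type.items():
                fp_types[k] += v
        if total:
            pct = lambda v: 100.0 * v / total  # noqa: E731
            row = SweepRow(t, total, tp, fn, pct(tp), pct(fp_types[FP_WRONG_BOUNDARY]),
                           pct(fp_types[FP_BACKGROUND] + fp_types[FP_DOUBLET]))
        else:
            row = SweepRow(t, 0, 0, fn, 0.0, 0.0, 0.0)
        rows.append(row)
        if headline is None:
            p = precision(tp, fp) if tp + fp else float("nan")
            r = recall(tp, fn) if tp + fn else float("nan")
            y = yield_rate(tp, n_gt_total) if n_gt_total else float("nan")
            headline = (p, r, y)
    return EvalSummary(*headline, rows=rows)
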