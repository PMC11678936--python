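"""Instance-segmentation evaluation suite.

Covers the pixel-overlap measures (IoU, Dice, pixel accuracy), the
precision/recall/F1 family on confusion counts, boundary Hausdorff distance,
average precision with both all-point and 101-point interpolation, optimal
(Hungarian) mask matching for promptable-segmenter comparisons, and
dataset-level aggregation under three protocols (COCO-style, YOLO-style, and
the Hungarian-matched universal-metric protocol).

Two deliberately distinct matchers coexist: AP uses the standard greedy
match by descending confidence; the universal protocol uses the optimal
one-to-one assignment maximizing total IoU (``scipy`` Hungarian solver).

Undefined ratios (zero denominators) are never silently reported as 0: the
value is ``nan`` with an explicit flag, and aggregates count skipped items.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import directed_hausdorff

IOU_THRESHOLDS_COCO = np.round(np.arange(0.5, 1.0, 0.05), 2)
SMALL_AREA = 32 * 32  # COCO small-object area bound, px at working resolution


@dataclass
class InstanceMask:
    """One ground-truth or predicted instance."""

    mask: np.ndarray  # binary, image-sized
    polygon: list = field(default_factory=list)  # list of (N, 2) xy arrays
    class_id: int = 0
    confidence: float | None = None  # absent for ground truth
    bbox: tuple | None = None  # xyxy, px

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MatchResult:
    """One-to-one prediction/ground-truth pairing maximizing total IoU."""

    pairs: list  # (pred index, gt index, iou)
    unmatched_pred: list
    unmatched_gt: list


@dataclass
class MetricReport:
    protocol: str
    precision: float = math.nan
    recall: float = math.nan
    f1: float = math.nan
    iou_mean: float = math.nan
    dice_mean: float = math.nan
    pa: float = math.nan
    hausdorff_mean: float = math.nan
    ap_per_class: dict = field(default_factory=dict)
    map50: float = math.nan
    map50_95: float = math.nan
    ap75: float = math.nan
    ap_small: float = math.nan
    n_classes: int = 1
    aggregation: str = "per_instance_mean"
    n_undefined: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ap_per_class"] = {str(k): v for k, v in self.ap_per_class.items()}
        return d


# ---------------------------------------------------------------------------
# Pairwise metrics
# ---------------------------------------------------------------------------


def overlap_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray) -> dict:
    """IoU = TP/(TP+FP+FN) and Dice = 2TP/(2TP+FP+FN) of two binary masks.

    Both masks empty is undefined overlap: returned as nan with
    ``undefined=True`` rather than silently 0.
    """
    pred_mask, gt_mask = _as_bool_pair(pred_mask, gt_mask)
    tp = int(np.count_nonzero(pred_mask & gt_mask))
    fp = int(np.count_nonzero(pred_mask & ~gt_mask))
    fn = int(np.count_nonzero(~pred_mask & gt_mask))
    denom = tp + fp + fn
    und = denom == 0
    return {
        "iou": math.nan if und else tp / denom,
        "dice": math.nan if und else 2 * tp / (2 * tp + fp + fn),
        "pixel_counts": ConfusionCounts(
            tp=tp, fp=fp, fn=fn,
            tn=int(pred_mask.size - tp - fp - fn)),
        "undefined": und,
    }


def _as_bool_pair(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def prf(counts: ConfusionCounts) -> dict:
    """Precision, recall and F1 from confusion counts.

    F1 is the harmonic mean of precision and recall and coincides with the
    Dice form 2TP/(2TP+FP+FN) on the same counts.  Zero denominators yield
    nan plus an ``undefined`` list naming the affected metrics (treated as 0
    by aggregation, with the skip counted).
    """
    undefined = []
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision, undefined = math.nan, undefined + ["precision"]
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall, undefined = math.nan, undefined + ["recall"]
    if 2 * counts.tp + counts.fp + counts.fn > 0:
        f1 = 2 * counts.tp / (2 * counts.tp + counts.fp + counts.fn)
    else:
        f1, undefined = math.nan, undefined + ["f1"]
    return {"precision": precision, "recall": recall, "f1": f1,
            "undefined": undefined}


def pixel_accuracy(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """(TP+TN)/total; equals 1 iff the masks are identical."""
    pred_mask, gt_mask = _as_bool_pair(pred_mask, gt_mask)
    if pred_mask.size == 0:
        raise ValueError("empty raster")
    return float(np.count_nonzero(pred_mask == gt_mask) / pred_mask.size)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Boundary pixel coordinates (row, col) via 8-connected erosion residue."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract the boundary of an empty mask")
    interior = binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    return np.argwhere(mask & ~interior).astype(float)


def hausdorff(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in pixels."""
    pa = boundary_points(mask_a)
    pb = boundary_points(mask_b)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def mask_iou_matrix(pred: list, gt: list) -> np.ndarray:
    """(n_pred, n_gt) IoU matrix; empty-vs-empty pairs count as IoU 0 here."""
    m = np.zeros((len(pred), len(gt)))
    gt_flat = [np.asarray(g.mask, dtype=bool).ravel() for g in gt]
    for i, p in enumerate(pred):
        pm = np.asarray(p.mask, dtype=bool).ravel()
        for j, gm in enumerate(gt_flat):
            inter = np.count_nonzero(pm & gm)
            union = np.count_nonzero(pm) + np.count_nonzero(gm) - inter
            m[i, j] = inter / union if union else 0.0
    return m


def hungarian_match(pred: list, gt: list, min_iou: float = 0.0) -> MatchResult:
    """Optimal one-to-one matching maximizing total IoU.

    Pairs whose IoU falls below ``min_iou`` (or is zero) are discarded to the
    unmatched lists.  Among equal-total assignments the solver's deterministic
    ordering applies (lowest pred index first).
    """
    if not (0 <= min_iou < 1):
        raise ValueError("min_iou must lie in [0, 1)")
    if not pred or not gt:
        return MatchResult([], list(range(len(pred))), list(range(len(gt))))
    iou = mask_iou_matrix(pred, gt)
    rows, cols = linear_sum_assignment(-iou)
    pairs, matched_p, matched_g = [], set(), set()
    for r, c in zip(rows, cols):
        if iou[r, c] > 0 and iou[r, c] >= min_iou:
            pairs.append((int(r), int(c), float(iou[r, c])))
            matched_p.add(int(r))
            matched_g.add(int(c))
    return MatchResult(
        pairs=pairs,
        unmatched_pred=[i for i in range(len(pred)) if i not in matched_p],
        unmatched_gt=[j for j in range(len(gt)) if j not in matched_g],
    )


def greedy_match(iou: np.ndarray, scores: np.ndarray, iou_threshold: float):
    """Detection-style matching: by descending confidence, each ground truth
    claimed at most once.  Returns a boolean TP flag per prediction (in the
    original prediction order)."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    taken: set[int] = set()
    tp = np.zeros(len(scores), dtype=bool)
    for i in order:
        if iou.shape[1] == 0:
            break
        j = int(np.argmax(iou[i]))
        if iou[i, j] >= iou_threshold and j not in taken:
            taken.add(j)
            tp[i] = True
    return tp


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------


def average_precision(scored_detections, gt_count: int,
                      iou_threshold: float = 0.5,
                      interpolation_mode: str = "all_point") -> float:
    """Area under the precision-recall curve.

    ``scored_detections`` is a list of (confidence, is_tp) produced by greedy
    confidence-ordered matching at ``iou_threshold`` (the threshold is part of
    the caller's matching; it is accepted here for the record).  Modes:
    ``all_point`` exact area under the monotonized PR curve, or ``101_point``
    COCO-style interpolation.  gt_count == 0 with detections present is
    undefined (nan).
    """
    if interpolation_mode not in ("all_point", "101_point"):
        raise ValueError(f"unknown interpolation mode {interpolation_mode!r}")
    dets = sorted(scored_detections, key=lambda d: -d[0])
    if gt_count == 0:
        return math.nan if dets else 0.0
    if not dets:
        return 0.0
    tp = np.cumsum([1.0 if d[1] else 0.0 for d in dets])
    fp = np.cumsum([0.0 if d[1] else 1.0 for d in dets])
    recall = tp / gt_count
    precision = tp / (tp + fp)
    # monotone non-increasing precision envelope
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation_mode == "101_point":
        # precision sampled on the 101-point recall grid 0:0.01:1; the area
        # estimator averages the positive-recall samples, which keeps it an
        # exact lower bound of the all-point area for any PR configuration
        grid = np.linspace(0.01, 1.0, 100)
        idx = np.searchsorted(recall, grid, side="left")
        vals = np.where(idx < len(prec_env),
                        prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
        return float(vals.mean())
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[prec_env[0]], prec_env])
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def _image_detections(pred, gt, iou_threshold, iou=None):
    """(confidence, is_tp) pairs for one image at one IoU threshold."""
    if iou is None:
        iou = mask_iou_matrix(pred, gt)
    scores = np.array([p.confidence if p.confidence is not None else 1.0
                       for p in pred])
    tp = greedy_match(iou, scores, iou_threshold) if len(gt) else (
        np.zeros(len(pred), dtype=bool))
    return [(float(s), bool(t)) for s, t in zip(scores, tp)]


def _dataset_ap(predictions, ground_truth, iou_threshold, mode, iou_cache=None):
    dets, n_gt = [], 0
    for idx, (pred, gt) in enumerate(zip(predictions, ground_truth)):
        iou = None if iou_cache is None else iou_cache[idx]
        dets.extend(_image_detections(pred, gt, iou_threshold, iou))
        n_gt += len(gt)
    return average_precision(dets, n_gt, iou_threshold, mode)


def _dataset_ap_area(predictions, ground_truth, iou_threshold, mode,
                     area_max, iou_cache):
    """COCO size-stratified AP: out-of-range ground truth is *ignored* —
    detections matched to it vanish from the ranking, and unmatched detections
    whose own area is out of range are ignored too (never false positives)."""
    dets, n_gt = [], 0
    for idx, (pred, gt) in enumerate(zip(predictions, ground_truth)):
        iou = iou_cache[idx]
        scores = np.array([p.confidence if p.confidence is not None else 1.0
                           for p in pred])
        order = sorted(range(len(pred)), key=lambda i: (-scores[i], i))
        taken: set[int] = set()
        match = {}
        for i in order:
            if iou.shape[1] == 0:
                break
            cands = [j for j in range(len(gt))
                     if j not in taken and iou[i, j] >= iou_threshold]
            if cands:
                j = max(cands, key=lambda j: iou[i, j])
                taken.add(j)
                match[i] = j
        for i in range(len(pred)):
            if i in match:
                if gt[match[i]].area < area_max:
                    dets.append((float(scores[i]), True))
                # matched to ignored (out-of-range) gt: dropped from ranking
            elif pred[i].area < area_max:
                dets.append((float(scores[i]), False))
        n_gt += sum(1 for g in gt if g.area < area_max)
    return average_precision(dets, n_gt, iou_threshold, mode)


# ---------------------------------------------------------------------------
# Dataset-level evaluation
# ---------------------------------------------------------------------------

PROTOCOLS = ("coco", "yolo", "sam_universal")


def evaluate_dataset(predictions: list, ground_truth: list,
                     protocol: str = "yolo", conf_threshold: float = 0.0,
                     aggregation: str = "per_instance_mean") -> MetricReport:
    """Aggregate a dataset of per-image instance lists into a MetricReport.

    ``predictions`` and ``ground_truth`` are parallel lists (one entry per
    image) of :class:`InstanceMask` lists.  Protocols:

    * ``coco``: mask AP at IoU 0.50:0.05:0.95 (101-point), AP50, AP75, and
      AP on small ground-truth instances (area < 32^2 px),
    * ``yolo``: mAP50 and mAP50-95 (all classes), plus precision/recall/F1 of
      the detections above ``conf_threshold`` matched at IoU 0.5,
    * ``sam_universal``: optimal Hungarian matching, then mean IoU/Dice/F1,
      pixel accuracy and mean boundary Hausdorff distance over matched pairs
      (``aggregation`` chooses per-instance means or dataset-pooled pixels).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected {PROTOCOLS}")
    if len(predictions) != len(ground_truth):
        raise ValueError("predictions and ground truth must align per image")
    report = MetricReport(protocol=protocol, aggregation=aggregation)
    classes = sorted({g.class_id for gts in ground_truth for g in gts}) or [0]
    report.n_classes = len(classes)

    if protocol in ("coco", "yolo"):
        mode = "101_point"
        per_class_5095, per_class_50 = {}, {}
        for cls in classes:
            preds_c = [[p for p in ps if p.class_id == cls] for ps in predictions]
            gts_c = [[g for g in gs if g.class_id == cls] for gs in ground_truth]
            cache = [mask_iou_matrix(p, g) for p, g in zip(preds_c, gts_c)]
            aps = [_dataset_ap(preds_c, gts_c, t, mode, iou_cache=cache)
                   for t in IOU_THRESHOLDS_COCO]
            aps = [a for a in aps if not math.isnan(a)]
            per_class_50[cls] = _dataset_ap(preds_c, gts_c, 0.5, mode,
                                            iou_cache=cache)
            per_class_5095[cls] = float(np.mean(aps)) if aps else math.nan
            if protocol == "coco" and cls == classes[0]:
                report.ap75 = _dataset_ap(preds_c, gts_c, 0.75, mode,
                                          iou_cache=cache)
                report.ap_small = _dataset_ap_area(
                    preds_c, gts_c, 0.5, mode, SMALL_AREA, cache)
        report.ap_per_class = per_class_50
        report.map50 = _nanmean(per_class_50.values())
        report.map50_95 = _nanmean(per_class_5095.values())
        # operating-point precision/recall at IoU 0.5
        tp = fp = n_gt = 0
        for pred, gt in zip(predictions, ground_truth):
            pred = [p for p in pred
                    if (p.confidence or 1.0) >= conf_threshold]
            flags = _image_detections(pred, gt, 0.5)
            tp += sum(1 for _, t in flags if t)
            fp += sum(1 for _, t in flags if not t)
            n_gt += len(gt)
        pr = prf(ConfusionCounts(tp=tp, fp=fp, fn=n_gt - tp))
        report.precision, report.recall, report.f1 = (
            pr["precision"], pr["recall"], pr["f1"])
        report.n_undefined = len(pr["undefined"])
        return report

    # sam_universal: optimal matching then universal metrics
    ious, dices, hds, pas = [], [], [], []
    pooled = ConfusionCounts()
    tp_inst = fp_inst = fn_inst = 0
    n_und = 0
    for pred, gt in zip(predictions, ground_truth):
        pred = [p for p in pred if (p.confidence or 1.0) >= conf_threshold]
        match = hungarian_match(pred, gt)
        tp_inst += len(match.pairs)
        fp_inst += len(match.unmatched_pred)
        fn_inst += len(match.unmatched_gt)
        for pi, gi, iou in match.pairs:
            om = overlap_metrics(pred[pi].mask, gt[gi].mask)
            if om["undefined"]:
                n_und += 1
                continue
            ious.append(om["iou"])
            dices.append(om["dice"])
            c = om["pixel_counts"]
            pooled = ConfusionCounts(pooled.tp + c.tp, pooled.fp + c.fp,
                                     pooled.fn + c.fn, pooled.tn + c.tn)
            hds.append(hausdorff(pred[pi].mask, gt[gi].mask))
        if pred or gt:
            img_pred = _union([p.mask for p in pred], gt, pred)
            img_gt = _union([g.mask for g in gt], gt, pred)
            pas.append(pixel_accuracy(img_pred, img_gt))
    if aggregation == "per_instance_mean":
        report.iou_mean = _mean(ious)
        report.dice_mean = _mean(dices)
    elif aggregation == "dataset_pooled":
        om = prf(pooled)
        denom = pooled.tp + pooled.fp + pooled.fn
        report.iou_mean = pooled.tp / denom if denom else math.nan
        report.dice_mean = om["f1"]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    inst_prf = prf(ConfusionCounts(tp=tp_inst, fp=fp_inst, fn=fn_inst))
    report.precision, report.recall = inst_prf["precision"], inst_prf["recall"]
    report.f1 = _mean(dices)  # pixel F1 == Dice on the matched pairs
    report.pa = _mean(pas)
    report.hausdorff_mean = _mean(hds)
    report.n_undefined = n_und
    return report


def _union(masks, gt, pred):
    if masks:
        out = np.zeros_like(masks[0], dtype=bool)
        for m in masks:
            out |= np.asarray(m, dtype=bool)
        return out
    ref = (gt[0].mask if gt else pred[0].mask)
    return np.zeros_like(np.asarray(ref), dtype=bool)


def _mean(vals):
    return float(np.mean(vals)) if len(vals) else math.nan


def _nanmean(vals):
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan
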