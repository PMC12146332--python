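"""Detector evaluation: IoU matching, precision/recall, AP/mAP, rate report.

Matching follows the common detection-benchmark protocol: detections are
processed in descending confidence and greedily claim the unmatched ground
truth of highest IoU at or above the threshold; everything else is a false
positive, and unclaimed ground truths are misses.  AP uses the all-points
interpolation: precision is replaced by its running maximum over higher
recalls (the envelope) and integrated exactly over recall.

Undefined precision/recall (empty denominators) are reported as ``None``,
never silently coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from seedlapse.voc_io import BoundingBox

#: Default IoU-threshold grid for the averaged mAP (0.50 to 0.95, 10 steps).
DEFAULT_IOU_GRID = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class Detection:
    image_id: str
    box: BoundingBox
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass
class MatchLedger:
    """Outcome of matching one image/class: per-detection flags and FN count."""

    iou_thr: float
    is_tp: list[bool]  # per detection, in descending-confidence order
    confidences: list[float]
    gt_matched: list[bool]

    @property
    def tp(self) -> int:
        return sum(self.is_tp)

    @property
    def fp(self) -> int:
        return len(self.is_tp) - self.tp

    @property
    def fn(self) -> int:
        return len(self.gt_matched) - sum(self.gt_matched)

    @property
    def n_gt(self) -> int:
        return len(self.gt_matched)


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points swept over descending confidence."""

    recalls: tuple[float, ...]
    precisions: tuple[float, ...]


@dataclass(frozen=True)
class GerminationRateReport:
    n_germinated: int
    n_total: int
    rate: float  # percent, one decimal, half-up


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes (half-open convention)."""
    ix = max(0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    if inter == 0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union


def match(dets: Sequence[Detection], gts: Sequence[BoundingBox], iou_thr: float) -> MatchLedger:
    """Greedy one-to-one matching of detections to ground truths."""
    image_ids = {d.image_id for d in dets}
    if len(image_ids) > 1:
        raise ValueError(f"match() expects a single image, got ids {sorted(image_ids)}")
    labels = {d.label for d in dets} | {g.label for g in gts}
    if len(labels) > 1:
        raise ValueError(f"match() expects a single class, got labels {sorted(labels)}")

    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    gt_matched = [False] * len(gts)
    is_tp: list[bool] = []
    confidences: list[float] = []
    for i in order:
        det = dets[i]
        best_j, best_v = -1, 0.0
        for j, gt in enumerate(gts):
            if gt_matched[j]:
                continue
            v = iou(det.box, gt)
            if v >= iou_thr and v > best_v:
                best_j, best_v = j, v
        matched = best_j >= 0
        if matched:
            gt_matched[best_j] = True
        is_tp.append(matched)
        confidences.append(det.confidence)
    return MatchLedger(iou_thr=iou_thr, is_tp=is_tp, confidences=confidences, gt_matched=gt_matched)


def precision_recall(ledger: MatchLedger) -> tuple[float | None, float | None]:
    """Exact precision and recall; ``None`` when a denominator is empty."""
    tp, fp, fn = ledger.tp, ledger.fp, ledger.fn
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return precision, recall


def pr_curve(
    dets_by_image: Mapping[str, Sequence[Detection]],
    gts_by_image: Mapping[str, Sequence[BoundingBox]],
    iou_thr: float,
) -> PRCurve:
    """Sweep the confidence threshold over all images of one class."""
    flags: list[tuple[float, bool]] = []
    n_gt = 0
    for image_id in sorted(set(dets_by_image) | set(gts_by_image)):
        dets = list(dets_by_image.get(image_id, ()))
        gts = list(gts_by_image.get(image_id, ()))
        n_gt += len(gts)
        if dets:
            ledger = match(dets, gts, iou_thr)
            flags.extend(zip(ledger.confidences, ledger.is_tp))
    flags.sort(key=lambda cf: -cf[0])
    recalls: list[float] = []
    precisions: list[float] = []
    tp = fp = 0
    for _, matched in flags:
        if matched:
            tp += 1
        else:
            fp += 1
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt if n_gt > 0 else 0.0)
    return PRCurve(recalls=tuple(recalls), precisions=tuple(precisions))


def average_precision(curve: PRCurve) -> float:
    """Area under the precision envelope (all-points interpolation)."""
    if len(curve.recalls) == 0:
        return 0.0
    recalls = np.asarray(curve.recalls)
    precisions = np.asarray(curve.precisions)
    # Envelope: precision at recall r becomes max precision at recall >= r.
    env = np.maximum.accumulate(precisions[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def mean_ap(per_class_ap: Sequence[float] | Sequence[Sequence[float]]) -> float:
    """Mean AP over classes, or over per-threshold class lists.

    A flat list averages APs at one IoU threshold; a nested list (one inner
    list of per-class APs per threshold) averages the per-threshold means,
    yielding the grid-averaged mAP.
    """
    items = list(per_class_ap)
    if not items:
        raise ValueError("mean_ap needs at least one AP value")
    if isinstance(items[0], (list, tuple, np.ndarray)):
        per_thr = [mean_ap(sub) for sub in items]
        return float(np.mean(per_thr))
    return float(np.mean([float(v) for v in items]))


def germination_rate(n_germinated: int, n_total: int) -> GerminationRateReport:
    """Percentage of germinated seeds, rounded half-up to one decimal."""
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if n_germinated < 0:
        raise ValueError(f"n_germinated must be non-negative, got {n_germinated}")
    rate = Decimal(100 * n_germinated) / Decimal(n_total)
    rate = float(rate.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return GerminationRateReport(n_germinated=n_germinated, n_total=n_total, rate=rate)


def evaluate_detections(
    detections: Sequence[Detection],
    ground_truth: Mapping[str, Sequence[BoundingBox]],
    labels: Iterable[str] | None = None,
    iou_grid: Sequence[float] = DEFAULT_IOU_GRID,
) -> dict:
    """Full evaluation: per-class AP at each IoU threshold, mAP50, averaged mAP."""
    if labels is None:
        labels = sorted({d.label for d in detections} | {g.label for boxes in ground_truth.values() for g in boxes})
    labels = list(labels)
    if not labels:
        raise ValueError("no classes to evaluate")

    ap_table: dict[float, dict[str, float]] = {}
    for thr in iou_grid:
        ap_table[thr] = {}
        for label in labels:
            dets_by_image: dict[str, list[Detection]] = {}
            for d in detections:
                if d.label == label:
                    dets_by_image.setdefault(d.image_id, []).append(d)
            gts_by_image = {
                image_id: [g for g in boxes if g.label == label] for image_id, boxes in ground_truth.items()
            }
            curve = pr_curve(dets_by_image, gts_by_image, thr)
            ap_table[thr][label] = average_precision(curve)

    map_per_thr = {thr: mean_ap(list(aps.values())) for thr, aps in ap_table.items()}
    return {
        "labels": labels,
        "iou_grid": list(iou_grid),
        "ap": {thr: dict(aps) for thr, aps in ap_table.items()},
        "mAP_per_threshold": map_per_thr,
        "mAP50": map_per_thr.get(0.5),
        "mAP_grid": float(np.mean(list(map_per_thr.values()))),
    }


def read_detections_tsv(path: str | Path) -> list[Detection]:
    """Read the TSV exchange format: image_id label confidence xmin ymin xmax ymax."""
    dets: list[Detection] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 tab-separated fields, got {len(parts)}")
        image_id, label, conf, xmin, ymin, xmax, ymax = parts
        dets.append(
            Detection(
                image_id=image_id,
                label=label,
                confidence=float(conf),
                box=BoundingBox(int(xmin), int(ymin), int(xmax), int(ymax), label),
            )
        )
    return dets


def write_detections_tsv(dets: Sequence[Detection], path: str | Path) -> None:
    lines = [
        f"{d.image_id}\t{d.label}\t{d.confidence}\t{d.box.xmin}\t{d.box.ymin}\t{d.box.xmax}\t{d.box.ymax}"
        for d in dets
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))
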