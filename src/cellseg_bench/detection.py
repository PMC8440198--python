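"""Cell-adapted COCO-style detection and segmentation metrics.

Predictions are matched to ground truth greedily in descending score order at
each IoU threshold in {0.50, 0.55, ..., 0.95}.  Per threshold the toolkit
reports AP (area under the interpolated precision-recall curve, all-points
summation) and FNR = 1 - Recall; the overall AP and AFNR are the means over the
ten thresholds.  Size-stratified evaluation restricts ground truth to pixel-area
bands (defaults 500 px and 1,500 px, the cell-adapted small/medium/large
boundaries) and ignores, rather than penalizes, out-of-band objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import AnnotationSet, ImageRecord, InstanceMask, PredictionSet, ValidationError

IOU_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
DEFAULT_DETECTION_CAP = 3000


@dataclass(frozen=True)
class SizeCategorySpec:
    """Pixel-area boundaries between small/medium and medium/large objects."""

    small_max_px: float = 500.0   # ~320 um^2 at the default pixel size
    large_min_px: float = 1500.0  # ~970 um^2

    def __post_init__(self) -> None:
        if not (0 < self.small_max_px < self.large_min_px):
            raise ValueError("require 0 < small boundary < large boundary")

    def band(self, name: str) -> tuple[float, float]:
        return {
            "small": (0.0, self.small_max_px),
            "medium": (self.small_max_px, self.large_min_px),
            "large": (self.large_min_px, np.inf),
            "all": (0.0, np.inf),
        }[name]


@dataclass
class MatchResult:
    """Greedy matching outcome for one image at one IoU threshold."""

    iou_threshold: float
    tp_flags: np.ndarray          # per retained prediction, score order
    fn: int
    matches: list[tuple[int, int, float]]  # (pred idx, gt idx, IoU)

    @property
    def tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def fp(self) -> int:
        return int((~self.tp_flags).sum())


@dataclass
class PRCurve:
    """Cumulative precision/recall after each prediction, plus the
    right-to-left running-max interpolated precision."""

    recall: np.ndarray
    precision: np.ndarray
    precision_interp: np.ndarray

    def interp_at(self, r: float) -> float:
        """max precision at recall >= r (0 beyond the achieved recall)."""
        idx = np.searchsorted(self.recall, r, side="left")
        if idx >= len(self.recall):
            return 0.0
        return float(self.precision_interp[idx:].max())


@dataclass
class EvaluationReport:
    ap_per_threshold: dict[float, float]
    fnr_per_threshold: dict[float, float]
    size_ap: dict[str, float] = field(default_factory=dict)
    size_afnr: dict[str, float] = field(default_factory=dict)
    groups: dict[str, "EvaluationReport"] = field(default_factory=dict)
    detection_cap: int = DEFAULT_DETECTION_CAP
    interpolation: str = "all_points"

    @property
    def overall_ap(self) -> float:
        return float(np.mean(list(self.ap_per_threshold.values())))

    @property
    def afnr(self) -> float:
        return float(np.mean(list(self.fnr_per_threshold.values())))

    def to_dict(self) -> dict:
        d = {
            "overall_ap": self.overall_ap,
            "afnr": self.afnr,
            "ap_per_threshold": {f"{t:.2f}": v for t, v in self.ap_per_threshold.items()},
            "fnr_per_threshold": {f"{t:.2f}": v for t, v in self.fnr_per_threshold.items()},
            "size_ap": self.size_ap,
            "size_afnr": self.size_afnr,
            "detection_cap": self.detection_cap,
            "interpolation": self.interpolation,
        }
        if self.groups:
            d["groups"] = {k: v.to_dict() for k, v in self.groups.items()}
        return d


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

def mask_iou(a: InstanceMask, b: InstanceMask, image: ImageRecord) -> float:
    """Pixel-set intersection-over-union of two masks on one image grid."""
    if a.image_id != b.image_id:
        raise ValueError(f"masks from different images: {a.image_id!r} vs {b.image_id!r}")
    w, h = image.width_px, image.height_px
    ma, mb = a.rasterize(w, h), b.rasterize(w, h)
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        raise ValueError("both masks are empty")
    return float(np.logical_and(ma, mb).sum() / union)


def _iou_matrix(
    gts: list[InstanceMask], preds: list[InstanceMask], image: ImageRecord
) -> np.ndarray:
    """(n_pred, n_gt) IoU table using bbox-cropped rasters."""
    w, h = image.width_px, image.height_px
    out = np.zeros((len(preds), len(gts)))
    g_boxes = [g.bbox(w, h) for g in gts]
    g_areas = np.array([g.area_px(w, h) for g in gts], dtype=float)
    for i, p in enumerate(preds):
        pr0, pr1, pc0, pc1 = p.bbox(w, h)
        pm = p.rasterize(w, h)
        pa = pm.sum()
        for j, g in enumerate(gts):
            gr0, gr1, gc0, gc1 = g_boxes[j]
            r0, r1 = max(pr0, gr0), min(pr1, gr1)
            c0, c1 = max(pc0, gc0), min(pc1, gc1)
            if r0 >= r1 or c0 >= c1:
                continue
            inter = np.logical_and(
                pm[r0:r1, c0:c1], g.rasterize(w, h)[r0:r1, c0:c1]
            ).sum()
            if inter:
                out[i, j] = inter / (pa + g_areas[j] - inter)
    return out


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _score_order(preds: list[InstanceMask], cap: int) -> list[int]:
    """Indices of the retained predictions in descending score order
    (ties by insertion order), truncated to the cap."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    return order[:cap]


def match_at_threshold(
    gts: list[InstanceMask],
    preds: list[InstanceMask],
    image: ImageRecord,
    t: float,
    cap: int = DEFAULT_DETECTION_CAP,
    iou: np.ndarray | None = None,
    order: list[int] | None = None,
) -> MatchResult:
    """Greedy matching at IoU threshold ``t`` for one image.

    Each prediction, in descending score order, claims the still-unmatched
    ground truth of highest IoU >= t; otherwise it is a false positive.
    """
    if not (0 < t < 1):
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    if order is None:
        order = _score_order(preds, cap)
    retained = [preds[i] for i in order]
    if iou is None:
        iou = _iou_matrix(gts, retained, image)
    else:
        iou = iou[order, :]
    assign = _greedy(iou, t)
    tp_flags = assign >= 0
    matches = [
        (order[i], int(j), float(iou[i, j])) for i, j in enumerate(assign) if j >= 0
    ]
    fn = len(gts) - int(tp_flags.sum())
    return MatchResult(iou_threshold=t, tp_flags=tp_flags, fn=fn, matches=matches)


# ---------------------------------------------------------------------------
# PR curve and AP
# ---------------------------------------------------------------------------

def pr_curve(
    tp_flags: np.ndarray, scores: np.ndarray, n_gt: int
) -> PRCurve:
    """Global PR curve from per-prediction TP flags and scores.

    Predictions are ordered by descending score (stable for ties); cumulative
    precision and recall are evaluated after each one.
    """
    if n_gt == 0:
        raise ValueError("recall undefined: zero ground-truth instances")
    order = np.argsort(-np.asarray(scores), kind="stable")
    flags = np.asarray(tp_flags, dtype=bool)[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    return PRCurve(recall=recall, precision=precision, precision_interp=p_interp)


def ap_at_threshold(curve: PRCurve | None, interpolation: str = "all_points") -> float:
    """Area under the interpolated PR curve.

    ``all_points``: sum of (r_i - r_{i-1}) * p_interp(r_i) over the recall steps
    (with r_0 = 0).  ``101_point``: mean interpolated precision over the 101
    recall levels 0.00, 0.01, ..., 1.00, the convention of standard COCO tooling.
    """
    if curve is None or len(curve.recall) == 0:
        warnings.warn("empty PR curve; AP set to 0", stacklevel=2)
        return 0.0
    if interpolation == "all_points":
        r = np.concatenate(([0.0], curve.recall))
        return float(np.sum(np.diff(r) * curve.precision_interp))
    if interpolation == "101_point":
        levels = np.linspace(0, 1, 101)
        idx = np.searchsorted(curve.recall, levels, side="left")
        vals = np.where(
            idx < len(curve.recall),
            curve.precision_interp[np.minimum(idx, len(curve.recall) - 1)],
            0.0,
        )
        return float(vals.mean())
    raise ValueError(f"unknown interpolation mode {interpolation!r}")


def overall_ap(ap_per_threshold: dict[float, float]) -> float:
    """Mean AP over the ten IoU thresholds 0.50-0.95."""
    return float(np.mean([ap_per_threshold[t] for t in IOU_THRESHOLDS]))


def afnr(fnr_per_threshold: dict[float, float]) -> float:
    """Mean over thresholds of FNR = 1 - Recall."""
    return float(np.mean([fnr_per_threshold[t] for t in IOU_THRESHOLDS]))


# ---------------------------------------------------------------------------
# full evaluation
# ---------------------------------------------------------------------------

def evaluate(
    gt: AnnotationSet,
    preds: PredictionSet,
    sizes: SizeCategorySpec | None = None,
    cap: int = DEFAULT_DETECTION_CAP,
    interpolation: str = "all_points",
    group_by: str | None = None,
    thresholds: tuple[float, ...] = IOU_THRESHOLDS,
) -> EvaluationReport:
    """Evaluate predictions against ground truth over all images.

    Size-stratified metrics restrict ground truth (and their matched
    predictions) to each pixel-area band; matches to out-of-band ground truth
    and unmatched predictions whose own area is out of band are ignored.
    """
    sizes = sizes or SizeCategorySpec()
    for image_id in preds.instances:
        if image_id not in gt.images:
            raise ValidationError(f"prediction for unknown image {image_id!r}")

    per_image = _precompute(gt, preds, cap)
    report = _evaluate_bands(per_image, sizes, cap, interpolation, thresholds)

    if group_by is not None:
        groups: dict[str, EvaluationReport] = {}
        for label in sorted(
            {getattr(rec, group_by) for rec in gt.images.values() if getattr(rec, group_by)}
        ):
            sub = [pi for pi in per_image if getattr(pi["record"], group_by) == label]
            groups[label] = _evaluate_bands(sub, sizes, cap, interpolation, thresholds)
        report.groups = groups
    return report


def _precompute(gt: AnnotationSet, preds: PredictionSet, cap: int) -> list[dict]:
    """Per image: retained predictions (score order, capped), IoU table, areas."""
    out = []
    for image_id, rec in gt.images.items():
        g = gt.instances.get(image_id, [])
        p = preds.instances.get(image_id, [])
        order = _score_order(p, cap)
        retained = [p[i] for i in order]
        w, h = rec.width_px, rec.height_px
        out.append(
            {
                "record": rec,
                "gts": g,
                "preds": retained,
                "iou": _iou_matrix(g, retained, rec),
                "scores": np.array([m.score for m in retained]),
                "gt_areas": np.array([m.area_px(w, h) for m in g], dtype=float),
                "pred_areas": np.array([m.area_px(w, h) for m in retained], dtype=float),
            }
        )
    return out


def _greedy(iou: np.ndarray, t: float) -> np.ndarray:
    """Row-order greedy assignment: per prediction row, the claimed gt column
    (highest IoU >= t among unclaimed, first index on ties) or -1."""
    n_p, n_g = iou.shape
    taken = np.zeros(n_g, dtype=bool)
    assign = np.full(n_p, -1, dtype=int)
    for i in range(n_p):
        best_j = -1
        best = t - 1e-12  # >= t admits exact-threshold IoU
        for j in range(n_g):
            if not taken[j] and iou[i, j] > best:
                best, best_j = iou[i, j], j
        if best_j >= 0 and iou[i, best_j] >= t:
            taken[best_j] = True
            assign[i] = best_j
    return assign


def _evaluate_bands(
    per_image: list[dict],
    sizes: SizeCategorySpec,
    cap: int,
    interpolation: str,
    thresholds: tuple[float, ...],
) -> EvaluationReport:
    ap_pt: dict[float, float] = {}
    fnr_pt: dict[float, float] = {}
    size_ap: dict[str, float] = {}
    size_afnr: dict[str, float] = {}
    for band in ("all", "small", "medium", "large"):
        lo, hi = sizes.band(band)
        band_aps, band_fnrs = [], []
        n_gt_band = sum(
            int(((pi["gt_areas"] > lo) & (pi["gt_areas"] <= hi)).sum())
            if band != "all"
            else len(pi["gts"])
            for pi in per_image
        )
        for t in thresholds:
            flags, scores, keep = [], [], []
            tp_total = 0
            for pi in per_image:
                assign = _greedy(pi["iou"], t)
                if band == "all":
                    in_band_gt = np.ones(len(pi["gts"]), dtype=bool)
                    in_band_pred = np.ones(len(pi["preds"]), dtype=bool)
                else:
                    in_band_gt = (pi["gt_areas"] > lo) & (pi["gt_areas"] <= hi)
                    in_band_pred = (pi["pred_areas"] > lo) & (pi["pred_areas"] <= hi)
                for i, j in enumerate(assign):
                    if j >= 0:
                        if in_band_gt[j]:
                            flags.append(True)
                            scores.append(pi["scores"][i])
                            tp_total += 1
                        # matched to out-of-band gt: ignored
                    else:
                        if in_band_pred[i]:
                            flags.append(False)
                            scores.append(pi["scores"][i])
                        # out-of-band unmatched prediction: ignored
            if n_gt_band == 0:
                continue
            if flags:
                curve = pr_curve(np.array(flags), np.array(scores), n_gt_band)
                band_ap = ap_at_threshold(curve, interpolation)
            else:
                band_ap = 0.0
            band_recall = tp_total / n_gt_band
            band_aps.append(band_ap)
            band_fnrs.append(1.0 - band_recall)
            if band == "all":
                ap_pt[t] = band_ap
                fnr_pt[t] = 1.0 - band_recall
        if band != "all" and n_gt_band > 0:
            size_ap[band] = float(np.mean(band_aps))
            size_afnr[band] = float(np.mean(band_fnrs))
    if not ap_pt:
        # no ground truth anywhere: report zeros with a warning
        warnings.warn("no ground-truth instances; AP/AFNR set to 0/1", stacklevel=2)
        ap_pt = {t: 0.0 for t in thresholds}
        fnr_pt = {t: 1.0 for t in thresholds}
    return EvaluationReport(
        ap_per_threshold=ap_pt,
        fnr_per_threshold=fnr_pt,
        size_ap=size_ap,
        size_afnr=size_afnr,
        detection_cap=cap,
        interpolation=interpolation,
    )
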