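"""Segmentation evaluation: per-class IoU/accuracy, directional overlap
indexes and their harmonic means.

For ground-truth mask S and predicted mask T over a class universe:

* ``IoU_c   = |S_c ∩ T_c| / |S_c ∪ T_c|``
* ``acc_c   = |S_c ∩ T_c| / |S_c|``
* ``f_min(S→T) = min_i  max_j |S_i ∩ T_j| / |S_i|`` — the worst-category
  overlap between the regions of the source mask and the regions of the
  target mask;
* ``f_sum(S→T) = Σ_i max_j |S_i ∩ T_j| / Σ_i |S_i|`` — the pixel-weighted
  average category overlap;
* ``F_x = 2 f_x(S→T) f_x(T→S) / (f_x(S→T) + f_x(T→S))`` — the harmonic mean
  of the two directions.

Regions ``S_i`` / ``T_j`` are whole per-category label sets (not connected
components); the background label is excluded from the directional indexes
and, by default, from the per-class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "iou",
    "mean_iou",
    "class_accuracy",
    "mean_accuracy",
    "f_directional",
    "f_harmonic",
    "SegReport",
    "full_report",
    "confusion_matrix",
]


def _check_shapes(gt: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"mask shapes differ: {gt.shape} vs {pred.shape}")
    return gt, pred


def confusion_matrix(gt: np.ndarray, pred: np.ndarray, n_classes: int) -> np.ndarray:
    """n_classes x n_classes counts, rows = ground truth, cols = prediction."""
    gt, pred = _check_shapes(gt, pred)
    if gt.min() < 0 or gt.max() >= n_classes or pred.min() < 0 or pred.max() >= n_classes:
        raise ValueError("labels outside class universe")
    idx = gt.reshape(-1).astype(np.int64) * n_classes + pred.reshape(-1).astype(np.int64)
    return np.bincount(idx, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )


def iou(gt: np.ndarray, pred: np.ndarray, c: int) -> float:
    """Intersection over union of class ``c``; NaN when absent from both."""
    gt, pred = _check_shapes(gt, pred)
    g = gt == c
    p = pred == c
    union = np.count_nonzero(g | p)
    if union == 0:
        return float("nan")
    return np.count_nonzero(g & p) / union


def class_accuracy(gt: np.ndarray, pred: np.ndarray, c: int) -> float:
    """|gt_c ∩ pred_c| / |gt_c|; NaN when class ``c`` is absent from gt."""
    gt, pred = _check_shapes(gt, pred)
    g = gt == c
    n = np.count_nonzero(g)
    if n == 0:
        return float("nan")
    return np.count_nonzero(g & (pred == c)) / n


def _per_class(gt, pred, classes, include_background, fn):
    vals = {}
    for c in classes:
        if c == 0 and not include_background:
            continue
        vals[c] = fn(gt, pred, c)
    return vals


def mean_iou(
    gt: np.ndarray,
    pred: np.ndarray,
    classes: "list[int] | None" = None,
    include_background: bool = False,
) -> float:
    """Mean IoU over classes; classes absent from both masks contribute no term."""
    gt, pred = _check_shapes(gt, pred)
    if classes is None:
        classes = sorted(set(np.unique(gt)) | set(np.unique(pred)))
    vals = [
        v
        for v in _per_class(gt, pred, classes, include_background, iou).values()
        if not np.isnan(v)
    ]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def mean_accuracy(
    gt: np.ndarray,
    pred: np.ndarray,
    classes: "list[int] | None" = None,
    include_background: bool = False,
) -> float:
    gt, pred = _check_shapes(gt, pred)
    if classes is None:
        classes = sorted(set(np.unique(gt)) | set(np.unique(pred)))
    vals = [
        v
        for v in _per_class(gt, pred, classes, include_background, class_accuracy).values()
        if not np.isnan(v)
    ]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def f_directional(
    source: np.ndarray,
    target: np.ndarray,
    mode: str,
    background: int = 0,
) -> float:
    """Directional overlap index from ``source`` regions onto ``target`` regions.

    For each non-background category region S_i of the source, the best
    single-region overlap ``max_j |S_i ∩ T_j|`` with the target's category
    regions is taken; ``mode='min'`` returns the worst ratio to |S_i|,
    ``mode='sum'`` the aggregate ratio Σ max / Σ |S_i|.
    """
    if mode not in ("min", "sum"):
        raise ValueError(f"mode must be 'min' or 'sum', got {mode!r}")
    source, target = _check_shapes(source, target)
    src_classes = [c for c in np.unique(source) if c != background]
    if not src_classes:
        raise ValueError("source mask has no non-background region")
    tgt_classes = [c for c in np.unique(target) if c != background]

    best = []
    sizes = []
    for ci in src_classes:
        s = source == ci
        sizes.append(np.count_nonzero(s))
        overlaps = [np.count_nonzero(s & (target == cj)) for cj in tgt_classes]
        best.append(max(overlaps) if overlaps else 0)
    best_a = np.array(best, dtype=np.float64)
    sizes_a = np.array(sizes, dtype=np.float64)
    if mode == "min":
        return float(np.min(best_a / sizes_a))
    return float(best_a.sum() / sizes_a.sum())


def f_harmonic(forward: float, backward: float) -> float:
    """Harmonic mean ``2ab/(a+b)`` of the two directional indexes (0 at a=b=0)."""
    for v in (forward, backward):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"directional index {v} outside [0, 1]")
    if forward + backward == 0.0:
        return 0.0
    return 2.0 * forward * backward / (forward + backward)


@dataclass
class SegReport:
    """All mask-pair metrics for one evaluation run."""

    per_class_iou: dict[int, float]
    mean_iou: float
    per_class_accuracy: dict[int, float]
    mean_accuracy: float
    fmin_s_to_t: float
    fmin_t_to_s: float
    f_min: float
    fsum_s_to_t: float
    fsum_t_to_s: float
    f_sum: float
    include_background: bool = False
    notes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "per_class_iou": {int(k): v for k, v in self.per_class_iou.items()},
            "mean_iou": self.mean_iou,
            "per_class_accuracy": {
                int(k): v for k, v in self.per_class_accuracy.items()
            },
            "mean_accuracy": self.mean_accuracy,
            "fmin_s_to_t": self.fmin_s_to_t,
            "fmin_t_to_s": self.fmin_t_to_s,
            "f_min": self.f_min,
            "fsum_s_to_t": self.fsum_s_to_t,
            "fsum_t_to_s": self.fsum_t_to_s,
            "f_sum": self.f_sum,
            "include_background": self.include_background,
        }
        d.update(self.notes)
        return d


def full_report(
    gt: np.ndarray,
    pred: np.ndarray,
    classes: "list[int] | None" = None,
    include_background: bool = False,
) -> SegReport:
    """Assemble every metric for a ground-truth / prediction mask pair.

    Classes absent from the ground truth contribute no per-class term (the
    report notes which were skipped).  ``include_background`` folds label 0
    into the per-class means; the directional indexes always exclude it.
    """
    gt, pred = _check_shapes(gt, pred)
    if classes is None:
        classes = sorted(set(np.unique(gt)) | set(np.unique(pred)))
    ious = _per_class(gt, pred, classes, include_background, iou)
    accs = _per_class(gt, pred, classes, include_background, class_accuracy)
    fmin_st = f_directional(gt, pred, "min")
    fmin_ts = f_directional(pred, gt, "min")
    fsum_st = f_directional(gt, pred, "sum")
    fsum_ts = f_directional(pred, gt, "sum")
    skipped = sorted(
        int(c) for c, v in ious.items() if isinstance(v, float) and np.isnan(v)
    )
    return SegReport(
        per_class_iou=ious,
        mean_iou=float(np.nanmean(list(ious.values()))),
        per_class_accuracy=accs,
        mean_accuracy=float(np.nanmean(list(accs.values()))),
        fmin_s_to_t=fmin_st,
        fmin_t_to_s=fmin_ts,
        f_min=f_harmonic(fmin_st, fmin_ts),
        fsum_s_to_t=fsum_st,
        fsum_t_to_s=fsum_ts,
        f_sum=f_harmonic(fsum_st, fsum_ts),
        include_background=include_background,
        notes={"skipped_absent_classes": skipped},
    )
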