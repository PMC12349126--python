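"""Segmentation evaluation metrics.

Overlap metrics follow the foreground-count formulas standard in the skin
lesion segmentation literature:

    mIoU = TP / (FP + TP + FN)          (foreground IoU)
    DSC  = 2 TP / (FP + 2 TP + FN)
    ACC  = (TP + TN) / total
    SE   = TP / (TP + FN)
    SP   = TN / (TN + FP)

``mIoU`` is foreground IoU by default, exactly as printed in the source
formulas; a two-class (foreground/background mean) variant is available via
``mean_over_classes=True``.

HD95 is the 95th percentile of Euclidean boundary-to-boundary distances.
Boundaries are 8-connected mask border pixels; by default the two directed
distance sets are pooled before taking the percentile (symmetric by
construction), with the max-of-directed-percentiles variant behind a flag.

Edge conventions (documented, deterministic):
* both masks empty -> mIoU = DSC = 1, HD95 = 0;
* exactly one mask empty -> HD95 = image diagonal;
* an undefined ratio (zero denominator) -> 1.0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    miou: float
    dsc: float
    acc: float
    se: float
    sp: float
    hd95: float
    counts: ConfusionCounts | None = None

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        d = {k: getattr(self, k) * scale
             for k in ("miou", "dsc", "acc", "se", "sp")}
        d["hd95"] = self.hd95
        if self.counts is not None:
            d.update(asdict(self.counts))
        return d


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must contain only {{0,1}}, found {vals[:5]}")
    return arr.astype(bool)


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    p = _as_binary(pred_mask, "pred_mask")
    t = _as_binary(true_mask, "true_mask")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 1.0


def scalar_metrics(c: ConfusionCounts,
                   mean_over_classes: bool = False) -> tuple[float, ...]:
    """(mIoU, DSC, ACC, SE, SP) from confusion counts."""
    iou_fg = _ratio(c.tp, c.fp + c.tp + c.fn)
    if mean_over_classes:
        iou_bg = _ratio(c.tn, c.tn + c.fp + c.fn)
        miou = 0.5 * (iou_fg + iou_bg)
    else:
        miou = iou_fg
    dsc = _ratio(2 * c.tp, c.fp + 2 * c.tp + c.fn)
    acc = _ratio(c.tp + c.tn, c.total)
    se = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    return miou, dsc, acc, se, sp


_CONN8 = np.ones((3, 3), dtype=bool)


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """8-connected border pixels (mask minus its erosion)."""
    m = np.asarray(mask, dtype=bool)
    return m & ~ndimage.binary_erosion(m, structure=_CONN8, border_value=0)


def hd95(pred_mask: np.ndarray, true_mask: np.ndarray,
         percentile: float = 95.0, variant: str = "pooled") -> float:
    """95th-percentile symmetric boundary distance, in pixels."""
    p = _as_binary(pred_mask, "pred_mask")
    t = _as_binary(true_mask, "true_mask")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p_any, t_any = bool(p.any()), bool(t.any())
    if not p_any and not t_any:
        return 0.0
    if p_any != t_any:
        return float(np.hypot(*p.shape))
    bp, bt = mask_boundary(p), mask_boundary(t)
    # distance_transform_edt of the complement gives, at every pixel, the
    # distance to the nearest boundary pixel of the other mask
    dist_to_t = ndimage.distance_transform_edt(~bt)
    dist_to_p = ndimage.distance_transform_edt(~bp)
    d_pt = dist_to_t[bp]
    d_tp = dist_to_p[bt]
    if variant == "pooled":
        return float(np.percentile(np.concatenate([d_pt, d_tp]), percentile))
    if variant == "max_directed":
        return float(max(np.percentile(d_pt, percentile),
                         np.percentile(d_tp, percentile)))
    raise ValueError(f"unknown hd95 variant {variant!r}")


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold sigmoid probabilities into a {0,1} mask."""
    return (np.asarray(prob_map) > threshold).astype(np.uint8)


def evaluate(pairs, aggregate: str = "global",
             mean_over_classes: bool = False) -> MetricsReport:
    """Evaluate an iterable of (pred_mask, true_mask) binary pairs.

    ``aggregate='global'`` sums confusion counts over the dataset before
    computing ratios (the default); ``'per_image'`` averages per-image
    metrics.  HD95 is averaged per image in both modes (boundary distances
    do not pool across images).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no prediction/mask pairs to evaluate")
    counts = [confusion(p, t) for p, t in pairs]
    hds = [hd95(p, t) for p, t in pairs]
    if aggregate == "global":
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        miou, dsc, acc, se, sp = scalar_metrics(total, mean_over_classes)
        return MetricsReport(miou, dsc, acc, se, sp, float(np.mean(hds)), total)
    if aggregate == "per_image":
        per = np.array([scalar_metrics(c, mean_over_classes) for c in counts])
        miou, dsc, acc, se, sp = per.mean(axis=0)
        return MetricsReport(float(miou), float(dsc), float(acc), float(se),
                             float(sp), float(np.mean(hds)), None)
    raise ValueError(f"unknown aggregate mode {aggregate!r}")


def write_report(report: MetricsReport, path: str | Path,
                 percent: bool = True):
    """Write a metrics report as JSON or CSV (by file extension)."""
    path = Path(path)
    data = report.as_dict(percent=percent)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    elif path.suffix == ".csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(data.keys())
            w.writerow([f"{v:.4f}" if isinstance(v, float) else v
                        for v in data.values()])
    else:
        raise ValueError(f"unsupported report format {path.suffix!r}")
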