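"""Evaluation: image metrics, point matching, detection rates, aggregation.

Image-level metrics compare a predicted heatmap with the ground-truth map:
MAE (mean absolute pixel error), SSIM (standard windowed structural
similarity, Gaussian window sigma 1.5 / width 11, C1 = (0.01 L)^2,
C2 = (0.03 L)^2 with L = 1), and the Dice coefficient on binarized maps.

Point-level evaluation extracts peaks from the prediction and matches them
one-to-one against annotated centers within a declared radius (maximum
cardinality, ties broken by minimum total distance). Matched peaks are
true positives (TP); unmatched predictions are "untrue positives" (UP,
spurious detections); unmatched ground-truth points are "untrue negatives"
(UN, missed papillae). The three headline rates are::

    TP rate           = TP / ground-truth count * 100 %
    accurate count    = TP / (TP + UP) * 100 %
    complete accuracy = TP / (TP + UP + UN) * 100 %

Folds aggregate as mean +/- SD; fold-level rates are computed from summed
counts (normalizing by the real number of papillae in the fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage.metrics import structural_similarity

from .core import Heatmap, PointSet
from .errors import ValidationError
from .heatmap import HeatmapConfig, detect_peaks, points_to_heatmap


# ---------------------------------------------------------------------------
# Image metrics
# ---------------------------------------------------------------------------

def _check_shapes(pred: Heatmap, gt: Heatmap) -> None:
    if pred.shape != gt.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {gt.shape}")


def mae_metric(pred: Heatmap, gt: Heatmap) -> float:
    """Mean absolute pixel error between prediction and ground truth."""
    _check_shapes(pred, gt)
    return float(np.mean(np.abs(pred.values.astype(np.float64)
                                - gt.values.astype(np.float64))))


def ssim_metric(pred: Heatmap, gt: Heatmap) -> float:
    """Structural similarity with the standard published constants."""
    _check_shapes(pred, gt)
    return float(structural_similarity(
        pred.values.astype(np.float64), gt.values.astype(np.float64),
        data_range=1.0, gaussian_weights=True, sigma=1.5, win_size=11,
        use_sample_covariance=False,
    ))


def dice_metric(pred: Heatmap, gt: Heatmap, threshold: float = 0.5) -> float:
    """Dice overlap 2|A^B| / (|A|+|B|) of maps binarized at ``threshold``.

    Defined as 1.0 when both binarized maps are empty.
    """
    _check_shapes(pred, gt)
    a = pred.values >= threshold
    b = gt.values >= threshold
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


# ---------------------------------------------------------------------------
# Point matching
# ---------------------------------------------------------------------------

@dataclass
class DetectionOutcome:
    """TP/UP/UN counts plus the matched (gt, pred, distance) pairs."""

    tp: int
    up: int
    un: int
    matched_pairs: list[tuple[tuple[float, float], tuple[float, float], float]]


def match_points(gt: PointSet, pred: PointSet, radius: float) -> DetectionOutcome:
    """Optimal one-to-one matching of predictions to ground truth.

    Maximizes the number of pairs within ``radius`` (Euclidean), breaking
    count ties by minimum total distance; deterministic and independent of
    input order.
    """
    if radius <= 0:
        raise ValidationError("matching radius must be > 0")
    n_gt, n_pred = len(gt), len(pred)
    if n_gt == 0 or n_pred == 0:
        return DetectionOutcome(tp=0, up=n_pred, un=n_gt, matched_pairs=[])
    d = np.sqrt(
        ((gt.coords[:, None, :] - pred.coords[None, :, :]) ** 2).sum(-1)
    )
    feasible = d <= radius
    # A single infeasible assignment must cost more than any all-feasible
    # matching, so minimizing total cost maximizes matched-pair count first.
    big = radius * (min(n_gt, n_pred) + 1) + 1.0
    cost = np.where(feasible, d, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    for r, c in zip(rows, cols):
        if feasible[r, c]:
            pairs.append((
                (float(gt.coords[r, 0]), float(gt.coords[r, 1])),
                (float(pred.coords[c, 0]), float(pred.coords[c, 1])),
                float(d[r, c]),
            ))
    tp = len(pairs)
    return DetectionOutcome(tp=tp, up=n_pred - tp, un=n_gt - tp,
                            matched_pairs=pairs)


@dataclass
class RateReport:
    """The headline detection percentages; ``None`` marks an undefined rate
    (zero denominator) — never silently reported as 0."""

    tp_rate_pct: float | None
    un_rate_pct: float | None
    up_rate_pct: float | None
    accurate_count_pct: float | None
    complete_accuracy_pct: float | None


def detection_rates(outcome: DetectionOutcome) -> RateReport:
    """Compute the rate report from TP/UP/UN counts."""
    tp, up, un = outcome.tp, outcome.up, outcome.un
    n_gt = tp + un
    tp_rate = 100.0 * tp / n_gt if n_gt > 0 else None
    un_rate = 100.0 * un / n_gt if n_gt > 0 else None
    up_rate = 100.0 * up / n_gt if n_gt > 0 else None
    acc_count = 100.0 * tp / (tp + up) if (tp + up) > 0 else None
    complete = 100.0 * tp / (tp + up + un) if (tp + up + un) > 0 else None
    return RateReport(tp_rate_pct=tp_rate, un_rate_pct=un_rate,
                      up_rate_pct=up_rate, accurate_count_pct=acc_count,
                      complete_accuracy_pct=complete)


# ---------------------------------------------------------------------------
# Fold-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class FoldReport:
    """Per-image metric table plus fold aggregates.

    ``per_image`` columns: sample_id, mae, ssim, dice, gt_count, pred_count,
    tp, up, un. ``rates`` normalizes summed counts by the real number of
    papillae in the fold. The matching radius used is recorded.
    """

    per_image: pd.DataFrame
    radius: float
    aggregates: dict[str, tuple[float, float]] = field(default_factory=dict)
    rates: RateReport | None = None

    def __post_init__(self) -> None:
        if not self.aggregates:
            for col in ("mae", "ssim", "dice", "gt_count", "pred_count",
                        "tp", "up", "un"):
                vals = self.per_image[col].to_numpy(dtype=float)
                self.aggregates[col] = (float(vals.mean()),
                                        float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        if self.rates is None:
            total = DetectionOutcome(
                tp=int(self.per_image["tp"].sum()),
                up=int(self.per_image["up"].sum()),
                un=int(self.per_image["un"].sum()),
                matched_pairs=[],
            )
            self.rates = detection_rates(total)


def evaluate_fold(
    model,
    val_set: list[tuple[str, np.ndarray, PointSet]],
    heatmap_config: HeatmapConfig,
    radius: float = 5.0,
) -> FoldReport:
    """Evaluate a trained model on a held-out fold.

    ``val_set`` holds (sample_id, (H,W,C) image, annotation PointSet)
    triples; ground-truth heatmaps are rebuilt from the annotations with
    ``heatmap_config``.
    """
    if not val_set:
        raise ValidationError("val_set must be non-empty")
    rows = []
    for sample_id, image, annotations in val_set:
        try:
            pred = model.predict(image)
            shape = pred.shape
            gt_map = points_to_heatmap(annotations, shape, heatmap_config)
            peaks = detect_peaks(pred, heatmap_config)
            outcome = match_points(annotations, peaks, radius)
            rows.append({
                "sample_id": sample_id,
                "mae": mae_metric(pred, gt_map),
                "ssim": ssim_metric(pred, gt_map),
                "dice": dice_metric(pred, gt_map),
                "gt_count": len(annotations),
                "pred_count": len(peaks),
                "tp": outcome.tp, "up": outcome.up, "un": outcome.un,
            })
        except ValidationError as exc:
            raise ValidationError(f"sample '{sample_id}': {exc}") from exc
    return FoldReport(per_image=pd.DataFrame(rows), radius=radius)


def aggregate_runs(fold_reports: list[FoldReport]) -> dict:
    """Cross-fold mean +/- SD summary plus the per-image count export.

    Fold-level TP/UN/UP percentages are computed per fold from summed
    counts, then averaged across folds. Returns a dict with:

    * ``summary`` — DataFrame of metric -> (mean, sd) across folds,
    * ``fold_rates`` — DataFrame of per-fold percentages,
    * ``counts`` — per-image ground-truth vs predicted counts, one row per
      image, for external statistical analysis.
    """
    if not fold_reports:
        raise ValidationError("need at least one fold report")
    metric_rows = {}
    for metric in ("mae", "ssim", "dice", "gt_count", "pred_count"):
        vals = np.array([fr.aggregates[metric][0] for fr in fold_reports])
        metric_rows[metric] = (float(vals.mean()),
                               float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    rate_rows = []
    for i, fr in enumerate(fold_reports):
        r = fr.rates
        rate_rows.append({
            "fold": i, "radius": fr.radius,
            "tp_rate_pct": r.tp_rate_pct, "un_rate_pct": r.un_rate_pct,
            "up_rate_pct": r.up_rate_pct,
            "accurate_count_pct": r.accurate_count_pct,
            "complete_accuracy_pct": r.complete_accuracy_pct,
        })
    fold_rates = pd.DataFrame(rate_rows)
    for col in ("tp_rate_pct", "un_rate_pct", "up_rate_pct",
                "accurate_count_pct", "complete_accuracy_pct"):
        vals = fold_rates[col].dropna().to_numpy(dtype=float)
        if len(vals):
            metric_rows[col] = (float(vals.mean()),
                                float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    counts = pd.concat(
        [fr.per_image[["sample_id", "gt_count", "pred_count"]]
         for fr in fold_reports],
        ignore_index=True,
    )
    summary = pd.DataFrame(
        [{"metric": k, "mean": m, "sd": s} for k, (m, s) in metric_rows.items()]
    )
    return {"summary": summary, "fold_rates": fold_rates, "counts": counts}
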