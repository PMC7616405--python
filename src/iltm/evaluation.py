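"""Pixel-level segmentation metrics: AUROC, AUPRO and best-achievable DICE.

All metrics treat HIGHER scores as more anomalous, so KDE log-likelihood
maps (where low means anomalous) should be negated before evaluation —
:func:`maps_to_scores` does this.  AUROC and best-DICE pool pixels across
the test set; AUPRO averages the per-connected-region overlap (true
positive rate computed per ground-truth region) against the pooled
false-positive rate, integrated up to an FPR limit and normalized by it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationReport",
    "maps_to_scores",
    "pixel_auroc",
    "aupro",
    "best_dice",
    "evaluate",
]


@dataclass(frozen=True)
class EvaluationReport:
    auroc: float
    aupro: float
    best_dice: float
    dice_threshold: float
    fpr_limit: float
    n_pixels: int
    n_regions: int
    per_image_auroc: tuple[float, ...] = ()


def maps_to_scores(maps) -> np.ndarray:
    """Stack AnomalyMap objects (or L arrays) into negated score maps."""
    arrs = [m.L if hasattr(m, "L") else np.asarray(m) for m in maps]
    return -np.stack(arrs)


def _pool(scores, gt):
    scores = np.asarray(scores, dtype=float)
    gt = np.asarray(gt, dtype=bool)
    if scores.shape != gt.shape:
        raise ValueError("scores and ground truth shapes differ")
    return scores.reshape(-1), gt.reshape(-1)


def pixel_auroc(scores: np.ndarray, gt: np.ndarray) -> float:
    """Rank-based AUROC over pixels pooled across images."""
    s, y = _pool(scores, gt)
    if y.all() or not y.any():
        raise ValueError("ground truth contains a single class")
    return float(roc_auc_score(y, s))


def _candidate_thresholds(scores, max_candidates):
    uniq = np.unique(scores)
    if len(uniq) <= max_candidates:
        return uniq
    qs = np.linspace(0.0, 1.0, max_candidates)
    return np.unique(np.quantile(scores, qs))


def aupro(scores: np.ndarray, gt: np.ndarray, fpr_limit: float = 0.3, *,
          max_candidates: int = 1000) -> float:
    """Area under the per-region-overlap vs FPR curve, up to ``fpr_limit``.

    For each threshold, the overlap of each ground-truth connected region
    with the binarized prediction is averaged over regions (across all
    images); the x-axis is the pooled false-positive rate.  The area up to
    ``fpr_limit`` is normalized by ``fpr_limit`` so a perfect detector
    scores 1.
    """
    if not 0.0 < fpr_limit <= 1.0:
        raise ValueError("fpr_limit must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    gt = np.asarray(gt, dtype=bool)
    if scores.ndim == 2:
        scores, gt = scores[None], gt[None]
    if not gt.any():
        raise ValueError("no anomalous regions in ground truth")

    regions = []  # flat pixel indices per connected component
    offset = 0
    npix = scores[0].size
    for g in gt:
        lab = measure.label(g, connectivity=2)
        for r in range(1, lab.max() + 1):
            regions.append(np.flatnonzero(lab.reshape(-1) == r) + offset)
        offset += npix
    flat_s = scores.reshape(-1)
    flat_g = gt.reshape(-1)
    negatives = ~flat_g
    n_neg = int(negatives.sum())
    if n_neg == 0:
        raise ValueError("ground truth has no normal pixels")

    thresholds = _candidate_thresholds(flat_s, max_candidates)[::-1]
    fprs, pros = [0.0], [0.0]
    for thr in thresholds:
        pred = flat_s >= thr
        fpr = (pred & negatives).sum() / n_neg
        pro = float(np.mean([pred[r].mean() for r in regions]))
        fprs.append(float(fpr))
        pros.append(pro)
    fprs.append(1.0)
    pros.append(1.0)
    fprs, pros = np.asarray(fprs), np.asarray(pros)
    order = np.argsort(fprs, kind="stable")
    fprs, pros = fprs[order], pros[order]
    # clip the curve at the FPR limit (linear interpolation at the cut)
    if fprs[-1] > fpr_limit:
        pro_at = np.interp(fpr_limit, fprs, pros)
        keep = fprs < fpr_limit
        fprs = np.append(fprs[keep], fpr_limit)
        pros = np.append(pros[keep], pro_at)
    return float(np.trapezoid(pros, fprs) / fpr_limit)


def best_dice(scores: np.ndarray, gt: np.ndarray, *,
              max_candidates: int = 10_000) -> tuple[float, float]:
    """Maximum DICE over score thresholds (prediction: score >= threshold).

    Evaluates every distinct score when there are at most
    ``max_candidates`` of them, otherwise a 1000-point quantile grid.
    Returns (best value, threshold achieving it).
    """
    s, y = _pool(scores, gt)
    if y.all() or not y.any():
        raise ValueError("ground truth contains a single class")
    uniq = np.unique(s)
    if len(uniq) > max_candidates:
        uniq = np.unique(np.quantile(s, np.linspace(0, 1, 1000)))
    # descending thresholds via cumulative counts of sorted scores
    order = np.argsort(s, kind="stable")[::-1]
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    n_pos = int(y.sum())
    # last index where s_sorted >= thr, for each candidate threshold
    idx = len(s_sorted) - 1 - np.searchsorted(s_sorted[::-1], uniq, side="left")
    valid = idx >= 0
    idx = idx[valid]
    dice = 2.0 * tp[idx] / (tp[idx] + fp[idx] + n_pos)
    best = int(np.argmax(dice))
    return float(dice[best]), float(uniq[valid][best])


def evaluate(maps, gt_masks, *, fpr_limit: float = 0.3) -> EvaluationReport:
    """Full report from anomaly maps (low = anomalous) and ground truth."""
    scores = maps_to_scores(maps)
    gt = np.asarray(gt_masks, dtype=bool)
    auroc = pixel_auroc(scores, gt)
    pro = aupro(scores, gt, fpr_limit)
    dice, thr = best_dice(scores, gt)
    per_image = []
    for s, g in zip(scores, gt):
        if g.any() and not g.all():
            per_image.append(float(roc_auc_score(g.reshape(-1), s.reshape(-1))))
    n_regions = sum(int(measure.label(g, connectivity=2).max()) for g in gt)
    return EvaluationReport(auroc=auroc, aupro=pro, best_dice=dice,
                            dice_threshold=thr, fpr_limit=fpr_limit,
                            n_pixels=int(gt.size), n_regions=n_regions,
                            per_image_auroc=tuple(per_image))
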