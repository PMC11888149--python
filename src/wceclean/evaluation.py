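"""Segmentation evaluation: pixel metrics, agreement, and the trial protocol.

The positive class is *clean* throughout (white in ground-truth masks), so
sensitivity is clean recall and specificity is the true-negative rate on
contaminated pixels.  Metrics are computed per frame and then aggregated as
mean +/- sample standard deviation over frames; frames where a metric is
undefined (a 0/0 ratio, or AUROC on a single-class frame) are excluded from
that metric's aggregate and counted.

``run_trials`` implements the repeated-trial protocol: in each trial the
corpus is re-clustered by CIELAB histogram K-means with a fresh seed, one
frame per cluster is selected for model fitting, and the remaining frames
are segmented and scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import color_clustering as cc
from . import gbc
from .image_io import validate_mask

__all__ = [
    "ConfusionCounts",
    "SegmentationMetrics",
    "TrialReport",
    "METRIC_NAMES",
    "confusion",
    "metrics_from_confusion",
    "auroc",
    "evaluate_frame",
    "aggregate",
    "clean_fraction_correlation",
    "run_trials",
]

METRIC_NAMES = ("accuracy", "precision", "specificity", "sensitivity", "auroc", "dsc", "iou")

UNDEFINED = float("nan")  # marker for 0/0 metrics; excluded from aggregation


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts with clean as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegmentationMetrics:
    """Per-frame segmentation scores; NaN marks an undefined (0/0) metric."""

    accuracy: float
    precision: float
    specificity: float
    sensitivity: float
    auroc: float
    dsc: float
    iou: float
    clean_fraction_pred: float = UNDEFINED
    clean_fraction_gt: float = UNDEFINED


@dataclass(frozen=True)
class TrialReport:
    """One trial: per-frame metrics plus per-metric mean and sample std."""

    per_image: list[SegmentationMetrics]
    mean: dict[str, float]
    std: dict[str, float]
    n_undefined: dict[str, int]
    trial_seed: int
    dataset_id: str = ""
    fit_indices: tuple[int, ...] = ()
    clean_fraction_pearson: float = field(default=UNDEFINED)


def confusion(
    pred: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None
) -> ConfusionCounts:
    """Confusion counts of a predicted vs ground-truth clean mask."""
    pred = validate_mask(pred)
    gt = validate_mask(gt, pred.shape)
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        pred, gt = pred[fov], gt[fov]
    return ConfusionCounts(
        tp=int((pred & gt).sum()),
        fp=int((pred & ~gt).sum()),
        fn=int((~pred & gt).sum()),
        tn=int((~pred & ~gt).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def metrics_from_confusion(c: ConfusionCounts) -> SegmentationMetrics:
    """Accuracy, precision, specificity, sensitivity, DSC and IOU from counts.

    Any 0/0 ratio yields the NaN undefined-marker.  AUROC needs the
    posterior map and is filled in by :func:`evaluate_frame`.
    """
    return SegmentationMetrics(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        specificity=_ratio(c.tn, c.tn + c.fp),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        auroc=UNDEFINED,
        dsc=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
    )


def auroc(p_clean: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None) -> float:
    """Rank-based (Mann-Whitney) AUROC of the clean posterior, midrank ties.

    Undefined (NaN) when the ground truth is single-class.
    """
    gt = validate_mask(gt)
    p = np.asarray(p_clean, dtype=float)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {gt.shape}")
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        p, gt = p[fov], gt[fov]
    y = gt.ravel()
    if y.all() or not y.any():
        return UNDEFINED
    return float(roc_auc_score(y, p.ravel()))


def evaluate_frame(
    pred: np.ndarray,
    p_clean: np.ndarray,
    gt: np.ndarray,
    fov: np.ndarray | None = None,
) -> SegmentationMetrics:
    """All per-frame metrics for one (prediction, posterior, ground truth) triple."""
    c = confusion(pred, gt, fov)
    base = metrics_from_confusion(c)
    return SegmentationMetrics(
        accuracy=base.accuracy,
        precision=base.precision,
        specificity=base.specificity,
        sensitivity=base.sensitivity,
        auroc=auroc(p_clean, gt, fov),
        dsc=base.dsc,
        iou=base.iou,
        clean_fraction_pred=gbc.clean_fraction(pred, fov),
        clean_fraction_gt=gbc.clean_fraction(gt, fov),
    )


def aggregate(
    per_image: Sequence[SegmentationMetrics],
    trial_seed: int = 0,
    dataset_id: str = "",
    fit_indices: tuple[int, ...] = (),
) -> TrialReport:
    """Mean and sample std (ddof=1) per metric over frames with defined values."""
    if not per_image:
        raise ValueError("no per-image metrics to aggregate")
    mean, std, n_undef = {}, {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_image], dtype=float)
        defined = vals[~np.isnan(vals)]
        n_undef[name] = int(np.isnan(vals).sum())
        mean[name] = float(defined.mean()) if defined.size else UNDEFINED
        std[name] = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
    pairs = [
        (m.clean_fraction_pred, m.clean_fraction_gt)
        for m in per_image
        if not (math.isnan(m.clean_fraction_pred) or math.isnan(m.clean_fraction_gt))
    ]
    pearson = clean_fraction_correlation(pairs) if len(pairs) >= 3 else UNDEFINED
    return TrialReport(
        per_image=list(per_image),
        mean=mean,
        std=std,
        n_undefined=n_undef,
        trial_seed=trial_seed,
        dataset_id=dataset_id,
        fit_indices=tuple(fit_indices),
        clean_fraction_pearson=pearson,
    )


def clean_fraction_correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation between predicted and annotated clean fractions.

    This is the inter-observer agreement on visualisation quality.  Returns
    the NaN undefined-marker when either marginal is constant.
    """
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(pairs)}")
    pred = np.array([p for p, _ in pairs], dtype=float)
    gt = np.array([g for _, g in pairs], dtype=float)
    if np.ptp(pred) == 0 or np.ptp(gt) == 0:
        import warnings

        warnings.warn("constant clean fractions: Pearson correlation undefined")
        return UNDEFINED
    return float(stats.pearsonr(pred, gt).statistic)


def run_trials(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    n_trials: int = 5,
    k: int = 20,
    seed: int = 0,
    bins_per_channel: int = 8,
    epsilon: float = 1e-3,
    fov: np.ndarray | None = None,
    dataset_id: str = "",
) -> list[TrialReport]:
    """Repeated-trial protocol: re-cluster, select K fit frames, fit, evaluate.

    Histogram features are computed once; each trial re-runs K-means and
    the per-cluster random selection with a seed derived from ``seed``,
    fits the classifier on the K selected frames, segments the remaining
    frames and aggregates their metrics.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks differ in length")
    if len(images) < k + 1:
        raise ValueError(f"need more than k={k} frames, got {len(images)}")
    features = [
        cc.histogram_3d(cc.rgb_to_cielab(img), bins_per_channel, fov=fov) for img in images
    ]
    trial_seeds = np.random.SeedSequence(seed).generate_state(n_trials, np.uint32) % (2**31)
    reports = []
    for t, tseed in enumerate(int(s) for s in trial_seeds):
        assignment = cc.cluster_frames(features, k=k, seed=tseed)
        fit_idx = cc.select_representatives(assignment, seed=tseed)
        model = gbc.fit(
            [images[i] for i in fit_idx],
            [masks[i] for i in fit_idx],
            epsilon=epsilon,
            fov=fov,
            fit_seed=tseed,
        )
        per_image = []
        for i in range(len(images)):
            if i in fit_idx:
                continue
            pred, p_clean = gbc.segment(images[i], model, fov=fov)
            per_image.append(evaluate_frame(pred, p_clean, masks[i], fov=fov))
        reports.append(
            aggregate(per_image, trial_seed=tseed, dataset_id=dataset_id, fit_indices=tuple(fit_idx))
        )
    return reports
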