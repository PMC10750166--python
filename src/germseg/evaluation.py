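"""Instance-matched Jaccard evaluation of predicted vs ground-truth labels.

The score follows the convention of the Cellpose literature: predicted and
ground-truth instances are matched one-to-one at an IoU threshold (default
0.5) and the Jaccard index is TP / (TP + FP + FN). The matching maximizes
the number of matched pairs; at thresholds above 0.5 this coincides with
greedy matching because a voxel set can exceed 0.5 IoU with at most one
partner.

Both 3D volumes and single 2D slices are accepted, since ground truth is
typically annotated on 2D orthogonal views.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "iou_matrix",
    "match_instances",
    "jaccard_index",
    "evaluate_dataset",
]


@dataclasses.dataclass(frozen=True)
class MatchResult:
    """One-to-one instance matching at an IoU threshold.

    ``pairs`` holds (gt_id, pred_id, IoU) triples with IoU strictly above
    the threshold; each id appears in at most one pair. ``n_tp`` equals
    ``len(pairs)``; FP counts unmatched predictions and FN unmatched
    ground-truth instances.
    """

    pairs: tuple[tuple[int, int, float], ...]
    n_tp: int
    n_fp: int
    n_fn: int
    iou_threshold: float

    @property
    def jaccard(self) -> float:
        denom = self.n_tp + self.n_fp + self.n_fn
        return 1.0 if denom == 0 else self.n_tp / denom


def _as_labels(x) -> np.ndarray:
    labels = getattr(x, "labels", x)
    return np.asarray(labels)


def iou_matrix(gt, pred) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise IoU between every gt and pred instance.

    Returns ``(gt_ids, pred_ids, iou)`` where ``iou[i, j]`` is the IoU of
    gt instance ``gt_ids[i]`` with pred instance ``pred_ids[j]``. Computed
    from the sparse joint histogram of the two label images, never by
    all-pairs voxel scans.
    """
    g = _as_labels(gt).ravel()
    p = _as_labels(pred).ravel()
    if g.shape != p.shape:
        raise ValueError("gt and pred label volumes must have the same shape")
    gt_ids = np.unique(g)
    gt_ids = gt_ids[gt_ids > 0]
    pred_ids = np.unique(p)
    pred_ids = pred_ids[pred_ids > 0]
    if gt_ids.size == 0 or pred_ids.size == 0:
        return gt_ids, pred_ids, np.zeros((gt_ids.size, pred_ids.size))

    gi = np.searchsorted(gt_ids, g)      # row index; background handled by mask
    pj = np.searchsorted(pred_ids, p)
    both = (g > 0) & (p > 0)
    inter = sparse.coo_matrix(
        (np.ones(both.sum(), dtype=np.int64), (gi[both], pj[both])),
        shape=(gt_ids.size, pred_ids.size),
    ).toarray()
    gt_sizes = np.bincount(gi[g > 0], minlength=gt_ids.size)
    pred_sizes = np.bincount(pj[p > 0], minlength=pred_ids.size)
    union = gt_sizes[:, None] + pred_sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return gt_ids, pred_ids, iou


def match_instances(
    iou: np.ndarray,
    iou_threshold: float = 0.5,
    gt_ids: Sequence[int] | None = None,
    pred_ids: Sequence[int] | None = None,
) -> MatchResult:
    """Maximum-cardinality one-to-one matching among pairs with IoU > threshold.

    Among maximum-cardinality matchings the one with the largest total IoU
    is chosen (assignment weights 1 + IoU on admissible pairs), and pairs
    are reported sorted by descending IoU then ascending (gt_id, pred_id).
    """
    if not 0 <= iou_threshold < 1:
        raise ValueError("iou_threshold must be in [0, 1)")
    iou = np.atleast_2d(np.asarray(iou, dtype=float))
    n_gt, n_pred = iou.shape
    if gt_ids is None:
        gt_ids = np.arange(1, n_gt + 1)
    if pred_ids is None:
        pred_ids = np.arange(1, n_pred + 1)

    admissible = iou > iou_threshold
    pairs: list[tuple[int, int, float]] = []
    if admissible.any():
        # cardinality dominates (the +1), total IoU breaks ties among
        # maximum matchings
        weights = np.where(admissible, 1.0 + iou, 0.0)
        rows, cols = linear_sum_assignment(weights, maximize=True)
        for i, j in zip(rows, cols):
            if admissible[i, j]:
                pairs.append((int(gt_ids[i]), int(pred_ids[j]), float(iou[i, j])))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    n_tp = len(pairs)
    return MatchResult(
        pairs=tuple(pairs),
        n_tp=n_tp,
        n_fp=n_pred - n_tp,
        n_fn=n_gt - n_tp,
        iou_threshold=iou_threshold,
    )


def jaccard_index(gt, pred, iou_threshold: float = 0.5) -> float:
    """TP / (TP + FP + FN) after instance matching; 1.0 when both are empty."""
    gt_ids, pred_ids, iou = iou_matrix(gt, pred)
    result = match_instances(iou, iou_threshold, gt_ids=gt_ids, pred_ids=pred_ids)
    return result.jaccard


def evaluate_dataset(
    gt_list: Sequence,
    pred_list: Sequence,
    iou_threshold: float = 0.5,
    image_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-image Jaccard scores plus mean/std/median/IQR summary.

    Returns a tidy report (columns image_id, n_gt, n_pred, tp, fp, fn,
    jaccard) and a summary dict.
    """
    if len(gt_list) != len(pred_list):
        raise ValueError(
            f"gt and pred lists differ in length ({len(gt_list)} vs {len(pred_list)})"
        )
    if image_ids is None:
        image_ids = [f"image_{i:03d}" for i in range(len(gt_list))]
    rows = []
    for img_id, gt, pred in zip(image_ids, gt_list, pred_list):
        gt_ids, pred_ids, iou = iou_matrix(gt, pred)
        res = match_instances(iou, iou_threshold, gt_ids=gt_ids, pred_ids=pred_ids)
        rows.append(
            {
                "image_id": img_id,
                "n_gt": len(gt_ids),
                "n_pred": len(pred_ids),
                "tp": res.n_tp,
                "fp": res.n_fp,
                "fn": res.n_fn,
                "jaccard": res.jaccard,
            }
        )
    report = pd.DataFrame(rows)
    scores = report["jaccard"].to_numpy(dtype=float)
    q1, med, q3 = (np.percentile(scores, q) for q in (25, 50, 75)) if len(scores) else (np.nan,) * 3
    summary = {
        "n_images": len(scores),
        "mean": float(np.mean(scores)) if len(scores) else float("nan"),
        "std": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
        "median": float(med),
        "iqr": float(q3 - q1),
        "iou_threshold": iou_threshold,
    }
    return report, summary
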