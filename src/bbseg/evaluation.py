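"""Segmentation scoring with the SEG measure.

Each true region is compared with the predicted region of highest pixel
overlap; their Jaccard index (|intersection| / |union|) is the region's
score, except that a true region whose best overlap covers less than half
of its area scores 0.  The reported SEG is the mean over true regions,
1 being perfect.  Regions are pooled over a dataset by concatenating the
per-region rows of each image and averaging once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two pixel sets given as boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any():
        raise ValueError("reference pixel set is empty")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union)


@dataclass
class SegResult:
    """Per-true-region match rows and their mean (the SEG score)."""

    rows: pd.DataFrame

    @property
    def seg(self) -> float:
        if len(self.rows) == 0:
            return float("nan")
        return float(self.rows["score"].mean())


def seg_score(
    truth: np.ndarray,
    pred: np.ndarray,
    aoi: np.ndarray | None = None,
    strict_half: bool = False,
) -> SegResult:
    """Score a predicted label map against ground truth.

    For each true region the predicted region (background excluded) with
    the largest intersection is matched; ties go to the larger Jaccard,
    then the lower predicted ID.  The region scores its Jaccard index if
    the intersection covers at least half of the true region's area
    (strictly more than half with ``strict_half``), else 0.  Pixels
    outside the area-of-interest are excluded from every count.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction shapes differ")
    if aoi is not None:
        if aoi.shape != truth.shape:
            raise ValueError("AOI shape differs")
        t = truth[aoi]
        p = pred[aoi]
    else:
        t = truth.ravel()
        p = pred.ravel()

    true_ids, t_inv = np.unique(t, return_inverse=True)
    pred_ids, p_inv = np.unique(p, return_inverse=True)
    # sparse contingency table over (true, pred) id pairs
    pair = t_inv.astype(np.int64) * len(pred_ids) + p_inv
    counts = np.bincount(pair, minlength=len(true_ids) * len(pred_ids)).reshape(
        len(true_ids), len(pred_ids)
    )
    t_areas = counts.sum(axis=1)
    p_areas = counts.sum(axis=0)

    rows = []
    for ti, tid in enumerate(true_ids):
        if tid == 0:
            continue
        area = int(t_areas[ti])
        best = None  # (inter, jacc, pid)
        for pj, pid in enumerate(pred_ids):
            if pid == 0:
                continue
            inter = int(counts[ti, pj])
            if inter == 0:
                continue
            union = area + int(p_areas[pj]) - inter
            jacc = inter / union
            key = (inter, jacc, -int(pid))
            if best is None or key > best[0]:
                best = (key, inter, jacc, int(pid))
        if best is None:
            rows.append(
                {"true_id": int(tid), "pred_id": 0, "area": area,
                 "intersection": 0, "union": area, "jaccard": 0.0, "score": 0.0}
            )
            continue
        _, inter, jacc, pid = best
        covered = inter * 2 > area if strict_half else inter * 2 >= area
        rows.append(
            {
                "true_id": int(tid),
                "pred_id": pid if covered else 0,
                "area": area,
                "intersection": inter,
                "union": area + int(p_areas[pred_ids == pid][0]) - inter,
                "jaccard": jacc,
                "score": jacc if covered else 0.0,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["true_id", "pred_id", "area", "intersection", "union",
                 "jaccard", "score"],
    )
    return SegResult(rows=frame)


def pooled_seg(results: list[SegResult]) -> float:
    """Dataset-level SEG: mean over all true regions of all images."""
    frames = [r.rows for r in results if len(r.rows)]
    if not frames:
        return float("nan")
    return float(pd.concat(frames, ignore_index=True)["score"].mean())
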