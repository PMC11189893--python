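"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_edge_distance(ids: np.ndarray, d_max: float) -> np.ndarray:
    """O(N^2) oracle: per labeled pixel, the minimum Euclidean distance to
    any pixel with a different ID, capped at d_max; 0 on background."""
    ids = np.asarray(ids)
    H, W = ids.shape
    ys, xs = np.mgrid[0:H, 0:W]
    out = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            k = ids[r, c]
            if k == 0:
                continue
            diff = ids != k
            if not diff.any():
                out[r, c] = d_max
                continue
            d = np.sqrt((ys[diff] - r) ** 2 + (xs[diff] - c) ** 2).min()
            out[r, c] = min(d, d_max)
    return out


def brute_seg_score(truth: np.ndarray, pred: np.ndarray, strict_half=False):
    """All-pairs-overlap oracle for the SEG measure.

    Enumerates every (true, predicted) region pair, matches each true
    region to the predicted one of largest intersection (ties: larger
    Jaccard, then lower ID), zeroes scores whose overlap covers less than
    half the true area, and averages.
    """
    scores = []
    for tid in np.unique(truth):
        if tid == 0:
            continue
        tmask = truth == tid
        area = tmask.sum()
        best = None
        for pid in np.unique(pred):
            if pid == 0:
                continue
            pmask = pred == pid
            inter = (tmask & pmask).sum()
            if inter == 0:
                continue
            jacc = inter / (tmask | pmask).sum()
            key = (inter, jacc, -pid)
            if best is None or key > best[0]:
                best = (key, inter, jacc)
        if best is None:
            scores.append(0.0)
            continue
        _, inter, jacc = best
        ok = inter * 2 > area if strict_half else inter * 2 >= area
        scores.append(jacc if ok else 0.0)
    return float(np.mean(scores)) if scores else float("nan")


def random_label_map(rng, max_side=32, n_ids=4) -> np.ndarray:
    """A random small label map with touching blobby regions."""
    h = int(rng.integers(5, max_side + 1))
    w = int(rng.integers(5, max_side + 1))
    kind = rng.integers(0, 2)
    if kind == 0:
        return rng.integers(0, n_ids + 1, size=(h, w)).astype(np.int32)
    # voronoi-ish: seeds claim nearest pixels, some cells left background
    n = int(rng.integers(2, 7))
    ys = rng.uniform(0, h, n)
    xs = rng.uniform(0, w, n)
    yy, xx = np.mgrid[0:h, 0:w]
    d = (yy[..., None] - ys) ** 2 + (xx[..., None] - xs) ** 2
    lab = d.argmin(axis=-1) + 1
    for k in range(1, n + 1):
        if rng.uniform() < 0.3:
            lab[lab == k] = 0
    return lab.astype(np.int32)
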