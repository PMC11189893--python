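"""Per-pixel training targets derived from user label maps.

A label map assigns one positive integer ID per region, 0 to background.
Two targets are derived for every pixel:

* a binary class — inside any region ("innie") vs outside ("outie");
* the Euclidean distance (px) to the nearest *differently labeled* pixel,
  capped at ``d_max`` and 0 on all background pixels.

"Differently labeled" includes background *and* other regions, so two
regions in contact both carry a distance valley along the contact — the
feature the watershed later uses to split them.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def binarize_labels(ids: np.ndarray) -> np.ndarray:
    """True exactly where a pixel belongs to some region (ID > 0)."""
    return np.asarray(ids) > 0


def edge_distance(ids: np.ndarray, d_max: float) -> np.ndarray:
    """Capped Euclidean distance to the nearest differently labeled pixel.

    For each pixel of region ``k`` the distance is measured center-to-center
    to the nearest pixel whose ID differs from ``k`` (background or another
    region), capped at ``d_max``.  Background pixels get 0.  A region with
    no differently labeled pixel in the image (degenerate single-region map)
    gets ``d_max`` everywhere.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    ids = np.asarray(ids)
    out = np.zeros(ids.shape, dtype=np.float32)
    pad = int(np.ceil(d_max)) + 2
    for k in np.unique(ids):
        if k == 0:
            continue
        rows, cols = np.nonzero(ids == k)
        r0 = max(rows.min() - pad, 0)
        r1 = min(rows.max() + pad + 1, ids.shape[0])
        c0 = max(cols.min() - pad, 0)
        c1 = min(cols.max() + pad + 1, ids.shape[1])
        window = ids[r0:r1, c0:c1]
        same = window == k
        if same.all():
            # no differently labeled pixel within reach -> capped everywhere
            out[rows, cols] = d_max
            continue
        dist = ndimage.distance_transform_edt(same)
        out[r0:r1, c0:c1][same] = np.minimum(dist[same], d_max)
    return out


def default_aoi(shape: tuple[int, int]) -> np.ndarray:
    """The all-true area-of-interest used when no mask is supplied."""
    return np.ones(shape, dtype=bool)
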