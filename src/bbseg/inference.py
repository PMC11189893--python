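"""Whole-image prediction and assembly into labeled segmentations.

The trained network is evaluated once per area-of-interest pixel
(batched), giving a class-probability map and a predicted distance map.
The probability map is thresholded into foreground; plateaus of the
distance map seed a watershed on the inverted distances, which splits
touching regions along their predicted valleys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed as _watershed

from .labels import default_aoi
from .network import DualHeadCNN
from .params import ParamSet
from .sampling import MultiScaleExtractor, normalize_image

_EIGHT = np.ones((3, 3), dtype=int)


def predict_maps(
    net: DualHeadCNN,
    image,
    aoi: np.ndarray | None,
    params: ParamSet,
    batch: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel probability and distance maps for one image.

    ``image`` is an :class:`~bbseg.io.ImageRecord` or raw array; it is
    normalized exactly as during training.  Pixels outside the
    area-of-interest are 0 in both maps; the distance map is clipped to
    [0, dist_cap].
    """
    norm = normalize_image(image, params.rgb_mode)
    shape = norm.shape[:2]
    if aoi is None:
        aoi = default_aoi(shape)
    if aoi.shape != shape:
        raise ValueError("AOI shape does not match image")
    extractor = MultiScaleExtractor(norm, params.scales, params.patch_side)
    rows, cols = np.nonzero(aoi)
    pmap = np.zeros(shape, dtype=np.float32)
    dmap = np.zeros(shape, dtype=np.float32)
    for start in range(0, len(rows), batch):
        rr = rows[start : start + batch]
        cc = cols[start : start + batch]
        prob, dist = net.predict(extractor.stacks(rr, cc))
        pmap[rr, cc] = prob
        dmap[rr, cc] = np.clip(dist, 0.0, float(params.dist_cap))
    return pmap, dmap


def binarize(pmap: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground where probability >= threshold (ties count as inside)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(pmap) >= threshold


@dataclass
class Segmentation:
    """Labeled raster (0 = background) with its per-region table."""

    labels: np.ndarray

    @property
    def n_regions(self) -> int:
        ids = np.unique(self.labels)
        return int((ids > 0).sum())


def watershed_split(
    binary: np.ndarray,
    dmap: np.ndarray,
    params: ParamSet,
) -> Segmentation:
    """Split thresholded foreground into regions along distance valleys.

    Markers are the 8-connected components of the high-distance plateau
    ``{d >= marker_level}`` within the foreground; any foreground component
    without a plateau still gets one marker at its distance maximum, so no
    foreground pixel is left unassigned.  The watershed floods the inverted
    distance map (8-connected).  Components smaller than ``min_region_px``
    are removed; surviving labels are renumbered 1..K in raster-scan order
    of each region's first pixel.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != dmap.shape:
        raise ValueError("binary mask and distance map shapes differ")
    level = params.effective_marker_level
    markers_mask = binary & (dmap >= level)
    fg_comp, n_comp = ndimage.label(binary, structure=_EIGHT)
    if n_comp:
        # fallback marker at the distance argmax of any plateau-free component
        has_marker = np.zeros(n_comp + 1, dtype=bool)
        has_marker[np.unique(fg_comp[markers_mask])] = True
        for comp in range(1, n_comp + 1):
            if not has_marker[comp]:
                sel = fg_comp == comp
                flat = np.where(sel.ravel(), dmap.ravel(), -np.inf)
                markers_mask.ravel()[int(flat.argmax())] = True
    markers, n_markers = ndimage.label(markers_mask, structure=_EIGHT)
    if n_markers == 0:
        warnings.warn("no watershed markers found; returning empty segmentation")
        return Segmentation(labels=np.zeros(binary.shape, dtype=np.int32))
    lab = _watershed(-dmap, markers=markers, mask=binary, connectivity=2)
    lab = lab.astype(np.int32)
    if params.min_region_px > 0:
        ids, counts = np.unique(lab[lab > 0], return_counts=True)
        small = ids[counts < params.min_region_px]
        if len(small):
            lab[np.isin(lab, small)] = 0
    return Segmentation(labels=_renumber(lab))


def _renumber(lab: np.ndarray) -> np.ndarray:
    """Relabel 1..K by raster-scan order of each region's first pixel."""
    flat = lab.ravel()
    ids, first = np.unique(flat, return_index=True)
    keep = ids > 0
    order = np.argsort(first[keep])
    mapping = np.zeros(int(ids.max(initial=0)) + 1, dtype=np.int32)
    mapping[ids[keep][order]] = np.arange(1, keep.sum() + 1, dtype=np.int32)
    return mapping[lab]


def region_table(seg: Segmentation) -> pd.DataFrame:
    """One row per region: id, area, centroid, bounding box (CSV-friendly)."""
    lab = seg.labels
    rows = []
    for k in np.unique(lab):
        if k == 0:
            continue
        rr, cc = np.nonzero(lab == k)
        rows.append(
            {
                "id": int(k),
                "area": int(len(rr)),
                "centroid_row": float(rr.mean()),
                "centroid_col": float(cc.mean()),
                "bbox_top": int(rr.min()),
                "bbox_left": int(cc.min()),
                "bbox_bottom": int(rr.max()),
                "bbox_right": int(cc.max()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "area", "centroid_row", "centroid_col",
            "bbox_top", "bbox_left", "bbox_bottom", "bbox_right",
        ],
    )


def segment_image(
    net: DualHeadCNN,
    image,
    aoi: np.ndarray | None,
    params: ParamSet,
) -> tuple[Segmentation, np.ndarray, np.ndarray]:
    """Full pipeline for one image: predict maps, threshold, watershed."""
    pmap, dmap = predict_maps(net, image, aoi, params)
    fg = binarize(pmap, params.prob_threshold)
    if aoi is not None:
        fg &= aoi
    seg = watershed_split(fg, dmap, params)
    return seg, pmap, dmap
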