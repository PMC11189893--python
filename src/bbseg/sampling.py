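"""Training-set construction: pixel draws, multi-scale patches, augmentation.

Every training example is one pixel.  Its network input is a stack of S
concentric square windows ("patch stack"): the window at scale ``s`` has
side ``patch_side * s`` and is reduced to ``patch_side``² by ``s x s``
block averaging, so the network sees several length scales at a fixed
input size.  Out-of-image content is filled by edge replication.

The draw honors the area-of-interest mask, uses a fraction ``F`` of the
``M`` eligible pixels, and (optionally) balances inside vs outside pixels
by oversampling the minority class with replacement.  The total training
budget is ``T = round(E * F * M)`` sample presentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageRecord
from .labels import binarize_labels, default_aoi, edge_distance
from .params import ParamSet

# ITU-R 601 luma weights for collapsing RGB to one channel
_LUMA = np.array([0.299, 0.587, 0.114])


def normalize_image(img: ImageRecord | np.ndarray, rgb_mode: str = "luma") -> np.ndarray:
    """Rescale an image to zero mean, unit variance (per image).

    RGB input is collapsed to a single luma channel (``rgb_mode='luma'``)
    or kept as three channels normalized jointly (``'keep3'``), preserving
    relative color.  A constant image maps to all zeros.
    Normalization is invariant to any positive affine rescale of the input.
    """
    px = img.pixels if isinstance(img, ImageRecord) else np.asarray(img)
    px = px.astype(np.float64)
    if px.ndim == 3:
        px = px[:, :, :3]
        if rgb_mode == "luma":
            px = px @ _LUMA
    if px.max() == px.min():
        return np.zeros_like(px, dtype=np.float32)
    mu = px.mean()
    sigma = px.std()
    return ((px - mu) / sigma).astype(np.float32)


def _channels(norm: np.ndarray) -> list[np.ndarray]:
    if norm.ndim == 2:
        return [norm]
    return [norm[:, :, c] for c in range(norm.shape[2])]


def extract_stack(
    norm: np.ndarray,
    center: tuple[int, int],
    scales: tuple[int, ...],
    patch_side: int,
) -> np.ndarray:
    """Extract the multi-scale patch stack around one pixel.

    Reference (per-pixel) implementation: for each scale ``s`` the
    ``patch_side*s`` window centered on the pixel is cut from the
    edge-replicated image and reduced by ``s x s`` block means.  Channels
    are stacked scale-major (for multi-channel input, all scales of channel
    0 first).  Returns ``(patch_side, patch_side, S*C)`` float32.
    """
    if any(s < 1 for s in scales):
        raise ValueError("scales must be >= 1")
    r, c = center
    if not (0 <= r < norm.shape[0] and 0 <= c < norm.shape[1]):
        raise ValueError("center outside image")
    half = patch_side // 2
    planes = []
    for chan in _channels(norm):
        for s in scales:
            margin = half * s + s // 2
            padded = np.pad(chan, margin, mode="edge")
            top = r + margin - half * s - s // 2
            left = c + margin - half * s - s // 2
            win = padded[top : top + patch_side * s, left : left + patch_side * s]
            block = win.reshape(patch_side, s, patch_side, s).mean(axis=(1, 3))
            planes.append(block)
    return np.stack(planes, axis=-1).astype(np.float32)


class MultiScaleExtractor:
    """Vectorized patch-stack extraction for many pixels of one image.

    Precomputes, per scale, a box-filtered edge-padded copy of the image;
    a patch pixel is then a single gather, which makes whole-image
    prediction and batched training draws cheap.  Agrees exactly with
    :func:`extract_stack`.
    """

    def __init__(self, norm: np.ndarray, scales: tuple[int, ...], patch_side: int):
        if any(s < 1 for s in scales):
            raise ValueError("scales must be >= 1")
        self.scales = tuple(scales)
        self.patch_side = patch_side
        self.shape = norm.shape[:2]
        half = patch_side // 2
        self._planes: list[tuple[np.ndarray, int, int]] = []
        for chan in _channels(norm):
            for s in self.scales:
                margin = half * s + s // 2
                padded = np.pad(chan, margin, mode="edge").astype(np.float32)
                if s > 1:
                    # box filter = block mean at every offset; scipy's window
                    # convention matches the block layout used above
                    padded = ndimage.uniform_filter(padded, size=s, mode="nearest")
                self._planes.append((padded, margin, s))

    @property
    def n_channels(self) -> int:
        return len(self._planes)

    def stacks(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Patch stacks for pixel centers ``(rows[i], cols[i])``."""
        half = self.patch_side // 2
        offsets = np.arange(self.patch_side) - half
        out = np.empty(
            (len(rows), self.patch_side, self.patch_side, self.n_channels),
            dtype=np.float32,
        )
        for p, (padded, margin, s) in enumerate(self._planes):
            rr = rows[:, None] + margin + offsets[None, :] * s
            cc = cols[:, None] + margin + offsets[None, :] * s
            out[:, :, :, p] = padded[rr[:, :, None], cc[:, None, :]]
        return out


def dihedral(stack: np.ndarray, k: int) -> np.ndarray:
    """Apply the k-th symmetry of the square (k in 0..7) to every channel.

    k % 4 counts quarter-turn rotations; k >= 4 adds a horizontal flip
    before rotating.  k = 0 is the identity.
    """
    if not 0 <= k <= 7:
        raise ValueError("k must be in 0..7")
    out = stack
    if k >= 4:
        out = out[:, ::-1]
    return np.rot90(out, k % 4, axes=(0, 1)).copy()


@dataclass(frozen=True)
class SampleBudget:
    """Training-budget bookkeeping: T = round(E*F*M) sample presentations."""

    M: int
    F: float
    E: int

    @property
    def n_drawn(self) -> int:
        return int(round(self.F * self.M))

    @property
    def T(self) -> int:
        return int(round(self.E * self.F * self.M))

    @property
    def EF(self) -> float:
        """The collapse variable T/M controlling segmentation quality."""
        return self.T / self.M


@dataclass
class SampleDraw:
    """A seeded draw of training pixels over one or more images.

    Arrays are aligned: sample ``i`` is pixel ``(rows[i], cols[i])`` of
    image ``image_index[i]`` with binary class ``class_label[i]`` and
    capped edge distance ``dist_label[i]``.  Order is a seeded permutation.
    """

    image_index: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    class_label: np.ndarray
    dist_label: np.ndarray
    budget: SampleBudget
    extractors: list[MultiScaleExtractor]

    def __len__(self) -> int:
        return len(self.rows)

    def stacks(self, idx: np.ndarray) -> np.ndarray:
        """Materialize the patch stacks for the samples at positions idx."""
        out = None
        for img_i in np.unique(self.image_index[idx]):
            sel = self.image_index[idx] == img_i
            sub = self.extractors[img_i].stacks(
                self.rows[idx][sel], self.cols[idx][sel]
            )
            if out is None:
                out = np.empty((len(idx),) + sub.shape[1:], dtype=np.float32)
            out[sel] = sub
        return out


def _draw_from_pool(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    """Draw k indices: without replacement until the pool is exhausted,
    then whole reshuffled passes (minority oversampling)."""
    if k <= len(pool):
        return rng.choice(pool, size=k, replace=False)
    reps, rem = divmod(k, len(pool))
    parts = [rng.permutation(pool) for _ in range(reps)]
    if rem:
        parts.append(rng.choice(pool, size=rem, replace=False))
    return np.concatenate(parts)


def draw_samples(
    images: list[np.ndarray],
    label_maps: list[np.ndarray],
    aois: list[np.ndarray] | None,
    params: ParamSet,
    rng: np.random.Generator,
) -> tuple[SampleDraw, SampleBudget]:
    """Draw the training pixels for a set of normalized images.

    ``images`` are normalized arrays (see :func:`normalize_image`).  Only
    pixels where the area-of-interest is true are eligible; of the ``M``
    eligible pixels ``round(F*M)`` are drawn.  With class balancing the
    inside/outside counts differ by at most 1, oversampling the minority
    class with replacement once its pool is exhausted.
    """
    if aois is None:
        aois = [default_aoi(lm.shape) for lm in label_maps]
    per_image = []
    for i, (img, lm, aoi) in enumerate(zip(images, label_maps, aois)):
        if img.shape[:2] != lm.shape or lm.shape != aoi.shape:
            raise ValueError(f"image {i}: image/labels/AOI shapes differ")
        rr, cc = np.nonzero(aoi)
        inside = binarize_labels(lm)[rr, cc]
        dmap = edge_distance(lm, params.dist_cap)[rr, cc]
        per_image.append((np.full(len(rr), i), rr, cc, inside, dmap))
    image_index = np.concatenate([p[0] for p in per_image])
    rows = np.concatenate([p[1] for p in per_image])
    cols = np.concatenate([p[2] for p in per_image])
    inside = np.concatenate([p[3] for p in per_image])
    dists = np.concatenate([p[4] for p in per_image])

    M = len(rows)
    if M == 0:
        raise ValueError("no eligible pixels (area of interest is empty)")
    budget = SampleBudget(M=M, F=params.fraction, E=params.epochs)
    n = budget.n_drawn

    if params.balance_classes:
        pool_out = np.nonzero(~inside)[0]
        pool_in = np.nonzero(inside)[0]
        if len(pool_out) == 0 or len(pool_in) == 0:
            pool = pool_in if len(pool_out) == 0 else pool_out
            chosen = _draw_from_pool(rng, pool, n)
        else:
            # innies get the odd draw when n is odd
            part_out = _draw_from_pool(rng, pool_out, n // 2)
            part_in = _draw_from_pool(rng, pool_in, n - n // 2)
            chosen = np.concatenate([part_out, part_in])
        chosen = chosen[rng.permutation(len(chosen))]
    else:
        chosen = rng.permutation(M)[:n]

    extractors = [
        MultiScaleExtractor(img, params.scales, params.patch_side) for img in images
    ]
    draw = SampleDraw(
        image_index=image_index[chosen],
        rows=rows[chosen],
        cols=cols[chosen],
        class_label=inside[chosen].astype(np.float32),
        dist_label=dists[chosen].astype(np.float32),
        budget=budget,
        extractors=extractors,
    )
    return draw, budget
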