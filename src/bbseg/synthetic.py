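"""Synthetic scenes with the structure the method targets.

Two generators:

* :func:`make_disks` — packed textured disks (optionally in contact), the
  granular/bubble use case.  Textures include a birefringence-like
  four-lobe angular pattern that forces the network to use shape rather
  than raw brightness.
* :func:`make_lattice` — a thin bright strut grid with randomly deleted
  ("fractured") struts, the structure-tracking use case.

Images get an illumination gradient, Gaussian blur and Gaussian noise;
label maps stay clean.  All randomness flows through one seeded generator
per call, so identical seeds give identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageRecord


class PlacementError(RuntimeError):
    """Could not place the requested number of particles."""

    def __init__(self, placed: int, requested: int):
        super().__init__(
            f"placed only {placed} of {requested} disks within the attempt budget"
        )
        self.placed = placed


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic disk scene.

    ``contact_allowance`` is how far (px) two disk rims may interpenetrate;
    2 allows genuine contacts, 0 keeps disks separated.  ``texture`` is
    one of ``flat``, ``radial``, ``birefringence``.
    """

    height: int = 256
    width: int = 256
    n_particles: int = 30
    radius_range: tuple[float, float] = (8.0, 14.0)
    contact_allowance: float = 2.0
    texture: str = "birefringence"
    illumination: float = 0.15
    blur_sigma: float = 0.8
    noise_sigma: float = 0.02
    background: float = 0.12

    def __post_init__(self):
        if self.radius_range[0] < 3:
            raise ValueError("radii must be >= 3 px")
        if self.texture not in ("flat", "radial", "birefringence"):
            raise ValueError(f"unknown texture {self.texture!r}")


def _disk_texture(spec: SceneSpec, rel_r, theta, rng) -> np.ndarray:
    """Per-pixel intensity of one disk given relative radius and angle."""
    if spec.texture == "flat":
        return np.full_like(rel_r, 0.55 + 0.3 * rng.uniform())
    if spec.texture == "radial":
        peak = 0.6 + 0.35 * rng.uniform()
        return peak * (1.0 - 0.65 * rel_r)
    # birefringence-like: four angular lobes plus a radial ramp, with a
    # random lobe orientation and amplitude per disk
    phase = rng.uniform(0, np.pi)
    amp = 0.35 + 0.4 * rng.uniform()
    base = 0.30 + 0.25 * rng.uniform()
    lobes = np.cos(2.0 * (theta - phase)) ** 2
    return base + amp * lobes * (1.0 - 0.5 * rel_r**2)


def make_disks(
    spec: SceneSpec, rng: np.random.Generator, max_attempts: int = 20000
) -> tuple[ImageRecord, np.ndarray]:
    """Generate one disk scene: 16-bit image plus clean integer label map.

    Disk centers are rejection-sampled so rims interpenetrate by at most
    ``contact_allowance`` px; a pixel claimed by several disks goes to the
    one whose rim it is deepest inside, so touching disks keep distinct
    labels separated along the contact line.
    """
    h, w = spec.height, spec.width
    centers: list[tuple[float, float, float]] = []
    attempts = 0
    while len(centers) < spec.n_particles:
        if attempts >= max_attempts:
            raise PlacementError(len(centers), spec.n_particles)
        attempts += 1
        r = rng.uniform(*spec.radius_range)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        ok = True
        for oy, ox, orr in centers:
            if np.hypot(cy - oy, cx - ox) < r + orr - spec.contact_allowance:
                ok = False
                break
        if ok:
            centers.append((cy, cx, r))

    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)
    depth = np.full((h, w), -np.inf)  # how deep inside a rim each pixel is
    img = np.full((h, w), spec.background, dtype=np.float64)
    for k, (cy, cx, r) in enumerate(centers, start=1):
        dist = np.hypot(yy - cy, xx - cx)
        inside = dist <= r
        signed = r - dist  # positive inside, the claim priority
        claim = inside & (signed > depth)
        labels[claim] = k
        depth[claim] = signed[claim]
        rel_r = np.clip(dist / r, 0, 1)
        theta = np.arctan2(yy - cy, xx - cx)
        tex = _disk_texture(spec, rel_r, theta, rng)
        img[claim] = tex[claim]

    if spec.illumination > 0:
        ramp_dir = rng.uniform(0, 2 * np.pi)
        ramp = (yy * np.sin(ramp_dir) + xx * np.cos(ramp_dir)) / max(h, w)
        img = img * (1.0 + spec.illumination * (ramp - ramp.mean()))
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    pixels = np.round(img * 65535).astype(np.uint16)
    return ImageRecord(name="disks", pixels=pixels), labels


@dataclass(frozen=True)
class LatticeSpec:
    """Parameters of a synthetic fractured-lattice scene."""

    height: int = 192
    width: int = 192
    spacing: int = 24
    strut_width: int = 3
    deletion_rate: float = 0.0
    noise_sigma: float = 0.02
    blur_sigma: float = 0.6
    background: float = 0.1


def make_lattice(
    spec: LatticeSpec, rng: np.random.Generator
) -> tuple[ImageRecord, np.ndarray]:
    """Generate a strut grid with random strut deletions ("fractures").

    Strut survival is thresholded against per-strut uniforms drawn once,
    so for a fixed seed the surviving set shrinks monotonically as the
    deletion rate grows.  Returns the image and the binary strut mask.
    """
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    bright = np.zeros((h, w), dtype=np.float64)
    sw = spec.strut_width
    rows = list(range(spec.spacing // 2, h - sw, spec.spacing))
    cols = list(range(spec.spacing // 2, w - sw, spec.spacing))
    # horizontal segments between adjacent junctions, then vertical ones
    segments = []
    for r in rows:
        for ci in range(len(cols) - 1):
            segments.append(("h", r, cols[ci], cols[ci + 1]))
    for c in cols:
        for ri in range(len(rows) - 1):
            segments.append(("v", c, rows[ri], rows[ri + 1]))
    draws = rng.uniform(size=len(segments))
    brightness = 0.6 + 0.4 * rng.uniform(size=len(segments))
    for seg, u, b in zip(segments, draws, brightness):
        if u < spec.deletion_rate:
            continue
        kind, a, lo, hi = seg
        if kind == "h":
            mask[a : a + sw, lo : hi + sw] = True
            bright[a : a + sw, lo : hi + sw] = np.maximum(
                bright[a : a + sw, lo : hi + sw], b
            )
        else:
            mask[lo : hi + sw, a : a + sw] = True
            bright[lo : hi + sw, a : a + sw] = np.maximum(
                bright[lo : hi + sw, a : a + sw], b
            )
    img = np.where(mask, bright, spec.background)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    pixels = np.round(img * 65535).astype(np.uint16)
    return ImageRecord(name="lattice", pixels=pixels), mask
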