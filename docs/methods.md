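# Methods

## The segmentation model

`bbseg` treats instance segmentation as a per-pixel prediction problem.
For every pixel of an image a small convolutional network answers two
questions simultaneously:

1. **Class** — is this pixel inside any region of interest ("innie") or
   outside ("outie")?  Output: a sigmoid probability.
2. **Edge distance** — how far (in pixels) is it from the nearest edge of
   its region?  Output: a linear scalar, trained against the Euclidean
   distance to the nearest *differently labeled* pixel, capped at a
   user-set `dist_cap` (default 10 px) and fixed to 0 outside regions.

The cap matters in both directions: deep interiors all map to the same
plateau value, so the network never wastes capacity localizing itself far
from an edge, while the uncapped range 0..`dist_cap` near edges is exactly
the part the assembly step needs.  "Differently labeled" deliberately
includes *other regions*, not just background: two touching regions then
carry a distance valley (d ≤ 1 on both first rows of pixels) along their
contact, and this valley is what allows them to be separated later.

Segmentation of a new image proceeds in three steps: predict both maps
pixel-by-pixel; threshold the probability map (default 0.5, ties count as
inside) into a foreground mask; run a marker-based watershed on the
*inverted* predicted distance map restricted to the foreground.  Markers
are the 8-connected components of the high-distance plateau
`{d >= marker_level}` (default `dist_cap - 2`; a high plateau makes the
seeding insensitive to regression noise near edges).  Any foreground
component that contains no plateau pixel still receives one marker at its
distance maximum, so the watershed assigns every foreground pixel —
thresholded foreground is partitioned, never silently dropped.  Finally,
components smaller than `min_region_px` (default 10) are discarded as
speckle and labels are renumbered 1..K in raster-scan order, which makes
outputs reproducible byte-for-byte.

## Network input: multi-scale patch stacks

The network never sees whole images.  Its input for one pixel is a stack
of S concentric square windows at integer scales (default 1, 3, 9, 27):
the window at scale s has side `patch_side*s` (default 25·s) and is
reduced to `patch_side`² by s×s block averaging.  The stack therefore
shows the pixel's immediate neighborhood at full resolution and
progressively wider context at progressively coarser resolution, at a
fixed input size.  Out-of-image content is filled by edge replication —
replication avoids inventing dark borders that the network would learn as
spurious edge features.  Block-mean down-sampling doubles as
anti-aliasing and is exactly the identity on constant images.

Whole-image prediction uses the identity "block mean at every offset =
box filter": per scale, one `scipy.ndimage.uniform_filter` pass over the
edge-padded image turns patch extraction into pure gathers.  The batched
path agrees with the per-pixel reference extractor to float32 rounding
and is tested against it.

Images are normalized per image to zero mean and unit variance before
patching (constant images map to all zeros), making training invariant to
brightness and contrast offsets between images.  RGB input is collapsed
to ITU-R 601 luma by default; `rgb_mode=keep3` instead feeds each color
channel as its own set of scale planes (S·3 input channels), normalized
jointly so relative color survives.

## Architecture

The network has 15 counted layers — 6 convolutions, 3 max-pools, 4 dense
layers, 2 heads — arranged as three blocks of
[3×3 conv, 3×3 conv, 2×2 max-pool] with channel widths 24, 48, 96,
followed by a flatten and dense layers of widths 384, 96, 48, 16.
Blocks 2 and 3 are residual: the block input, average-pooled to the
output's spatial size and projected by an (uncounted) 1×1 convolution, is
added before the block's final ReLU.  With 25×25 input the spatial plan
is 25 → 12 → 6 → 2; pooling uses stride-2 floor semantics (a trailing
odd row/column is dropped), and block 3 opens with one valid-padded
convolution (6 → 4) so that the map entering the flatten is exactly
2×2×96.  Hidden activations are ReLU; the class head is a sigmoid, the
distance head linear.  Initialization is He-normal for ReLU layers and
Glorot-uniform for the heads, from a seeded generator, so two builds with
one seed are identical arrays.

The forward and backward passes are written directly in NumPy against
im2col matrix products.  The backward pass is verified against central
finite differences in float64 in the test suite (tolerance 1e-4), which
pins every layer's gradient, including the residual projections and the
pooling argmax routing.

## Losses, optimizer, budget

Training minimizes `BCE(class) + MAE(distance)` with equal 1:1 weighting.
MAE is preferred over MSE because segmentation quality hinges on the
accuracy of *small* distances near edges and contacts; MSE would let the
plateau dominate.  Distance targets are kept in raw pixel units
(0..`dist_cap`), not normalized.

The optimizer is Adam, learning rate 0.001, β₁ = 0.9, β₂ = 0.999,
ε = 1e-8, no schedule and no early stopping.  The single capacity knob is
the presentation budget: with M eligible pixels, a fraction F of them
drawn and E epochs, training runs exactly T = round(E·F·M) sample
presentations and the log records it, so the collapse variable EF = T/M
is recomputable from any run.  A "step" in this accounting is one sample
presentation; the optimizer updates once per mini-batch.  The default
batch size is 64: at desk-scale budgets (T in the tens of thousands) this
yields several hundred Adam updates, enough for the distance head to
form a usable map, while remaining comfortable for laptop memory.

Pixel draws honor the area-of-interest mask absolutely; of the M eligible
pixels, round(F·M) distinct pixels are drawn.  With class balancing on
(default), innies and outies are drawn in counts differing by at most
one, the minority class cycling through reshuffled passes of its pool
once exhausted.  With balancing off the native class ratio is kept.
Augmentation applies one of the 8 symmetries of the square (4 rotations ×
optional flip), drawn per presentation, to the extracted stack — for
these targets this is equivalent to transforming the whole image (class
and capped edge distance are invariant under the symmetries) and far
cheaper.  All randomness flows from the single `seed` parameter, so full
runs are reproducible to the byte.

## Evaluation: the SEG measure

Each true region is matched to the predicted region with the largest
pixel overlap (ties: larger Jaccard index, then lower predicted ID, for
determinism).  The region scores the Jaccard index
|∩|/|∪| of the matched pair, except that a true region whose best overlap
covers less than half of its own area scores 0.  The "at least half" rule
is inclusive (≥) by default; `seg_strict_half` switches to the strict
variant (>) used by some benchmark suites.  The reported SEG is the mean
over true regions; for multi-image datasets regions are pooled across
images before averaging (per-image values are also reported).  Pixels
outside the area-of-interest are excluded from every count.  The
implementation is tested against an independent all-pairs-overlap brute
force on random label maps.

## Synthetic scenes

The generator produces the two structures the method targets, with known
ground truth, so the whole pipeline is testable without any downloads.

*Disks* (`SceneSpec`): rejection-sampled circles whose rims may
interpenetrate up to `contact_allowance` (default 2 px — genuine contacts
occur), with per-disk texture (flat, radial gradient, or a
birefringence-like pattern: four angular lobes with random orientation
plus a radial ramp, mimicking the look of photoelastic particles without
modeling photoelasticity), a random-direction illumination gradient
(amplitude 0.15), Gaussian blur (0.8 px) and Gaussian noise (σ = 0.02 of
full scale).  Defaults: 256×256, 30 disks of radius 8–14 px.  Pixels
claimed by two disks go to the one whose rim they are deepest inside, so
labels stay distinct along contacts.  The label maps are clean; only the
image is degraded.

*Lattice* (`LatticeSpec`): a thin bright strut grid with per-strut
brightness variation; struts are deleted by thresholding per-strut
uniforms drawn once, so for a fixed seed the surviving structure shrinks
monotonically ("fractures") as the deletion rate grows.

What the synthetic scenes do **not** emulate: out-of-focus gradients
across a field of view, perspective/tilt distortion, true photoelastic
fringe physics, shape variability beyond circles, and temporal
correlation between frames.  Passing the end-to-end tests therefore shows
the machinery learns and assembles correctly under controlled confounds
(texture, contacts, illumination, noise); it does not certify accuracy on
any particular real imaging setup.

## Problem sizes and numerical choices

The end-to-end checks train on a single 256×256 scene with scales
(1, 3, 9), F = 0.2, E = 2 (T = 26 214 presentations, ≈ 410 Adam updates)
and score an unseen scene from the same distribution; this runs in a few
minutes on one CPU core and reaches SEG ≥ 0.9 on the shipped seeds, with
0.8 used as the test threshold.  Determinism is checked by running a
smaller project twice and comparing written rasters byte-for-byte.

Other fixed choices: probabilities are clamped to [1e-7, 1 − 1e-7] inside
the BCE; the predicted distance map is clipped to [0, `dist_cap`] at
inference only (training sees raw head output); the distance transform
uses exact Euclidean distances between pixel centers (no sub-pixel edge
refinement); per-region distance transforms run on bounding boxes padded
by `dist_cap` + 2, which provably contains every uncapped distance; the
degenerate map with a single region and no background caps everywhere at
`dist_cap`.  Inference batches 512 pixels per forward pass to bound the
im2col working set.

## Limitations

* The network is intentionally small and trained from scratch; it will
  not compete with large pretrained models on hard natural-image tasks.
  Its niche is lab imagery with many repeated, roughly similar regions
  and little labeled data.
* One forward pass per pixel makes inference O(H·W) network evaluations;
  a 256×256 image takes on the order of a minute per scale set on one
  CPU core.
* `patch_side` is fixed at 25 by the pooling plan; other input sides
  would need a different spatial plan.
* Watershed assembly assumes regions are blob-like enough that their
  distance plateaus are one connected component each; long thin regions
  with internal valleys can over-segment (raise `marker_level` caution:
  lower it, or raise `min_region_px`, for such data).
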