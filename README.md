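# bbseg

Pixel-classifier instance segmentation for experimental images: train a
small dual-output convolutional network on a handful of user-labeled
images (or a sub-selection of one), then segment new images — including
regions in contact — with no GPU and no code.

Many lab imaging problems (bubbles in a foam, packed granular particles,
a thin lattice that fractures over time, cells and their organelles)
share a shape: lots of repeated, roughly similar regions; confounding
lighting, focus and texture variation; and far too few labeled examples
for large segmentation models.  `bbseg` targets exactly this regime.

## Method in brief

For every pixel the network predicts two scalars from a stack of
concentric context windows (scales 1, 3, 9, 27×, each reduced to 25×25 by
block averaging):

* **p ∈ [0, 1]** — probability the pixel is inside a region (sigmoid head,
  binary cross-entropy loss);
* **d̂ ∈ [0, d_max]** — distance in pixels to the nearest region edge,
  capped at `d_max` (default 10; linear head, mean-absolute-error loss,
  equal 1:1 weighting with the class term).

The distance target is measured to the nearest *differently labeled*
pixel, so touching regions carry a valley along their contact.  A new
image is segmented by thresholding p into foreground and watershedding
the inverted d̂ map: markers are the plateaus `{d̂ ≥ d_max − 2}`, and the
flood fills each region up to the valleys, splitting contacts.

The network is a 15-layer CNN (three [conv3×3, conv3×3, maxpool2×2]
blocks with residual skips, widths 24/48/96, a 2×2×96 map flattened
through four dense layers into the two heads), trained with Adam
(lr 0.001).  Training cost is controlled by one number: with M eligible
pixels, fraction F of them used and E epochs, exactly T = round(E·F·M)
samples are presented, and quality tracks the collapse variable
EF = T/M.  Forward and backward passes are implemented in NumPy and
verified against finite differences; everything is seeded and
byte-for-byte reproducible.

Results are scored with the SEG measure: each true region's Jaccard index
with its best-overlapping predicted region, zeroed when the overlap
covers less than half the true region, averaged over regions.

## Worked example

`examples/02_train_and_segment.py` generates a 128×128 scene of twelve
textured, touching disks with ground-truth labels, trains on 30 % of its
pixels for two epochs, and segments a second, unseen scene:

```
$ python examples/02_train_and_segment.py
trained for T = 9830 sample presentations (EF = T/M = 0.60)
loss: 1.956 -> 0.337 (binary cross-entropy + mean absolute distance error)
unseen scene: 12 true regions, 11 found
SEG = 0.825  (mean Jaccard of matched regions; 1 is perfect)
```

T is the presentation budget round(E·F·M) = round(2·0.3·128²); the loss
is the sum of the class and distance terms, so 0.337 means both heads fit
well; SEG = 0.825 says the matched regions overlap their truth by ≈ 83 %
area on average — with one of the twelve missed, the remaining eleven are
nearly exact.  The other examples show the label/distance-map machinery
(`01`), the SEG metric's half-overlap rule (`03`) and the fractured
lattice generator (`04`).

## No-code workflow

The same pipeline is available as a project-folder CLI:

```bash
bbseg create myproj          # folder layout + editable params.txt
# drop images into myproj/train_images, masks into myproj/train_masks
bbseg train myproj
bbseg predict myproj         # writes <name>_seg.tif + region CSVs
bbseg eval myproj --truth test_masks
bbseg fixtures demo --preset disks   # a ready-to-train synthetic project
```

Masks are integer label maps (one positive ID per region, 0 background;
a plain binary mask is fine when no regions touch).  Optional binary
area-of-interest masks exclude pixels from training and scoring.

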