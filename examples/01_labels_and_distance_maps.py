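"""From a labeled mask to the two per-pixel training targets.

Builds a tiny scene of touching disks, then derives what the network is
trained to reproduce for every pixel: the binary inside/outside class and
the capped distance to the nearest region edge.  The distance valley
along the contact between two touching disks is what later lets the
watershed split them.
"""

import numpy as np

from bbseg import SceneSpec, binarize_labels, edge_distance, make_disks

scene = SceneSpec(height=96, width=96, n_particles=8, radius_range=(9, 12))
image, labels = make_disks(scene, np.random.default_rng(0))

inside = binarize_labels(labels)
dmap = edge_distance(labels, d_max=10)

print(f"scene: {labels.shape[0]}x{labels.shape[1]} px, "
      f"{len(np.unique(labels)) - 1} regions")
print(f"inside pixels: {inside.sum()} ({100 * inside.mean():.1f}% of the image)")
print(f"distance map range: {dmap.min():.1f}..{dmap.max():.1f} px "
      f"(capped at 10)")
plateau = (dmap == 10).sum()
print(f"pixels at the cap (deep interiors): {plateau}")

# contacts show up as low distance on both sides of the touching line
from scipy import ndimage

contacts = 0
for k in np.unique(labels):
    if k == 0:
        continue
    ring = ndimage.binary_dilation(labels == k) & (labels > 0) & (labels != k)
    if ring.any():
        contacts += 1
        assert dmap[ring].max() <= np.sqrt(2)
print(f"regions touching another region: {contacts} "
      "(distance <= sqrt(2) px along every contact)")
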