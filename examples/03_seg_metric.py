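"""The SEG score on hand-drawn toy segmentations.

Each true region is matched to the predicted region of largest overlap
and scored by their Jaccard index (intersection over union); a true
region whose best match covers less than half of it scores 0.  SEG is
the mean over true regions.
"""

import numpy as np

from bbseg import seg_score

truth = np.zeros((8, 12), np.int32)
truth[2:6, 1:5] = 1   # a 4x4 square
truth[2:6, 7:11] = 2  # another

# prediction: first square matched exactly, second covered only 7/16
pred = np.zeros_like(truth)
pred[2:6, 1:5] = 5
pred[2:6, 7:11] = 9
pred[2:5, 7:10] = 0

res = seg_score(truth, pred)
print(res.rows[["true_id", "pred_id", "area", "intersection", "jaccard", "score"]])
print(f"SEG = {res.seg:.3f}")
print("region 2 overlaps 7/16 < 1/2 of its area, so it scores 0 even though")
print("its Jaccard index would be", round(res.rows.loc[1, 'jaccard'], 3))
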