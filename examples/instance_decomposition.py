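"""Split touching tumors into instances with marker-controlled watershed.

Two radius-10 discs whose centers are 16 px apart form one connected
"tumor" region with a neck. The instance stage computes the Euclidean
distance transform, extracts h-maxima markers, floods the negated
distance map, and undoes shallow splits by the saddle-depth rule --
without moving a single semantic pixel.
"""

import numpy as np

from mammoseg import dice, panoptic_decompose

r = np.arange(48)[:, None]
c = np.arange(64)[None, :]
dumbbell = (
    (np.hypot(r - 24, c - 24) <= 10) | (np.hypot(r - 24, c - 40) <= 10)
).astype(np.uint8)

pm = panoptic_decompose(dumbbell, tau=0)
union = (pm.instance_ids > 0).astype(np.uint8)

print(f"instances found          : {pm.n_instances}")
print(f"instance areas           : {[p['area'] for p in pm.provenance]}")
print(f"Dice(mask, instance union): {dice(dumbbell, union):.4f}")

# Exactly 2 instances of near-equal area, and Dice exactly 1.0: the
# decomposition assigns every tumor pixel to an instance and nothing more.
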