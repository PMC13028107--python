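"""Run the full hybrid pipeline on one synthetic mammogram phantom.

Builds a 256x256 phantom (breast silhouette, smooth multiplicative bias,
two bright tumors with soft rims, noise), runs normalization -> breast
ROI -> MICO bias correction -> multiphase level-set global segmentation
-> LAC/LIF localized refinement -> panoptic instance decomposition, and
scores every stage against the exact ground truth.
"""

import mammoseg as ms

spec = ms.PhantomSpec(seed=0, n_tumors=2)
image, semantic, instances, true_bias = ms.generate_phantom(spec)

result = ms.run_pipeline(image, ms.fast_config())

print(f"global-stage mask  Dice = {ms.dice(semantic, result.S_g):.4f}")
print(f"refined mask       Dice = {ms.dice(semantic, result.S_r):.4f}")
sq, rq, pq = ms.panoptic_quality(result.panoptic.instance_ids, instances)
print(f"instances found    = {result.panoptic.n_instances} (truth {instances.max()})")
print(f"panoptic quality   SQ = {sq:.4f}  RQ = {rq:.4f}  PQ = {pq:.4f}")
print(f"stage seconds      = { {k: round(v, 2) for k, v in result.timings.items()} }")

# The refined Dice should sit near 0.98: boundary-level agreement with the
# soft-edged truth. RQ = 1 means every true tumor was found exactly once;
# SQ is the mean per-tumor overlap of the matched instances.
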