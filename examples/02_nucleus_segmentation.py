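"""Segment the nucleus of a single white blood cell and score it.

Runs the complete nucleus pipeline (histogram -> extrema -> branch rule
-> binarize -> clean up) on a synthetic cell with known ground truth and
prints the threshold audit plus Jaccard/Dice agreement.
"""

from lminseg import FixtureSpec, generate_cell_image, segment_nucleus
from lminseg.imgio import trilevel_to_binary
from lminseg.metrics import evaluate_masks

spec = FixtureSpec(random_seed=42, nucleus_lobes=3)
gray, truth, _ = generate_cell_image(spec)

mask, est = segment_nucleus(gray)
scores = evaluate_masks(mask, trilevel_to_binary(truth))

print(f"threshold eps_t = {est.epsilon_t:.4f} via branch {est.branch!r}")
print(f"nucleus area    = {int(mask.sum())} px (truth {int((truth == 255).sum())} px)")
print(f"Jaccard         = {scores.ji:.4f}")
print(f"Dice            = {scores.dsc:.4f}")
print()
print("Dice near 1 means the estimated threshold recovered the multi-lobed")
print("nucleus almost pixel-perfectly from intensity alone.")
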