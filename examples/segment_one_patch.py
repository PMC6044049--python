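"""Walk through the cleft-segmentation stages on a single detection patch.

Crops one planted synapse from a synthetic section and shows each stage:
adaptive binarization, morphological cleanup, the quadratic curve fit, the
intensity-weighted shortest path, and the seeded GrabCut result.
"""
import numpy as np

from synrec import (SynthConfig, binarize_adaptive, curve_endpoints,
                    fit_quadratic, generate_volume, grabcut, init_trimap,
                    jaccard, morph_clean, shortest_cleft_path)

stack, truth = generate_volume(SynthConfig(seed=0))
box = truth.boxes[0]
pad = 10
y1, x1 = max(0, box.y1 - pad), max(0, box.x1 - pad)
patch = stack[box.section][y1:box.y2 + pad, x1:box.x2 + pad]
gt = truth.masks[box.section][y1:box.y2 + pad, x1:box.x2 + pad]

mask = morph_clean(binarize_adaptive(patch))
print(f"patch {patch.shape}, morphological foreground: {int(mask.sum())} px")

curve = fit_quadratic(mask, rng_seed=0)
print(f"fitted cleft curve y = {curve.a:.4f} x^2 + {curve.b:.2f} x + {curve.c:.1f} "
      f"({curve.m} sampled points)")

p1, pn = curve_endpoints(curve, mask)
path = shortest_cleft_path(patch, p1, pn)
print(f"shortest path {p1} -> {pn}: {len(path)} pixels, "
      f"mean intensity {np.mean([patch[r, c] for r, c in path]):.1f} "
      f"(dark = the path follows the cleft)")

inner = (box.x1 - x1, box.y1 - y1, box.x2 - x1, box.y2 - y1)
trimap = init_trimap(patch.shape, inner, path, rng_seed=0)
result, energy = grabcut(patch, trimap)
print(f"GrabCut energy per iteration: {[round(e) for e in energy]}")
print(f"Jaccard vs planted cleft: {jaccard(result, gt):.3f}")
# The energy sequence is non-increasing (each iteration refits the GMMs and
# re-solves the min-cut exactly); the final mask should overlap the planted
# ribbon almost perfectly in this high-contrast regime.
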