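"""Generate a synthetic EM-like volume and reconstruct its synapses.

Builds a 768x768x12 volume containing 4 dark, curved, multi-section clefts
plus 4 single-section distractors, runs the full pipeline (tiled baseline
detection -> duplicate fusion -> z-continuity screening -> GrabCut
segmentation), and scores the result against the planted truth.
"""
import numpy as np

from synrec import (SynthConfig, generate_volume, jaccard_k, match_detections,
                    run_pipeline)
from synrec.config import preset

stack, truth = generate_volume(SynthConfig(seed=0))
result = run_pipeline(stack, preset("synthetic"), seed=0)

print(f"raw detections:     {len(result.raw_boxes)}")
print(f"after fusion:       {len(result.fused_boxes)}")
print(f"after screening:    {len(result.kept_boxes)} in {len(result.tracks)} tracks")
print(f"planted truth:      {len(truth.boxes)} boxes in {len(truth.tracks)} tracks")

match = match_detections(result.kept_boxes, truth.boxes, overlap_min=0.5)
j3 = np.mean([
    jaccard_k(result.labels[i], truth.masks[i], 3)
    for i in range(stack.n_sections) if truth.masks[i].any()
])
print(f"detection precision {match.precision:.3f}, recall {match.recall:.3f}")
print(f"segmentation Jaccard (3-px tolerance): {j3:.3f}")
# Precision/recall near 1 mean fusion collapsed tile duplicates and the
# z-continuity screen removed the single-section distractors; the Jaccard
# value measures pixel agreement of the GrabCut masks with the planted
# clefts, tolerating 3 px of boundary error.
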