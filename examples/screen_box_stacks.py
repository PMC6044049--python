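"""Fusion and z-continuity screening on box stacks, without any images.

Plants true multi-section tracks, duplicate boxes, and single-section
spurious boxes, then shows fusion collapsing the duplicates and the
z-continuity rule removing the spurious boxes.
"""
from synrec import (ContinuityParams, FusionParams, SynthConfig, fuse_all,
                    generate_detection_stack, screen_boxes)

cfg = SynthConfig(seed=2)
boxes, labels = generate_detection_stack(cfg, fp_rate=0.5, dup_rate=0.5)
n_true = labels.count("true")
print(f"emitted {len(boxes)} boxes: {n_true} true, "
      f"{labels.count('duplicate')} duplicates, {labels.count('false')} spurious")

fused = fuse_all(boxes, FusionParams(distance_threshold=100))
print(f"after fusion: {len(fused)} boxes (duplicates merged into envelopes)")

kept, tracks = screen_boxes(fused, ContinuityParams(layers=3, distance_threshold=80))
print(f"after screening (L=3): {len(kept)} boxes in {len(tracks)} tracks")
for t in tracks:
    z0, z1 = t.z_extent
    print(f"  track {t.id}: sections {z0}..{z1} ({len(t.members)} boxes)")
# Every surviving box appears in >= 3 of the 5 sections centered on it;
# the spurious single-section boxes cannot meet that and are dropped, so
# the track count equals the number of planted synapses.
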