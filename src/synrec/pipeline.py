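"""End-to-end composition: detect -> fuse -> screen -> segment."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cleft import segment_cleft
from .config import PipelineConfig
from .continuity import screen_boxes
from .fusion import fuse_all
from .stack_io import DetectionBox, ImageStack, LabelStack, SynapseTrack
from .tiling import Detector, baseline_detect, detect_tiles, make_tile_grid

logger = logging.getLogger("synrec")


@dataclass
class PipelineResult:
    """Intermediate and final products of one pipeline run."""

    raw_boxes: list[DetectionBox]
    fused_boxes: list[DetectionBox]
    kept_boxes: list[DetectionBox]
    tracks: list[SynapseTrack]
    labels: LabelStack | None = None


def _patch_seed(global_seed: int, section: int, index: int) -> int:
    """Derive a per-patch seed; bitwise reproducibility of the stochastic
    stages flows from (global_seed, section, box index)."""
    ss = np.random.SeedSequence([int(global_seed), int(section), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def detect_stack(
    stack: ImageStack,
    config: PipelineConfig,
    detector: Detector | None = None,
) -> list[DetectionBox]:
    """Tile every section and run the detector (baseline by default)."""
    h, w = stack.section_shape
    grid = make_tile_grid((w, h), config.tile_size, config.tile_overlap)
    if detector is None:
        params = config.detector
        detector = lambda tile: baseline_detect(tile, params)  # noqa: E731
    return detect_tiles(stack, grid, detector)


def segment_boxes(
    stack: ImageStack,
    boxes: Sequence[DetectionBox],
    config: PipelineConfig,
    seed: int = 0,
) -> LabelStack:
    """Segment the cleft inside every kept box and assemble a label stack.

    Each box is cropped with ``config.segmentation.pad`` pixels of context;
    the segmentation runs in the crop and only the part inside the box is
    pasted into the per-section mask.
    """
    z = stack.n_sections
    h, w = stack.section_shape
    masks = np.zeros((z, h, w), dtype=np.uint8)
    pad = config.segmentation.pad
    for b in boxes:
        x1 = max(0, b.x1 - pad)
        y1 = max(0, b.y1 - pad)
        x2 = min(w, b.x2 + pad)
        y2 = min(h, b.y2 + pad)
        patch = stack[b.section][y1:y2, x1:x2]
        inner_box = (b.x1 - x1, b.y1 - y1, b.x2 - x1, b.y2 - y1)
        mask = segment_cleft(
            patch,
            rng_seed=_patch_seed(seed, b.section, b.index),
            config=config.segmentation,
            box=inner_box,
        )
        sub = masks[b.section, y1:y2, x1:x2]
        np.logical_or(sub, mask, out=sub.view(bool))
    logger.info("segment: %d boxes -> %d foreground px", len(boxes),
                int(masks.sum()))
    return LabelStack(data=masks, voxel_size=stack.voxel_size)


def run_pipeline(
    stack: ImageStack,
    config: PipelineConfig,
    seed: int = 0,
    detector: Detector | None = None,
    boxes: Sequence[DetectionBox] | None = None,
    segment: bool = True,
) -> PipelineResult:
    """Run detection (or take external boxes), fusion, screening and
    segmentation on a stack."""
    raw = list(boxes) if boxes is not None else detect_stack(stack, config, detector)
    fused = fuse_all(raw, config.fusion_params)
    kept, tracks = screen_boxes(fused, config.continuity_params)
    logger.info("pipeline: %d raw -> %d fused -> %d kept in %d tracks",
                len(raw), len(fused), len(kept), len(tracks))
    labels = segment_boxes(stack, kept, config, seed) if segment else None
    return PipelineResult(raw_boxes=raw, fused_boxes=fused, kept_boxes=kept,
                          tracks=tracks, labels=labels)
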