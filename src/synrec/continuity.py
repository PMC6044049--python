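"""False-positive screening by z-continuity, and 3-D track linking.

A synapse is a flat 3-D structure roughly 400 nm along its long axis, so in
a serial-section stack a real synapse appears in several consecutive
sections at nearly the same (x, y) location, while detector false positives
appear in only one or two.  A detection in section ``i`` is kept iff boxes
appear in the same area (center distance <= ``distance_threshold``) in at
least ``L`` of the ``2L - 1`` sections centered on ``i``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .stack_io import DetectionBox, SynapseTrack, group_by_section

logger = logging.getLogger("synrec")


@dataclass
class ContinuityParams:
    """z-continuity screening parameters.

    ``layers`` (L) is the minimum number of supporting sections within the
    window of ``2L - 1`` consecutive sections; ``distance_threshold``
    (pixels) defines "the same area" as a center distance bound.  Typical
    values: L=3, 200 px for 50 nm-thick anisotropic sections; L=20, 100 px
    for 5 nm isotropic ones.
    """

    layers: int = 3
    distance_threshold: float = 200.0

    def __post_init__(self) -> None:
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if not self.distance_threshold > 0:
            raise ValueError("distance_threshold must be > 0")


def _center_dist(a: DetectionBox, b: DetectionBox) -> float:
    (ax, ay), (bx, by) = a.center, b.center
    return math.hypot(ax - bx, ay - by)


def support_count(
    box: DetectionBox,
    volume: Mapping[int, Sequence[DetectionBox]],
    params: ContinuityParams,
) -> int:
    """Number of window sections supporting ``box``.

    Counts sections ``w`` in ``[i - (L-1), i + (L-1)]`` (clipped to the
    stack) that contain at least one box whose center lies within the
    distance threshold of ``box``'s center.  A section with several nearby
    boxes still contributes one — support counts layers, not boxes.  The
    box's own section always qualifies, so the result is >= 1.
    """
    L = params.layers
    count = 0
    for w in range(box.section - (L - 1), box.section + L):
        near = any(
            _center_dist(box, other) <= params.distance_threshold
            for other in volume.get(w, ())
        )
        if near:
            count += 1
    return count


def screen_volume(
    volume: Mapping[int, Sequence[DetectionBox]],
    params: ContinuityParams,
) -> tuple[dict[int, list[DetectionBox]], list[SynapseTrack]]:
    """Screen a fused detection volume and link survivors into 3-D tracks.

    A box is kept iff its :func:`support_count` reaches ``layers``.  Kept
    boxes are then chained across nearby sections (z gap of at most one
    missing section) by greedy nearest-center matching within the distance
    threshold; ties break toward smaller x then y.  Tracks are numbered
    1, 2, ... ordered by (first section, x, y) of their first box.

    Windows are clipped at the stack boundary, so detections in the first or
    last ``L - 1`` sections can still be kept when supported from one side.
    """
    kept: dict[int, list[DetectionBox]] = {}
    n_in = n_out = 0
    for sec in sorted(volume):
        survivors = [
            b for b in volume[sec] if support_count(b, volume, params) >= params.layers
        ]
        n_in += len(volume[sec])
        n_out += len(survivors)
        if survivors:
            kept[sec] = survivors
    logger.info("screen: %d boxes in -> %d kept (L=%d, dist<=%g)",
                n_in, n_out, params.layers, params.distance_threshold)

    tracks = _link_tracks(kept, params)
    return kept, tracks


def _link_tracks(
    kept: Mapping[int, Sequence[DetectionBox]], params: ContinuityParams
) -> list[SynapseTrack]:
    # active track tails: list of (track member list, last box)
    open_tracks: list[list[DetectionBox]] = []
    for sec in sorted(kept):
        boxes = list(kept[sec])
        # candidate (distance, tiebreak, track_idx, box_idx) pairs against
        # tracks whose tail is 1 or 2 sections behind (one-section gaps heal)
        cands = []
        for ti, members in enumerate(open_tracks):
            tail = members[-1]
            if not (1 <= sec - tail.section <= 2):
                continue
            for bi, b in enumerate(boxes):
                d = _center_dist(tail, b)
                if d <= params.distance_threshold:
                    cands.append((d, b.center[0], b.center[1], ti, bi))
        cands.sort()
        used_tracks: set[int] = set()
        used_boxes: set[int] = set()
        for d, _, _, ti, bi in cands:
            if ti in used_tracks or bi in used_boxes:
                continue
            open_tracks[ti].append(boxes[bi])
            used_tracks.add(ti)
            used_boxes.add(bi)
        for bi, b in enumerate(boxes):
            if bi not in used_boxes:
                open_tracks.append([b])

    open_tracks.sort(
        key=lambda ms: (ms[0].section, ms[0].center[0], ms[0].center[1])
    )
    return [SynapseTrack(id=n + 1, members=ms) for n, ms in enumerate(open_tracks)]


def screen_boxes(
    boxes: Sequence[DetectionBox], params: ContinuityParams
) -> tuple[list[DetectionBox], list[SynapseTrack]]:
    """Flat-list convenience wrapper around :func:`screen_volume`."""
    kept, tracks = screen_volume(group_by_section(boxes), params)
    flat = [b for sec in sorted(kept) for b in kept[sec]]
    return flat, tracks
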