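"""Within-section fusion of duplicate detection boxes.

Overlap tiling makes one synapse near a tile border appear in two or more
tiles, so the same object yields several nearby boxes in one section.
Because synapses are sparsely distributed, nearby boxes can be assumed to
be duplicates: boxes whose centers lie within a distance threshold are
grouped (transitively) and each group is replaced by its coordinate
envelope.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .stack_io import DetectionBox

logger = logging.getLogger("synrec")


@dataclass
class FusionParams:
    """Fusion distance threshold in pixels.

    Typical values: 100 px for 2 nm/px anisotropic data, 50 px for 5 nm/px
    isotropic data (~200-250 nm, the scale of one synapse).
    """

    distance_threshold: float = 100.0

    def __post_init__(self) -> None:
        if not self.distance_threshold > 0:
            raise ValueError("distance_threshold must be > 0")


def box_distance(a: DetectionBox, b: DetectionBox) -> float:
    """Euclidean distance between box centers; requires one shared section."""
    if a.section != b.section:
        raise ValueError(
            f"box_distance compares boxes of one section, got {a.section} and {b.section}"
        )
    (ax, ay), (bx, by) = a.center, b.center
    return math.hypot(ax - bx, ay - by)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def fuse_section(
    boxes: Sequence[DetectionBox], params: FusionParams
) -> list[DetectionBox]:
    """Merge duplicate boxes of one section.

    The relation ``box_distance <= threshold`` is closed transitively
    (single-link grouping); each group is replaced by one box spanning the
    group envelope (min x1, min y1, max x2, max y2) with the group-maximum
    score.  The result is independent of input order and re-indexed
    ``0..N'-1`` sorted by (x1, y1).

    Note a fused envelope's center can move, so a second pass may merge
    further if envelopes of distinct groups end up within the threshold;
    fusion is applied as a single pass.
    """
    boxes = list(boxes)
    if not boxes:
        return []
    sections = {b.section for b in boxes}
    if len(sections) != 1:
        raise ValueError(f"fuse_section expects one section, got {sorted(sections)}")
    section = sections.pop()

    uf = _UnionFind(len(boxes))
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if box_distance(boxes[i], boxes[j]) <= params.distance_threshold:
                uf.union(i, j)

    groups: dict[int, list[DetectionBox]] = {}
    for i, b in enumerate(boxes):
        groups.setdefault(uf.find(i), []).append(b)

    fused = [
        DetectionBox(
            section=section,
            index=0,
            x1=min(b.x1 for b in grp),
            y1=min(b.y1 for b in grp),
            x2=max(b.x2 for b in grp),
            y2=max(b.y2 for b in grp),
            score=max(b.score for b in grp),
        )
        for grp in groups.values()
    ]
    fused.sort(key=lambda b: (b.x1, b.y1, b.x2, b.y2))
    fused = [
        DetectionBox(section=section, index=j, x1=b.x1, y1=b.y1, x2=b.x2, y2=b.y2,
                     score=b.score)
        for j, b in enumerate(fused)
    ]
    logger.info("fuse: section %d, %d boxes -> %d", section, len(boxes), len(fused))
    return fused


def fuse_all(
    boxes: Sequence[DetectionBox], params: FusionParams
) -> list[DetectionBox]:
    """Apply :func:`fuse_section` to every section of a flat box list."""
    from .stack_io import group_by_section

    per_section = group_by_section(boxes)
    out: list[DetectionBox] = []
    for sec in sorted(per_section):
        out.extend(fuse_section(per_section[sec], params))
    return out
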