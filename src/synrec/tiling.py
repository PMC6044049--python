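"""Overlap tiling of large sections and per-tile detection.

EM sections can be far larger (8000+ px) than what an object detector
accepts, so each section is split into overlapping tiles, the detector runs
per tile, and tile-local boxes are mapped back to global section
coordinates.  Duplicates created by the overlap are resolved later by
:mod:`synrec.fusion`.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import label as cc_label, regionprops

from .stack_io import DetectionBox, ImageStack

logger = logging.getLogger("synrec")

#: a detector maps a 2-D grayscale tile to ``[((x1, y1, x2, y2), score), ...]``
#: in tile-local coordinates with scores in [0, 1]
Detector = Callable[[np.ndarray], list[tuple[tuple[int, int, int, int], float]]]


class TileParameterError(ValueError):
    """Invalid tiling parameters (tile_size <= overlap)."""


class DetectorError(RuntimeError):
    """A plugged-in detector raised; the tile id is carried in the message."""


@dataclass
class TileGrid:
    """A minimal covering grid of equally sized, overlapping tiles.

    Per axis of length ``D`` the tile count is
    ``max(1, ceil((D - overlap) / (tile_size - overlap)))``; anchors sit at
    multiples of the stride ``tile_size - overlap`` with the final anchor
    clamped to ``D - tile_size`` (0 when the image is no larger than one
    tile).  Every pixel is covered by at least one tile and every tile lies
    fully inside the image.
    """

    tile_size: int
    overlap: int
    image_size: tuple[int, int]  # (W, H)
    origins: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_tiles(self) -> int:
        return len(self.origins)

    def tile_bounds(self, origin: tuple[int, int]) -> tuple[int, int, int, int]:
        """Half-open pixel bounds (x0, y0, x1, y1) of the tile at ``origin``,
        clipped to the image for images smaller than one tile."""
        w, h = self.image_size
        x0, y0 = origin
        return x0, y0, min(x0 + self.tile_size, w), min(y0 + self.tile_size, h)


def _axis_anchors(extent: int, tile: int, overlap: int) -> list[int]:
    if extent <= tile:
        return [0]
    stride = tile - overlap
    count = max(1, math.ceil((extent - overlap) / stride))
    anchors = [min(k * stride, extent - tile) for k in range(count)]
    return anchors


def make_tile_grid(
    image_size: tuple[int, int], tile_size: int, overlap: int
) -> TileGrid:
    """Build the minimal covering tile grid for an image.

    Parameters
    ----------
    image_size
        ``(W, H)`` in pixels.
    tile_size
        Side length of the square tiles.
    overlap
        Minimum overlap, in pixels, between adjacent tiles (~50 px avoids
        false negatives for objects straddling a tile border).
    """
    if not tile_size > overlap >= 0:
        raise TileParameterError(
            f"need tile_size > overlap >= 0, got tile_size={tile_size}, overlap={overlap}"
        )
    w, h = image_size
    xs = _axis_anchors(w, tile_size, overlap)
    ys = _axis_anchors(h, tile_size, overlap)
    origins = [(x, y) for y in ys for x in xs]
    return TileGrid(tile_size=tile_size, overlap=overlap, image_size=(w, h), origins=origins)


def detect_tiles(
    stack: ImageStack, grid: TileGrid, detector: Detector
) -> list[DetectionBox]:
    """Run ``detector`` on every tile of every section.

    Tile-local boxes are translated by their tile origin into global section
    coordinates.  No deduplication happens here — overlapping tiles will
    produce duplicate boxes for straddling synapses, which
    :func:`synrec.fusion.fuse_section` merges.
    """
    out: list[DetectionBox] = []
    for i in range(stack.n_sections):
        section = stack[i]
        j = 0
        for origin in grid.origins:
            x0, y0, x1, y1 = grid.tile_bounds(origin)
            tile = section[y0:y1, x0:x1]
            try:
                results = detector(tile)
            except Exception as exc:  # re-raise with tile context
                raise DetectorError(
                    f"detector failed on section {i}, tile origin ({x0},{y0}): {exc}"
                ) from exc
            for (bx1, by1, bx2, by2), score in results:
                out.append(
                    DetectionBox(
                        section=i,
                        index=j,
                        x1=int(bx1) + x0,
                        y1=int(by1) + y0,
                        x2=int(bx2) + x0,
                        y2=int(by2) + y0,
                        score=float(score),
                    )
                )
                j += 1
        logger.info("detect: section %d -> %d raw boxes", i, j)
    return out


@dataclass
class BaselineParams:
    """Knobs of the classical dark-ridge baseline detector.

    The defaults are tuned against the synthetic generator only; the
    detector exists so the pipeline runs end-to-end without any trained
    CNN weights — real deployments plug in an external detector via the
    :data:`Detector` contract or a detection file.
    """

    block_size: int = 51          # adaptive-threshold neighbourhood (odd)
    offset: float = 10.0          # intensity units below the local mean
    min_area: int = 60            # px, reject speckle
    max_area: int = 5000          # px, reject huge dark patches
    min_elongation: float = 2.0   # major/minor axis ratio of a ridge
    pad: int = 5                  # px added around the component bbox


def baseline_detect(
    image: np.ndarray, params: BaselineParams | None = None
) -> list[tuple[tuple[int, int, int, int], float]]:
    """Classical dark-ridge candidate detector.

    Adaptive binarization of dark pixels, a morphological opening, then
    connected components filtered by area and elongation.  The box is the
    component bounding box padded by ``params.pad`` (clipped to the image);
    the score is the component's normalized mean darkness.
    """
    if params is None:
        params = BaselineParams()
    img = np.asarray(image)
    if img.size == 0 or img.max() == img.min():
        return []
    imax = float(np.iinfo(img.dtype).max) if img.dtype.kind in "ui" else float(img.max())
    loc = threshold_local(img.astype(float), params.block_size, method="mean",
                          offset=params.offset)
    mask = img.astype(float) < loc
    mask = ndimage.binary_opening(mask, structure=ndimage.generate_binary_structure(2, 1))
    h, w = img.shape
    out = []
    for prop in regionprops(cc_label(mask, connectivity=2)):
        if not (params.min_area <= prop.area <= params.max_area):
            continue
        minor = prop.axis_minor_length
        elong = np.inf if minor == 0 else prop.axis_major_length / minor
        if elong < params.min_elongation:
            continue
        r0, c0, r1, c1 = prop.bbox
        x1 = max(0, c0 - params.pad)
        y1 = max(0, r0 - params.pad)
        x2 = min(w, c1 + params.pad)
        y2 = min(h, r1 + params.pad)
        comp = img[prop.slice][prop.image]
        score = float(np.clip(1.0 - comp.mean() / imax, 0.0, 1.0))
        out.append(((x1, y1, x2, y2), score))
    return out
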