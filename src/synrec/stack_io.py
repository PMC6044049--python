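"""Image-stack, detection-box and label-stack I/O.

Conventions used throughout the package:

* Pixel coordinates are 0-based with ``x`` = column and ``y`` = row.
* Detection boxes are half-open rectangles ``[x1, x2) x [y1, y2)`` so that
  box area is simply ``(x2 - x1) * (y2 - y1)`` and overlap arithmetic is
  unambiguous.
* Stacks are ordered by z: section index equals z order equals TIFF page
  order (or lexicographic filename order for a directory of sections).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("synrec")

DETECTION_COLUMNS = ["section", "index", "x1", "y1", "x2", "y2", "score"]

#: declared in file headers so external detectors know what they are writing
COORDINATE_CONVENTION = "0-based, x=column, y=row, half-open [x1,x2)x[y1,y2)"


class StackShapeError(ValueError):
    """Sections of a stack do not share a single width/height."""


class DetectionValidationError(ValueError):
    """A detection record violates the box invariants (e.g. x1 >= x2)."""


@dataclass
class ImageStack:
    """A z-ordered stack of equally sized 2-D grayscale sections.

    Parameters
    ----------
    data
        Array of shape ``(n_sections, height, width)``; 8- or 16-bit
        intensities are preserved bit-exactly through I/O.
    voxel_size
        Physical voxel size ``(x, y, z)`` in nanometres.  Anisotropic
        serial-section data is typically ``(2, 2, 50)``; isotropic FIB
        milling yields ``(5, 5, 5)``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 50.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise StackShapeError(
                f"stack data must be (n_sections, H, W), got shape {self.data.shape}"
            )
        if self.n_sections < 1:
            raise StackShapeError("a stack needs at least one section")

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def section_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]


@dataclass
class LabelStack:
    """Per-section binary cleft masks aligned with an :class:`ImageStack`."""

    data: np.ndarray  # (n_sections, H, W), values in {0, 1}
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 50.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise StackShapeError("label stack must be (n_sections, H, W)")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label stack values must be 0/1, got {vals[:10]}")

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]


@dataclass(frozen=True)
class DetectionBox:
    """One 2-D synapse detection, localized to a section.

    ``(x1, y1)`` is the upper-left corner and ``(x2, y2)`` the lower-right
    corner of the half-open box; ``score`` is the detector confidence in
    ``[0, 1]``.
    """

    section: int
    index: int
    x1: int
    y1: int
    x2: int
    y2: int
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise DetectionValidationError(
                f"degenerate box (section={self.section}, index={self.index}): "
                f"need x1 < x2 and y1 < y2, got "
                f"({self.x1},{self.y1},{self.x2},{self.y2})"
            )

    @property
    def center(self) -> tuple[float, float]:
        """Box center ``(x, y)`` in pixels."""
        return ((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)

    @property
    def width(self) -> int:
        return self.x2 - self.x1

    @property
    def height(self) -> int:
        return self.y2 - self.y1

    @property
    def area(self) -> int:
        return self.width * self.height

    def translated(self, dx: int, dy: int) -> "DetectionBox":
        return replace(
            self, x1=self.x1 + dx, y1=self.y1 + dy, x2=self.x2 + dx, y2=self.y2 + dy
        )


@dataclass
class SynapseTrack:
    """A linked 3-D synapse: the boxes of one synapse across sections."""

    id: int
    members: list[DetectionBox] = field(default_factory=list)

    @property
    def z_extent(self) -> tuple[int, int]:
        secs = [b.section for b in self.members]
        return min(secs), max(secs)

    @property
    def n_sections(self) -> int:
        return len({b.section for b in self.members})


# ---------------------------------------------------------------------------
# image stacks


def read_stack(
    path: str | Path, voxel_size: tuple[float, float, float] = (2.0, 2.0, 50.0)
) -> ImageStack:
    """Read a multi-page TIFF or a directory of single-page sections.

    Directory entries are ordered lexicographically by filename; all
    sections must share one width/height.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise FileNotFoundError(f"no section images in {path}")
        sections = [iio.imread(f) for f in files]
        shapes = {s.shape for s in sections}
        if len(shapes) != 1:
            raise StackShapeError(f"mixed section shapes in {path}: {sorted(shapes)}")
        data = np.stack(sections)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    return ImageStack(data=data, voxel_size=voxel_size)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF, one page per section."""
    tifffile.imwrite(Path(path), stack.data, photometric="minisblack")


# ---------------------------------------------------------------------------
# detection files


def _records_to_boxes(df: pd.DataFrame) -> list[DetectionBox]:
    # positional iteration: "index" clashes with namedtuple attributes
    boxes = []
    for sec, idx, x1, y1, x2, y2, score in df[DETECTION_COLUMNS].to_numpy():
        boxes.append(
            DetectionBox(
                section=int(sec),
                index=int(idx),
                x1=int(x1),
                y1=int(y1),
                x2=int(x2),
                y2=int(y2),
                score=float(score),
            )
        )
    return boxes


def read_detections(path: str | Path) -> list[DetectionBox]:
    """Read detection boxes from CSV (header ``section,index,x1,y1,x2,y2,score``)
    or the mirroring JSON format."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["boxes"], columns=DETECTION_COLUMNS)
    else:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        missing = set(DETECTION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"detection file {path} missing columns {sorted(missing)}")
        df = df[DETECTION_COLUMNS]
    if len(df) == 0:
        return []
    return _records_to_boxes(df)


def write_detections(boxes: Iterable[DetectionBox], path: str | Path) -> None:
    """Write detection boxes as CSV or JSON depending on the file suffix."""
    path = Path(path)
    rows = [
        [b.section, b.index, b.x1, b.y1, b.x2, b.y2, b.score] for b in boxes
    ]
    if path.suffix.lower() == ".json":
        payload = {
            "coordinate_convention": COORDINATE_CONVENTION,
            "boxes": [dict(zip(DETECTION_COLUMNS, r)) for r in rows],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
        with open(path, "w") as fh:
            fh.write(f"# coordinates: {COORDINATE_CONVENTION}\n")
            df.to_csv(fh, index=False, float_format="%.17g")


def group_by_section(boxes: Iterable[DetectionBox]) -> dict[int, list[DetectionBox]]:
    """Group a flat box list into the per-section lists used by screening."""
    out: dict[int, list[DetectionBox]] = {}
    for b in boxes:
        out.setdefault(b.section, []).append(b)
    return out


# ---------------------------------------------------------------------------
# label stacks


def export_label_stack(labels: LabelStack, path: str | Path) -> None:
    """Write masks as an ImageJ-importable 8-bit multi-page TIFF.

    Foreground pixels are written as 255, background as 0, one page per
    section in z order.
    """
    out = (labels.data.astype(np.uint8) * 255).astype(np.uint8)
    tifffile.imwrite(Path(path), out, photometric="minisblack")


def read_label_stack(
    path: str | Path, voxel_size: tuple[float, float, float] = (2.0, 2.0, 50.0)
) -> LabelStack:
    """Read back an exported label TIFF (any nonzero pixel is foreground)."""
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[None]
    return LabelStack(data=(data > 0).astype(np.uint8), voxel_size=voxel_size)


def tracks_to_json(tracks: Sequence[SynapseTrack], path: str | Path) -> None:
    """Dump linked tracks as ``{track id: [member boxes]}`` JSON."""
    payload = {
        str(t.id): [
            dict(zip(DETECTION_COLUMNS, [b.section, b.index, b.x1, b.y1, b.x2, b.y2, b.score]))
            for b in t.members
        ]
        for t in tracks
    }
    Path(path).write_text(json.dumps(payload, indent=1))
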