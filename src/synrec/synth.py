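"""Synthetic EM-like volumes and detection stacks with known ground truth.

Real serial-section EM shows synaptic clefts as dark, curved, ribbon-like
structures persisting across a handful of consecutive sections, embedded
in textured neuropil.  The generator emulates exactly those features —
quadratic ribbons of configurable length, thickness, curvature and z-span,
rendered dark on a noisy, low-frequency-textured background, plus
single-section dark distractors that mimic detector false positives — so
that every pipeline stage (detection, fusion, screening, segmentation,
evaluation) is testable without EM data or a trained network.

Two generators share one geometric plan: :func:`generate_volume` renders
images, :func:`generate_detection_stack` emits only boxes, so fusion and
screening unit tests run in milliseconds without rendering.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stack_io import DetectionBox, ImageStack

logger = logging.getLogger("synrec")


class PlacementError(RuntimeError):
    """Could not place all objects without violating the separation rule."""


@dataclass
class SynthConfig:
    """Study conditions for the synthetic volumes.

    The geometry follows anisotropic EM proportions: at ~2 nm/px a synapse
    is ~100-200 px along its long axis (~400 nm), a few px thick, and spans
    a few 50 nm sections.  ``min_separation`` keeps object centers at least
    twice the screening distance threshold apart so single-section
    distractors are unambiguous screening fodder.
    """

    width: int = 768
    height: int = 768
    n_sections: int = 12
    n_synapses: int = 4
    length_range: tuple[float, float] = (100.0, 200.0)
    thickness_range: tuple[int, int] = (4, 8)
    curvature_range: tuple[float, float] = (-0.004, 0.004)
    tilt_range: tuple[float, float] = (-0.2, 0.2)
    cubic_perturbation: float = 0.0   # optional cubic term testing model mismatch
    z_span_range: tuple[int, int] = (3, 6)
    jitter_px: int = 2                # per-section center wobble
    cleft_intensity: float = 60.0
    background_intensity: float = 160.0
    noise_sd: float = 10.0
    texture_amplitude: float = 8.0    # low-frequency background texture
    texture_sigma: float = 40.0
    n_distractors: int = 4
    distractor_length_range: tuple[float, float] = (60.0, 100.0)
    min_separation: float = 160.0     # 2 * screening distance threshold
    box_pad: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cleft_intensity < self.background_intensity:
            raise ValueError("clefts must be darker than background")
        if self.z_span_range[0] < 1:
            raise ValueError("z-span must be >= 1")
        for lo, hi in (self.length_range, self.thickness_range,
                       self.curvature_range, self.z_span_range):
            if lo > hi:
                raise ValueError("empty parameter range")


@dataclass
class _ObjectPlan:
    """Geometry of one ribbon: a synapse track or a 1-section distractor."""

    xc: float
    yc: float
    length: float
    thickness: int
    a: float               # quadratic coefficient (curvature)
    b: float               # linear coefficient (tilt)
    cubic: float
    z0: int
    span: int
    jitters: np.ndarray    # (span, 2) int offsets (dx, dy)
    is_distractor: bool

    def curve_y(self, xs: np.ndarray) -> np.ndarray:
        u = xs - self.xc
        return self.yc + self.a * u**2 + self.b * u + self.cubic * u**3

    def extent(self, pad: float) -> tuple[float, float]:
        """Conservative (x, y) half-extents of the rendered ribbon."""
        half = self.length / 2.0
        u = np.linspace(-half, half, 64)
        dy = np.abs(self.a * u**2 + self.b * u + self.cubic * u**3).max()
        r = self.thickness / 2.0 + self.jitters_abs() + pad
        return half + r, dy + r

    def jitters_abs(self) -> float:
        return float(np.abs(self.jitters).max()) if self.jitters.size else 0.0


@dataclass
class GroundTruth:
    """Planted truth of a synthetic volume.

    ``masks`` is the union of all synapse cleft masks per section; ``boxes``
    are the per-section true boxes (mask envelope plus pad); ``tracks`` maps
    each planted synapse id to its boxes across sections.  Distractor boxes
    are recorded separately and are *not* part of the truth.
    """

    masks: np.ndarray                              # (Z, H, W) uint8
    boxes: list[DetectionBox] = field(default_factory=list)
    tracks: dict[int, list[DetectionBox]] = field(default_factory=dict)
    distractor_boxes: list[DetectionBox] = field(default_factory=list)


def _plan_objects(config: SynthConfig, rng: np.random.Generator) -> list[_ObjectPlan]:
    plans: list[_ObjectPlan] = []
    specs = [(False, config.length_range, None) for _ in range(config.n_synapses)]
    specs += [(True, config.distractor_length_range, 1) for _ in range(config.n_distractors)]
    for is_distractor, length_range, forced_span in specs:
        for attempt in range(100):
            length = rng.uniform(*length_range)
            thickness = int(rng.integers(config.thickness_range[0],
                                         config.thickness_range[1] + 1))
            a = rng.uniform(*config.curvature_range)
            b = rng.uniform(*config.tilt_range)
            cubic = (rng.uniform(-1, 1) * config.cubic_perturbation)
            span = forced_span or int(rng.integers(config.z_span_range[0],
                                                   config.z_span_range[1] + 1))
            span = min(span, config.n_sections)
            z0 = int(rng.integers(0, config.n_sections - span + 1))
            jitters = rng.integers(-config.jitter_px, config.jitter_px + 1,
                                   size=(span, 2))
            plan = _ObjectPlan(xc=0.0, yc=0.0, length=length, thickness=thickness,
                               a=a, b=b, cubic=cubic, z0=z0, span=span,
                               jitters=jitters, is_distractor=is_distractor)
            ex, ey = plan.extent(config.box_pad + 2)
            if 2 * ex >= config.width or 2 * ey >= config.height:
                continue
            plan.xc = float(rng.uniform(ex, config.width - ex))
            plan.yc = float(rng.uniform(ey, config.height - ey))
            ok = all(
                math.hypot(plan.xc - p.xc, plan.yc - p.yc) >= config.min_separation
                for p in plans
            )
            if ok:
                plans.append(plan)
                break
        else:
            raise PlacementError(
                "could not place all objects after 100 attempts; "
                "reduce object count or min_separation"
            )
    return plans


def _render_ribbon(plan: _ObjectPlan, shape: tuple[int, int],
                   jitter: tuple[int, int]) -> np.ndarray:
    """Rasterize one ribbon (with one section's jitter) as a boolean mask."""
    h, w = shape
    half = plan.length / 2.0
    xs = np.arange(plan.xc - half, plan.xc + half, 0.25)
    ys = plan.curve_y(xs)
    cols = np.clip(np.round(xs + jitter[0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(ys + jitter[1]).astype(int), 0, h - 1)
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    radius = max(1, plan.thickness // 2)
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    selem = xx**2 + yy**2 <= radius**2
    return ndimage.binary_dilation(mask, structure=selem)


def _mask_box(mask: np.ndarray, section: int, index: int, pad: int,
              score: float = 1.0) -> DetectionBox:
    rows, cols = np.nonzero(mask)
    h, w = mask.shape
    return DetectionBox(
        section=section, index=index,
        x1=max(0, int(cols.min()) - pad), y1=max(0, int(rows.min()) - pad),
        x2=min(w, int(cols.max()) + 1 + pad), y2=min(h, int(rows.max()) + 1 + pad),
        score=score,
    )


def generate_volume(config: SynthConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic stack and its ground truth.

    Deterministic given ``config.seed``: the same configuration always
    yields a bit-identical stack.
    """
    rng = np.random.default_rng(config.seed)
    plans = _plan_objects(config, rng)
    shape = (config.height, config.width)
    z = config.n_sections

    stack = np.empty((z, *shape), dtype=np.uint8)
    gt_masks = np.zeros((z, *shape), dtype=np.uint8)
    truth = GroundTruth(masks=gt_masks)

    # low-frequency texture shared across sections, drifting slightly
    base_texture = ndimage.gaussian_filter(
        rng.standard_normal(shape), config.texture_sigma
    )
    tmax = np.abs(base_texture).max() or 1.0
    base_texture = base_texture / tmax * config.texture_amplitude

    per_section_masks: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(z)}
    for oid, plan in enumerate(plans):
        for s in range(plan.span):
            sec = plan.z0 + s
            m = _render_ribbon(plan, shape, tuple(plan.jitters[s]))
            per_section_masks[sec].append((oid, m))

    box_index: dict[int, int] = {i: 0 for i in range(z)}
    tid_of_oid: dict[int, int] = {}
    for oid, plan in enumerate(plans):
        if not plan.is_distractor:
            tid_of_oid[oid] = len(tid_of_oid) + 1
            truth.tracks[tid_of_oid[oid]] = []

    for sec in range(z):
        img = np.full(shape, config.background_intensity, dtype=float) + base_texture
        for oid, m in per_section_masks[sec]:
            img[m] = config.cleft_intensity
            box = _mask_box(m, sec, box_index[sec], config.box_pad)
            box_index[sec] += 1
            if plans[oid].is_distractor:
                truth.distractor_boxes.append(box)
            else:
                gt_masks[sec][m] = 1
                truth.boxes.append(box)
                truth.tracks[tid_of_oid[oid]].append(box)
        img += rng.normal(0.0, config.noise_sd, shape)
        stack[sec] = np.clip(img, 0, 255).astype(np.uint8)

    logger.info("simulate: %d synapses, %d distractors in %dx%dx%d volume",
                config.n_synapses, config.n_distractors,
                config.width, config.height, z)
    return ImageStack(data=stack, voxel_size=(2.0, 2.0, 50.0)), truth


def generate_detection_stack(
    config: SynthConfig,
    fp_rate: float = 0.0,
    dup_rate: float = 0.0,
    jitter_px: int = 2,
    dup_offset: float = 20.0,
) -> tuple[list[DetectionBox], list[str]]:
    """Emit synthetic detection boxes stressing fusion and screening.

    True boxes come from the planted geometry with centers jittered by at
    most ``jitter_px``; with probability ``dup_rate`` a true box is emitted
    a second time offset by at most ``dup_offset`` (fusion fodder); with
    probability ``fp_rate`` per section a spurious single-section box is
    planted at least ``config.min_separation`` from every track and every
    other spurious box (screening fodder).  Returns the boxes plus an
    aligned label list of ``"true" | "duplicate" | "false"``.
    """
    if not (0 <= fp_rate <= 1 and 0 <= dup_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    plans = _plan_objects(config, rng)
    synapse_plans = [p for p in plans if not p.is_distractor]
    # independent stream for the detection noise, so the geometry matches
    # generate_volume with the same config
    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9173]))

    def analytic_box(plan: _ObjectPlan, s: int, sec: int, index: int,
                     extra: tuple[float, float] = (0.0, 0.0)) -> DetectionBox:
        half = plan.length / 2.0
        xs = np.linspace(plan.xc - half, plan.xc + half, 64)
        ys = plan.curve_y(xs)
        dx = plan.jitters[s][0] + extra[0]
        dy = plan.jitters[s][1] + extra[1]
        r = plan.thickness / 2.0 + config.box_pad
        x1 = int(math.floor(xs.min() + dx - r))
        x2 = int(math.ceil(xs.max() + dx + r))
        y1 = int(math.floor(ys.min() + dy - r))
        y2 = int(math.ceil(ys.max() + dy + r))
        return DetectionBox(section=sec, index=index,
                            x1=max(0, x1), y1=max(0, y1),
                            x2=min(config.width, x2), y2=min(config.height, y2),
                            score=float(noise_rng.uniform(0.7, 1.0)))

    boxes: list[DetectionBox] = []
    labels: list[str] = []
    idx: dict[int, int] = {i: 0 for i in range(config.n_sections)}

    for plan in synapse_plans:
        for s in range(plan.span):
            sec = plan.z0 + s
            jx = float(noise_rng.uniform(-jitter_px, jitter_px))
            jy = float(noise_rng.uniform(-jitter_px, jitter_px))
            boxes.append(analytic_box(plan, s, sec, idx[sec], (jx, jy)))
            labels.append("true")
            idx[sec] += 1
            if noise_rng.uniform() < dup_rate:
                ang = noise_rng.uniform(0, 2 * math.pi)
                rad = noise_rng.uniform(0, dup_offset)
                boxes.append(analytic_box(plan, s, sec, idx[sec],
                                          (jx + rad * math.cos(ang),
                                           jy + rad * math.sin(ang))))
                labels.append("duplicate")
                idx[sec] += 1

    track_centers = [(p.xc, p.yc) for p in synapse_plans]
    fp_centers: list[tuple[float, float]] = []
    for sec in range(config.n_sections):
        if noise_rng.uniform() >= fp_rate:
            continue
        for _ in range(100):
            fx = float(noise_rng.uniform(60, config.width - 60))
            fy = float(noise_rng.uniform(60, config.height - 60))
            far = all(
                math.hypot(fx - cx, fy - cy) >= config.min_separation
                for cx, cy in track_centers + fp_centers
            )
            if far:
                half_w = float(noise_rng.uniform(30, 60))
                half_h = float(noise_rng.uniform(15, 30))
                boxes.append(DetectionBox(
                    section=sec, index=idx[sec],
                    x1=int(fx - half_w), y1=int(fy - half_h),
                    x2=int(fx + half_w), y2=int(fy + half_h),
                    score=float(noise_rng.uniform(0.5, 0.9)),
                ))
                labels.append("false")
                idx[sec] += 1
                fp_centers.append((fx, fy))
                break
    return boxes, labels
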