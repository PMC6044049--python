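"""Pipeline configuration with dataset presets.

Only three parameters normally change between acquisition modalities: the
fusion distance threshold, the z-continuity layer count L, and the
z-continuity distance threshold.  The GrabCut iteration budget (10) and
GMM component count (5) are modality-independent defaults.
"""
from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cleft import SegmentationConfig
from .continuity import ContinuityParams
from .fusion import FusionParams
from .tiling import BaselineParams


@dataclass
class PipelineConfig:
    """All tunables of the reconstruction pipeline.

    ``fusion_distance`` / ``z_layers`` / ``z_distance`` are the per-dataset
    knobs (pixels / sections / pixels); ``tile_size`` and ``tile_overlap``
    control section tiling for large images.
    """

    fusion_distance: float = 100.0
    z_layers: int = 3
    z_distance: float = 200.0
    grabcut_iters: int = 10
    gmm_components: int = 5
    tile_size: int = 1000
    tile_overlap: int = 50
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    detector: BaselineParams = field(default_factory=BaselineParams)

    @property
    def fusion_params(self) -> FusionParams:
        return FusionParams(distance_threshold=self.fusion_distance)

    @property
    def continuity_params(self) -> ContinuityParams:
        return ContinuityParams(layers=self.z_layers,
                                distance_threshold=self.z_distance)

    def __post_init__(self) -> None:
        self.segmentation.grabcut_iters = self.grabcut_iters
        self.segmentation.gmm_components = self.gmm_components


#: per-modality presets: anisotropic tape-collected sections (atum),
#: isotropic milled volumes (fib), and the synthetic generator's geometry
#: (~10x smaller canvas than a full EM section, thresholds scaled to match)
PRESETS: dict[str, dict] = {
    "atum": dict(fusion_distance=100.0, z_layers=3, z_distance=200.0,
                 tile_size=1000, tile_overlap=50),
    "fib": dict(fusion_distance=50.0, z_layers=20, z_distance=100.0,
                tile_size=500, tile_overlap=50),
    "synthetic": dict(fusion_distance=100.0, z_layers=3, z_distance=80.0,
                      tile_size=512, tile_overlap=50),
}


def preset(name: str) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a named preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PipelineConfig(**PRESETS[name])


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML or YAML config whose keys mirror the dataclass fields."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        payload = tomllib.loads(path.read_text())
    else:
        payload = yaml.safe_load(path.read_text()) or {}
    base = payload.pop("preset", None)
    cfg = preset(base) if base else PipelineConfig()
    seg = payload.pop("segmentation", {})
    det = payload.pop("detector", {})
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, val in payload.items():
        setattr(cfg, key, val)
    for key, val in seg.items():
        setattr(cfg.segmentation, key, val)
    for key, val in det.items():
        setattr(cfg.detector, key, val)
    cfg.__post_init__()
    return cfg
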