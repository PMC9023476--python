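"""End-to-end pipeline configuration."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig", "GeometryConfig", "StatsConfig"]


@dataclass
class GeometryConfig:
    min_spur_px: int = 10
    quality_floor: float = 0.5
    min_length_um: float = 50.0
    contrast_floor: float = 10.0


@dataclass
class StatsConfig:
    p_enter: float = 0.05
    p_remove: float = 0.10
    classification_cut: float = 0.5
    hosmer_lemeshow_groups: int = 10


@dataclass
class PipelineConfig:
    fps: float = 60.0
    um_per_px: float = 1.0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    k_axial_to_cross: float = 1.42
    wavelet_scales_um: tuple[float, float] = (20.0, 80.0)
    min_streak_snr: float = 5.0
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        geo = GeometryConfig(**raw.pop("geometry", {}))
        st = StatsConfig(**raw.pop("stats", {}))
        raw["wavelet_scales_um"] = tuple(raw.get("wavelet_scales_um",
                                                 (20.0, 80.0)))
        return cls(geometry=geo, stats=st, **raw)
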