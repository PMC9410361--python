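"""Run configuration: YAML-serializable defaults for the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path as FsPath

import yaml

from .curves import AnalysisConfig, SmoothingConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a run needs beyond its input paths.

    Defaults: 1 s moving-average smoothing, 3-sigma / 3-sample ingress-begin
    detection, 5 s egress window, 1 px motion threshold.
    """

    smoothing_window_s: float = 1.0
    k: float = 3.0
    m: int = 3
    egress_window_s: float = 5.0
    subtract_background: bool = False
    motion_threshold_px: float = 1.0
    frame_rate_override: float | None = None
    seed: int = 0
    export_maps: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.egress_window_s <= 0:
            raise ValueError("egress window must be positive")
        if self.motion_threshold_px <= 0:
            raise ValueError("motion threshold must be positive")

    def analysis(self) -> AnalysisConfig:
        return AnalysisConfig(
            smoothing=SmoothingConfig(window_s=self.smoothing_window_s),
            k=self.k, m=self.m, egress_window_s=self.egress_window_s,
            subtract_background=self.subtract_background)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(FsPath(path).read_text()) or {}
        known = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> FsPath:
        path = FsPath(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
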