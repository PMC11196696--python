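"""Run configuration: schema-validated YAML with the study constants as defaults.

All pipeline constants live here rather than in the stage logic, so
sensitivity sweeps only touch a config file: the 0.2 s spherical
structuring element, the 0.1 s Hamming/rectangular filter radii, the
50 ms minimum peak distance, the 95th-percentile height rule, the 50 ms
rolling-maximum aggregation window, 100 Hz sampling and the 488 cm
walkway. Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .morphology import StructuringElement
from .step_detection import DetectorConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # preprocessing
    agg_window_s: float = 0.05
    # morphology
    se_radius_s: float = 0.2
    se_shape: str = "spherical"
    se_height: float = 0.2
    # detector
    min_distance_s: float = 0.05
    height_percentile: float = 95.0
    hamming_radius_s: float = 0.1
    rect_radius_s: float = 0.1
    renormalize: bool = True
    # experiment
    fs: float = 100.0
    walkway_length_cm: float = 488.0
    first_foot: str = "unknown"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def detector(self) -> DetectorConfig:
        return DetectorConfig(
            min_distance=self.min_distance_s,
            height_percentile=self.height_percentile,
            hamming_radius=self.hamming_radius_s,
            rect_radius=self.rect_radius_s,
            renormalize=self.renormalize,
        )

    def structuring_element(self) -> StructuringElement:
        return StructuringElement(
            radius=self.se_radius_s, fs=self.fs, shape=self.se_shape, height=self.se_height
        )
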