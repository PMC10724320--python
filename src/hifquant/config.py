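"""Pipeline configuration: YAML round-trip with full defaulting.

Every parameter the source protocol leaves open (few/numerous cut, granule
size boundaries, fusion window, vessel blur/h/threshold) lives here so a
sensitivity analysis is a one-line config change.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .granules import GranuleSizeThresholds
from .vessels import VesselParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    um_per_pixel: float = 0.25
    fusion_window: int = 9
    few_max: int = 4
    size_thresholds_um: tuple[float, float, float] = (1.2, 1.6, 2.2)
    count_over_range_as_large: bool = False
    vessel_sigma: float = 20.0
    vessel_h_fraction: float = 0.5
    vessel_threshold: str = "otsu"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        t = tuple(self.size_thresholds_um)
        if len(t) != 3 or not (0 < t[0] < t[1] < t[2]):
            raise ValueError("size thresholds must be three strictly increasing values")
        self.size_thresholds_um = t
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        if self.fusion_window < 3 or self.fusion_window % 2 == 0:
            raise ValueError("fusion_window must be odd and >= 3")

    @property
    def granule_thresholds(self) -> GranuleSizeThresholds:
        a, b, c = self.size_thresholds_um
        return GranuleSizeThresholds(small_min=a, small_max=b, large_max=c)

    @property
    def vessel_params(self) -> VesselParams:
        return VesselParams(
            blur_sigma=self.vessel_sigma,
            h_fraction=self.vessel_h_fraction,
            threshold_method=self.vessel_threshold,
        )

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["size_thresholds_um"] = list(d["size_thresholds_um"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "size_thresholds_um" in data:
            data["size_thresholds_um"] = tuple(data["size_thresholds_um"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
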