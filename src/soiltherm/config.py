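"""Site configuration: soil profile depths, file paths, model settings.

One YAML document per site.  Layer depths are given in centimetres (as
soil-profile tables usually are) and converted to metres at load time;
a 0 cm surface layer is coerced to 1 cm, since a zero-thickness layer has
no heat capacity to integrate over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .calibration import ParameterRanges
from .model import SimulationConfig
from .snow import SnowModelParams

__all__ = ["SiteConfig"]

LAYER_ORDER = ("top", "middle", "bottom")


@dataclass
class SiteConfig:
    site: str
    layers: dict[str, float]  # label -> depth in metres
    forcing_path: Optional[Path] = None
    observation_paths: dict[str, Path] = field(default_factory=dict)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    snow: SnowModelParams = field(default_factory=SnowModelParams)
    ranges: ParameterRanges = field(default_factory=ParameterRanges)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("site config must define at least one layer")
        depths = [self.layers[k] for k in self._ordered_labels()]
        if any(d <= 0 for d in depths):
            raise ValueError("layer depths must be positive")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError(
                "layer depths must strictly increase from top to bottom"
            )

    def _ordered_labels(self) -> list[str]:
        known = [k for k in LAYER_ORDER if k in self.layers]
        extra = [k for k in self.layers if k not in LAYER_ORDER]
        return known + extra

    def depth(self, layer: str) -> float:
        if layer not in self.layers:
            raise KeyError(
                f"unknown layer {layer!r}; configured: {sorted(self.layers)}"
            )
        return self.layers[layer]

    @classmethod
    def from_yaml(cls, path) -> "SiteConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for key in ("site", "layers"):
            if key not in doc:
                raise ValueError(f"{path}: missing required config key {key!r}")

        layers = {}
        for label, depth_cm in doc["layers"].items():
            depth_cm = float(depth_cm)
            if depth_cm == 0.0:
                depth_cm = 1.0  # surface sensors are simulated as a 1 cm layer
            layers[label] = depth_cm / 100.0

        base = path.parent

        def _resolve(p):
            return (base / p) if not Path(p).is_absolute() else Path(p)

        forcing = doc.get("forcing")
        obs = {
            label: _resolve(p)
            for label, p in (doc.get("observations") or {}).items()
        }
        sim = SimulationConfig(**(doc.get("simulation") or {}))
        snow = SnowModelParams(**(doc.get("snow") or {}))
        range_overrides = doc.get("ranges") or {}
        defaults = ParameterRanges()
        kwargs = {
            name: tuple(range_overrides[name]) if name in range_overrides
            else getattr(defaults, name)
            for name in defaults.__dataclass_fields__
        }
        unknown = set(range_overrides) - set(kwargs)
        if unknown:
            raise ValueError(f"{path}: unknown parameter range keys {sorted(unknown)}")
        return cls(
            site=str(doc["site"]),
            layers=layers,
            forcing_path=_resolve(forcing) if forcing else None,
            observation_paths=obs,
            simulation=sim,
            snow=snow,
            ranges=ParameterRanges(**kwargs),
        )
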