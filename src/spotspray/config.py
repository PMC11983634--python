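"""YAML configuration mirroring :class:`~spotspray.bench_sim.SimConfig`.

The YAML keys match the dataclass field names exactly, with the nested
``geometry``, ``response`` and ``delays`` sections mapping to their
dataclasses. Missing keys take the dataclass defaults.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from spotspray.bench_sim import SimConfig
from spotspray.hysteresis import DelayConfig
from spotspray.spray_decision import GeometryConfig, ResponseConfig

__all__ = ["load_sim_config", "dump_sim_config"]


def load_sim_config(path: str | Path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    geometry = GeometryConfig(**raw.pop("geometry", {}))
    response = ResponseConfig(**raw.pop("response", {}))
    delays = DelayConfig(**raw.pop("delays", {}))
    if "speed_interval" in raw:
        raw["speed_interval"] = tuple(raw["speed_interval"])
    return SimConfig(geometry=geometry, response=response, delays=delays, **raw)


def dump_sim_config(cfg: SimConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["speed_interval"] = list(cfg.speed_interval)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
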