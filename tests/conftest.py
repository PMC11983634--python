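import pytest

from spotspray.bench_sim import SimConfig
from spotspray.hysteresis import DelayConfig
from spotspray.scene_gen import BeltScene, ScenarioConfig, generate_scene
from spotspray.spray_decision import GeometryConfig, ResponseConfig


@pytest.fixture
def geom() -> GeometryConfig:
    return GeometryConfig()


@pytest.fixture
def resp() -> ResponseConfig:
    return ResponseConfig(d_min=0.05)


@pytest.fixture
def lead_delays() -> DelayConfig:
    return DelayConfig(comp_mode="lead")


def constant_speed_cfg(v: float, **kwargs) -> SimConfig:
    """Trial config at constant speed v with lead-mode compensation."""
    defaults = dict(
        speed_interval=(v, v),
        delays=DelayConfig(comp_mode="lead"),
        speed_law="constant",
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def two_weed_scene(gap: float, seed: int = 7, belt_length: float = 4.0) -> BeltScene:
    """Two weeds stacked in one lane with an exact travel gap."""
    cfg = ScenarioConfig(
        scenario="vertical_close",
        n_weeds=2,
        gap_range=(gap, gap),
        belt_length=belt_length,
        seed=seed,
    )
    return generate_scene(cfg)


def empty_scene(belt_length: float = 4.0) -> BeltScene:
    cfg = ScenarioConfig(scenario="single", n_weeds=1, belt_length=belt_length, seed=0)
    return BeltScene(weeds=(), config=cfg)
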