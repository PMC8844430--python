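import numpy as np
import pytest

from beevr.protocol import ProtocolConfig
from beevr.vr_world import EgoMotion, WorldConfig


@pytest.fixture
def world():
    return WorldConfig()


@pytest.fixture
def protocol():
    return ProtocolConfig()


class ImmobileAgent:
    """Never moves; every trial times out."""

    def step(self, views, rng):
        return EgoMotion()

    def reinforce(self, chosen_role):
        pass


class BeelineAgent:
    """Steers straight at one stimulus (by view-order index) at fixed speed."""

    def __init__(self, target_index=0, speed=4.0, tick=0.017):
        self.target_index = target_index
        self.speed = speed
        self.tick = tick

    def step(self, views, rng):
        az = views[self.target_index].azimuth
        return EgoMotion(forward=self.speed * self.tick, lateral=0.0, yaw=az)

    def reinforce(self, chosen_role):
        pass


@pytest.fixture
def immobile_agent():
    return ImmobileAgent()


@pytest.fixture
def beeline_agent():
    return BeelineAgent()
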