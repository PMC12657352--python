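import numpy as np
import pytest

import aortaflow as af
from aortaflow.network import AorticNetwork, VesselSegment


@pytest.fixture(scope="session")
def healthy():
    return af.build_healthy_template()


@pytest.fixture(scope="session")
def targets_p1():
    return af.brachial_to_aortic(146, 87)


@pytest.fixture(scope="session")
def waveform_p1():
    return af.scale_waveform(af.default_template(), 87)


def make_single_vessel(length=10.0, radius=0.5, outlet="BT"):
    seg = VesselSegment("S0", "a", "b", length, radius)
    return AorticNetwork(nodes={"a", "b"}, segments=[seg],
                         inlet_node="a", outlets={outlet: "b"})


def make_y(r_left=0.5, r_right=0.5, stem_radius=0.8, length=8.0):
    """Inlet stem splitting into two branches (LEIA / REIA outlets)."""
    segs = [
        VesselSegment("STEM", "in", "j", length, stem_radius),
        VesselSegment("L", "j", "lo", length, r_left),
        VesselSegment("R", "j", "ro", length, r_right),
    ]
    return AorticNetwork(nodes={"in", "j", "lo", "ro"}, segments=segs,
                         inlet_node="in",
                         outlets={"LEIA": "lo", "REIA": "ro"})


@pytest.fixture
def single_vessel():
    return make_single_vessel()


@pytest.fixture
def symmetric_y():
    return make_y()
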