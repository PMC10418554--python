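"""Shared fixtures: small networks and session-scoped synthetic subjects."""

import pytest

from pulmo1d.calibration import ScalingFactors
from pulmo1d.network import VesselSegment, build_network
from pulmo1d.solver import FluidProperties
from pulmo1d.synthetic import SubjectConfig, apply_cteph, make_baseline_subject
from pulmo1d.units import MMHG


@pytest.fixture(scope="session")
def props():
    return FluidProperties()


@pytest.fixture()
def three_vessel_net():
    """MPA bifurcating into terminal LPA/RPA."""
    return build_network(
        [
            VesselSegment(
                id="0", name="MPA", length=3.0, radius=0.55,
                children=("1", "2"), is_extralobar=True,
            ),
            VesselSegment(id="1", name="LPA", length=2.5, radius=0.42,
                          parent="0", is_extralobar=True),
            VesselSegment(id="2", name="RPA", length=2.5, radius=0.45,
                          parent="0", is_extralobar=True),
        ]
    )


@pytest.fixture()
def seven_segment_net():
    """Two-generation strict bifurcating tree (4 terminals, 3 internal)."""
    segs = [
        VesselSegment(id="a", name="MPA", length=3.0, radius=0.6,
                      children=("b", "c"), is_extralobar=True),
        VesselSegment(id="b", name="LPA", length=2.0, radius=0.45, parent="a",
                      children=("d", "e"), is_extralobar=True),
        VesselSegment(id="c", name="RPA", length=2.0, radius=0.45, parent="a",
                      children=("f", "g"), is_extralobar=True),
        VesselSegment(id="d", length=1.5, radius=0.3, parent="b"),
        VesselSegment(id="e", length=1.5, radius=0.3, parent="b"),
        VesselSegment(id="f", length=1.5, radius=0.3, parent="c"),
        VesselSegment(id="g", length=1.5, radius=0.3, parent="c"),
    ]
    return build_network(segs)


THETA_TRUE = ScalingFactors(1.5, 0.7, 1.3)


@pytest.fixture(scope="session")
def baseline_subject():
    """Noise-free default subject with a known scaling triple."""
    cfg = SubjectConfig(true_theta=THETA_TRUE, flow_noise=0.0)
    return make_baseline_subject(cfg, seed=1)


@pytest.fixture(scope="session")
def cteph_subject(baseline_subject):
    return apply_cteph(baseline_subject, severity=5.0, left_fraction=0.8, stiffening=2.0)


@pytest.fixture(scope="session")
def mmhg():
    return MMHG
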