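import pytest

from clusterdamage import ClusterGeometry, EventProbabilities, RadicalFates


@pytest.fixture(scope="session")
def geometry():
    """Default 73 bp / 10 bp geometry with the printed q0 ladder."""
    return ClusterGeometry()


@pytest.fixture(scope="session")
def constant_geometry():
    """Constant-q0 geometry (q0 = 0.6) in which the symbolic expansions hold."""
    return ClusterGeometry.constant(0.6)


@pytest.fixture(scope="session")
def fates():
    return RadicalFates()


@pytest.fixture(scope="session")
def events():
    return EventProbabilities()
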