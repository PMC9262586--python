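import pytest

from mutascope import (
    ReporterGeometry,
    build_reporter,
    default_genome,
    synthesize_reference,
)


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def reference(genome):
    return synthesize_reference(genome, seed=7)


@pytest.fixture(scope="session")
def construct():
    return build_reporter(seed=0)


@pytest.fixture(scope="session")
def construct_ori2():
    return build_reporter(ReporterGeometry(orientation="Ori2"), seed=0)
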