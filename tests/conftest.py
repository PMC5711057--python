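import numpy as np
import pytest

import mlcport as m


@pytest.fixture(scope="session")
def hd120_geom():
    return m.hd120()


@pytest.fixture(scope="session")
def mill_geom():
    return m.millennium120()


@pytest.fixture(scope="session")
def source_6x():
    return m.SourceModel.preset("6X")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
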