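import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mrseqopt.acquisition import GEOMETRY_2D, GEOMETRY_3D
from mrseqopt.tissues import catalog


@pytest.fixture(scope="session")
def tissues_pre():
    return catalog("pre")


@pytest.fixture(scope="session")
def tissues_post():
    return catalog("post")


@pytest.fixture(scope="session")
def geom_2d():
    return GEOMETRY_2D


@pytest.fixture(scope="session")
def geom_3d():
    return GEOMETRY_3D
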