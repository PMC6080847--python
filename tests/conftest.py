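import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fibralign import DirectionalityParams
from helpers import make_family_image


@pytest.fixture(scope="session")
def params() -> DirectionalityParams:
    return DirectionalityParams()


@pytest.fixture(scope="session")
def single_family_image():
    """A tight single-family fibril image at 45 degrees with its scene."""
    return make_family_image(45.0, 1e6, seed=7)
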