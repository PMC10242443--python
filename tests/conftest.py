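import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from helpers import make_l_cloud, make_straight_cloud  # noqa: E402


@pytest.fixture
def straight_cloud():
    return make_straight_cloud


@pytest.fixture
def l_cloud():
    return make_l_cloud
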